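"""Interaction scoring, reciprocal confidence and interactome clustering.

Three lines of evidence are combined:

* SILAC pulldown enrichment — per-protein heavy/light ratio, median over
  replicates, enriched when strictly above 2 (heavy = bait-expressing
  cells, light = control);
* a simplified SAINT-style posterior from spectral counts — per replicate
  a two-component Poisson likelihood ratio with background rate taken from
  control runs, averaged over replicates (AvgP style), interactor when the
  score is >= 0.7 (inclusive);
* reciprocal confidence — a factor is *high* confidence when it appears in
  the hub-bait experiments (BioID or AP-MS) *and* its own bait experiment
  finds the hub (or the cullin); *lower* when exactly one side holds.

The count-profile clustering subtracts control counts (floored at zero),
keeps preys present in at least 20 % of baits, and cuts an average-linkage
tree on 1 - Pearson correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .errors import ConfigurationError
from .io_formats import ExperimentDesign, IntensityTable, SpectralCountRecord

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionScore",
    "DcafEvidence",
    "hl_enrichment",
    "saint_like_score",
    "score_all",
    "classify_interactor",
    "reciprocal_confidence",
    "control_subtract_counts",
    "prevalence_filter",
    "correlation_cluster",
]

DEFAULT_HL_RATIO_CUT = 2.0
DEFAULT_SAINT_CUT = 0.7
DEFAULT_PREVALENCE = 0.2
DEFAULT_N_CLUSTERS = 7
LAMBDA_FLOOR = 0.1
PRIOR_TRUE = 0.5

HIGH = "high"
LOWER = "lower"
NONE = "none"


@dataclass
class InteractionScore:
    bait: str
    prey: str
    hl_ratio: float = float("nan")
    saint_like: float = float("nan")
    enriched_silac: bool = False
    enriched_saint: bool = False
    h_only: bool = False


@dataclass
class DcafEvidence:
    """Reciprocal evidence for one candidate substrate receptor."""

    dcaf: str
    found_in_ddb1_bioid: bool = False
    found_in_ddb1_apms: bool = False
    dcaf_bait_finds_ddb1: bool = False
    dcaf_bait_finds_cul4: bool = False
    confidence: str = NONE


# ---------------------------------------------------------------------------
# SILAC pulldown enrichment
# ---------------------------------------------------------------------------


def hl_enrichment(
    table: IntensityTable,
    design: ExperimentDesign,
    ratio_cut: float = DEFAULT_HL_RATIO_CUT,
) -> pd.DataFrame:
    """Per-protein heavy/light enrichment from a paired-channel table.

    Replicate ratios (computed on the linear scale from the log2 table)
    are combined by median; ``enriched`` is strict (> *ratio_cut*).
    Proteins with heavy evidence but no light signal in any replicate are
    flagged ``h_only`` and treated as enriched with a missing ratio.
    Returns a frame indexed by protein with columns ``hl_ratio``,
    ``enriched``, ``h_only``.
    """
    reps = sorted(set(design.table["replicate"]))
    pairs: list[tuple[str, str]] = []
    for rep in reps:
        h = [s for s in design.samples(channel="heavy") if rep in set(design.rows_for(s)["replicate"])]
        l = [s for s in design.samples(channel="light") if rep in set(design.rows_for(s)["replicate"])]
        h = [s for s in h if s in table.samples]
        l = [s for s in l if s in table.samples]
        if len(h) == 1 and len(l) == 1:
            pairs.append((h[0], l[0]))
    if not pairs:
        raise ConfigurationError("design yields no paired heavy/light samples")

    out = {}
    for protein in table.proteins:
        ratios = []
        any_h = False
        any_l = False
        for hs, ls in pairs:
            hv = table.values.at[protein, hs]
            lv = table.values.at[protein, ls]
            if not pd.isna(hv):
                any_h = True
            if not pd.isna(lv):
                any_l = True
            if not pd.isna(hv) and not pd.isna(lv):
                ratios.append(2.0 ** (hv - lv))
        if ratios:
            ratio = float(np.median(ratios))
            out[protein] = (ratio, ratio > ratio_cut, False)
        elif any_h and not any_l:
            out[protein] = (float("nan"), True, True)
        else:
            out[protein] = (float("nan"), False, False)
    df = pd.DataFrame.from_dict(out, orient="index", columns=["hl_ratio", "enriched", "h_only"])
    df.index.name = "protein"
    return df


# ---------------------------------------------------------------------------
# SAINT-style scoring
# ---------------------------------------------------------------------------


def _control_runs(counts: list[SpectralCountRecord]) -> list[tuple[str, int]]:
    return sorted({(r.bait, r.replicate) for r in counts if r.is_control})


def _bait_runs(counts: list[SpectralCountRecord], bait: str) -> list[int]:
    return sorted({r.replicate for r in counts if r.bait == bait and not r.is_control})


def saint_like_score(
    counts: list[SpectralCountRecord],
    bait: str,
    prey: str,
    prior_true: float = PRIOR_TRUE,
    lambda_floor: float = LAMBDA_FLOOR,
) -> float:
    """Averaged posterior probability that (bait, prey) is a true interaction.

    Background rate = mean count of the prey over control runs (floored);
    true rate = mean bait count for the prey, floored at background + 0.1.
    Per replicate the posterior combines the two Poisson likelihoods with a
    flat prior; the score is the replicate mean (AvgP style).
    """
    controls = _control_runs(counts)
    if not controls:
        raise ConfigurationError("SAINT-style scoring requires control runs")
    reps = _bait_runs(counts, bait)
    if not reps:
        raise ConfigurationError(f"no replicate runs found for bait {bait!r}")

    ctl_counts = {(r.bait, r.replicate): r.count
                  for r in counts if r.is_control and r.prey == prey}
    bait_counts = {r.replicate: r.count
                   for r in counts if r.bait == bait and not r.is_control and r.prey == prey}
    x_ctl = np.array([ctl_counts.get(run, 0) for run in controls], dtype=float)
    x = np.array([bait_counts.get(rep, 0) for rep in reps], dtype=float)

    lam_f = max(float(x_ctl.mean()), lambda_floor)
    lam_t = max(float(x.mean()), lam_f + 0.1)

    f_t = stats.poisson.pmf(x, lam_t)
    f_f = stats.poisson.pmf(x, lam_f)
    post = prior_true * f_t / (prior_true * f_t + (1.0 - prior_true) * f_f)
    return float(np.mean(post))


def classify_interactor(score: float, cut: float = DEFAULT_SAINT_CUT) -> bool:
    """Interactor when the score reaches the cut (inclusive boundary)."""
    if not (0.0 <= score <= 1.0):
        raise ConfigurationError("score must lie in [0, 1]")
    return bool(score >= cut)


def score_all(
    counts: list[SpectralCountRecord],
    saint_cut: float = DEFAULT_SAINT_CUT,
) -> list[InteractionScore]:
    """Score every (bait, prey) pair appearing in the bait runs."""
    pairs = sorted({(r.bait, r.prey) for r in counts if not r.is_control})
    scores = []
    for bait, prey in pairs:
        s = saint_like_score(counts, bait, prey)
        scores.append(
            InteractionScore(
                bait=bait,
                prey=prey,
                saint_like=s,
                enriched_saint=classify_interactor(s, saint_cut),
            )
        )
    return scores


# ---------------------------------------------------------------------------
# reciprocal confidence
# ---------------------------------------------------------------------------


def reciprocal_confidence(evidence: list[DcafEvidence]) -> list[DcafEvidence]:
    """Assign high / lower / none confidence from the two evidence sides."""
    for ev in evidence:
        hub_side = ev.found_in_ddb1_bioid or ev.found_in_ddb1_apms
        bait_side = ev.dcaf_bait_finds_ddb1 or ev.dcaf_bait_finds_cul4
        if hub_side and bait_side:
            ev.confidence = HIGH
        elif hub_side or bait_side:
            ev.confidence = LOWER
        else:
            ev.confidence = NONE
    return evidence


# ---------------------------------------------------------------------------
# count-profile clustering
# ---------------------------------------------------------------------------


def control_subtract_counts(counts: list[SpectralCountRecord]) -> pd.DataFrame:
    """Bait x prey matrix of mean bait counts minus mean control counts,
    floored at zero.  Runs missing a (bait, prey) record contribute 0."""
    controls = _control_runs(counts)
    baits = sorted({r.bait for r in counts if not r.is_control})
    preys = sorted({r.prey for r in counts})
    if not baits:
        raise ConfigurationError("no bait runs present")

    bait_reps = {b: _bait_runs(counts, b) for b in baits}
    sums = {(b, p): 0.0 for b in baits for p in preys}
    for r in counts:
        if not r.is_control:
            sums[(r.bait, r.prey)] = sums.get((r.bait, r.prey), 0.0) + r.count
    ctl_sums = {p: 0.0 for p in preys}
    for r in counts:
        if r.is_control:
            ctl_sums[r.prey] += r.count
    n_ctl = len(controls)
    data = np.zeros((len(baits), len(preys)))
    for i, b in enumerate(baits):
        n_rep = len(bait_reps[b])
        for j, p in enumerate(preys):
            bait_mean = sums[(b, p)] / n_rep
            ctl_mean = (ctl_sums[p] / n_ctl) if n_ctl else 0.0
            data[i, j] = max(bait_mean - ctl_mean, 0.0)
    return pd.DataFrame(data, index=baits, columns=preys)


def prevalence_filter(
    matrix: pd.DataFrame, min_fraction: float = DEFAULT_PREVALENCE
) -> pd.DataFrame:
    """Keep preys with a positive value in at least
    ``ceil(min_fraction * n_baits)`` baits."""
    if not (0.0 < min_fraction <= 1.0):
        raise ConfigurationError("min_fraction must lie in (0, 1]")
    threshold = math.ceil(min_fraction * matrix.shape[0])
    keep = [(matrix[c] > 0).sum() >= threshold for c in matrix.columns]
    return matrix.loc[:, keep]


def correlation_cluster(
    matrix: pd.DataFrame, n_clusters: int = DEFAULT_N_CLUSTERS
) -> tuple[dict[str, int], pd.DataFrame]:
    """Cluster prey count-profiles across baits.

    Pearson correlation between prey columns; average-linkage agglomerative
    clustering on distance ``1 - r`` cut to *n_clusters*.  Constant-profile
    preys correlate 0 with everything (and are logged).
    Returns (prey -> cluster label, prey x prey correlation matrix).
    """
    if matrix.shape[1] < 2:
        raise ConfigurationError("need at least 2 preys to cluster")
    if matrix.shape[0] < 3:
        raise ConfigurationError("need at least 3 baits to correlate profiles")
    if n_clusters < 1 or n_clusters > matrix.shape[1]:
        raise ConfigurationError("n_clusters out of range")
    profiles = matrix.to_numpy(dtype=float)
    sd = profiles.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant prey profile(s) assigned zero correlation: %s",
            int(constant.sum()),
            list(matrix.columns[constant])[:5],
        )
    n = matrix.shape[1]
    corr = np.zeros((n, n))
    ok = ~constant
    if ok.sum() >= 2:
        corr_ok = np.corrcoef(profiles[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = corr_ok
    np.fill_diagonal(corr, 1.0)
    corr_df = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)

    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    model = AgglomerativeClustering(
        n_clusters=n_clusters, metric="precomputed", linkage="average"
    )
    labels = model.fit_predict(dist)
    return dict(zip(matrix.columns, (int(x) for x in labels))), corr_df
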