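"""Filtering, missing-value taxonomy, normalization and imputation.

The chain mirrors a standard SILAC differential-abundance workflow:

1. drop contaminant / reverse / site-only groups and those with fewer than
   two unique peptides (inclusive: exactly two is retained);
2. classify each protein x condition block as complete, partially observed
   (POV) or missing in the entire condition (MEC);
3. discard proteins whose POV count exceeds the per-design allowance
   (1 when N = 4, none when N = 2, ``floor(N/4)`` otherwise — MECs are
   always allowed);
4. median-normalize each sample to the grand median of sample medians;
5. impute POVs with an additive protein + sample least-squares fit and
   MECs with a deterministic low-quantile (1 %) per-sample value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError
from .io_formats import ExperimentDesign, IntensityTable, ProteinGroupRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MissingnessLabel",
    "MissingnessMap",
    "filter_protein_groups",
    "build_intensity_table",
    "condition_groups",
    "classify_missing",
    "filter_missing",
    "median_normalize",
    "impute_detquantile",
    "impute_slsa",
    "preprocess_table",
]

COMPLETE = "complete"
POV = "pov"
MEC = "mec"

# Rejection rules, applied in this order; the first match names the reason.
_FILTER_RULES = (
    ("contaminant", lambda r: r.contaminant_flag),
    ("reverse", lambda r: r.reverse_flag),
    ("only identified by site", lambda r: r.site_only_flag),
    ("min unique peptides", lambda r: r.unique_peptides < 2),
)


@dataclass(frozen=True)
class MissingnessLabel:
    """Status of one protein x condition block."""

    status: str  # complete | pov | mec
    n_missing: int
    n_replicates: int


@dataclass
class MissingnessMap:
    """Per-protein, per-condition missingness labels plus the condition ->
    sample grouping they were computed under."""

    condition_samples: dict[str, list[str]]
    labels: dict[str, dict[str, MissingnessLabel]] = field(default_factory=dict)

    def label(self, protein: str, condition: str) -> MissingnessLabel:
        return self.labels[protein][condition]

    @property
    def conditions(self) -> list[str]:
        return list(self.condition_samples)


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def filter_protein_groups(
    records: list[ProteinGroupRecord],
) -> tuple[list[ProteinGroupRecord], list[tuple[str, str]]]:
    """Apply the QC filter; returns (kept, rejection log).

    The log carries ``(protein_id, reason)`` with the first matching rule
    in the fixed rule order, so it is deterministic.
    """
    kept: list[ProteinGroupRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        for reason, hit in _FILTER_RULES:
            if hit(rec):
                rejected.append((rec.protein_id, reason))
                break
        else:
            kept.append(rec)
    return kept, rejected


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------


def build_intensity_table(
    records: list[ProteinGroupRecord],
    design: ExperimentDesign,
    channel: str,
) -> IntensityTable:
    """log2 protein x sample matrix for one channel, in design order."""
    samples = design.samples(channel=channel)
    if not samples:
        raise ConfigurationError(f"design has no samples for channel {channel!r}")
    rows = {}
    for rec in records:
        vals = rec.intensities(channel)
        rows[rec.protein_id] = [
            math.log2(vals[s]) if (s in vals and not math.isnan(vals[s])) else math.nan
            for s in samples
        ]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return IntensityTable(values=values, provenance=f"channel={channel}")


def condition_groups(
    design: ExperimentDesign,
    table: IntensityTable,
    by_timepoint: bool = False,
) -> dict[str, list[str]]:
    """Condition -> sample grouping restricted to the table's samples.

    With ``by_timepoint`` the grouping key becomes ``condition@t`` so the
    same machinery drives within-condition timepoint contrasts.
    """
    present = set(table.samples)
    groups: dict[str, list[str]] = {}
    for _, row in design.table.iterrows():
        sid = row["sample_id"]
        if sid not in present:
            continue
        key = (
            f"{row['condition']}@{row['timepoint_h']:g}h" if by_timepoint else row["condition"]
        )
        groups.setdefault(key, [])
        if sid not in groups[key]:
            groups[key].append(sid)
    return groups


# ---------------------------------------------------------------------------
# missingness taxonomy
# ---------------------------------------------------------------------------


def classify_missing(
    table: IntensityTable,
    design: ExperimentDesign | dict[str, list[str]],
) -> MissingnessMap:
    """Label each protein x condition block as complete / POV / MEC."""
    if isinstance(design, ExperimentDesign):
        groups = condition_groups(design, table)
    else:
        groups = {c: list(s) for c, s in design.items()}
    if not groups:
        raise ConfigurationError("no conditions overlap the intensity table")
    for cond, samples in groups.items():
        unknown = set(samples) - set(table.samples)
        if unknown:
            raise ConfigurationError(
                f"condition {cond!r} references samples absent from the table: {sorted(unknown)}"
            )
    mmap = MissingnessMap(condition_samples=groups)
    for cond, samples in groups.items():
        sub = table.values[samples]
        n_missing = sub.isna().sum(axis=1)
        n = len(samples)
        for protein, miss in n_missing.items():
            miss = int(miss)
            if miss == 0:
                lab = MissingnessLabel(COMPLETE, 0, n)
            elif miss == n:
                lab = MissingnessLabel(MEC, miss, n)
            else:
                lab = MissingnessLabel(POV, miss, n)
            mmap.labels.setdefault(protein, {})[cond] = lab
    return mmap


def max_pov_allowed(n_replicates: int) -> int:
    """POV allowance: 1 when N = 4, 0 when N = 2, ``floor(N/4)`` otherwise."""
    if n_replicates == 4:
        return 1
    if n_replicates == 2:
        return 0
    return n_replicates // 4


def filter_missing(table: IntensityTable, labels: MissingnessMap) -> IntensityTable:
    """Retain proteins whose every condition is complete, MEC, or a POV
    within the allowance for that condition's replicate count."""
    keep = []
    for protein in table.proteins:
        ok = True
        for cond in labels.conditions:
            lab = labels.label(protein, cond)
            if lab.status == POV and lab.n_missing > max_pov_allowed(lab.n_replicates):
                ok = False
                break
        if ok:
            keep.append(protein)
    out = table.copy()
    out.values = out.values.loc[keep]
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def median_normalize(table: IntensityTable) -> IntensityTable:
    """Shift every sample so its observed median equals the grand median of
    pre-normalization sample medians.  Missing entries are untouched."""
    out = table.copy()
    medians = out.values.median(axis=0, skipna=True)
    empty = medians.index[medians.isna()]
    if len(empty):
        raise NumericalError(f"sample {empty[0]!r} has no observed values")
    grand = float(np.median(medians.to_numpy()))
    out.values = out.values + (grand - medians)
    return out


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_detquantile(
    table: IntensityTable,
    labels: MissingnessMap,
    quantile: float = 0.01,
    scope: str = "mec",
) -> IntensityTable:
    """Deterministic low-quantile imputation.

    ``scope='mec'`` touches only missing cells inside MEC conditions;
    ``scope='all'`` replaces every missing cell (the minimum-value mode
    used for label-free validation contrasts).  The imputed value is the
    per-sample *quantile* of that sample's observed values, with linear
    interpolation between order statistics.
    """
    if not (0.0 < quantile < 0.5):
        raise ConfigurationError("quantile must lie in (0, 0.5)")
    if scope not in ("mec", "all"):
        raise ConfigurationError("scope must be 'mec' or 'all'")
    out = table.copy()
    fills: dict[str, float] = {}
    for sample in out.samples:
        observed = out.values[sample].dropna()
        if len(observed) >= 2:
            fills[sample] = float(np.quantile(observed.to_numpy(), quantile))

    for cond in labels.conditions:
        samples = labels.condition_samples[cond]
        for protein in out.proteins:
            lab = labels.label(protein, cond)
            if scope == "mec" and lab.status != MEC:
                continue
            for s in samples:
                if pd.isna(out.values.at[protein, s]):
                    if s not in fills:
                        raise NumericalError(
                            f"sample {s!r} has fewer than 2 observed values; "
                            "cannot compute its imputation quantile"
                        )
                    out.values.at[protein, s] = fills[s]
    return out


def impute_slsa(table: IntensityTable, labels: MissingnessMap) -> IntensityTable:
    """Impute POV cells with an additive two-way fit ``x(p, s) = a_p + b_s``.

    Per condition, the sample offsets ``b_s`` are the least-squares column
    effects estimated from proteins fully observed in that condition
    (row-centered column means); the protein level ``a_p`` is the mean of
    the protein's observed, offset-corrected values.  When a condition has
    no fully observed anchor proteins the offsets fall back to zero and a
    warning is logged.  Observed values are never modified.
    """
    out = table.copy()
    for cond in labels.conditions:
        samples = labels.condition_samples[cond]
        sub = out.values[samples]
        pov_proteins = [
            p for p in out.proteins if labels.label(p, cond).status == POV
        ]
        if not pov_proteins:
            continue
        anchors = sub.dropna(axis=0, how="any")
        if len(anchors):
            b = (anchors - anchors.mean(axis=1).to_numpy()[:, None]).mean(axis=0)
        else:
            logger.warning(
                "condition %r has no fully observed proteins; "
                "SLSA falls back to protein means", cond,
            )
            b = pd.Series(0.0, index=samples)
        for protein in pov_proteins:
            row = sub.loc[protein]
            observed = row.dropna()
            a_p = float((observed - b[observed.index]).mean())
            for s in samples:
                if pd.isna(out.values.at[protein, s]):
                    out.values.at[protein, s] = a_p + float(b[s])
    return out


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def preprocess_table(
    records: list[ProteinGroupRecord],
    design: ExperimentDesign | dict[str, list[str]],
    channel: str = "light",
    det_quantile: float = 0.01,
    groups: dict[str, list[str]] | None = None,
) -> tuple[IntensityTable, list[tuple[str, str]], MissingnessMap]:
    """Run filter -> classify -> missingness filter -> normalize -> impute.

    Returns the fully imputed table, the QC rejection log and the
    missingness labels of the retained proteins.  ``groups`` overrides the
    condition grouping (e.g. for timepoint contrasts).
    """
    kept, rejected = filter_protein_groups(records)
    if isinstance(design, ExperimentDesign):
        table = build_intensity_table(kept, design, channel)
    else:
        raise ConfigurationError("design must be an ExperimentDesign")
    grouping: ExperimentDesign | dict[str, list[str]] = groups if groups is not None else design
    if groups is not None:
        wanted = [s for ss in groups.values() for s in ss]
        table.values = table.values[wanted]
    labels = classify_missing(table, grouping)
    table = filter_missing(table, labels)
    labels = classify_missing(table, grouping if groups is not None else design)
    table = median_normalize(table)
    table = impute_slsa(table, labels)
    table = impute_detquantile(table, labels, quantile=det_quantile, scope="mec")
    return table, rejected, labels
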