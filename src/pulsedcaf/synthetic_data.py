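"""Ground-truth simulators for pulse-SILAC intensity tables and BioID counts.

The labeling model is a one-compartment, steady-state, first-order turnover
model with a constant amino-acid recycling fraction ``rho``::

    L(t) = P0 * exp(-k t) + rho * P0 * (1 - exp(-k t))
    H(t) = (1 - rho) * P0 * (1 - exp(-k t))

so that ``L + H == P0`` at every timepoint.  Substrate proteins use a
degradation rate ``k * f`` (``f > 1``) in the bait condition only, active
for the whole heavy phase.  Observed values carry multiplicative log-normal
noise and intensity-dependent (MNAR-logistic) dropout, which produces the
partially-observed / missing-entire-condition structure the preprocessing
stage expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .io_formats import (
    ExperimentDesign,
    ProteinGroupRecord,
    SpectralCountRecord,
    write_results_table,
)

__all__ = [
    "TurnoverParams",
    "TurnoverTruth",
    "kinetics_closed_form",
    "simulate_pulse_experiment",
    "simulate_null_pair",
    "simulate_bioid_counts",
]


# ---------------------------------------------------------------------------
# parameters and truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class TurnoverParams:
    """Per-protein turnover parameters plus noise/missingness settings.

    ``synthesis_rate`` and ``degradation_rate_k`` are arrays of length
    ``n_proteins`` (scalars broadcast); steady-state abundance is
    ``P0 = synthesis_rate / degradation_rate_k``.
    """

    n_proteins: int
    seed: int
    synthesis_rate: np.ndarray = field(default_factory=lambda: np.array([]))
    degradation_rate_k: np.ndarray = field(default_factory=lambda: np.array([]))
    recycling_fraction_rho: float = 0.02
    substrate_ids: frozenset[str] = frozenset()
    degradation_fold_f: float = 4.0
    noise_sd_log2: float = 0.3
    missing_logistic_midpoint_tau: float = 10.5
    missing_logistic_slope_s: float = 2.0
    missingness_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be positive")
        self.synthesis_rate = np.broadcast_to(
            np.asarray(self.synthesis_rate, dtype=float), (self.n_proteins,)
        ).copy()
        self.degradation_rate_k = np.broadcast_to(
            np.asarray(self.degradation_rate_k, dtype=float), (self.n_proteins,)
        ).copy()
        if (self.synthesis_rate <= 0).any():
            raise ConfigurationError("synthesis rates must be strictly positive")
        if (self.degradation_rate_k <= 0).any():
            raise ConfigurationError("degradation rates must be strictly positive")
        if not (0.0 <= self.recycling_fraction_rho < 1.0):
            raise ConfigurationError("recycling_fraction_rho must lie in [0, 1)")
        if self.degradation_fold_f <= 1.0:
            raise ConfigurationError("degradation_fold_f must exceed 1")
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be >= 0")
        if self.missing_logistic_slope_s <= 0:
            raise ConfigurationError("missing_logistic_slope_s must be > 0")
        self.substrate_ids = frozenset(self.substrate_ids)
        unknown = self.substrate_ids - set(self.protein_ids)
        if unknown:
            raise ConfigurationError(f"substrate_ids outside protein set: {sorted(unknown)[:3]}")

    @property
    def protein_ids(self) -> list[str]:
        return [f"P{i + 1:05d}" for i in range(self.n_proteins)]

    @property
    def steady_state_abundance(self) -> np.ndarray:
        return self.synthesis_rate / self.degradation_rate_k

    @classmethod
    def random(
        cls,
        n_proteins: int,
        n_substrates: int,
        seed: int,
        *,
        log2_p0_mean: float = 20.0,
        log2_p0_sd: float = 3.0,
        half_life_h_mean: float = 12.0,
        half_life_log_sd: float = 0.25,
        **kwargs,
    ) -> "TurnoverParams":
        """Draw a heterogeneous parameter set with the first ``n_substrates``
        proteins (after shuffling) marked as substrates."""
        rng = np.random.default_rng(seed)
        p0 = 2.0 ** rng.normal(log2_p0_mean, log2_p0_sd, n_proteins)
        half_life = half_life_h_mean * np.exp(rng.normal(0.0, half_life_log_sd, n_proteins))
        k = np.log(2.0) / half_life
        ids = [f"P{i + 1:05d}" for i in range(n_proteins)]
        substrates = frozenset(str(s) for s in rng.choice(ids, size=n_substrates, replace=False))
        return cls(
            n_proteins=n_proteins,
            seed=seed,
            synthesis_rate=p0 * k,
            degradation_rate_k=k,
            substrate_ids=substrates,
            **kwargs,
        )

    # -- config file round trip ------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_proteins": self.n_proteins,
            "seed": self.seed,
            "synthesis_rate": self.synthesis_rate.tolist(),
            "degradation_rate_k": self.degradation_rate_k.tolist(),
            "recycling_fraction_rho": self.recycling_fraction_rho,
            "substrate_ids": sorted(str(s) for s in self.substrate_ids),
            "degradation_fold_f": self.degradation_fold_f,
            "noise_sd_log2": self.noise_sd_log2,
            "missing_logistic_midpoint_tau": self.missing_logistic_midpoint_tau,
            "missing_logistic_slope_s": self.missing_logistic_slope_s,
            "missingness_enabled": self.missingness_enabled,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TurnoverParams":
        doc = yaml.safe_load(Path(path).read_text())
        if "seed" not in doc:
            raise ConfigurationError("simulation config must declare a seed")
        doc["substrate_ids"] = frozenset(doc.get("substrate_ids", ()))
        return cls(**doc)


@dataclass
class TurnoverTruth:
    """Noise-free bookkeeping for a simulated pulse experiment."""

    protein_ids: list[str]
    is_substrate: np.ndarray
    k_control: np.ndarray
    k_bait: np.ndarray
    #: (condition, timepoint_h) -> (light, heavy) expected intensity arrays
    expected: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]]

    def expected_intensity(self, condition: str, timepoint_h: float, channel: str) -> np.ndarray:
        light, heavy = self.expected[(condition, float(timepoint_h))]
        return light if channel == "light" else heavy

    def substrate_set(self) -> frozenset[str]:
        return frozenset(np.asarray(self.protein_ids)[self.is_substrate])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": self.protein_ids,
                "k_control": self.k_control,
                "k_bait": self.k_bait,
                "is_substrate": self.is_substrate,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        write_results_table(self.to_frame(), path)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def kinetics_closed_form(
    P0: float | np.ndarray,
    k: float | np.ndarray,
    rho: float,
    t: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Light/heavy intensities at time ``t`` after the medium switch.

    Returns ``(L, H)`` with ``L + H == P0`` exactly (up to floating point).
    """
    P0 = np.asarray(P0, dtype=float)
    k = np.asarray(k, dtype=float)
    if (P0 <= 0).any():
        raise ConfigurationError("P0 must be strictly positive")
    if (k <= 0).any():
        raise ConfigurationError("k must be strictly positive")
    if not (0.0 <= rho < 1.0):
        raise ConfigurationError("rho must lie in [0, 1)")
    if t < 0:
        raise ConfigurationError("t must be non-negative")
    decayed = np.exp(-k * t)
    turned_over = P0 * (1.0 - decayed)
    light = P0 * decayed + rho * turned_over
    heavy = (1.0 - rho) * turned_over
    return light, heavy


# ---------------------------------------------------------------------------
# pulse-SILAC simulator
# ---------------------------------------------------------------------------


def _simulate_intensity_records(
    params: TurnoverParams,
    design: ExperimentDesign,
    boosted_conditions: frozenset[str],
    rng: np.random.Generator,
) -> tuple[list[ProteinGroupRecord], TurnoverTruth]:
    """Shared engine: per design row draw noisy, MNAR-censored intensities."""
    ids = params.protein_ids
    p0 = params.steady_state_abundance
    k = params.degradation_rate_k
    is_sub = np.array([pid in params.substrate_ids for pid in ids])
    rho = params.recycling_fraction_rho

    k_bait = np.where(is_sub, k * params.degradation_fold_f, k)

    records = [
        ProteinGroupRecord(protein_ids=(pid,), gene_name=pid, unique_peptides=2)
        for pid in ids
    ]

    expected: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]] = {}
    rows = design.table[design.table["channel"].isin(["light", "heavy"])]
    for _, row in rows.iterrows():
        cond = row["condition"]
        t = float(row["timepoint_h"])
        k_eff = k_bait if cond in boosted_conditions else k
        key = (cond, t)
        if key not in expected:
            expected[key] = kinetics_closed_form(p0, k_eff, rho, t)
        light, heavy = expected[key]
        noiseless = light if row["channel"] == "light" else heavy

        # Draw full vectors unconditionally so the rng stream is stable.
        noise = rng.normal(0.0, 1.0, params.n_proteins) * params.noise_sd_log2
        dropout_u = rng.uniform(size=params.n_proteins)

        log2_exp = np.full(params.n_proteins, -np.inf)
        np.log2(noiseless, out=log2_exp, where=noiseless > 0)
        log2_obs = log2_exp + noise
        observed = np.where(np.isfinite(log2_obs), 2.0 ** log2_obs, np.nan)
        if params.missingness_enabled:
            p_miss = 1.0 / (
                1.0
                + np.exp(
                    params.missing_logistic_slope_s
                    * (log2_obs - params.missing_logistic_midpoint_tau)
                )
            )
            observed = np.where(dropout_u < p_miss, np.nan, observed)
        for rec, v in zip(records, observed):
            rec.intensities(row["channel"])[row["sample_id"]] = float(v)

    truth = TurnoverTruth(
        protein_ids=ids,
        is_substrate=is_sub,
        k_control=k.copy(),
        k_bait=k_bait,
        expected=expected,
    )
    return records, truth


def simulate_pulse_experiment(
    params: TurnoverParams, design: ExperimentDesign
) -> tuple[list[ProteinGroupRecord], TurnoverTruth]:
    """Simulate one pulse-labeling screen (bait vs control cell line).

    Conditions with role ``test`` get the substrate rate boost; the design
    must declare at least one ``reference`` (control cell line) condition.
    Fully deterministic for a given (params, design) pair.
    """
    baits = design.conditions_with_role("test")
    controls = design.conditions_with_role("reference")
    if not controls:
        raise ConfigurationError("design must declare a reference (control) condition")
    if not baits:
        raise ConfigurationError("design must declare a test (bait) condition")
    rng = np.random.default_rng(params.seed)
    return _simulate_intensity_records(params, design, frozenset(baits), rng)


def simulate_null_pair(
    params: TurnoverParams, design: ExperimentDesign
) -> list[ProteinGroupRecord]:
    """Simulate the two-control null experiment (no substrate effect anywhere).

    Both conditions are drawn from identical distributions; only noise and
    missingness differ between them.
    """
    null_conditions = design.conditions_with_role("null_a") + design.conditions_with_role("null_b")
    if len(null_conditions) < 2:
        raise ConfigurationError("null design must declare null_a and null_b conditions")
    rng = np.random.default_rng(params.seed)
    records, _ = _simulate_intensity_records(params, design, frozenset(), rng)
    return records


def pulse_design(
    bait: str,
    control: str,
    timepoints_h: Sequence[float] = (16.0,),
    n_replicates: int = 4,
    channels: Sequence[str] = ("light", "heavy"),
    roles: dict[str, str] | None = None,
) -> ExperimentDesign:
    """Convenience builder for a bait-vs-control pulse design.

    One sample id per (condition, replicate, timepoint) run, shared across
    channels — a single MS run quantifies both SILAC channels.
    """
    roles = roles or {bait: "test", control: "reference"}
    rows = []
    for cond in (bait, control):
        for t in timepoints_h:
            for rep in range(1, n_replicates + 1):
                sid = f"{cond}_t{t:g}_r{rep}"
                for ch in channels:
                    rows.append(
                        {
                            "sample_id": sid,
                            "condition": cond,
                            "replicate": rep,
                            "timepoint_h": t,
                            "channel": ch,
                            "role": roles[cond],
                        }
                    )
    return ExperimentDesign(pd.DataFrame(rows))


def null_design(
    line_a: str = "BirA1",
    line_b: str = "BirA2",
    timepoints_h: Sequence[float] = (16.0,),
    n_replicates: int = 4,
) -> ExperimentDesign:
    return pulse_design(
        line_a,
        line_b,
        timepoints_h,
        n_replicates,
        roles={line_a: "null_a", line_b: "null_b"},
    )


# ---------------------------------------------------------------------------
# BioID spectral-count simulator
# ---------------------------------------------------------------------------


def simulate_bioid_counts(
    n_preys: int,
    true_pairs: Iterable[tuple[str, str]],
    lambda_true: float,
    lambda_bg: float,
    n_reps: int,
    n_controls: int,
    seed: int,
    baits: Sequence[str] | None = None,
    control_label: str = "control",
) -> list[SpectralCountRecord]:
    """Poisson two-component spectral counts with known true interactions.

    True bait-prey pairs draw from ``Poisson(lambda_true)``; every other
    bait run and every control run draws from ``Poisson(lambda_bg)``.
    Prey ids are ``prey0001 .. preyNNNN``; true pairs must reference them.
    """
    if lambda_true <= lambda_bg:
        raise ConfigurationError("lambda_true must exceed lambda_bg (model unidentifiable)")
    if lambda_bg <= 0:
        raise ConfigurationError("lambda_bg must be strictly positive")
    if n_preys < 1 or n_reps < 1 or n_controls < 1:
        raise ConfigurationError("n_preys, n_reps and n_controls must be positive")
    preys = [f"prey{i + 1:04d}" for i in range(n_preys)]
    prey_set = set(preys)
    true_pairs = set(true_pairs)
    for b, p in true_pairs:
        if p not in prey_set:
            raise ConfigurationError(f"true pair references unknown prey {p!r}")
    if baits is None:
        baits = sorted({b for b, _ in true_pairs})
    if not baits:
        raise ConfigurationError("no baits declared")

    rng = np.random.default_rng(seed)
    records: list[SpectralCountRecord] = []
    for bait in baits:
        lam = np.array([lambda_true if (bait, p) in true_pairs else lambda_bg for p in preys])
        for rep in range(1, n_reps + 1):
            counts = rng.poisson(lam)
            records.extend(
                SpectralCountRecord(bait=bait, prey=p, replicate=rep, count=int(c))
                for p, c in zip(preys, counts)
            )
    for rep in range(1, n_controls + 1):
        counts = rng.poisson(lambda_bg, size=n_preys)
        records.extend(
            SpectralCountRecord(
                bait=control_label, prey=p, replicate=rep, count=int(c), is_control=True
            )
            for p, c in zip(preys, counts)
        )
    return records
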