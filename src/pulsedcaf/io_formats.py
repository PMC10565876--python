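"""Readers and writers for every external table the pipeline touches.

Supported dialects
------------------
* MaxQuant-style ``proteinGroups.txt`` (tab-separated, one row per protein
  group, per-sample intensity columns such as ``Intensity L <sample>``).
  Column names are resolved through a configurable template map so other
  MaxQuant versions can be adapted without code changes.
* A sample design table (TSV: ``sample_id, condition, replicate,
  timepoint_h, channel, role``).
* Bait-prey spectral-count tables (TSV: ``bait, prey, replicate, count,
  is_control``).
* Generic result tables, written with a fixed 17-significant-digit float
  format and the literal ``NA`` as missing marker so that a write/read
  round trip is the identity on values.

Raw intensity ``0`` is converted to missing at ingestion (MaxQuant writes
zeros for absent quantifications); downstream code never branches on zeros.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ParseError

MISSING = float("nan")
NA_TOKEN = "NA"

CHANNELS = ("light", "heavy", "lfq")
ROLES = ("test", "reference", "null_a", "null_b")

#: proteinGroups column templates, ``{sample}`` replaced by the sample id.
DEFAULT_COLUMN_TEMPLATES: dict[str, str] = {
    "light": "Intensity L {sample}",
    "heavy": "Intensity H {sample}",
    "lfq": "LFQ intensity {sample}",
    "msms": "MS/MS count {sample}",
}

#: Fixed (non per-sample) proteinGroups columns.
BASE_COLUMNS: dict[str, str] = {
    "protein_ids": "Majority protein IDs",
    "gene_name": "Gene names",
    "unique_peptides": "Unique peptides",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "site_only": "Only identified by site",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ProteinGroupRecord:
    """One row of a proteinGroups table after ingestion.

    Intensities are stored per sample id on the raw (linear) scale with
    ``nan`` as the missing marker; zeros never survive ingestion.
    """

    protein_ids: tuple[str, ...]
    gene_name: str = ""
    unique_peptides: int = 0
    reverse_flag: bool = False
    contaminant_flag: bool = False
    site_only_flag: bool = False
    intensity_light: dict[str, float] = field(default_factory=dict)
    intensity_heavy: dict[str, float] = field(default_factory=dict)
    lfq_intensity: dict[str, float] = field(default_factory=dict)
    msms_count: dict[str, float] = field(default_factory=dict)

    @property
    def protein_id(self) -> str:
        """Identity key: first accession of the majority-protein list."""
        return self.protein_ids[0]

    def intensities(self, channel: str) -> dict[str, float]:
        if channel == "light":
            return self.intensity_light
        if channel == "heavy":
            return self.intensity_heavy
        if channel == "lfq":
            return self.lfq_intensity
        raise ConfigurationError(f"unknown channel {channel!r}")


@dataclass
class SpectralCountRecord:
    """One bait-prey-replicate MS/MS count, with matched-control flag."""

    bait: str
    prey: str
    replicate: int
    count: int
    is_control: bool = False


@dataclass
class ExperimentDesign:
    """Sample -> (condition, replicate, timepoint, channel, role) mapping.

    Each ``(condition, replicate, channel, timepoint_h)`` combination maps
    to exactly one ``sample_id``; the same sample id may carry several
    channels (one MS run quantifies both SILAC channels).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "replicate", "timepoint_h", "channel", "role")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table lacks column(s): {', '.join(missing)}")
        t = self.table.copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["condition"] = t["condition"].astype(str)
        t["replicate"] = t["replicate"].astype(int)
        t["timepoint_h"] = t["timepoint_h"].astype(float)
        t["channel"] = t["channel"].astype(str)
        t["role"] = t["role"].astype(str)
        bad = set(t["channel"]) - set(CHANNELS)
        if bad:
            raise ConfigurationError(f"unknown channel value(s): {sorted(bad)}")
        bad = set(t["role"]) - set(ROLES)
        if bad:
            raise ConfigurationError(f"unknown role value(s): {sorted(bad)}")
        if (t["replicate"] < 1).any():
            raise ConfigurationError("replicate indices must be positive")
        if (t["timepoint_h"] < 0).any():
            raise ConfigurationError("timepoint_h must be non-negative")
        key = ["condition", "replicate", "channel", "timepoint_h"]
        dup = t.duplicated(subset=key)
        if dup.any():
            first = t.loc[dup, key].iloc[0].tolist()
            raise ConfigurationError(
                f"duplicate (condition, replicate, channel, timepoint_h) combination: {first}"
            )
        self.table = t.reset_index(drop=True)

    # -- queries ----------------------------------------------------------

    def samples(
        self,
        condition: str | None = None,
        channel: str | None = None,
        timepoint_h: float | None = None,
        role: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given restrictions, in table order."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        if condition is not None:
            mask &= t["condition"] == condition
        if channel is not None:
            mask &= t["channel"] == channel
        if timepoint_h is not None:
            mask &= t["timepoint_h"] == float(timepoint_h)
        if role is not None:
            mask &= t["role"] == role
        return list(dict.fromkeys(t.loc[mask, "sample_id"]))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["sample_id"]))

    @property
    def timepoints(self) -> list[float]:
        return sorted(set(self.table["timepoint_h"]))

    def conditions_with_role(self, role: str) -> list[str]:
        return list(dict.fromkeys(self.table.loc[self.table["role"] == role, "condition"]))

    def n_replicates(self, condition: str) -> int:
        sub = self.table[self.table["condition"] == condition]
        return int(sub["replicate"].nunique())

    def rows_for(self, sample_id: str) -> pd.DataFrame:
        return self.table[self.table["sample_id"] == sample_id]

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExperimentDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intensity table (log2 protein x sample matrix)
# ---------------------------------------------------------------------------


@dataclass
class IntensityTable:
    """Protein x sample matrix of log2 intensities; ``nan`` marks missing."""

    values: pd.DataFrame
    provenance: str = ""

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "IntensityTable":
        return IntensityTable(self.values.copy(), self.provenance)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.reset_index().rename(columns={"index": "protein"})
        out.columns = ["protein", *self.values.columns]
        write_results_table(out, path)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "IntensityTable":
        df = read_results_table(path)
        if "protein" not in df.columns:
            raise FormatError("intensity table lacks a 'protein' column")
        df = df.set_index("protein")
        df.index.name = None
        return cls(df.astype(float), provenance)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_flag(cell: object) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return False
    s = str(cell).strip()
    return s == "+"


def _parse_intensity(cell: object, row: int, column: str) -> float:
    """Raw intensity cell -> float, with zeros converted to missing."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return MISSING
    s = str(cell).strip()
    if s == "" or s == NA_TOKEN:
        return MISSING
    try:
        v = float(s)
    except ValueError as exc:
        raise ParseError(
            f"non-numeric intensity {s!r} at row {row}, column {column!r}"
        ) from exc
    if v < 0:
        raise ParseError(f"negative intensity {v} at row {row}, column {column!r}")
    if v == 0.0:
        return MISSING
    return v


def read_protein_groups(
    path: str | Path,
    design: ExperimentDesign,
    column_templates: Mapping[str, str] | None = None,
) -> list[ProteinGroupRecord]:
    """Read a proteinGroups TSV into typed records.

    Every sample/channel pair requested by *design* must resolve to a
    column; a missing one raises :class:`FormatError` naming the column.
    Zeros in intensity columns become the missing marker.  Row order is
    preserved and no row is silently dropped.
    """
    templates = dict(DEFAULT_COLUMN_TEMPLATES)
    if column_templates:
        templates.update(column_templates)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    for key in ("protein_ids", "unique_peptides", "reverse", "contaminant", "site_only"):
        col = BASE_COLUMNS[key]
        if col not in df.columns:
            raise FormatError(f"proteinGroups table lacks mandatory column {col!r}")

    # Resolve (channel, sample) -> column up front so contract violations
    # surface before any row work.
    wanted: list[tuple[str, str, str]] = []  # (channel, sample, column)
    for _, row in design.table.iterrows():
        col = templates[row["channel"]].format(sample=row["sample_id"])
        if col not in df.columns:
            raise FormatError(f"proteinGroups table lacks column {col!r}")
        wanted.append((row["channel"], row["sample_id"], col))
    msms_cols = {
        s: templates["msms"].format(sample=s)
        for s in design.sample_ids
        if templates["msms"].format(sample=s) in df.columns
    }

    gene_col = BASE_COLUMNS["gene_name"] if BASE_COLUMNS["gene_name"] in df.columns else None

    records: list[ProteinGroupRecord] = []
    for i, row in df.iterrows():
        ids = tuple(p.strip() for p in str(row[BASE_COLUMNS["protein_ids"]]).split(";") if p.strip())
        if not ids:
            raise ParseError(f"empty protein id list at row {i}")
        try:
            up = int(float(row[BASE_COLUMNS["unique_peptides"]]))
        except ValueError as exc:
            raise ParseError(
                f"non-numeric unique-peptide count at row {i}, "
                f"column {BASE_COLUMNS['unique_peptides']!r}"
            ) from exc
        rec = ProteinGroupRecord(
            protein_ids=ids,
            gene_name=str(row[gene_col]) if gene_col else "",
            unique_peptides=up,
            reverse_flag=_parse_flag(row[BASE_COLUMNS["reverse"]]),
            contaminant_flag=_parse_flag(row[BASE_COLUMNS["contaminant"]]),
            site_only_flag=_parse_flag(row[BASE_COLUMNS["site_only"]]),
        )
        for channel, sample, col in wanted:
            rec.intensities(channel)[sample] = _parse_intensity(row[col], i, col)
        for sample, col in msms_cols.items():
            v = _parse_intensity(row[col], i, col)
            rec.msms_count[sample] = v
        records.append(rec)
    return records


def write_protein_groups(
    records: Iterable[ProteinGroupRecord],
    design: ExperimentDesign,
    path: str | Path,
    column_templates: Mapping[str, str] | None = None,
) -> None:
    """Emit the same proteinGroups dialect :func:`read_protein_groups` reads.

    Missing intensities are written as ``0`` (the MaxQuant convention),
    so a round trip restores the missing marker.
    """
    templates = dict(DEFAULT_COLUMN_TEMPLATES)
    if column_templates:
        templates.update(column_templates)
    records = list(records)
    cols: dict[str, list] = {
        BASE_COLUMNS["protein_ids"]: [";".join(r.protein_ids) for r in records],
        BASE_COLUMNS["gene_name"]: [r.gene_name for r in records],
        BASE_COLUMNS["unique_peptides"]: [r.unique_peptides for r in records],
        BASE_COLUMNS["reverse"]: ["+" if r.reverse_flag else "" for r in records],
        BASE_COLUMNS["contaminant"]: ["+" if r.contaminant_flag else "" for r in records],
        BASE_COLUMNS["site_only"]: ["+" if r.site_only_flag else "" for r in records],
    }
    seen: set[str] = set()
    for _, row in design.table.iterrows():
        col = templates[row["channel"]].format(sample=row["sample_id"])
        if col in seen:
            continue
        seen.add(col)
        vals = []
        for r in records:
            v = r.intensities(row["channel"]).get(row["sample_id"], MISSING)
            vals.append(0.0 if math.isnan(v) else v)
        cols[col] = vals
    if any(r.msms_count for r in records):
        for s in design.sample_ids:
            col = templates["msms"].format(sample=s)
            vals = []
            for r in records:
                v = r.msms_count.get(s, MISSING)
                vals.append(0 if (isinstance(v, float) and math.isnan(v)) else v)
            cols[col] = vals
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_spectral_counts(path: str | Path) -> list[SpectralCountRecord]:
    """Read a bait/prey/replicate/count/is_control TSV.

    Duplicate ``(bait, prey, replicate, is_control)`` rows and negative or
    fractional counts are rejected with an error naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("bait", "prey", "replicate", "count", "is_control"):
        if col not in df.columns:
            raise FormatError(f"spectral-count table lacks column {col!r}")
    records: list[SpectralCountRecord] = []
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except ValueError as exc:
            raise ParseError(f"non-integer replicate {row['replicate']!r} at row {i}") from exc
        if rep < 1:
            raise ParseError(f"replicate must be positive at row {i}")
        raw = str(row["count"]).strip()
        try:
            count = int(raw)
        except ValueError as exc:
            raise ParseError(
                f"count must be a non-negative integer, got {raw!r} at row {i}"
            ) from exc
        if count < 0:
            raise ParseError(f"negative count {count} at row {i}")
        ctl = str(row["is_control"]).strip().lower()
        if ctl in ("true", "1", "yes", "+"):
            is_control = True
        elif ctl in ("false", "0", "no", ""):
            is_control = False
        else:
            raise ParseError(f"unparseable is_control {row['is_control']!r} at row {i}")
        key = (row["bait"], row["prey"], rep, is_control)
        if key in seen:
            raise ParseError(f"duplicate (bait, prey, replicate) key {key}")
        seen.add(key)
        records.append(
            SpectralCountRecord(
                bait=str(row["bait"]), prey=str(row["prey"]),
                replicate=rep, count=count, is_control=is_control,
            )
        )
    return records


def write_spectral_counts(records: Iterable[SpectralCountRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "bait": [r.bait for r in records],
            "prey": [r.prey for r in records],
            "replicate": [r.replicate for r in records],
            "count": [r.count for r in records],
            "is_control": ["true" if r.is_control else "false" for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------


def _format_cell(v: object) -> str:
    if v is None:
        return NA_TOKEN
    if isinstance(v, float):
        if math.isnan(v):
            return NA_TOKEN
        return f"{v:.17g}"
    if isinstance(v, (np.floating,)):
        return _format_cell(float(v))
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return str(v)


def write_results_table(records: object, path: str | Path) -> None:
    """Write a homogeneous record collection as TSV.

    Accepts a pandas DataFrame or a sequence of dataclass instances that
    share a type.  Column order is deterministic (dataclass field order or
    frame column order), floats carry 17 significant digits and missing
    values are encoded as the literal ``NA`` — never as NaN text.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and not dataclasses.is_dataclass(records[0]):
            raise ConfigurationError("records must be dataclasses or a DataFrame")
        if records:
            fields = [f.name for f in dataclasses.fields(records[0])]
            df = pd.DataFrame([{f: getattr(r, f) for f in fields} for r in records], columns=fields)
        else:
            df = pd.DataFrame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results_table`.

    ``NA`` maps back to NaN, ``true``/``false`` to booleans and numeric
    columns are restored to numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for col in df.columns:
        s = df[col].where(df[col] != NA_TOKEN, np.nan)
        non_na = s.dropna()
        if len(non_na) and set(non_na) <= {"true", "false"}:
            out[col] = s.map({"true": True, "false": False})
            continue
        try:
            if len(non_na) and non_na.str.fullmatch(r"[+-]?\d+").all():
                out[col] = pd.to_numeric(s)
            else:
                # numpy's parser round-trips 17-digit doubles exactly;
                # pandas' fast to_numeric path does not
                out[col] = s.astype(float)
        except (ValueError, TypeError):
            out[col] = s
    return pd.DataFrame(out, columns=df.columns)
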