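"""Domain tables and CSV readers/writers.

Canonical on-disk format is tidy (long) UTF-8 CSV with one header row:
one measurement per row, indexed by taxon/compound, treatment, time in
hours, experimental replica and technical replica.  A wide reader is
provided for printed-table style files (one column per treatment x time
condition, cells formatted ``mean±sd``), matching how qPCR results are
conventionally reported.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import BASELINE_LABEL, DesignRegistry
from .errors import SchemaError, ValidationError

#: Taxa quantified by the core qPCR panel.  Extensible: pass a custom
#: vocabulary to the table constructor to accept additional targets.
DEFAULT_TAXA: tuple[str, ...] = (
    "Eubacteria", "Firmicutes", "Bacteroidetes", "Lactobacillales",
    "Bifidobacteriaceae", "Enterobacteriaceae", "Clostridium gI",
    "Clostridium gIV", "E. coli", "F. prausnitzii", "A. muciniphila",
)

TAXON_KEY = ["taxon", "treatment", "time_h", "experiment", "replicate"]
VOC_KEY = ["compound", "treatment", "time_h", "experiment", "replicate"]

VOC_CLASSES = ("SCFA", "MCFA", "BCFA", "indole", "organic_acid",
               "aldehyde", "ketone", "alcohol", "alkene", "other")
#: Classes whose members are prebiotic-activity-related volatiles.
PRE_VOC_CLASSES = ("SCFA", "MCFA", "BCFA", "indole")

_FLOAT_FMT = "%.17g"  # 17 significant digits: exact float64 text round-trip


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_duplicates(df: pd.DataFrame, key: list[str], what: str) -> None:
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        keys = df.loc[dup, key].drop_duplicates().head(5).to_dict("records")
        raise ValidationError(f"duplicate {what} row(s) for key(s): {keys}")


def _parse_values(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        raise ValidationError(
            f"{path}: unparseable value(s) in column '{col}' at row(s) {rows}")
    return vals


@dataclass
class TaxonAbundanceTable:
    """Absolute taxa loads in Log10 gene copies/mL, replicate level.

    ``data`` columns: taxon, treatment, time_h, experiment, replicate,
    log10_gcn (plus optional auxiliary columns such as ``sd`` for
    printed-means tables or ``out_of_range`` flags from quantification).
    """

    data: pd.DataFrame
    vocabulary: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        _require_columns(self.data, TAXON_KEY + ["log10_gcn"], "taxon table")
        self.data = self.data.reset_index(drop=True)
        vals = self.data["log10_gcn"].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            rows = np.flatnonzero(~np.isfinite(vals)).tolist()[:10]
            raise ValidationError(f"non-finite abundance at row(s) {rows}")
        out = (vals < 0) | (vals > 12)
        if out.any():
            rows = np.flatnonzero(out).tolist()[:10]
            raise ValidationError(
                f"abundance outside [0, 12] Log10 GCN/mL at row(s) {rows}")
        _check_duplicates(self.data, TAXON_KEY, "taxon")
        if self.vocabulary is not None:
            unknown = sorted(set(self.data["taxon"]) - set(self.vocabulary))
            if unknown:
                raise ValidationError(f"taxa not in vocabulary: {unknown}")

    # -- access ------------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return sorted(self.data["taxon"].unique())

    def select(self, taxon: str, treatment: str, time_h: float) -> pd.DataFrame:
        d = self.data
        return d[(d["taxon"] == taxon) & (d["treatment"] == treatment)
                 & (d["time_h"] == time_h)]

    def condition_mean(self, taxon: str, treatment: str, time_h: float) -> float:
        sub = self.select(taxon, treatment, time_h)
        if sub.empty:
            raise ValidationError(
                f"no rows for ({taxon!r}, {treatment!r}, {time_h} h)")
        return float(sub["log10_gcn"].mean())

    def conditions(self) -> pd.DataFrame:
        return (self.data[["treatment", "time_h"]]
                .drop_duplicates().reset_index(drop=True))

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path,
                 registry: DesignRegistry | None = None,
                 vocabulary: tuple[str, ...] | None = None,
                 ) -> "TaxonAbundanceTable":
        return read_taxon_table(path, registry=registry, vocabulary=vocabulary)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class VocTable:
    """VOC abundances per compound x sample.

    ``unit`` is uniform over the table: ``relative_percent``, ``mg_per_kg``
    or ``centered`` (after mean-centering).  Non-detects carry
    ``detected == False`` and a value of 0; analyses decide their own
    substitution and must not treat the 0 as a measurement.
    """

    data: pd.DataFrame
    unit: str = "mg_per_kg"

    def __post_init__(self) -> None:
        _require_columns(self.data, VOC_KEY + ["value"], "VOC table")
        self.data = self.data.reset_index(drop=True)
        if "detected" not in self.data.columns:
            self.data["detected"] = True
        if self.unit not in ("relative_percent", "mg_per_kg", "centered"):
            raise ValidationError(f"unknown unit flag {self.unit!r}")
        vals = self.data["value"].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite VOC value(s)")
        det = self.data["detected"].to_numpy(bool)
        if self.unit != "centered" and np.any(vals[det] < 0):
            rows = self.data.index[det & (vals < 0)].tolist()[:10]
            raise ValidationError(f"negative detected value(s) at row(s) {rows}")
        _check_duplicates(self.data, VOC_KEY, "VOC")
        if self.unit == "relative_percent":
            totals = self.data.groupby(VOC_KEY[1:])["value"].sum()
            if (totals > 100.0 + 0.5).any():
                bad = totals[totals > 100.5].index.tolist()[:5]
                raise ValidationError(
                    f"relative_percent sample total(s) exceed 100%: {bad}")

    @property
    def compounds(self) -> list[str]:
        return sorted(self.data["compound"].unique())

    def condition_mean(self, compound: str, treatment: str, time_h: float,
                       nondetect_as_zero: bool = True) -> float:
        d = self.data
        sub = d[(d["compound"] == compound) & (d["treatment"] == treatment)
                & (d["time_h"] == time_h)]
        if sub.empty:
            return float("nan")
        vals = sub["value"].where(sub["detected"] | nondetect_as_zero, np.nan)
        return float(vals.mean())

    @classmethod
    def from_csv(cls, path: str | Path) -> "VocTable":
        return read_voc_table(path)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["unit"] = self.unit
        out.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class VocClassMap:
    """Compound -> chemical class; preVOC = SCFA/MCFA/BCFA/indole members."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c: k for c, k in self.mapping.items() if k not in VOC_CLASSES}
        if bad:
            raise ValidationError(f"unknown chemical class(es): {bad}")

    def class_of(self, compound: str) -> str:
        try:
            return self.mapping[compound]
        except KeyError:
            raise ValidationError(f"compound {compound!r} has no class") from None

    def is_pre_voc(self, compound: str) -> bool:
        return self.class_of(compound) in PRE_VOC_CLASSES

    @property
    def pre_vocs(self) -> list[str]:
        return sorted(c for c in self.mapping if self.is_pre_voc(c))

    def check_covers(self, vocs: VocTable) -> None:
        missing = sorted(set(vocs.data["compound"]) - set(self.mapping))
        if missing:
            raise ValidationError(f"compounds without a class: {missing}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "VocClassMap":
        df = pd.read_csv(path)
        _require_columns(df, ["compound", "voc_class"], path)
        _check_duplicates(df, ["compound"], "class-map")
        return cls(dict(zip(df["compound"], df["voc_class"])))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"compound": list(self.mapping),
                      "voc_class": list(self.mapping.values())}
                     ).to_csv(path, index=False)


# -- readers ---------------------------------------------------------------

def read_taxon_table(path: str | Path,
                     registry: DesignRegistry | None = None,
                     vocabulary: tuple[str, ...] | None = None,
                     ) -> TaxonAbundanceTable:
    """Read a tidy taxa CSV, validate, and cross-check against a registry."""
    df = pd.read_csv(path)
    _require_columns(df, TAXON_KEY + ["log10_gcn"], path)
    df["log10_gcn"] = _parse_values(df, "log10_gcn", path)
    table = TaxonAbundanceTable(df, vocabulary=vocabulary)
    if registry is not None:
        _audit_against_registry(table.data, registry,
                                registry.technical_replicas_qpcr, path)
    return table


def read_voc_table(path: str | Path) -> VocTable:
    df = pd.read_csv(path)
    _require_columns(df, VOC_KEY + ["value"], path)
    df["value"] = _parse_values(df, "value", path)
    unit = "mg_per_kg"
    if "unit" in df.columns:
        units = df["unit"].unique()
        if len(units) != 1:
            raise ValidationError(f"{path}: unit flag not uniform: {units}")
        unit = str(units[0])
        df = df.drop(columns=["unit"])
    if "detected" in df.columns:
        df["detected"] = df["detected"].astype(bool)
    return VocTable(df, unit=unit)


def _audit_against_registry(df: pd.DataFrame, registry: DesignRegistry,
                            max_tech: int, path) -> None:
    bad_treat = set(df["treatment"]) - set(registry.treatments) - {BASELINE_LABEL}
    if bad_treat:
        raise ValidationError(f"{path}: treatments not in registry: {sorted(bad_treat)}")
    bad_time = set(df["time_h"]) - set(registry.time_points_h)
    if bad_time:
        raise ValidationError(f"{path}: time points not in registry: {sorted(bad_time)}")
    counts = df.groupby(TAXON_KEY[:3]).size()
    too_many = counts[counts > registry.experimental_replicas * max_tech]
    if not too_many.empty:
        warnings.warn(
            f"{path}: replicate count exceeds registry for {len(too_many)} "
            "condition(s); accepting unbalanced replication", stacklevel=2)


# -- printed-table (wide) fixture ------------------------------------------

def read_table1_wide(path: str | Path,
                     ) -> tuple[TaxonAbundanceTable, pd.DataFrame]:
    """Read a printed-style wide table of ``mean±sd`` cells.

    Columns are ``treatment:time_h`` conditions; the baseline column is
    ``BL:0``.  A row labelled ``F/B`` (the printed Firmicutes-to-
    Bacteroidetes ratio) is split off and returned separately so the
    computed ratio can be checked against it.

    Returns
    -------
    (table, printed_fb)
        ``table`` holds one pseudo-replicate per condition (the printed
        mean) with the printed SD in an ``sd`` column; ``printed_fb`` has
        columns treatment, time_h, fb, sd.
    """
    wide = pd.read_csv(path, index_col=0)
    if wide.index.name != "taxon":
        raise SchemaError(f"{path}: first column must be 'taxon'")
    records, fb_records = [], []
    for cond in wide.columns:
        try:
            treatment, time_s = cond.split(":")
            time_h = float(time_s)
        except ValueError:
            raise SchemaError(
                f"{path}: condition column {cond!r} is not 'treatment:hours'"
            ) from None
        for taxon, cell in wide[cond].items():
            mean_s, _, sd_s = str(cell).partition("±")
            try:
                mean, sd = float(mean_s), float(sd_s) if sd_s else np.nan
            except ValueError:
                raise ValidationError(
                    f"{path}: unparseable cell {cell!r} at ({taxon}, {cond})"
                ) from None
            rec = dict(treatment=treatment, time_h=time_h,
                       experiment=1, replicate=1, sd=sd)
            if taxon == "F/B":
                fb_records.append({**rec, "fb": mean})
            else:
                records.append({**rec, "taxon": taxon, "log10_gcn": mean})
    table = TaxonAbundanceTable(pd.DataFrame(records), vocabulary=DEFAULT_TAXA)
    fb = pd.DataFrame(fb_records,
                      columns=["treatment", "time_h", "experiment",
                               "replicate", "sd", "fb"])
    return table, fb[["treatment", "time_h", "fb", "sd"]]


def load_table1() -> tuple[TaxonAbundanceTable, pd.DataFrame]:
    """Load the bundled printed qPCR means fixture (11 taxa x 10 conditions)."""
    ref = importlib.resources.files("gutferm") / "data" / "table1_means.csv"
    with importlib.resources.as_file(ref) as p:
        return read_table1_wide(p)
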