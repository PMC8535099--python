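"""Microbiota indicators: F/B ratio, the qPI prebiotic index, shift letters.

The Firmicutes-to-Bacteroidetes ratio is taken on the Log10 loads (the
scale on which qPCR panels report); values around or below 1.5 read as
eubiosis, above 2 as dysbiosis.  The qPI (qPCR Prebiotic Index) scores a
substrate by four taxon-to-total ratios::

    qPI = Bifidobacteriaceae/Eubacteria - Enterobacteriaceae/Eubacteria
        + Lactobacillales/Eubacteria    - Clostridium gI/Eubacteria

so growth of bifidobacteria and lactic acid bacteria raises the index
while growth of enterobacteria and Clostridium group I lowers it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError, ValidationError
from .io import TaxonAbundanceTable
from .posthoc import LetterResult, tukey_letters

QPI_TAXA = ("Bifidobacteriaceae", "Enterobacteriaceae",
            "Lactobacillales", "Clostridium gI", "Eubacteria")

EUBIOSIS_MAX = 1.5
DYSBIOSIS_MIN = 2.0


@dataclass
class FbRatio:
    treatment: str
    time_h: float
    ratio: float
    band: str                          # eubiosis / intermediate / dysbiosis
    firmicutes: float
    bacteroidetes: float
    replicate_ratios: np.ndarray = field(default_factory=lambda: np.array([]))


def _band(ratio: float) -> str:
    if ratio <= EUBIOSIS_MAX:
        return "eubiosis"
    if ratio > DYSBIOSIS_MIN:
        return "dysbiosis"
    return "intermediate"


def fb_ratio(table: TaxonAbundanceTable, treatment: str, time_h: float,
             linear_domain: bool = False) -> FbRatio:
    """Firmicutes/Bacteroidetes ratio of mean Log10 loads at one condition.

    ``linear_domain=True`` computes the ratio of linear copy numbers
    instead — a clearly labelled alternative, not the reporting
    convention (printed F/B cells are ratios of Log10 loads).
    Replicate-level ratios (paired by experiment and replicate where both
    taxa are present) are returned for dispersion.
    """
    f = table.select("Firmicutes", treatment, time_h)
    b = table.select("Bacteroidetes", treatment, time_h)
    if f.empty or b.empty:
        raise ValidationError(
            f"Firmicutes/Bacteroidetes missing at ({treatment!r}, {time_h} h)")
    fm, bm = float(f["log10_gcn"].mean()), float(b["log10_gcn"].mean())
    if linear_domain:
        fm, bm = 10.0 ** fm, 10.0 ** bm
    if bm == 0:
        raise UndefinedRatioError("Bacteroidetes load is zero")
    merged = f.merge(b, on=["experiment", "replicate"], suffixes=("_f", "_b"))
    reps = merged["log10_gcn_f"].to_numpy() / merged["log10_gcn_b"].to_numpy()
    ratio = fm / bm
    return FbRatio(treatment, time_h, ratio, _band(ratio), fm, bm, reps)


def fb_table(table: TaxonAbundanceTable) -> pd.DataFrame:
    """F/B for every (treatment, time) condition present in the table."""
    rows = []
    for _, cond in table.conditions().iterrows():
        r = fb_ratio(table, cond["treatment"], cond["time_h"])
        rows.append(dict(treatment=r.treatment, time_h=r.time_h,
                         fb=r.ratio, band=r.band))
    return pd.DataFrame(rows)


@dataclass
class QpiResult:
    treatment: str
    time_h: float
    term_bif: float
    term_ent: float
    term_lact: float
    term_closI: float
    normalization_mode: str = "raw_log"

    @property
    def qpi(self) -> float:
        return self.term_bif - self.term_ent + self.term_lact - self.term_closI


def compute_qpi(table: TaxonAbundanceTable, treatment: str, time_h: float,
                mode: str = "raw_log") -> QpiResult:
    """qPI at one condition.

    raw_log
        Each term is the taxon's mean Log10 load at the condition divided
        by the Eubacteria mean Log10 load there.
    mean_centered
        The four numerator taxa are first mean-centered across all
        conditions in the table (per taxon, on condition means); the
        Eubacteria denominator stays on the raw Log10 scale so the index
        remains bounded.  Requires >= 2 conditions.
    """
    if mode not in ("raw_log", "mean_centered"):
        raise ValidationError(f"unknown qPI mode {mode!r}")
    means = {t: table.condition_mean(t, treatment, time_h) for t in QPI_TAXA}
    eub = means["Eubacteria"]
    if eub == 0:
        raise UndefinedRatioError("Eubacteria load is zero")
    if mode == "mean_centered":
        conds = table.conditions()
        if len(conds) < 2:
            raise ValidationError(
                "mean_centered qPI needs >= 2 conditions to center over")
        for taxon in QPI_TAXA[:4]:
            grand = np.mean([table.condition_mean(taxon, c["treatment"],
                                                  c["time_h"])
                             for _, c in conds.iterrows()])
            means[taxon] = means[taxon] - grand
    return QpiResult(treatment, time_h,
                     term_bif=means["Bifidobacteriaceae"] / eub,
                     term_ent=means["Enterobacteriaceae"] / eub,
                     term_lact=means["Lactobacillales"] / eub,
                     term_closI=means["Clostridium gI"] / eub,
                     normalization_mode=mode)


def qpi_table(table: TaxonAbundanceTable,
              modes: tuple[str, ...] = ("raw_log", "mean_centered"),
              ) -> pd.DataFrame:
    """qPI for every condition, in each requested normalization mode."""
    rows = []
    for mode in modes:
        for _, cond in table.conditions().iterrows():
            try:
                r = compute_qpi(table, cond["treatment"], cond["time_h"], mode)
            except ValidationError:
                continue
            rows.append(dict(treatment=r.treatment, time_h=r.time_h,
                             mode=mode, qpi=r.qpi, term_bif=r.term_bif,
                             term_ent=r.term_ent, term_lact=r.term_lact,
                             term_closI=r.term_closI))
    return pd.DataFrame(rows)


def taxa_shift_letters(table: TaxonAbundanceTable, taxon: str,
                       alpha: float = 0.05) -> LetterResult:
    """Compact letters over conditions for one taxon (Tukey-Kramer, alpha).

    Conditions sharing no letter differ significantly; letters are
    assigned in descending-mean order so 'a' marks the highest loads.
    Condition labels are ``"treatment@hours"``.
    """
    d = table.data[table.data["taxon"] == taxon]
    if d.empty:
        raise ValidationError(f"taxon {taxon!r} not in table")
    groups = {f"{tr}@{th:g}": sub["log10_gcn"].to_numpy()
              for (tr, th), sub in d.groupby(["treatment", "time_h"])}
    return tukey_letters(groups, alpha=alpha)
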