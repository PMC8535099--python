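"""Absolute qPCR quantification via five-point standard curves.

Each target is calibrated with a dilution series of its own amplicon:
ordinary least squares of quantification cycle (Cq) on log10 copy number
gives slope and intercept; amplification efficiency is
``E = 10^(-1/slope) - 1`` (a perfect doubling per cycle has slope
-3.3219 and E = 100%).  Sample cycles are inverted through the curve and
scaled to gene copies per mL.  Replicates are aggregated on the Log10
scale (mean and sample SD), matching how such loads are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateCurveError, ValidationError
from .io import TAXON_KEY, TaxonAbundanceTable

#: Efficiency band outside which a curve draws a report-level warning.
EFFICIENCY_BAND = (0.90, 1.10)


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration of quantification cycle on log10 copies."""

    slope: float          # cycles per decade, negative for a working assay
    intercept: float      # cycles at 1 copy (log10 = 0)
    r_squared: float
    points: tuple[tuple[float, float], ...] = ()

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, derived from the slope."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def efficiency_ok(self) -> bool:
        lo, hi = EFFICIENCY_BAND
        return lo <= self.efficiency <= hi


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """OLS fit of cycle on log10 copies over a dilution series.

    Parameters
    ----------
    points
        (log10_copies, cycle) pairs; at least two distinct log10 values.
    """
    pts = tuple((float(x), float(y)) for x, y in points)
    if len(pts) < 2:
        raise DegenerateCurveError("need at least 2 calibration points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise DegenerateCurveError("all calibration points at one log10 value")
    res = stats.linregress(x, y)
    curve = StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2), points=pts)
    if curve.slope >= 0:
        warnings.warn("standard curve slope is non-negative; check input",
                      stacklevel=2)
    elif not curve.efficiency_ok():
        warnings.warn(
            f"amplification efficiency {curve.efficiency:.1%} outside "
            f"{EFFICIENCY_BAND[0]:.0%}-{EFFICIENCY_BAND[1]:.0%}", stacklevel=2)
    return curve


def cycle_to_log10_gcn(cycle: float, curve: StandardCurve,
                       dilution_factor: float = 1.0,
                       volume_scale: float = 1.0) -> tuple[float, bool]:
    """Invert a quantification cycle to Log10 gene copies/mL.

    ``log10_copies = (cycle - intercept) / slope`` plus the log10 of the
    combined dilution and per-mL volume scaling.  Returns the value and an
    in-range flag (False when outside [0, 12] Log10; flagged, not raised).
    """
    if curve.slope == 0:
        raise DegenerateCurveError("curve slope is zero")
    scale = dilution_factor * volume_scale
    if scale <= 0:
        raise ValidationError("dilution_factor x volume_scale must be > 0")
    value = (float(cycle) - curve.intercept) / curve.slope + math.log10(scale)
    return value, (0.0 <= value <= 12.0)


def quantify(cq: pd.DataFrame, curves: Mapping[str, StandardCurve],
             dilution_factor: float = 1.0, volume_scale: float = 1.0,
             ) -> TaxonAbundanceTable:
    """Convert a tidy Cq table into a taxon abundance table.

    ``cq`` columns: taxon, treatment, time_h, experiment, replicate, cq.
    Values outside the plausible [0, 12] Log10 range are clipped into
    range and flagged in an ``out_of_range`` column rather than dropped.
    """
    missing = sorted(set(cq["taxon"]) - set(curves))
    if missing:
        raise ValidationError(f"no standard curve for taxa: {missing}")
    rows = []
    for rec in cq.to_dict("records"):
        value, ok = cycle_to_log10_gcn(rec["cq"], curves[rec["taxon"]],
                                       dilution_factor, volume_scale)
        rows.append({k: rec[k] for k in TAXON_KEY}
                    | {"log10_gcn": min(max(value, 0.0), 12.0),
                       "out_of_range": not ok})
    n_bad = sum(r["out_of_range"] for r in rows)
    if n_bad:
        warnings.warn(f"{n_bad} quantification(s) outside [0, 12] Log10 "
                      "GCN/mL were clipped and flagged", stacklevel=2)
    return TaxonAbundanceTable(pd.DataFrame(rows))


def aggregate_replicates(table: TaxonAbundanceTable, level: str = "all",
                         linear_domain: bool = False) -> pd.DataFrame:
    """Mean and sample SD per condition, on the Log10 scale by default.

    ``level='technical'`` averages technical replicas within each
    experimental replica; ``level='all'`` pools everything per
    (taxon, treatment, time).  SD uses the n-1 denominator and is missing
    (NaN), never 0, for single-replicate cells.  ``linear_domain=True``
    averages linear copy numbers and reports the Log10 of the mean — an
    explicitly labelled alternative, not the reporting convention.
    """
    if level not in ("technical", "all"):
        raise ValidationError(f"unknown aggregation level {level!r}")
    key = TAXON_KEY[:3] + (["experiment"] if level == "technical" else [])
    vals = table.data.copy()
    if linear_domain:
        vals["log10_gcn"] = 10.0 ** vals["log10_gcn"]
    g = vals.groupby(key)["log10_gcn"]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size").reset_index()
    if linear_domain:
        out["mean"] = np.log10(out["mean"])
        out["sd"] = np.nan  # SD not defined on the mixed scale
    return out
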