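"""The preVOC shift pipeline and chemical-class bookkeeping.

The order of operations is fixed: (1) one-way ANOVA screen keeps
compounds that vary anywhere in the design; (2) each surviving compound
is mean-centered over all samples; (3) the baseline (time-0) mean is
subtracted, giving a per-condition shift; (4) Tukey post hoc letters
compare conditions per compound.  Class sums and percent shifts operate
on the un-centered (relative or absolute) values; ordination (PCA) on
the centered matrix.

Non-detects are substituted with 0 for sums, shifts and the screen, and
excluded pairwise for ordination; both substitutions are flagged in the
output rather than silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import VOC_KEY, VocClassMap, VocTable
from .posthoc import tukey_letters

SAMPLE_KEY = VOC_KEY[1:]  # treatment, time_h, experiment, replicate


# -- significance screen ---------------------------------------------------

def anova_screen(vocs: VocTable, alpha: float = 0.05, fdr: bool = False,
                 exclude: Sequence[str] = ()) -> pd.DataFrame:
    """Per-compound one-way ANOVA across all (treatment, time) groups.

    Returns a frame with compound, p, significant, constant.  Compounds
    constant everywhere get p = 1 and are never significant.  ``fdr``
    applies Benjamini-Hochberg adjustment before thresholding (off by
    default — the screen is conventionally run unadjusted).  ``exclude``
    drops listed compounds up front (the minor-compound cast-out list).
    """
    d = vocs.data[~vocs.data["compound"].isin(set(exclude))].copy()
    d.loc[~d["detected"], "value"] = 0.0
    wide = d.pivot_table(index=SAMPLE_KEY, columns="compound",
                         values="value", aggfunc="first")
    group_ids = wide.index.to_frame(index=False)[["treatment", "time_h"]]
    keys = list(map(tuple, group_ids.itertuples(index=False)))
    uniq = sorted(set(keys))
    if len(uniq) < 2:
        raise ValidationError("ANOVA screen needs >= 2 groups")
    arrays = [wide.to_numpy()[[k == u for k in keys], :] for u in uniq]
    if any(a.shape[0] < 2 for a in arrays):
        raise ValidationError("every group needs >= 2 replicates")
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-input warnings
            _, p = stats.f_oneway(*arrays, axis=0)
    p = np.asarray(p, dtype=float)
    constant = np.ptp(wide.to_numpy(), axis=0) == 0
    p[constant | ~np.isfinite(p)] = 1.0
    out = pd.DataFrame({"compound": wide.columns, "p": p,
                        "constant": constant})
    p_eff = _bh_adjust(out["p"].to_numpy()) if fdr else out["p"].to_numpy()
    out["p_adjusted"] = p_eff if fdr else np.nan
    out["significant"] = (p_eff < alpha) & ~out["constant"]
    return out.reset_index(drop=True)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


# -- normalization ---------------------------------------------------------

def mean_center(vocs: VocTable) -> tuple[VocTable, pd.Series]:
    """Subtract each compound's mean over all samples (mean centering).

    Non-detects are substituted with 0 before centering (they keep their
    ``detected`` flag).  Returns the centered table (unit ``centered``)
    and the per-compound means, so centering is exactly invertible.
    """
    d = vocs.data.copy()
    d.loc[~d["detected"], "value"] = 0.0
    means = d.groupby("compound")["value"].transform("mean")
    stored = d.groupby("compound")["value"].mean()
    d["value"] = d["value"] - means
    return VocTable(d, unit="centered"), stored


# -- baseline-referenced shifts --------------------------------------------

@dataclass
class ShiftTable:
    """Per (compound, condition) shift vs baseline in normalized units."""

    data: pd.DataFrame  # compound, treatment, time_h, delta, letter


def baseline_shift(normalized: VocTable, baseline_time_h: float = 0.0,
                   alpha: float = 0.05, letters: bool = True) -> ShiftTable:
    """Subtract the baseline mean from each condition mean, per compound.

    The baseline is all samples at ``baseline_time_h`` pooled (it is a
    single pre-fermentation state, expressed as the mean of its samples).
    Tukey letters compare all conditions — baseline included — per
    compound; they are omitted (None) when any condition has < 2
    replicates.
    """
    d = normalized.data.copy()
    d.loc[~d["detected"], "value"] = 0.0
    bl = d[d["time_h"] == baseline_time_h]
    if bl.empty:
        raise ValidationError(f"no baseline samples at {baseline_time_h} h")
    bl_mean = bl.groupby("compound")["value"].mean()
    rows = []
    for compound, sub in d.groupby("compound"):
        base = bl_mean.get(compound, np.nan)
        cond_means = sub.groupby(["treatment", "time_h"])["value"].mean()
        letter_map = {}
        if letters:
            groups = {f"{tr}@{th:g}": s["value"].to_numpy()
                      for (tr, th), s in sub.groupby(["treatment", "time_h"])}
            if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
                letter_map = tukey_letters(groups, alpha=alpha).letters
        for (tr, th), m in cond_means.items():
            delta = 0.0 if th == baseline_time_h else m - base
            rows.append(dict(compound=compound, treatment=tr, time_h=th,
                             delta=float(delta),
                             letter=letter_map.get(f"{tr}@{th:g}")))
    return ShiftTable(pd.DataFrame(rows))


# -- class bookkeeping -----------------------------------------------------

def class_percent_change(vocs: VocTable, classes: VocClassMap,
                         endpoint_treatment: str, endpoint_time_h: float,
                         baseline_time_h: float = 0.0) -> pd.DataFrame:
    """Percent change of per-class summed abundance vs baseline.

    Per class: ``100 * (sum_endpoint - sum_baseline) / sum_baseline``
    where sums are over condition-mean compound abundances (non-detects
    contribute 0).  A class absent (zero) at both ends is reported
    missing; a class absent only at baseline is flagged newly detected.
    Requires un-centered units.
    """
    if vocs.unit == "centered":
        raise ValidationError("class sums need relative or absolute units")
    classes.check_covers(vocs)
    d = vocs.data.copy()
    d.loc[~d["detected"], "value"] = 0.0
    d["voc_class"] = d["compound"].map(classes.mapping)

    def _class_sums(sub: pd.DataFrame) -> pd.Series:
        per_compound = sub.groupby(["voc_class", "compound"])["value"].mean()
        return per_compound.groupby("voc_class").sum()

    base = _class_sums(d[d["time_h"] == baseline_time_h])
    end = _class_sums(d[(d["treatment"] == endpoint_treatment)
                        & (d["time_h"] == endpoint_time_h)])
    rows = []
    for cls in sorted(set(base.index) | set(end.index)):
        b, e = float(base.get(cls, 0.0)), float(end.get(cls, 0.0))
        if b == 0.0 and e == 0.0:
            rows.append(dict(voc_class=cls, percent_change=np.nan,
                             newly_detected=False))
        elif b == 0.0:
            rows.append(dict(voc_class=cls, percent_change=np.nan,
                             newly_detected=True))
        else:
            rows.append(dict(voc_class=cls,
                             percent_change=100.0 * (e - b) / b,
                             newly_detected=False))
    return pd.DataFrame(rows)


class PercentShift(NamedTuple):
    percent: float            # NaN when newly detected
    newly_detected: bool


def percent_shift(vocs: VocTable, compound: str,
                  condition_a: tuple[str, float],
                  condition_b: tuple[str, float]) -> PercentShift:
    """100 x (mean_b - mean_a) / mean_a for one compound, absolute units."""
    if vocs.unit == "centered":
        raise ValidationError("percent shift needs un-centered units")
    ma = vocs.condition_mean(compound, *condition_a)
    mb = vocs.condition_mean(compound, *condition_b)
    if np.isnan(ma) or np.isnan(mb):
        raise ValidationError(f"{compound!r} missing at a requested condition")
    if ma == 0.0:
        if mb > 0.0:
            return PercentShift(float("nan"), True)
        return PercentShift(0.0, False)
    return PercentShift(100.0 * (mb - ma) / ma, False)


# -- ordination ------------------------------------------------------------

@dataclass
class Ordination:
    scores: pd.DataFrame            # cases x components
    loadings: pd.DataFrame          # variables x components
    explained_variance_ratio: np.ndarray


def ordination_scores(data: pd.DataFrame, n_components: int = 2) -> Ordination:
    """PCA of a cases x variables matrix via SVD of the centered data.

    Missing entries (non-detects excluded pairwise upstream) are imputed
    at the column mean — i.e. at 0 after centering — with a warning.
    Sign convention: the largest-magnitude loading of each component is
    positive, making scores reproducible across platforms.
    """
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValidationError("ordination needs >= 2 cases and >= 2 variables")
    x = data.to_numpy(float)
    if np.isnan(x).any():
        warnings.warn("missing entries imputed at the column mean for "
                      "ordination", stacklevel=2)
        col_means = np.nanmean(x, axis=0)
        x = np.where(np.isnan(x), col_means[None, :], x)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; "
                      "truncating", stacklevel=2)
        n_components = max(rank, 1)
    # fix signs: largest-|loading| entry of each component positive
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    var = s ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{i+1}" for i in range(n_components)]
    scores = pd.DataFrame((u[:, :n_components] * s[:n_components]),
                          index=data.index, columns=comps)
    loadings = pd.DataFrame(vt[:n_components].T, index=data.columns,
                            columns=comps)
    return Ordination(scores, loadings, ratio[:n_components])


def to_case_matrix(vocs: VocTable) -> pd.DataFrame:
    """Pivot a VOC table to cases x compounds (non-detects as NaN)."""
    d = vocs.data.copy()
    d.loc[~d["detected"], "value"] = np.nan
    return d.pivot_table(index=SAMPLE_KEY, columns="compound",
                         values="value", aggfunc="first")
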