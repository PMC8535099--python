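"""All-pairs post hoc comparison with compact letter display.

One engine serves both the microbiota tables and the volatilome shift
analysis: one-way ANOVA context, Tukey-Kramer all-pairs comparisons
(studentized-range based, valid for unequal group sizes), and an
insert-and-absorb compact letter display so that two groups share no
letter exactly when they differ significantly.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass
class LetterResult:
    letters: dict[str, str]          # group label -> e.g. "a", "ab"
    p_matrix: np.ndarray             # pairwise Tukey p-values, label order
    labels: list[str]
    degenerate: bool = False         # True when fell back to exact equality

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def tukey_letters(groups: Mapping[str, Sequence[float]],
                  alpha: float = 0.05) -> LetterResult:
    """Tukey-Kramer all-pairs test with compact letters.

    Parameters
    ----------
    groups
        Label -> replicate values.  Needs >= 2 groups with >= 2 values
        each.  Output is invariant to the mapping's insertion order.
    alpha
        Family-wise significance level.

    When every group has zero within-group variance the studentized-range
    statistic is undefined; the comparison falls back to exact-equality
    grouping with a warning.
    """
    labels = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs at least 2 replicates")
    k = len(labels)
    means = np.array([a.mean() for a in arrays])

    pooled_var = np.concatenate([a - a.mean() for a in arrays]).var(ddof=0)
    if pooled_var == 0.0:
        warnings.warn("zero within-group variance everywhere; falling back "
                      "to exact-equality grouping", stacklevel=2)
        p = np.where(np.abs(means[:, None] - means[None, :]) > 0, 0.0, 1.0)
        sig = p < alpha
        letters = _insert_absorb(sig, means)
        return LetterResult({g: letters[i] for i, g in enumerate(labels)},
                            p, labels, degenerate=True)

    res = stats.tukey_hsd(*arrays)
    p = np.asarray(res.pvalue)
    sig = p < alpha
    letters = _insert_absorb(sig, means)
    return LetterResult({g: letters[i] for i, g in enumerate(labels)},
                        p, labels)


def _insert_absorb(sig: np.ndarray, means: np.ndarray) -> list[str]:
    """Insert-and-absorb compact letter display.

    Maintains a list of letter columns (sets of group indices).  Each
    significant pair splits every column containing both members; columns
    that become subsets of others are absorbed.  Letters are assigned to
    the surviving columns in descending-mean order, so 'a' marks the
    highest groups — the convention of agronomy/food-science tables.
    """
    k = len(means)
    order = np.argsort(-means, kind="stable")  # descending mean
    columns: list[set[int]] = [set(range(k))]
    # fixed pair order (by descending-mean rank) for determinism
    pairs = [(order[i], order[j])
             for i in range(k) for j in range(i + 1, k)
             if sig[order[i], order[j]]]
    for i, j in pairs:
        new: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new.append(col - {i})
                new.append(col - {j})
            else:
                new.append(col)
        # absorb: drop any column that is a subset of another
        new = [c for c in new if c]
        columns = [c for idx, c in enumerate(new)
                   if not any(c < other or (c == other and idx > jdx)
                              for jdx, other in enumerate(new))]
    rank = {g: r for r, g in enumerate(order)}
    columns.sort(key=lambda c: tuple(sorted(rank[g] for g in c)))
    out = [""] * k
    for letter, col in zip(_letter_stream(), columns):
        for g in col:
            out[g] += letter
    return ["".join(sorted(s)) for s in out]


def _letter_stream():
    for ch in string.ascii_lowercase:
        yield ch
    # beyond 26 groups: aa, ab, ... (practically never reached)
    for ch1 in string.ascii_lowercase:
        for ch2 in string.ascii_lowercase:
            yield ch1 + ch2
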