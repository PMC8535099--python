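"""Brute-force reference implementations used only as test oracles.

Each oracle is written independently of the library code path it checks:
closed-form normal equations for the standard-curve fit, ranked Pearson
for Spearman, direct studentized-range pairwise tests for Tukey, and a
naive O(n^3) agglomerator for complete linkage.
"""

import numpy as np
from scipy import stats


def ols_normal_equations(x, y):
    """Slope/intercept of y on x via the closed-form normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = (x ** 2).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean()


def midrank(v):
    """Average ranks computed by direct comparison counting."""
    v = np.asarray(v, float)
    return np.array([1 + np.sum(v < x) + (np.sum(v == x) - 1) / 2.0 for x in v])


def ranked_pearson(x, y):
    """Spearman rho as the Pearson correlation of midranks."""
    rx, ry = midrank(x), midrank(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    return float((rxc * ryc).sum()
                 / np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum()))


def tukey_significant_pairs(groups, alpha=0.05):
    """All-pairs Tukey-Kramer decisions from the studentized-range quantile.

    Returns a boolean matrix over groups in the given (list) order:
    True where the pair differs significantly.
    """
    arrays = [np.asarray(g, float) for g in groups]
    k = len(arrays)
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df = int(ns.sum() - k)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    crit = stats.studentized_range.ppf(1 - alpha, k, df)
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            sig[i, j] = sig[j, i] = q > crit
    return sig


def complete_linkage_merges(dist):
    """Naive O(n^3) complete-linkage agglomeration.

    ``dist`` is a square distance matrix.  Returns the merge sequence as
    a list of (frozenset_members_a, frozenset_members_b, height), merging
    the globally closest cluster pair at each step (ties: smallest
    member indices).
    """
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                key = (d, tuple(sorted(clusters[a])), tuple(sorted(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        merges.append((clusters[a], clusters[b], d))
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return merges


def linkage_to_merges(z, n):
    """Convert a scipy linkage matrix into the oracle's merge-set form."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (a, b, d, _) in enumerate(z):
        ca, cb = members[int(a)], members[int(b)]
        merges.append((ca, cb, float(d)))
        members[n + row_idx] = ca | cb
    return merges
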