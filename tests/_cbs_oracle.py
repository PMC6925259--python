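"""Brute-force segmentation oracle shared by the CNV test modules.

Implements the same model (recursive circular max-t with a permutation
acceptance rule) by direct enumeration with plain Python loops and its own
random draws, independent of the vectorised cumulative-sum implementation
under test.  Boundary agreement is asserted only on instances whose
permutation p-values sit far from alpha, where the two independent
permutation streams must reach the same decision.
"""

import numpy as np


def _naive_max_t(x, min_width=2):
    """Brute-force max circular two-sample t over all arcs."""
    n = len(x)
    best = (0.0, 0, n)
    for i in range(n + 1):
        for j in range(i + min_width, n + 1):
            m = j - i
            if n - m < min_width:
                continue
            inside = x[i:j]
            outside = np.concatenate([x[:i], x[j:]])
            ss = ((inside - inside.mean()) ** 2).sum() \
                + ((outside - outside.mean()) ** 2).sum()
            diff = inside.mean() - outside.mean()
            if ss == 0:
                t = np.inf if diff != 0 else 0.0
            else:
                pooled = ss / (n - 2)
                t = abs(diff) / np.sqrt(pooled * (1 / m + 1 / (n - m)))
            if t > best[0]:
                best = (t, i, j)
    return best


def _naive_recursive_boundaries(x, min_width=2, alpha=0.01, n_perm=200,
                                seed=12345):
    """Exhaustive recursive segmentation with a brute-force permutation test."""
    rng = np.random.default_rng(seed)
    bounds = {0, len(x)}

    def rec(lo, hi):
        seg = x[lo:hi]
        t, i, j = _naive_max_t(seg, min_width)
        if t == 0.0:
            return
        exceed = sum(_naive_max_t(rng.permutation(seg), min_width)[0] >= t
                     for _ in range(n_perm))
        if (1 + exceed) / (1 + n_perm) >= alpha:
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        bounds.update(cuts)
        for a, b in zip(cuts[:-1], cuts[1:]):
            rec(a, b)

    rec(0, len(x))
    return sorted(bounds)
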