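"""Exact paired Wilcoxon signed-rank test and multiple-testing helpers.

The barrier-detection test asks whether per-locus cross-barrier FST values
are systematically larger than the paired background values, treating each
locus as the replicate unit.  The null distribution is obtained exactly by
dynamic programming over all 2^n sign assignments (equivalent to full
enumeration, and valid with tied ranks) for n <= 25 pairs, with a normal
approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs after dropping zero differences
    all_ties: bool = False


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray | None = None,
    alternative: str = "greater",
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test; one- or two-sided.

    ``alternative='greater'`` tests x > y (or x > 0 when y is omitted).
    Zero differences are dropped.  For n <= exact_max_n the p-value comes
    from the exact sign-flip distribution of W+ (average ranks for ties;
    DP over doubled ranks keeps sums integral).
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, all_ties=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        # counts[s] = number of sign assignments with doubled W+ == s
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        counts /= counts.sum()
        w2 = int(np.rint(2 * w_plus))
        p_ge = float(counts[w2:].sum())
        p_le = float(counts[: w2 + 1].sum())
    else:
        mean = n * (n + 1) / 4
        tie_corr = ((ranks[None, :] == ranks[:, None]).sum() - n) / 2  # pairs tied
        var = n * (n + 1) * (2 * n + 1) / 24 - tie_corr / 2
        z_ge = (w_plus - 0.5 - mean) / np.sqrt(var)
        z_le = (w_plus + 0.5 - mean) / np.sqrt(var)
        p_ge = float(sps.norm.sf(z_ge))
        p_le = float(sps.norm.cdf(z_le))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return WilcoxonResult(w_plus, min(p, 1.0), n)


def barrier_wilcoxon(
    fst_cross: np.ndarray, fst_background: np.ndarray
) -> WilcoxonResult:
    """One-sided test that cross-barrier FST exceeds background FST.

    Inputs are paired per-locus values (the same loci in the same order).
    """
    fst_cross = np.asarray(fst_cross, dtype=float)
    fst_background = np.asarray(fst_background, dtype=float)
    if fst_cross.shape != fst_background.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(fst_cross) | np.isnan(fst_background))
    fst_cross, fst_background = fst_cross[keep], fst_background[keep]
    if fst_cross.size < 5:
        raise ValueError("need at least 5 paired loci")
    return wilcoxon_signed_rank(fst_cross, fst_background, alternative="greater")


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg: boolean rejection mask at FDR level alpha."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.nonzero(passed)[0])
        reject[order[: k + 1]] = True
    return reject
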