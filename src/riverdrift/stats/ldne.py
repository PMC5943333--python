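"""Linkage-disequilibrium effective-size point estimate (Burrows r^2).

For every pair of loci and every pair of alleles across them, the Burrows
composite disequilibrium coefficient is computed from diploid dosages; the
mean squared correlation r^2 is bias-adjusted for sample size and inverted
to an Ne estimate with the random-mating quadratic of Waples (2006).
Confidence intervals are out of scope; only the point estimate is produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ..genotypes import MISSING, AlleleMatrix
from ._util import typed_mask


@dataclass
class LdNeResult:
    ne: float  # point estimate; inf when drift signal is absent
    r2_mean: float
    r2_adjusted: float
    n_comparisons: int
    harmonic_s: float  # harmonic mean sample size over locus pairs


def _locus_dosages(genos: np.ndarray, locus: int, maf: float) -> tuple[np.ndarray, np.ndarray]:
    """Dosage matrix (n x kept alleles) and typed mask at one locus."""
    mask = typed_mask(genos, locus)
    g = genos[:, locus, :]
    states, counts = np.unique(g[mask].ravel(), return_counts=True)
    keep = states != MISSING
    states, counts = states[keep], counts[keep]
    freqs = counts / counts.sum()
    states = states[freqs >= maf]
    dos = np.zeros((genos.shape[0], len(states)))
    for j, s in enumerate(states):
        dos[:, j] = (g == s).sum(axis=1)
    return dos, mask


def ld_ne(matrix: AlleleMatrix, pool: str, maf_threshold: float = 0.02) -> LdNeResult:
    """LD-based Ne point estimate for one pool (random mating assumed).

    Alleles with frequency below ``maf_threshold`` are excluded (rare
    alleles inflate r^2).  r^2' = r^2 - E[r^2 | Ne=inf] uses the S >= 30
    expectation 1/S + 3.19/S^2 and its small-sample counterpart below 30.
    """
    genos = matrix.pool_genotypes(pool)
    per_locus = [_locus_dosages(genos, l, maf_threshold) for l in range(matrix.n_loci)]
    usable = [i for i, (dos, _) in enumerate(per_locus) if dos.shape[1] >= 2]
    if len(usable) < 2:
        raise ValueError("need >= 2 polymorphic loci after rare-allele filtering")

    r2_vals: list[float] = []
    s_vals: list[float] = []
    for l1, l2 in combinations(usable, 2):
        dos1, m1 = per_locus[l1]
        dos2, m2 = per_locus[l2]
        both = m1 & m2
        s = int(both.sum())
        if s < 3:
            continue
        x = dos1[both]
        y = dos2[both]
        pair_r2 = []
        for i in range(x.shape[1]):
            p = x[:, i].mean() / 2
            if p <= 0 or p >= 1:
                continue
            for j in range(y.shape[1]):
                q = y[:, j].mean() / 2
                if q <= 0 or q >= 1:
                    continue
                delta = (s / (s - 1)) * ((x[:, i] * y[:, j]).mean() / 2 - 2 * p * q)
                r2 = delta**2 / (p * (1 - p) * q * (1 - q))
                pair_r2.append(r2)
        if pair_r2:
            r2_vals.append(float(np.mean(pair_r2)))
            s_vals.append(s)
    if not r2_vals:
        raise ValueError("no usable locus pairs")
    r2_mean = float(np.mean(r2_vals))
    s_harm = len(s_vals) / np.sum(1.0 / np.asarray(s_vals))

    if s_harm >= 30:
        expected = 1.0 / s_harm + 3.19 / s_harm**2
    else:
        expected = 0.0018 + 0.907 / s_harm + 4.44 / s_harm**2
    r2_adj = r2_mean - expected

    ne = np.inf
    if r2_adj > 0:
        if s_harm >= 30:
            disc = 1.0 / 9.0 - 2.76 * r2_adj
            ne = (1.0 / 3.0 + np.sqrt(disc)) / (2 * r2_adj) if disc >= 0 else (1.0 / 3.0) / (2 * r2_adj)
        else:
            disc = 0.308**2 - 2.08 * r2_adj
            ne = (0.308 + np.sqrt(disc)) / (2 * r2_adj) if disc >= 0 else 0.308 / (2 * r2_adj)
        ne = max(ne, 0.0)
    return LdNeResult(float(ne), r2_mean, float(r2_adj), len(r2_vals), float(s_harm))
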