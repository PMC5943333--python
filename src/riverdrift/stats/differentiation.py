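"""Between-pool differentiation: Weir–Cockerham theta (FST) and Jost's D.

Theta follows the 1984 variance-component estimator: per allele and locus,
components a (among populations), b (among individuals within populations)
and c (within individuals); the multilocus estimate is the ratio of summed
components.  Negative estimates are reported as computed, not truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genotypes import MISSING, AlleleMatrix
from ._util import typed_mask


def _wc_components_locus(groups: list[np.ndarray], locus: int) -> tuple[float, float, float]:
    """Summed-over-alleles WC (a, b, c) at one locus for r >= 2 groups.

    Each group is a genotype array (n_i, n_loci, 2); individuals missing at
    the locus are dropped group-wise.
    """
    gs = []
    for g in groups:
        m = typed_mask(g, locus)
        if m.sum() > 0:
            gs.append(g[m, locus, :])
    r = len(gs)
    if r < 2:
        return 0.0, 0.0, 0.0
    n_i = np.array([g.shape[0] for g in gs], dtype=float)
    n_tot = n_i.sum()
    nbar = n_tot / r
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    states = np.unique(np.concatenate([g.ravel() for g in gs]))
    states = states[states != MISSING]
    if len(states) <= 1:
        return 0.0, 0.0, 0.0
    a_sum = b_sum = c_sum = 0.0
    for s in states:
        p_i = np.array([(g == s).sum() / (2 * g.shape[0]) for g in gs])
        h_i = np.array([((g == s).sum(axis=1) == 1).mean() for g in gs])
        pbar = (n_i * p_i).sum() / n_tot
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / n_tot
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def wc_theta(groups: list[np.ndarray], n_loci: int | None = None) -> tuple[float, np.ndarray]:
    """Multilocus and per-locus WC theta for genotype-array groups."""
    if n_loci is None:
        n_loci = groups[0].shape[1]
    a = np.zeros(n_loci)
    d = np.zeros(n_loci)
    for l in range(n_loci):
        al, bl, cl = _wc_components_locus(groups, l)
        a[l] = al
        d[l] = al + bl + cl
    per_locus = np.where(d != 0, a / np.where(d == 0, 1.0, d), np.nan)
    total = a.sum() / d.sum() if d.sum() != 0 else np.nan
    return float(total), per_locus


@dataclass
class FstResult:
    theta: float
    theta_by_locus: np.ndarray
    p_value: float | None = None
    permutations: int = 0


def fst_wc(
    matrix: AlleleMatrix,
    pool_a: str,
    pool_b: str,
    permutations: int = 0,
    seed: int | None = None,
) -> FstResult:
    """Pairwise WC theta between two pools with an optional permutation test.

    The permutation null shuffles individuals between the two pools keeping
    pool sizes; p is the fraction of permuted data sets with theta >= the
    observed value (add-one corrected).
    """
    ga = matrix.pool_genotypes(pool_a)
    gb = matrix.pool_genotypes(pool_b)
    if ga.shape[0] < 2 or gb.shape[0] < 2:
        raise ValueError("each pool needs at least 2 individuals")
    theta, per_locus = wc_theta([ga, gb])
    if np.isnan(theta):
        raise ValueError("theta undefined: both pools monomorphic at all loci")
    p_value = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        combined = np.concatenate([ga, gb], axis=0)
        na = ga.shape[0]
        hits = 0
        for _ in range(permutations):
            idx = rng.permutation(combined.shape[0])
            t, _ = wc_theta([combined[idx[:na]], combined[idx[na:]]])
            if not np.isnan(t) and t >= theta:
                hits += 1
        p_value = (hits + 1) / (permutations + 1)
    return FstResult(theta, per_locus, p_value, permutations)


def pairwise_fst_table(
    matrix: AlleleMatrix, pools: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric matrix of pairwise multilocus theta between pools."""
    pools = pools or matrix.pools
    out = pd.DataFrame(np.nan, index=pools, columns=pools, dtype=float)
    genos = {p: matrix.pool_genotypes(p) for p in pools}
    for i, a in enumerate(pools):
        out.loc[a, a] = 0.0
        for b in pools[i + 1 :]:
            theta, _ = wc_theta([genos[a], genos[b]])
            out.loc[a, b] = theta
            out.loc[b, a] = theta
    return out


def _nei_chesser_d_locus(ga: np.ndarray, gb: np.ndarray, locus: int) -> float:
    """Jost's D at one locus from Nei–Chesser unbiased Hs/Ht (r = 2)."""
    parts = []
    for g in (ga, gb):
        m = typed_mask(g, locus)
        if m.sum() < 2:
            return np.nan
        gg = g[m, locus, :]
        states, counts = np.unique(gg.ravel(), return_counts=True)
        keep = states != MISSING
        states, counts = states[keep], counts[keep]
        p = counts / counts.sum()
        ho = float((gg[:, 0] != gg[:, 1]).mean())
        parts.append((gg.shape[0], dict(zip(states, p)), ho))
    (n1, p1, ho1), (n2, p2, ho2) = parts
    states = sorted(set(p1) | set(p2))
    if len(states) <= 1:
        return np.nan
    r = 2
    ntilde = r / (1 / n1 + 1 / n2)
    ho_bar = (ho1 + ho2) / 2
    sum_within = sum(p1.get(s, 0.0) ** 2 + p2.get(s, 0.0) ** 2 for s in states) / r
    hs_plug = 1.0 - sum_within
    hs = (ntilde / (ntilde - 1)) * (hs_plug - ho_bar / (2 * ntilde))
    pbar2 = sum(((p1.get(s, 0.0) + p2.get(s, 0.0)) / r) ** 2 for s in states)
    ht = 1.0 - pbar2 + hs / (r * ntilde) - ho_bar / (2 * r * ntilde)
    if hs >= 1.0:
        return np.nan
    return (ht - hs) / (1.0 - hs) * r / (r - 1)


def jost_dest(matrix: AlleleMatrix, pool_a: str, pool_b: str) -> tuple[float, np.ndarray]:
    """Jost's differentiation D between two pools.

    Loci are combined by the harmonic mean when every per-locus D is
    positive (the usual recommendation); otherwise the arithmetic mean is
    used, since a harmonic mean is undefined across signs.
    """
    ga = matrix.pool_genotypes(pool_a)
    gb = matrix.pool_genotypes(pool_b)
    per_locus = np.array(
        [_nei_chesser_d_locus(ga, gb, l) for l in range(matrix.n_loci)]
    )
    usable = per_locus[~np.isnan(per_locus)]
    if usable.size == 0:
        raise ValueError("D undefined: no polymorphic locus")
    if (usable > 0).all():
        multi = len(usable) / (1.0 / usable).sum()
    else:
        multi = float(usable.mean())
    return float(multi), per_locus
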