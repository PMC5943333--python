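"""Heterozygosity-excess bottleneck test (Cornuet–Luikart style).

A recently bottlenecked population loses alleles faster than gene
diversity, so its observed He exceeds the equilibrium He expected for the
observed allele count.  For each locus an equilibrium distribution of He
given the allele count k is built from single-population coalescent samples
under the chosen microsatellite mutation model: theta is tuned by bisection
so simulated allele counts centre on the observed k, then replicates are
rejection-sampled until the allele count matches exactly.  Per-locus
standardized differences (He_obs - mean He_eq)/sd feed a one-tailed
Wilcoxon signed-rank test across loci, plus the qualitative mode-shift
indicator on the pooled allele-frequency spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ..genotypes import MISSING, AlleleMatrix
from ._util import typed_mask
from .testing import WilcoxonResult, wilcoxon_signed_rank

# (p_single_step, p_geometric) per mutation model; the multi-step component
# is 1 + Geometric-failures with variance p/(1-p)^2.
SMM = (1.0, 0.0)
TPM = (0.70, 5.0 / 6.0)  # multi-step variance 30


@njit(cache=True)
def _batch_k_he(n_genes, theta, p_single, p_geo, reps, seed):
    """Allele count and unbiased He of `reps` equilibrium coalescent samples."""
    np.random.seed(seed)
    ks = np.empty(reps, np.int64)
    hes = np.empty(reps, np.float64)
    n_nodes = 2 * n_genes - 1
    parent = np.empty(n_nodes, np.int64)
    time = np.empty(n_nodes, np.float64)
    state = np.empty(n_nodes, np.int64)
    active = np.empty(n_genes, np.int64)
    for rep in range(reps):
        # Kingman genealogy with times in units of 2N generations
        for i in range(n_genes):
            active[i] = i
            time[i] = 0.0
        k = n_genes
        nxt = n_genes
        t = 0.0
        while k > 1:
            t += np.random.exponential(2.0 / (k * (k - 1)))
            i = np.random.randint(k)
            j = np.random.randint(k - 1)
            if j >= i:
                j += 1
            parent[active[i]] = nxt
            parent[active[j]] = nxt
            time[nxt] = t
            lo = i if i < j else j
            hi = j if i < j else i
            active[lo] = nxt
            active[hi] = active[k - 1]
            k -= 1
            nxt += 1
        parent[n_nodes - 1] = -1
        # mutations root-down; states are unbounded integers
        state[n_nodes - 1] = 0
        for node in range(n_nodes - 2, -1, -1):
            length = time[parent[node]] - time[node]
            nmut = np.random.poisson(0.5 * theta * length)
            s = state[parent[node]]
            for _ in range(nmut):
                if np.random.random() < p_single:
                    step = 1
                else:
                    step = np.random.geometric(1.0 - p_geo)  # 1 + failures
                if np.random.random() < 0.5:
                    s += step
                else:
                    s -= step
            state[node] = s
        leaves = state[:n_genes]
        lo_s = leaves.min()
        counts = np.bincount(leaves - lo_s)
        nz = counts[counts > 0]
        ks[rep] = nz.size
        p2 = 0.0
        for c in nz:
            p2 += (c / n_genes) ** 2
        hes[rep] = (n_genes / (n_genes - 1.0)) * (1.0 - p2)
    return ks, hes


@dataclass
class BottleneckResult:
    p_value: float  # one-tailed Wilcoxon for heterozygosity excess
    dh_sd: np.ndarray  # per-locus standardized differences
    locus_names: list[str]
    mode_shift: bool | None  # None when < 5 polymorphic loci
    wilcoxon: WilcoxonResult | None = None
    skipped_loci: list[str] = field(default_factory=list)


def _equilibrium_he_given_k(
    n_genes: int,
    k_obs: int,
    model: tuple[float, float],
    iters: int,
    seed: int,
    budget_factor: int = 200,
) -> np.ndarray | None:
    """He values of equilibrium samples conditioned on allele count k_obs."""
    p_single, p_geo = model
    rng = np.random.default_rng(seed)

    def batch(theta: float, reps: int) -> tuple[np.ndarray, np.ndarray]:
        s = int(rng.integers(1, 2**31 - 1))
        return _batch_k_he(n_genes, theta, p_single, p_geo, reps, s)

    lo, hi = 0.005, 400.0
    for _ in range(14):
        mid = np.sqrt(lo * hi)
        ks, _ = batch(mid, 30)
        if ks.mean() < k_obs:
            lo = mid
        else:
            hi = mid
    theta_star = np.sqrt(lo * hi)

    accepted: list[float] = []
    tried = 0
    budget = budget_factor * iters
    while len(accepted) < iters and tried < budget:
        reps = min(4 * iters, budget - tried)
        ks, hes = batch(theta_star, reps)
        tried += reps
        accepted.extend(hes[ks == k_obs].tolist())
    if len(accepted) < max(20, iters // 10):
        return None
    return np.asarray(accepted[:iters])


def heterozygosity_excess_test(
    matrix: AlleleMatrix,
    pool: str,
    model: tuple[float, float] = TPM,
    iters: int = 1000,
    seed: int | None = None,
) -> BottleneckResult:
    """Test a pool for heterozygosity excess relative to drift-mutation
    equilibrium under SMM or TPM.

    Requires >= 4 polymorphic loci for the Wilcoxon step; the mode-shift
    indicator needs >= 5.
    """
    genos = matrix.pool_genotypes(pool)
    rng = np.random.default_rng(seed)
    dh = []
    names = []
    skipped = []
    poly = 0
    all_freqs: list[np.ndarray] = []
    for l, name in enumerate(matrix.locus_names):
        mask = typed_mask(genos, l)
        g = genos[mask, l, :]
        n_genes = 2 * g.shape[0]
        if n_genes < 4:
            skipped.append(name)
            continue
        states, counts = np.unique(g.ravel(), return_counts=True)
        keep = states != MISSING
        counts = counts[keep]
        k_obs = counts.size
        if k_obs < 2:
            skipped.append(name)
            continue
        poly += 1
        p = counts / counts.sum()
        all_freqs.append(p)
        he_obs = (n_genes / (n_genes - 1.0)) * (1.0 - float((p**2).sum()))
        he_eq = _equilibrium_he_given_k(
            n_genes, k_obs, model, iters, int(rng.integers(1, 2**31 - 1))
        )
        if he_eq is None or he_eq.std() == 0:
            skipped.append(name)
            continue
        dh.append((he_obs - he_eq.mean()) / he_eq.std())
        names.append(name)
    if poly < 4 or len(dh) < 4:
        raise ValueError("heterozygosity-excess test needs >= 4 usable polymorphic loci")

    wres = wilcoxon_signed_rank(np.asarray(dh), alternative="greater")

    mode_shift: bool | None = None
    if poly >= 5:
        freqs = np.concatenate(all_freqs)
        hist, _ = np.histogram(freqs, bins=np.arange(0.0, 1.0001, 0.1))
        mode_shift = int(np.argmax(hist)) != 0
    return BottleneckResult(wres.p_value, np.asarray(dh), names, mode_shift, wres, skipped)
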