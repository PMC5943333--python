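"""Hardy–Weinberg exact probability test (Monte-Carlo, GENEPOP-style).

Conditional on the observed allele counts, genotype tables are generated by
random pairing of the allele multiset; the p-value is the probability of a
table with conditional (Levene) probability no larger than the observed
one.  Only the table-dependent part of the log-probability is needed:
h*log(2) - sum log(n_ab!), with h the number of heterozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from ..genotypes import AlleleMatrix
from ._util import typed_mask


@dataclass
class HweResult:
    p_value: float
    monomorphic: bool = False
    reps: int = 0


def _log_table_prob(pairs: np.ndarray, n_states: int) -> float:
    """Variable part of log P(table | allele counts) for (n, 2) allele pairs."""
    a = np.minimum(pairs[:, 0], pairs[:, 1])
    b = np.maximum(pairs[:, 0], pairs[:, 1])
    key = a * n_states + b
    counts = np.bincount(key)
    counts = counts[counts > 0]
    h = int((a != b).sum())
    return h * np.log(2.0) - float(gammaln(counts + 1.0).sum())


def hwe_exact_test(
    matrix: AlleleMatrix,
    pool: str,
    locus: int,
    reps: int = 10_000,
    seed: int | None = None,
) -> HweResult:
    """Monte-Carlo exact HWE test for one locus in one pool."""
    genos = matrix.pool_genotypes(pool)
    mask = typed_mask(genos, locus)
    g = genos[mask, locus, :]
    if g.shape[0] == 0:
        raise ValueError(f"locus {locus} has no data in pool {pool}")
    alleles = g.ravel()
    if np.unique(alleles).size <= 1:
        return HweResult(1.0, monomorphic=True)
    n_states = int(alleles.max()) + 1
    obs = _log_table_prob(g, n_states)
    rng = np.random.default_rng(seed)
    hits = 0
    work = alleles.copy()
    for _ in range(reps):
        rng.shuffle(work)
        sim = _log_table_prob(work.reshape(-1, 2), n_states)
        if sim <= obs + 1e-12:
            hits += 1
    return HweResult((hits + 1) / (reps + 1), reps=reps)
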