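"""Within-pool diversity: Ho/He, Weir–Cockerham FIS, rarefied allelic
richness, and the effective inbreeding coefficient.

He is Nei's unbiased estimator (2n/(2n-1))(1 - sum p^2), the GENEPOP
convention; the plug-in frequency version 1 - sum p^2 is downward-biased at
small n, noticeably so below ~20 individuals.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from ..genotypes import MISSING, AlleleMatrix
from ._util import locus_allele_counts, typed_mask


def heterozygosity(matrix: AlleleMatrix, pool: str) -> tuple[pd.DataFrame, float, float]:
    """Per-locus Ho and unbiased He plus their unweighted multilocus means.

    Returns (per_locus_table, Ho_mean, He_mean); loci with no typed
    individuals are dropped with a warning.
    """
    genos = matrix.pool_genotypes(pool)
    rows = []
    for l, name in enumerate(matrix.locus_names):
        mask = typed_mask(genos, l)
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"locus {name} has no data in pool {pool}; excluded")
            continue
        g = genos[mask, l, :]
        ho = float((g[:, 0] != g[:, 1]).mean())
        _, counts = locus_allele_counts(genos, l)
        p = counts / counts.sum()
        if len(p) <= 1:
            he = 0.0
        else:
            he = (2 * n / (2 * n - 1)) * (1.0 - float((p**2).sum()))
        rows.append({"locus": name, "n": n, "Ho": ho, "He": he})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError(f"no usable loci in pool {pool}")
    return table, float(table["Ho"].mean()), float(table["He"].mean())


def _fis_components(genos: np.ndarray, locus: int) -> tuple[float, float]:
    """Weir–Cockerham within-population components (b, c) summed over alleles."""
    mask = typed_mask(genos, locus)
    n = int(mask.sum())
    if n < 2:
        return 0.0, 0.0
    g = genos[mask, locus, :]
    states, counts = locus_allele_counts(genos[mask], locus)
    if len(states) <= 1:
        return 0.0, 0.0
    b_sum = c_sum = 0.0
    for s, cnt in zip(states, counts):
        p = cnt / (2 * n)
        h = float(((g == s).sum(axis=1) == 1).mean())
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2
        b_sum += b
        c_sum += c
    return b_sum, c_sum


def fis_wc(matrix: AlleleMatrix, pool: str) -> tuple[float, pd.Series]:
    """Weir–Cockerham small f (FIS) per locus and multilocus.

    Multilocus f sums variance components over loci; a pool monomorphic at
    every locus yields NaN.
    """
    genos = matrix.pool_genotypes(pool)
    if genos.shape[0] < 2:
        raise ValueError("FIS needs at least 2 individuals")
    per_locus = {}
    b_tot = c_tot = 0.0
    for l, name in enumerate(matrix.locus_names):
        b, c = _fis_components(genos, l)
        per_locus[name] = 1.0 - c / (b + c) if (b + c) > 0 else np.nan
        b_tot += b
        c_tot += c
    multi = 1.0 - c_tot / (b_tot + c_tot) if (b_tot + c_tot) > 0 else np.nan
    return multi, pd.Series(per_locus)


def allelic_richness(matrix: AlleleMatrix, pool: str, g: int) -> tuple[pd.Series, float]:
    """Rarefied allelic richness: expected allele count in g sampled genes.

    Ar = sum_a [1 - C(N - N_a, g) / C(N, g)] with N the typed gene count and
    N_a the copies of allele a (hypergeometric rarefaction).
    """
    if g < 1:
        raise ValueError("rarefaction size must be >= 1 gene")
    genos = matrix.pool_genotypes(pool)
    out = {}
    for l, name in enumerate(matrix.locus_names):
        states, counts = locus_allele_counts(genos, l)
        n_genes = int(counts.sum())
        if n_genes == 0:
            out[name] = np.nan
            continue
        if g > n_genes:
            raise ValueError(
                f"rarefaction size {g} exceeds {n_genes} genes at locus {name} in pool {pool}"
            )
        denom = math.comb(n_genes, g)
        ar = 0.0
        for c in counts:
            ar += 1.0 - math.comb(n_genes - int(c), g) / denom
        out[name] = ar
    series = pd.Series(out)
    return series, float(series.mean())


def effective_inbreeding(he_focal: float, he_ref: float) -> float:
    """Fe = 1 - He_focal / He_ref (Fe > 0: diversity deficit vs reference)."""
    if he_ref <= 0:
        raise ValueError("reference He must be positive")
    return 1.0 - he_focal / he_ref


def diversity_summary(
    matrix: AlleleMatrix,
    rarefaction_g: int | None = None,
    reference_pools: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per pool: n, Na, Ar, Ho, He, FIS (and Fe against a reference).

    ``reference_pools`` maps a pool to the pool whose He serves as the
    outbred reference for Fe (e.g. above-barrier -> below-barrier).
    """
    rows = []
    he_by_pool: dict[str, float] = {}
    for p in matrix.pools:
        genos = matrix.pool_genotypes(p)
        na = np.mean(
            [len(locus_allele_counts(genos, l)[0]) for l in range(matrix.n_loci)]
        )
        _, ho, he = heterozygosity(matrix, p)
        he_by_pool[p] = he
        fis, _ = fis_wc(matrix, p)
        row = {"pool": p, "n": genos.shape[0], "Na": float(na), "Ho": ho, "He": he, "FIS": fis}
        if rarefaction_g is not None:
            _, row["Ar"] = allelic_richness(matrix, p, rarefaction_g)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("pool")
    if reference_pools:
        table["Fe"] = [
            effective_inbreeding(he_by_pool[p], he_by_pool[reference_pools[p]])
            if p in reference_pools
            else np.nan
            for p in table.index
        ]
    return table
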