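"""Shared low-level helpers for genotype statistics."""

from __future__ import annotations

import numpy as np

from ..genotypes import MISSING


def locus_allele_counts(genos: np.ndarray, locus: int) -> tuple[np.ndarray, np.ndarray]:
    """(allele states, counts) among non-missing gene copies at one locus."""
    alleles = genos[:, locus, :].ravel()
    alleles = alleles[alleles != MISSING]
    if alleles.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    states, counts = np.unique(alleles, return_counts=True)
    return states, counts


def typed_mask(genos: np.ndarray, locus: int) -> np.ndarray:
    """Boolean mask of individuals with a non-missing genotype at locus."""
    return genos[:, locus, 0] != MISSING


def allele_freqs(genos: np.ndarray, locus: int) -> dict[int, float]:
    states, counts = locus_allele_counts(genos, locus)
    total = counts.sum()
    return {int(s): c / total for s, c in zip(states, counts)}
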