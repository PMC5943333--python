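"""Background spatial structure: Ritland kinship autocorrelograms and
isolation-by-distance regression with Mantel tests.

The IBD regression follows Rousset's linearization: pairwise FST/(1-FST)
between sample sites is regressed on river distance in metres; under
one-dimensional habitat the expected slope is 1/(4 D sigma^2) with D the
effective density per metre and sigma^2 the axial dispersal variance.  The
Mantel statistic is the regression slope itself (one-tailed for a positive
association), permuting site identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genotypes import MISSING, AlleleMatrix
from ._util import typed_mask
from .differentiation import wc_theta


def ritland_kinship(matrix: AlleleMatrix, reference_pool: str | None = None) -> np.ndarray:
    """Pairwise Ritland kinship matrix over all individuals.

    Per locus F_ij = [sum_a x_ia x_ja / p_a - 1] / (k - 1) with x the allele
    dosage / 2 and p_a reference frequencies; loci are combined weighting by
    (k_l - 1).  Reference frequencies come from the whole analysis set by
    default (SPAGeDi convention) or from one pool.
    """
    n = matrix.n_individuals
    ref = matrix.pool_genotypes(reference_pool) if reference_pool else matrix.genotypes
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for l in range(matrix.n_loci):
        ref_states, ref_counts = np.unique(ref[:, l, :].ravel(), return_counts=True)
        keep = ref_states != MISSING
        ref_states, ref_counts = ref_states[keep], ref_counts[keep]
        if ref_states.size <= 1:
            continue
        p = ref_counts / ref_counts.sum()
        k = ref_states.size
        valid = typed_mask(matrix.genotypes, l)
        g = matrix.genotypes[:, l, :]
        x = np.zeros((n, k))
        observed_extras = False
        for j, s in enumerate(ref_states):
            x[:, j] = (g == s).sum(axis=1) / 2.0
        # alleles absent from the reference cannot be scored at this locus
        dose_total = (g != MISSING).sum(axis=1) / 2.0
        extra = valid & (x.sum(axis=1) < dose_total)
        if extra.any():
            observed_extras = True
            x[extra] = x[extra] * 0  # drop the locus for those individuals
            valid = valid & ~extra
        if observed_extras:
            warnings.warn(f"locus {matrix.locus_names[l]}: alleles missing from reference excluded")
        s_mat = (x / p) @ x.T
        pair_valid = np.outer(valid, valid)
        num += np.where(pair_valid, s_mat - 1.0, 0.0)
        den += np.where(pair_valid, k - 1.0, 0.0)
    with np.errstate(invalid="ignore"):
        kin = np.where(den > 0, num / np.where(den == 0, 1.0, den), np.nan)
    np.fill_diagonal(kin, np.nan)
    return kin


@dataclass
class Autocorrelogram:
    class_edges: np.ndarray  # metres; class 0 is the co-located class
    mean_kinship: np.ndarray
    pair_counts: np.ndarray
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    significant: np.ndarray


def _class_index(dist: np.ndarray, class_width: float, n_classes: int) -> np.ndarray:
    """Class 0 = identical positions; class j >= 1 covers ((j-1)w, jw]."""
    idx = np.ceil(dist / class_width).astype(int)
    idx[dist == 0] = 0
    return np.clip(idx, 0, n_classes - 1)


def autocorrelogram(
    kinship: np.ndarray,
    positions: np.ndarray,
    class_width: float = 2000.0,
    max_distance: float | None = None,
    permutations: int = 10_000,
    seed: int | None = None,
) -> Autocorrelogram:
    """Distance-class means of pairwise kinship with a permutation envelope.

    The null shuffles individual locations (positions permuted among
    individuals), which covers both the co-located class and the distance
    classes; flags mark observed means outside the central 95% envelope.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.size
    iu = np.triu_indices(n, k=1)
    kin_pairs = kinship[iu]
    ok = ~np.isnan(kin_pairs)

    if max_distance is None:
        max_distance = float(np.abs(positions[:, None] - positions[None, :]).max())
    n_classes = max(1, int(np.ceil(max_distance / class_width))) + 1

    def class_means(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.abs(pos[iu[0]] - pos[iu[1]])
        idx = _class_index(d, class_width, n_classes)
        sums = np.bincount(idx[ok], weights=kin_pairs[ok], minlength=n_classes)
        counts = np.bincount(idx[ok], minlength=n_classes)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts

    obs_mean, obs_counts = class_means(positions)

    rng = np.random.default_rng(seed)
    perm_means = np.empty((permutations, n_classes))
    for b in range(permutations):
        perm_means[b], _ = class_means(rng.permutation(positions))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        low = np.nanpercentile(perm_means, 2.5, axis=0)
        high = np.nanpercentile(perm_means, 97.5, axis=0)
    significant = (obs_counts > 0) & ((obs_mean < low) | (obs_mean > high))

    edges = np.concatenate([[0.0], np.arange(1, n_classes) * class_width])
    return Autocorrelogram(edges, obs_mean, obs_counts, low, high, significant)


@dataclass
class IbdFit:
    slope: float  # per metre
    intercept: float
    mantel_p: float
    linearized_fst: pd.DataFrame
    distances_m: pd.DataFrame
    excluded_pairs: list[tuple[str, str]]


def _pairs_slope(y: np.ndarray, x: np.ndarray, iu: tuple) -> tuple[float, float]:
    yv, xv = y[iu], x[iu]
    keep = np.isfinite(yv)
    yv, xv = yv[keep], xv[keep]
    vx = xv.var()
    if vx == 0:
        raise ValueError("all pairwise distances equal; slope undefined")
    slope = float(np.cov(xv, yv, bias=True)[0, 1] / vx)
    return slope, float(yv.mean() - slope * xv.mean())


def ibd_regression(
    matrix: AlleleMatrix,
    permutations: int = 10_000,
    seed: int | None = None,
) -> IbdFit:
    """Isolation-by-distance fit over the sample sites of a matrix.

    Sites (metadata ``site``; positions from ``position_m`` means) are the
    analysis units.  Pairs with FST = 1 cannot be linearized and are
    excluded with a warning.
    """
    meta = matrix.individuals
    sites = list(dict.fromkeys(meta["site"]))
    if len(sites) < 3:
        raise ValueError("IBD regression needs at least 3 sites")
    pos = np.array([meta.loc[meta["site"] == s, "position_m"].mean() for s in sites])
    groups = [matrix.genotypes[(meta["site"] == s).to_numpy()] for s in sites]

    k = len(sites)
    y = np.full((k, k), np.nan)
    excluded = []
    for i in range(k):
        for j in range(i + 1, k):
            theta, _ = wc_theta([groups[i], groups[j]])
            if np.isnan(theta) or theta >= 1.0:
                if theta >= 1.0:
                    warnings.warn(f"FST=1 between {sites[i]} and {sites[j]}; pair excluded")
                    excluded.append((sites[i], sites[j]))
                continue
            y[i, j] = y[j, i] = theta / (1.0 - theta)
    x = np.abs(pos[:, None] - pos[None, :])

    iu = np.triu_indices(k, k=1)
    slope, intercept = _pairs_slope(y, x, iu)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        idx = rng.permutation(k)
        yp = y[np.ix_(idx, idx)]
        s, _ = _pairs_slope(yp, x, iu)
        if s >= slope:
            hits += 1
    mantel_p = (hits + 1) / (permutations + 1)

    return IbdFit(
        slope,
        intercept,
        mantel_p,
        pd.DataFrame(y, index=sites, columns=sites),
        pd.DataFrame(x, index=sites, columns=sites),
        excluded,
    )
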