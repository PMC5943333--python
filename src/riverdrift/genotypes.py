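"""Diploid microsatellite genotype container and empirical-like fixtures.

The central data structure is :class:`AlleleMatrix`: an ``(n_individuals,
n_loci, 2)`` integer array of allele states together with per-individual
metadata (stream, site, position along the stream in metres, side relative
to a barrier, and pool label).  Allele states are small positive integers
(repeat classes); 0 is the reserved missing code.  Every statistic in the
package consumes this container, whether the genotypes came from a Genepop
file or from the coalescent simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0

META_COLUMNS = ["id", "stream", "site", "position_m", "side", "pool"]


@dataclass
class AlleleMatrix:
    """Diploid genotypes plus sample metadata.

    Parameters
    ----------
    individuals : pandas.DataFrame
        One row per individual with columns ``id, stream, site, position_m,
        side, pool``.  ``side`` is one of ``{"above", "below", "none"}``.
    genotypes : numpy.ndarray
        Integer array of shape ``(n_individuals, n_loci, 2)``; allele states
        are positive integers, 0 means missing.  Both alleles of a genotype
        are missing together.
    locus_names : list of str
    """

    individuals: pd.DataFrame
    genotypes: np.ndarray
    locus_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, n_loci, 2)")
        n, n_loci, _ = self.genotypes.shape
        if len(self.individuals) != n:
            raise ValueError("metadata rows do not match genotype rows")
        if n_loci < 1:
            raise ValueError("need at least one locus")
        if not self.locus_names:
            self.locus_names = [f"locus_{i + 1}" for i in range(n_loci)]
        if len(self.locus_names) != n_loci:
            raise ValueError("locus_names length mismatch")
        missing = self.individuals.columns.symmetric_difference(META_COLUMNS)
        extra = set(META_COLUMNS) - set(self.individuals.columns)
        if extra:
            raise ValueError(f"metadata missing columns: {sorted(extra)}")
        if (self.genotypes < 0).any():
            raise ValueError("allele states must be >= 0 (0 = missing)")
        half_missing = (self.genotypes == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("both alleles of a genotype must be missing together")
        if self.individuals["pool"].isna().any():
            raise ValueError("every individual needs a pool label")
        self.individuals = self.individuals.reset_index(drop=True)

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def pools(self) -> list[str]:
        return list(dict.fromkeys(self.individuals["pool"]))

    def pool_genotypes(self, pool: str) -> np.ndarray:
        """Genotypes of one pool, shape (n_pool, n_loci, 2)."""
        mask = (self.individuals["pool"] == pool).to_numpy()
        if not mask.any():
            raise KeyError(f"no individuals in pool {pool!r}")
        return self.genotypes[mask]

    def subset(self, mask: np.ndarray) -> "AlleleMatrix":
        mask = np.asarray(mask)
        return AlleleMatrix(
            self.individuals.loc[mask].reset_index(drop=True),
            self.genotypes[mask],
            list(self.locus_names),
        )


@dataclass
class PoolSpec:
    """Site-to-pool mapping used to merge neighbouring sample sites."""

    site_to_pool: Mapping[str, str]
    pool_order: Sequence[str] | None = None


def pool(matrix: AlleleMatrix, spec: PoolSpec) -> AlleleMatrix:
    """Rewrite pool labels according to ``spec``; genotypes are untouched."""
    sites = matrix.individuals["site"]
    unmapped = sorted(set(sites) - set(spec.site_to_pool))
    if unmapped:
        raise KeyError(f"sites not covered by pool spec: {unmapped}")
    meta = matrix.individuals.copy()
    meta["pool"] = sites.map(spec.site_to_pool)
    return AlleleMatrix(meta, matrix.genotypes.copy(), list(matrix.locus_names))


def simple_metadata(
    n: int,
    pool_label: str = "pool1",
    stream: str = "stream1",
    site: str | None = None,
    position_m: float = 0.0,
    side: str = "none",
    id_prefix: str = "ind",
    start: int = 0,
) -> pd.DataFrame:
    """Metadata block for n individuals sharing one site/pool."""
    return pd.DataFrame(
        {
            "id": [f"{id_prefix}{start + i + 1}" for i in range(n)],
            "stream": stream,
            "site": site if site is not None else pool_label,
            "position_m": float(position_m),
            "side": side,
            "pool": pool_label,
        }
    )


def concat_matrices(matrices: Sequence[AlleleMatrix]) -> AlleleMatrix:
    """Stack matrices that share the same loci."""
    names = matrices[0].locus_names
    for m in matrices[1:]:
        if m.locus_names != names:
            raise ValueError("locus names differ between matrices")
    meta = pd.concat([m.individuals for m in matrices], ignore_index=True)
    genos = np.concatenate([m.genotypes for m in matrices], axis=0)
    return AlleleMatrix(meta, genos, list(names))


# -- empirical-like fixture generator -------------------------------------


@dataclass
class PoolFixture:
    """One pool of the fixture: size, loci, and per-locus diversity targets."""

    pool_label: str
    n_individuals: int
    target_he: Sequence[float]
    n_alleles: Sequence[int]
    stream: str = "stream1"
    site: str | None = None
    position_m: float = 0.0
    side: str = "none"


@dataclass
class FixtureConfig:
    pools: Sequence[PoolFixture]
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.pools:
            if p.n_individuals <= 0:
                raise ValueError("pool sizes must be positive")
            if len(p.target_he) != len(p.n_alleles):
                raise ValueError("target_he and n_alleles lengths differ")
            for he, k in zip(p.target_he, p.n_alleles):
                if k < 1:
                    raise ValueError("need at least one allele")
                if not 0.0 <= he < 1.0:
                    raise ValueError("target He must be in [0, 1)")
                if k > 1 and he >= 1.0 - 1.0 / k:
                    raise ValueError(
                        f"He={he} unreachable with {k} alleles (max {1 - 1 / k:.3f})"
                    )
                if k == 1 and he > 0:
                    raise ValueError("monomorphic locus cannot have He > 0")


def _frequencies_for_he(k: int, target_he: float, rng: np.random.Generator) -> np.ndarray:
    """Allele frequencies with frequency-He (1 - sum p^2) == target_he.

    A random Dirichlet draw is sharpened/flattened by a power transform
    p(t) = q**t / sum(q**t): t=0 gives uniform frequencies (maximal He) and
    t -> inf a degenerate vector (He -> 0), so a bisection on t hits any
    attainable target.
    """
    if k == 1 or target_he <= 0:
        return np.ones(max(k, 1)) / max(k, 1) if target_he > 0 else np.r_[1.0, np.zeros(k - 1)]
    q = rng.dirichlet(np.ones(k))
    q = np.sort(q)[::-1]
    q = np.clip(q, 1e-12, None)
    logq = np.log(q)

    def he_at(t: float) -> float:
        w = np.exp(t * (logq - logq.max()))
        p = w / w.sum()
        return 1.0 - float((p**2).sum())

    lo, hi = 0.0, 1.0
    while he_at(hi) > target_he and hi < 1e4:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if he_at(mid) > target_he:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    w = np.exp(t * (logq - logq.max()))
    return w / w.sum()


def make_empirical_fixture(cfg: FixtureConfig) -> AlleleMatrix:
    """Hardy–Weinberg genotypes with per-pool/locus He calibrated to targets.

    Synthetic stand-in for an empirical microsatellite survey: it mimics the
    shape of a real above/below-barrier data set (pool sizes, locus count,
    expected heterozygosities) without any spatial genealogy behind it.
    """
    rng = np.random.default_rng(cfg.seed)
    blocks: list[AlleleMatrix] = []
    counter = 0
    for p in cfg.pools:
        n_loci = len(p.target_he)
        genos = np.zeros((p.n_individuals, n_loci, 2), dtype=np.int64)
        for l in range(n_loci):
            freqs = _frequencies_for_he(p.n_alleles[l], p.target_he[l], rng)
            states = np.arange(1, len(freqs) + 1)
            genos[:, l, :] = rng.choice(states, size=(p.n_individuals, 2), p=freqs)
        meta = simple_metadata(
            p.n_individuals,
            pool_label=p.pool_label,
            stream=p.stream,
            site=p.site,
            position_m=p.position_m,
            side=p.side,
            start=counter,
        )
        counter += p.n_individuals
        blocks.append(
            AlleleMatrix(meta, genos, [f"locus_{i + 1}" for i in range(n_loci)])
        )
    return concat_matrices(blocks)


# Pool sizes and multilocus expected heterozygosities that mirror the
# published river blackfish survey: five streams, one pool above and one
# below each water-supply barrier, eight microsatellite loci.
STUDY_POOLS: list[tuple[str, str, int, float]] = [
    ("Armstrong", "above", 40, 0.461),
    ("Armstrong", "below", 45, 0.442),
    ("Donnellys", "above", 30, 0.477),
    ("Donnellys", "below", 30, 0.505),
    ("McMahons", "above", 24, 0.396),
    ("McMahons", "below", 44, 0.472),
    ("Watts", "above", 45, 0.507),
    ("Watts", "below", 29, 0.463),
    ("Yarra", "above", 28, 0.466),
    ("Yarra", "below", 45, 0.419),
]


def study_like_config(seed: int = 0, n_loci: int = 8, n_alleles: int = 5) -> FixtureConfig:
    """Fixture config shaped like the empirical blackfish data set."""
    pools = [
        PoolFixture(
            pool_label=f"{stream}_{side}",
            n_individuals=n,
            target_he=[he] * n_loci,
            n_alleles=[n_alleles] * n_loci,
            stream=stream,
            side=side,
        )
        for stream, side, n, he in STUDY_POOLS
    ]
    return FixtureConfig(pools=pools, seed=seed)
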