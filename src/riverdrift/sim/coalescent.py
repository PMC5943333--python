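"""Generation-by-generation backward-in-time coalescent on the lattice.

Sampled gene copies are traced backwards one generation at a time: each
lineage draws a parent node from the epoch's dispersal kernel (the backward
kernel equals the forward kernel because density is homogeneous across
nodes), then a parent gene copy uniformly among the 2 x density genes of
that node; lineages landing on the same parent gene merge (simultaneous
multiple mergers are allowed).  The barrier kernel applies to the most
recent ``barrier_age`` generations, the unobstructed kernel before that.
Branch lengths are exact generation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .lattice import LatticeConfig, SampleDesign, kernel_matrix


@njit(cache=True)
def _simulate(cdf_barrier, cdf_open, t_switch, two_d, start_nodes, max_gen, seed):
    """Trace lineages to the grand MRCA.

    Returns (parent, time, node) arrays over tree nodes: leaves first
    (ids 0..n-1 at time 0), internal nodes in order of creation; the root
    has parent -1.  Returns arrays of length 0 if max_gen is exceeded.
    """
    np.random.seed(seed)
    n = start_nodes.shape[0]
    size = 2 * n  # <= n-1 internal nodes even with multiple mergers
    parent = np.full(size, -1, np.int64)
    time = np.zeros(size, np.float64)
    node_of = np.zeros(size, np.int64)
    for i in range(n):
        node_of[i] = start_nodes[i]

    lin_node = start_nodes.copy()
    lin_id = np.arange(n)
    key = np.empty(n, np.int64)
    k = n
    nxt = n
    t = 0
    while k > 1:
        t += 1
        if t > max_gen:
            return parent[:0], time[:0], node_of[:0]
        cdf = cdf_barrier if t <= t_switch else cdf_open
        for i in range(k):
            u = np.random.random()
            row = cdf[lin_node[i]]
            lo = 0
            hi = row.shape[0]
            while lo < hi:
                mid = (lo + hi) >> 1
                if row[mid] <= u:
                    lo = mid + 1
                else:
                    hi = mid
            lin_node[i] = lo
            key[i] = lo * two_d + np.random.randint(two_d)
        # merge lineages that picked the same parent gene copy
        i = 0
        while i < k:
            merged = -1
            j = i + 1
            while j < k:
                if key[j] == key[i]:
                    if merged == -1:
                        merged = nxt
                        parent[lin_id[i]] = merged
                        time[merged] = t
                        node_of[merged] = lin_node[i]
                        nxt += 1
                    parent[lin_id[j]] = merged
                    k -= 1
                    lin_node[j] = lin_node[k]
                    lin_id[j] = lin_id[k]
                    key[j] = key[k]
                else:
                    j += 1
            if merged != -1:
                lin_id[i] = merged
            i += 1
    return parent[:nxt], time[:nxt], node_of[:nxt]


@dataclass
class Genealogy:
    """Coalescent tree over sampled gene copies.

    Leaves are ids ``0 .. n_leaves-1`` (two consecutive ids per diploid);
    internal nodes follow in creation order; ``parent[root] == -1``.
    ``time`` is in generations before sampling, ``lattice_node`` the 1-based
    node where each tree node (lineage at that time) sat.
    """

    parent: np.ndarray
    time: np.ndarray
    lattice_node: np.ndarray
    n_leaves: int
    leaf_nodes: np.ndarray  # 1-based lattice node of each leaf

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    def branch_lengths(self) -> np.ndarray:
        """Generations between each non-root node and its parent."""
        bl = self.time[self.parent[:-1]] - self.time[:-1]
        return bl

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])


def sample_lineage_nodes(
    cfg: LatticeConfig, design: SampleDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Starting lattice node (1-based) of each sampled diploid and gene copy.

    The ``per_node`` diploids of a sampled node are drawn without
    replacement from the diploids of the ``window_nodes``-node window
    centred on it (at 3 diploids/node the 5-node window is exhausted
    exactly); both gene copies of a diploid start in its node.
    """
    design.validate(cfg)
    half = design.window_nodes // 2
    ind_nodes = []
    for s in design.nodes:
        window = np.arange(s - half, s + half + 1)
        slots = np.repeat(window, cfg.density)
        chosen = rng.choice(len(slots), size=design.per_node, replace=False)
        ind_nodes.extend(slots[np.sort(chosen)])
    ind_nodes = np.asarray(ind_nodes, dtype=np.int64)
    gene_nodes = np.repeat(ind_nodes, 2)
    return ind_nodes, gene_nodes


def simulate_genealogy(
    cfg: LatticeConfig,
    design: SampleDesign,
    seed: int,
    max_generations: int = 10_000_000,
    start_nodes: np.ndarray | None = None,
) -> Genealogy:
    """Simulate one locus genealogy for the sampling design.

    ``start_nodes`` (1-based, one per gene copy) overrides the design's
    window draw, which is useful for tests with hand-placed lineages.
    """
    rng = np.random.default_rng(seed)
    if start_nodes is None:
        _, gene_nodes = sample_lineage_nodes(cfg, design, rng)
    else:
        gene_nodes = np.asarray(start_nodes, dtype=np.int64)

    cdf_open = np.cumsum(kernel_matrix(cfg, "pre-barrier"), axis=1)
    if cfg.barrier_node is not None and cfg.barrier_age is not None:
        cdf_barrier = np.cumsum(kernel_matrix(cfg, "barrier"), axis=1)
        t_switch = int(cfg.barrier_age)
    else:
        cdf_barrier = cdf_open
        t_switch = 0

    core_seed = int(rng.integers(1, 2**31 - 1))
    parent, time, node_of = _simulate(
        cdf_barrier,
        cdf_open,
        t_switch,
        2 * cfg.density,
        gene_nodes - 1,
        max_generations,
        core_seed,
    )
    if len(parent) == 0:
        raise RuntimeError(
            f"no common ancestor within {max_generations} generations for {cfg}"
        )
    return Genealogy(parent, time, node_of + 1, len(gene_nodes), gene_nodes)
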