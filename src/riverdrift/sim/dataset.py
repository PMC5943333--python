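"""Multi-locus genotype data sets from independent genealogies."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..genotypes import AlleleMatrix
from .coalescent import sample_lineage_nodes, simulate_genealogy
from .lattice import LatticeConfig, MutationConfig, SampleDesign
from .mutation import drop_mutations


def simulate_dataset(
    cfg: LatticeConfig,
    design: SampleDesign,
    mut: MutationConfig,
    n_loci: int = 8,
    seed: int = 0,
) -> AlleleMatrix:
    """Simulate ``n_loci`` independent microsatellite loci for one sample.

    All loci share the sampled individuals (drawn once per data set); each
    locus gets its own genealogy and mutation history.  Metadata carries the
    node of each individual's sampled location (site = the design node whose
    window it came from), its position in metres, and the side relative to
    the barrier edge (``none`` without a barrier).
    """
    ss = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    ind_nodes, gene_nodes = sample_lineage_nodes(cfg, design, draw_rng)

    locus_seeds = [int(s.generate_state(1)[0] % (2**31 - 2)) + 1 for s in ss.spawn(2 * n_loci)]
    n_ind = len(ind_nodes)
    genos = np.zeros((n_ind, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        tree = simulate_genealogy(cfg, design, locus_seeds[2 * l], start_nodes=gene_nodes)
        leaf_states = drop_mutations(tree, mut, locus_seeds[2 * l + 1])
        genos[:, l, 0] = leaf_states[0::2]
        genos[:, l, 1] = leaf_states[1::2]

    design_nodes = np.repeat(design.nodes, design.per_node)
    if cfg.barrier_node is not None:
        side = np.where(ind_nodes > cfg.barrier_node, "above", "below")
    else:
        side = np.full(n_ind, "none", dtype=object)
    meta = pd.DataFrame(
        {
            "id": [f"sim{i + 1}" for i in range(n_ind)],
            "stream": "sim",
            "site": [f"node{s}" for s in design_nodes],
            "position_m": [cfg.node_position_m(int(s)) for s in design_nodes],
            "side": side,
            "pool": [f"node{s}" for s in design_nodes],
        }
    )
    return AlleleMatrix(meta, genos, [f"locus_{l + 1}" for l in range(n_loci)])
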