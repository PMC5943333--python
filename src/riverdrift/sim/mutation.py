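"""Generalized stepwise mutation on a genealogy.

Mutations fall on branches as a Poisson process with rate ``mu`` per
generation.  Each mutation moves the repeat count by 1 + V steps (V
geometric "failures", so the step-length variance is p/(1-p)^2), up or down
with equal probability; a mutation that would leave the allowed state range
[1, n_states] is re-drawn in full.
"""

from __future__ import annotations

import numpy as np

from .coalescent import Genealogy
from .lattice import MutationConfig


def _apply_mutations(
    state: int,
    n_mut: int,
    p_gsm: float,
    n_states: int,
    rng: np.random.Generator,
    max_redraws: int = 1000,
) -> int:
    for _ in range(n_mut):
        for _ in range(max_redraws):
            step = 1 + (rng.geometric(1.0 - p_gsm) - 1 if p_gsm > 0 else 0)
            new = state + step if rng.random() < 0.5 else state - step
            if 1 <= new <= n_states:
                state = new
                break
        # an unplaceable mutation (pathological range) leaves the state as is
    return state


def drop_mutations(tree: Genealogy, mut: MutationConfig, seed: int) -> np.ndarray:
    """Allele state (1..n_states) of every leaf after mutating the tree."""
    rng = np.random.default_rng(seed)
    n_nodes = len(tree.parent)
    lengths = np.zeros(n_nodes)
    lengths[:-1] = tree.branch_lengths()
    n_mut = rng.poisson(mut.mu * lengths)
    p = mut.p_gsm

    states = np.empty(n_nodes, dtype=np.int64)
    states[tree.root] = mut.root_state
    # parents are always created after children, so a reverse sweep works
    for node in range(n_nodes - 2, -1, -1):
        s = states[tree.parent[node]]
        if n_mut[node]:
            s = _apply_mutations(int(s), int(n_mut[node]), p, mut.n_states, rng)
        states[node] = s
    return states[: tree.n_leaves]
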