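"""Stream lattice, dispersal kernels, mutation model and sampling design.

The habitat is a linear array of ``n_nodes`` demes spaced ``spacing_m``
metres apart, each holding ``density`` diploids.  Dispersal is a truncated
geometric kernel: an offspring's parent lived in the same node with
probability 1-e, or at distance d (up- or downstream with equal odds) with
probability proportional to g**d up to ``max_distance`` nodes.  A barrier
between ``barrier_node`` and ``barrier_node + 1`` blocks crossing mass
(upstream completely; downstream scaled by ``downstream_leak``), with the
blocked mass reassigned to staying put; dispersal past either habitat end
is handled the same way.  Node indices are 1-based; node 1 is the
downstream end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LatticeConfig:
    n_nodes: int = 160
    spacing_m: float = 200.0
    density: int = 10  # diploids per node; 10/node == 50 per km at 200 m spacing
    emigration: float = 0.25  # e: probability the parent lived elsewhere
    geometric_g: float = 0.90  # g: decay of the dispersal-distance distribution
    max_distance: int = 40  # nodes
    barrier_node: int | None = None  # barrier sits between this node and the next
    barrier_age: int | None = None  # generations before sampling
    downstream_leak: float = 0.0  # 0 = complete barrier; 0.2 = leaky downstream

    def __post_init__(self) -> None:
        if not 0.0 <= self.emigration <= 1.0:
            raise ValueError("emigration rate must be in [0, 1]")
        if not 0.0 < self.geometric_g <= 1.0:
            raise ValueError("geometric parameter must be in (0, 1]")
        if self.max_distance > self.n_nodes:
            raise ValueError("max dispersal distance exceeds the lattice")
        if self.density < 1:
            raise ValueError("density must be >= 1 diploid per node")
        if self.barrier_node is not None and not 1 <= self.barrier_node < self.n_nodes:
            raise ValueError("barrier must sit between two lattice nodes")
        if not 0.0 <= self.downstream_leak <= 1.0:
            raise ValueError("downstream leak must be in [0, 1]")

    @property
    def density_per_km(self) -> float:
        return self.density * 1000.0 / self.spacing_m

    @property
    def is_panmictic(self) -> bool:
        return self.emigration >= 1.0 and self.geometric_g >= 1.0

    def node_position_m(self, node: int) -> float:
        return (node - 1) * self.spacing_m


@dataclass
class MutationConfig:
    mu: float = 3e-4  # mutations per gene copy per generation
    step_variance: float = 0.36  # variance of the geometric step-length law
    n_states: int = 60
    root_state: int = 30  # mid-range start minimises boundary re-draws
    variance_is_p: bool = False  # alternative reading: p_gsm given directly

    def __post_init__(self) -> None:
        if not 0 < self.root_state <= self.n_states:
            raise ValueError("root state outside allelic range")
        if self.n_states < 2:
            raise ValueError("need at least 2 allelic states")

    @property
    def p_gsm(self) -> float:
        """Geometric parameter of the step-length distribution.

        Step length = 1 + V with V geometric-failures(p); Var(V) =
        p/(1-p)^2 equals the configured variance (a per-mutation step
        cannot have variance < 1 around 0, so the variance is read as that
        of the step-length law).
        """
        if self.variance_is_p:
            return float(self.step_variance)
        v = self.step_variance
        if v <= 0:
            return 0.0
        # solve p/(1-p)^2 = v for the root in (0, 1)
        p = (2 * v + 1 - np.sqrt(4 * v + 1)) / (2 * v)
        return float(p)


@dataclass
class SampleDesign:
    nodes: tuple[int, ...] = (70, 80, 90, 100, 110, 120, 130, 140, 150)
    per_node: int = 15
    window_nodes: int = 5  # diploids drawn from this many nodes centred on each sample node

    def __post_init__(self) -> None:
        if self.window_nodes % 2 != 1:
            raise ValueError("window must span an odd number of nodes")

    def validate(self, cfg: LatticeConfig) -> None:
        half = self.window_nodes // 2
        for s in self.nodes:
            if not 1 + half <= s <= cfg.n_nodes - half:
                raise ValueError(f"sample window around node {s} leaves the lattice")
            if self.per_node > self.window_nodes * cfg.density:
                raise ValueError(
                    f"cannot draw {self.per_node} diploids from a "
                    f"{self.window_nodes}-node window at density {cfg.density}"
                )

    @property
    def n_individuals(self) -> int:
        return self.per_node * len(self.nodes)


def forward_kernel(cfg: LatticeConfig, node: int, epoch: str = "pre-barrier") -> np.ndarray:
    """Parent-node distribution for an offspring born at ``node`` (1-based).

    ``epoch`` is ``"pre-barrier"`` or ``"barrier"``.  Under homogeneous
    density the backward (parent-picking) kernel equals this forward kernel.
    """
    return kernel_matrix(cfg, epoch)[node - 1]


def kernel_matrix(cfg: LatticeConfig, epoch: str = "pre-barrier") -> np.ndarray:
    """(n_nodes, n_nodes) row-stochastic dispersal matrix for one epoch."""
    if epoch not in ("pre-barrier", "barrier"):
        raise ValueError("epoch must be 'pre-barrier' or 'barrier'")
    n = cfg.n_nodes
    if cfg.is_panmictic:
        mat = np.full((n, n), 1.0 / n)
    else:
        weights = cfg.geometric_g ** np.arange(1, cfg.max_distance + 1)
        weights = cfg.emigration / 2.0 * weights / weights.sum()
        mat = np.zeros((n, n))
        for i in range(n):
            # moves past a habitat end are not realized: that mass stays put,
            # the same convention used for mass blocked by the barrier
            mat[i, i] = 1.0 - cfg.emigration
            for d, w in enumerate(weights, start=1):
                if i - d >= 0:
                    mat[i, i - d] += w
                else:
                    mat[i, i] += w
                if i + d < n:
                    mat[i, i + d] += w
                else:
                    mat[i, i] += w

    if epoch == "barrier":
        if cfg.barrier_node is None:
            raise ValueError("barrier epoch requested but no barrier configured")
        b = cfg.barrier_node  # barrier between 0-based columns b-1 and b
        below = np.arange(n) < b
        for i in range(n):
            if below[i]:
                # moving upstream across the barrier: fully blocked
                blocked = mat[i, b:].sum()
                mat[i, b:] = 0.0
            else:
                # moving downstream across: scaled by the leak rate
                crossing = mat[i, :b].sum()
                mat[i, :b] *= cfg.downstream_leak
                blocked = crossing * (1.0 - cfg.downstream_leak)
            mat[i, i] += blocked
    assert np.allclose(mat.sum(axis=1), 1.0)
    return mat
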