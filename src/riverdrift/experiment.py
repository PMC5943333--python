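"""Scenario grid runner: replicate simulations, summary tables, power curves.

Reproduces the barrier power analysis: for each dispersal scenario
(panmixia / IBD / IBD with a leaky barrier), effective density and barrier
age, replicate data sets are simulated and reduced to the statistics the
study tracks — cross-barrier-position pooled FST versus a same-distance
background FST below the barrier, rarefied allelic richness above/below,
the IBD slope and Mantel test over the nine sampled nodes, and a paired
per-locus Wilcoxon barrier-detection test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import AlleleMatrix
from .sim import LatticeConfig, MutationConfig, SampleDesign, simulate_dataset
from .stats.differentiation import wc_theta
from .stats.diversity import allelic_richness
from .stats.spatial import ibd_regression
from .stats.testing import barrier_wilcoxon

log = logging.getLogger("riverdrift")

#: emigration rate and geometric parameter per diploids-per-node density
DISPERSAL_BY_DENSITY: dict[int, tuple[float, float]] = {
    3: (0.50, 0.95),
    10: (0.25, 0.90),
    30: (0.15, 0.85),
}

ABOVE_POOL = (130, 140, 150)
BELOW_POOL = (100, 110, 120)
BACKGROUND_POOL = (70, 80, 90)

SCENARIOS = ("panmixia", "ibd", "ibd_asym")


def scenario_lattice(
    scenario: str,
    density: int,
    barrier_age: int | None = None,
) -> LatticeConfig:
    """LatticeConfig for a named dispersal scenario at a per-node density."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "panmixia":
        e, g, dmax = 1.0, 1.0, 160
    else:
        if density not in DISPERSAL_BY_DENSITY:
            raise ValueError(f"density must be one of {sorted(DISPERSAL_BY_DENSITY)}")
        e, g = DISPERSAL_BY_DENSITY[density]
        dmax = 40
    leak = 0.2 if scenario == "ibd_asym" else 0.0
    return LatticeConfig(
        density=density,
        emigration=e,
        geometric_g=g,
        max_distance=dmax,
        barrier_node=125 if barrier_age is not None else None,
        barrier_age=barrier_age,
        downstream_leak=leak if barrier_age is not None else 0.0,
    )


@dataclass
class ScenarioGrid:
    scenarios: Sequence[str] = ("ibd",)
    densities: Sequence[int] = (3, 10, 30)  # diploids per node
    barrier_ages: Sequence[int | None] = (None,)
    n_loci: int = 8
    replicates: int = 50
    master_seed: int = 0
    mantel_permutations: int = 10_000
    mutation: MutationConfig = field(default_factory=MutationConfig)
    design: SampleDesign = field(default_factory=SampleDesign)


def replicate_seed(master_seed: int, scenario: str, density: int, age: int | None, rep: int) -> int:
    """Deterministic per-replicate seed, reproducible in isolation."""
    age_code = 0 if age is None else int(age) + 1
    ss = np.random.SeedSequence(
        [int(master_seed), SCENARIOS.index(scenario), int(density), age_code, int(rep)]
    )
    return int(ss.generate_state(1)[0] % (2**31 - 2)) + 1


def _pool_sites(matrix: AlleleMatrix, nodes: Sequence[int]) -> np.ndarray:
    labels = {f"node{n}" for n in nodes}
    return matrix.genotypes[matrix.individuals["site"].isin(labels).to_numpy()]


def replicate_statistics(
    matrix: AlleleMatrix,
    mantel_permutations: int = 10_000,
    mantel_seed: int | None = None,
) -> dict:
    """All per-replicate statistics from one simulated data set."""
    above = _pool_sites(matrix, ABOVE_POOL)
    below = _pool_sites(matrix, BELOW_POOL)
    background = _pool_sites(matrix, BACKGROUND_POOL)

    cross_fst, cross_by_locus = wc_theta([above, below])
    bg_fst, bg_by_locus = wc_theta([background, below])

    try:
        wilcoxon_p = barrier_wilcoxon(cross_by_locus, bg_by_locus).p_value
    except ValueError:
        wilcoxon_p = np.nan

    # rarefaction at the full pooled gene count (pools are equal-sized)
    g_genes = 2 * min(above.shape[0], below.shape[0])
    ar_above = _pooled_ar(matrix, ABOVE_POOL, g_genes)
    ar_below = _pooled_ar(matrix, BELOW_POOL, g_genes)

    fit = ibd_regression(matrix, permutations=mantel_permutations, seed=mantel_seed)
    return {
        "cross_fst": cross_fst,
        "background_fst": bg_fst,
        "wilcoxon_p": wilcoxon_p,
        "ar_above": ar_above,
        "ar_below": ar_below,
        "ibd_slope": fit.slope,
        "mantel_p": fit.mantel_p,
    }


def _pooled_ar(matrix: AlleleMatrix, nodes: Sequence[int], g_genes: int) -> float:
    labels = [f"node{n}" for n in nodes]
    mask = matrix.individuals["site"].isin(labels).to_numpy()
    sub = matrix.subset(mask)
    meta = sub.individuals.copy()
    meta["pool"] = "pooled"
    pooled = AlleleMatrix(meta, sub.genotypes, list(sub.locus_names))
    _, ar = allelic_richness(pooled, "pooled", g_genes)
    return ar


def run_grid(
    grid: ScenarioGrid, progress: bool = False, persist_dir: str | None = None
) -> pd.DataFrame:
    """Run every cell of the grid; one row per replicate.

    Failures in a replicate are logged and recorded as NaN rows so a long
    run survives isolated numerical problems.  With ``persist_dir`` each
    replicate's raw genotypes are also written as Genepop + sidecar.
    """
    from pathlib import Path

    from .genepop import write_genepop, write_metadata

    rows = []
    for scenario in grid.scenarios:
        for density in grid.densities:
            for age in grid.barrier_ages:
                cfg = scenario_lattice(scenario, density, age)
                for rep in range(grid.replicates):
                    seed = replicate_seed(grid.master_seed, scenario, density, age, rep)
                    row = {
                        "scenario": scenario,
                        "density": density,
                        "density_per_km": cfg.density_per_km,
                        "barrier_age": -1 if age is None else age,
                        "n_loci": grid.n_loci,
                        "rep": rep,
                        "seed": seed,
                    }
                    try:
                        matrix = simulate_dataset(
                            cfg, grid.design, grid.mutation, grid.n_loci, seed
                        )
                        if persist_dir is not None:
                            stem = f"{scenario}_d{density}_age{0 if age is None else age}_rep{rep}"
                            base = Path(persist_dir)
                            base.mkdir(parents=True, exist_ok=True)
                            write_genepop(matrix, base / f"{stem}.gen",
                                          title=f"riverdrift seed={seed}")
                            write_metadata(matrix, base / f"{stem}.meta.tsv")
                        row.update(
                            replicate_statistics(
                                matrix, grid.mantel_permutations, mantel_seed=seed
                            )
                        )
                    except Exception:  # noqa: BLE001 - keep the grid running
                        log.exception(
                            "replicate failed: %s density=%s age=%s rep=%s",
                            scenario, density, age, rep,
                        )
                    rows.append(row)
                    if progress:
                        log.info(
                            "%s density=%s age=%s rep=%d done", scenario, density, age, rep
                        )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Mean (SD) statistics and detection rates per scenario x density x age."""
    if results.empty:
        raise ValueError("no results to summarize")

    def _cell(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_reps": len(g),
                "mean_cross_fst": g["cross_fst"].mean(),
                "sd_cross_fst": g["cross_fst"].std(ddof=1),
                "mean_background_fst": g["background_fst"].mean(),
                "mean_ibd_slope": g["ibd_slope"].mean(),
                "sd_ibd_slope": g["ibd_slope"].std(ddof=1),
                "ar_ratio_above_below": (g["ar_above"] / g["ar_below"]).mean(),
                "pct_mantel_significant": 100.0 * (g["mantel_p"] < alpha).mean(),
                "pct_barrier_detected": 100.0 * (g["wilcoxon_p"] < alpha).mean(),
            }
        )

    grouped = results.groupby(["scenario", "density", "barrier_age", "n_loci"])
    return grouped.apply(_cell, include_groups=False).reset_index()


def power_curve(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Barrier-detection rate versus barrier age per scenario x density."""
    summary = summarize(results, alpha)
    curve = summary[summary["barrier_age"] >= 0][
        ["scenario", "density", "n_loci", "barrier_age", "pct_barrier_detected", "mean_cross_fst", "sd_cross_fst"]
    ].sort_values(["scenario", "density", "barrier_age"])
    return curve.reset_index(drop=True)


def plot_fst_curves(results: pd.DataFrame, path: str) -> None:
    """Mean +/- SD cross- and background-FST versus barrier age, one panel
    per scenario x density (the development-of-differentiation figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    aged = results[results["barrier_age"] >= 0]
    cells = sorted(set(zip(aged["scenario"], aged["density"])))
    fig, axes = plt.subplots(1, max(len(cells), 1), figsize=(4 * max(len(cells), 1), 3.2),
                             squeeze=False, sharey=True)
    for ax, (scenario, density) in zip(axes[0], cells):
        sub = aged[(aged["scenario"] == scenario) & (aged["density"] == density)]
        g = sub.groupby("barrier_age")
        for col, color, label in (
            ("cross_fst", "0.5", "above vs below barrier"),
            ("background_fst", "0.0", "below-barrier background"),
        ):
            ax.errorbar(g[col].mean().index, g[col].mean(), yerr=g[col].std(ddof=1),
                        color=color, marker="o", capsize=2, label=label)
        ax.set_title(f"{scenario}, {density} per node")
        ax.set_xlabel("generations since barrier")
    axes[0][0].set_ylabel(r"pairwise $F_{ST}$")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ne_from_fst(n_total: float, fst: float) -> float:
    """Wright's Ne = Nt / (1 - FST) for an isolated segment of Nt diploids."""
    if fst >= 1:
        raise ValueError("FST must be < 1")
    return n_total / (1.0 - fst)
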