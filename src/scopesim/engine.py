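"""Recurrent-selection orchestration across cycles and replicates.

One replicate runs the full breeding scheme: founders are phenotyped and
form the initial training panel; the initial crossing block pairs the
top 50 lines of each founder panel by phenotype (identical for every
method); each subsequent cycle fits RR-BLUP on the training panel,
predicts GEBVs for the 1000-line breeding population, selects and mates
100 parents according to the configured strategy, updates the training
panel by the tails rule (150 new phenotypes), and produces the next
breeding population as 50 couples x 20 F1 offspring advanced by two
generations of single-seed descent.

Replicates re-sample the QTL architecture and every stochastic stage
from independent sub-seeds of the master seed; reported trajectories are
per-cycle means across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import Population, load_founders, synth_founders
from .genome import QTLModel, cross_block, sample_qtl, single_seed_descent
from .metrics import CycleMetrics, metrics_frame, summarize_cycle
from .phenotyping import VarianceSettings, calibrate_variances, phenotype_values
from .prediction import TrainingPanel, fit_rrblup, predict_gebv, tails_update
from .selection import (
    Couple,
    pm_select,
    random_mating,
    scoping_select,
    truncation_select,
    mvt_select,
)

__all__ = ["SimConfig", "SimState", "Trajectory", "initial_crossing_block", "run_cycle", "run_replicate", "run_replicates"]

METHODS = ("baseline", "scoping", "population_merit", "mvt")


@dataclass(frozen=True)
class SimConfig:
    """Run configuration; defaults follow the standard barley recurrent-selection design."""

    method: str = "baseline"
    SR: float = 0.3  # scoping rate (scoping method only)
    c: float = 20.0  # relationship penalty (population merit only)
    n_cycles: int = 50
    n_reps: int = 250
    n_couples: int = 50
    offspring_per_couple: int = 20
    ssd_generations: int = 2
    tp_capacity: int | None = None  # default: all founders (764 for the barley panels)
    tp_update_n: int = 150
    maf_threshold: float = 0.03
    L: int = 100
    h2: float = 0.5
    env_ratio: float = 8.0
    n_env: int = 3
    mvt_pre_n: int = 300
    initial_per_panel: int = 50
    master_seed: int = 0
    # founder source: either two TSV paths, or synthetic-panel parameters
    founder_genotypes: str | None = None
    founder_map: str | None = None
    synth_lines_per_panel: int = 380
    synth_loci: int = 1590
    synth_chrom: int = 7
    synth_chrom_length_cM: float = 150.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.method == "scoping" and not 0.1 - 1e-9 <= self.SR <= 1 + 1e-9:
            raise ValueError("scoping rate must lie in [0.1, 1]")
        if self.tp_update_n % 2:
            raise ValueError("tails update size must be even")

    @property
    def n_parents(self) -> int:
        return 2 * self.n_couples

    @property
    def breeding_pop_size(self) -> int:
        return self.n_couples * self.offspring_per_couple


@dataclass
class SimState:
    """Mutable per-replicate simulation state between cycles."""

    pop: Population  # current breeding population
    tp: TrainingPanel
    q: QTLModel
    vs: VarianceSettings
    rng: np.random.Generator
    cycle: int


@dataclass
class Trajectory:
    """Per-replicate and aggregated per-cycle metrics."""

    per_rep: pd.DataFrame  # long format: rep, cycle, method, metric, value
    config: SimConfig
    log: list = field(default_factory=list)

    @property
    def aggregate(self) -> pd.DataFrame:
        """Per-cycle mean across replicates (NaN-aware for accuracy)."""
        return (
            self.per_rep.groupby(["cycle", "method", "metric"], as_index=False)["value"]
            .mean()
        )

    def final_cycle_value(self, metric: str) -> float:
        agg = self.aggregate
        sub = agg[agg["metric"] == metric]
        return float(sub.loc[sub["cycle"].idxmax(), "value"])


# ---------------------------------------------------------------------------
# Founder handling
# ---------------------------------------------------------------------------


def load_or_synthesize_founders(config: SimConfig) -> tuple[Population, Population]:
    """Two founder panels from files, or synthetic stand-ins."""
    if config.founder_genotypes is not None:
        pop = load_founders(config.founder_genotypes, config.founder_map)
        half = len(pop) // 2
        a = pop.subset(range(half), panel_label="panel_A")
        b = pop.subset(range(half, len(pop)), panel_label="panel_B")
        return a, b
    return synth_founders(
        n_lines_per_panel=config.synth_lines_per_panel,
        n_loci=config.synth_loci,
        n_chrom=config.synth_chrom,
        chrom_length_cM=config.synth_chrom_length_cM,
        seed=config.master_seed,
    )


# ---------------------------------------------------------------------------
# Cycle 0: initial crossing block
# ---------------------------------------------------------------------------


def initial_crossing_block(
    panel_a: Population,
    panel_b: Population,
    phen_a: np.ndarray,
    phen_b: np.ndarray,
    rng: np.random.Generator,
    n_per_panel: int = 50,
) -> tuple[Population, list[Couple]]:
    """Cross-panel crossing block: top lines of each panel by phenotype.

    Returns the combined parental population and couples pairing one
    line from each panel (random cross-panel matching).  This block is
    identical for every parental selection method.
    """
    if len(panel_a) < n_per_panel or len(panel_b) < n_per_panel:
        raise ValueError("founder panel smaller than the requested parental count")
    top_a = np.argsort(-np.asarray(phen_a), kind="stable")[:n_per_panel]
    top_b = np.argsort(-np.asarray(phen_b), kind="stable")[:n_per_panel]
    parents = Population.concatenate(
        [panel_a.subset(top_a), panel_b.subset(top_b)], panel_label="initial_parents"
    )
    order_b = rng.permutation(n_per_panel)
    couples = [Couple(int(i), int(n_per_panel + order_b[i])) for i in range(n_per_panel)]
    return parents, couples


# ---------------------------------------------------------------------------
# One breeding cycle
# ---------------------------------------------------------------------------


def _select_couples(config: SimConfig, gebv_values: np.ndarray, Z: np.ndarray, rng) -> list[Couple]:
    if config.method == "baseline":
        parents = truncation_select(gebv_values, config.n_parents)
        return random_mating(parents, rng)
    if config.method == "scoping":
        return scoping_select(gebv_values, Z, config.SR, config.n_couples)
    if config.method == "population_merit":
        return pm_select(gebv_values, Z, rng, c=config.c, n=config.n_parents)
    return mvt_select(gebv_values, Z, rng, pre_n=config.mvt_pre_n, n=config.n_parents)


def run_cycle(state: SimState, config: SimConfig) -> tuple[SimState, CycleMetrics, dict]:
    """Advance one breeding cycle; returns metrics of the evaluated population.

    Order: fit model -> predict GEBVs -> select & mate -> tails TP update
    -> cross -> single-seed descent -> summarize.
    """
    cycle = state.cycle + 1
    try:
        Z = state.pop.genotype_codes[:, state.q.marker_indices].astype(np.float64)
        model = fit_rrblup(state.tp, config.maf_threshold)
        gebvs = predict_gebv(Z, model, ids=state.pop.ids)
        couples = _select_couples(config, gebvs.values, Z, state.rng)

        def phenotyper(indices):
            return phenotype_values(
                state.pop.subset(indices), state.q, state.vs, state.rng, cycle
            )

        tp = tails_update(state.tp, Z, gebvs, phenotyper, cycle, config.tp_update_n)
        f1 = cross_block(
            state.pop,
            [(c.p1, c.p2) for c in couples],
            config.offspring_per_couple,
            state.rng,
            origin_cycle=cycle,
            id_prefix=f"c{cycle}",
        )
        next_pop = single_seed_descent(f1, config.ssd_generations, state.rng)
        metrics = summarize_cycle(state.pop, state.q, gebvs.values, cycle)
    except Exception as exc:
        raise RuntimeError(f"cycle {cycle} failed: {exc}") from exc
    info = {
        "cycle": cycle,
        "reml_converged": model.converged,
        "sigma_u2": model.sigma_u2,
        "sigma_e2": model.sigma_e2,
        "n_retained_markers": int(model.retained_markers.size),
        "couples": [(c.p1, c.p2) for c in couples],
    }
    new_state = SimState(next_pop, tp, state.q, state.vs, state.rng, cycle)
    return new_state, metrics, info


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------


def _init_replicate(
    config: SimConfig,
    panel_a: Population,
    panel_b: Population,
    rng: np.random.Generator,
) -> tuple[SimState, CycleMetrics]:
    """Cycle 0: phenotype founders, build TP, first crossing block."""
    founders = Population.concatenate([panel_a, panel_b], panel_label="founders")
    q = sample_qtl(founders.map, config.L, rng)
    vs = calibrate_variances(founders, q, config.h2, config.env_ratio, config.n_env)
    phen = phenotype_values(founders, q, vs, rng, cycle=0)
    phen_a, phen_b = phen[: len(panel_a)], phen[len(panel_a) :]

    capacity = config.tp_capacity or len(founders)
    if capacity != len(founders):
        raise ValueError("initial TP is the full founder panel; capacity must match")
    tp = TrainingPanel(
        genotypes=founders.genotype_codes[:, q.marker_indices].astype(np.float64),
        phenotypes=phen,
        cycle_added=np.zeros(len(founders), dtype=np.int64),
        capacity=capacity,
        marker_ids=founders.map.locus_id[q.marker_indices],
    )
    parents, couples = initial_crossing_block(
        panel_a, panel_b, phen_a, phen_b, rng, config.initial_per_panel
    )
    f1 = cross_block(
        parents,
        [(c.p1, c.p2) for c in couples],
        config.offspring_per_couple,
        rng,
        origin_cycle=0,
        id_prefix="c0",
    )
    pop = single_seed_descent(f1, config.ssd_generations, rng)
    founder_metrics = summarize_cycle(founders, q, None, cycle=0)
    return SimState(pop, tp, q, vs, rng, cycle=0), founder_metrics


def run_replicate(
    config: SimConfig,
    panel_a: Population,
    panel_b: Population,
    rng: np.random.Generator,
) -> tuple[list[CycleMetrics], list[dict]]:
    """One full trajectory of n_cycles breeding cycles."""
    state, m0 = _init_replicate(config, panel_a, panel_b, rng)
    metrics = [m0]
    log: list[dict] = []
    for _ in range(config.n_cycles):
        state, m, info = run_cycle(state, config)
        metrics.append(m)
        log.append(info)
    return metrics, log


def run_replicates(config: SimConfig, panels: tuple[Population, Population] | None = None) -> Trajectory:
    """Run n_reps independent replicates and aggregate per-cycle means.

    Each replicate draws its own generator from a child of the master
    seed; the QTL model, founder phenotype noise and every stochastic
    stage are re-sampled per replicate so that averages marginalize over
    genetic architectures.
    """
    panel_a, panel_b = panels if panels is not None else load_or_synthesize_founders(config)
    children = np.random.SeedSequence(config.master_seed).spawn(config.n_reps)
    records: list[tuple[int, str, CycleMetrics]] = []
    log: list = []
    for rep, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        try:
            metrics, rep_log = run_replicate(config, panel_a, panel_b, rng)
        except Exception as exc:
            partial = Trajectory(metrics_frame(records), config, log)
            err = RuntimeError(f"replicate {rep} failed: {exc}")
            err.partial_trajectory = partial
            raise err from exc
        records.extend((rep, config.method, m) for m in metrics)
        log.append({"rep": rep, "cycles": rep_log})
    return Trajectory(metrics_frame(records), config, log)
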