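"""Per-cycle summaries: genetic values, QTL fixation, variance, accuracy.

All genetic-value summaries are normalized by the maximum genetic value
(the sum of all favorable QTL effects), so 1.0 means every favorable
QTL allele is homozygous in every individual.  Fixation bookkeeping
follows the breeding population: a QTL is fixed once one of its alleles
reaches frequency 1, which is irreversible without mutation.  The
*maximum reachable* genetic value adds the favorable effects of all
still-segregating QTL to the (signed) effects of the fixed ones — the
best value the program could still attain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .founders import Population
from .genome import QTLModel, genetic_values

__all__ = ["CycleMetrics", "fixation_report", "summarize_cycle", "metrics_frame"]


@dataclass(frozen=True)
class CycleMetrics:
    cycle: int
    mean_gv: float
    top10_gv: float
    fixed_gv: float
    max_reachable_gv: float
    pct_qtl_fixed: float
    genetic_variance: float  # raw-value scale
    accuracy: float  # Pearson(GEBV, true value); NaN when undefined


def fixation_report(pop: Population, q: QTLModel) -> tuple[float, float, float]:
    """(fixed_gv, max_reachable_gv, fraction of QTL fixed), normalized.

    A QTL is fixed when every individual carries the same homozygous
    code.  fixed_gv sums the signed effects of fixed QTL;
    max_reachable_gv adds the favorable effect of every unfixed QTL.
    """
    if len(pop) == 0:
        raise ValueError("empty population")
    codes = pop.genotype_codes[:, q.qtl_indices]
    fixed = np.all(codes == codes[0], axis=0) & (codes[0] != 0)
    signed = codes[0] * q.favorable_sign * q.effects  # per-QTL signed effect if fixed
    denom = q.max_value
    fixed_gv = float(signed[fixed].sum())
    max_reachable = fixed_gv + float(q.effects[~fixed].sum())
    if denom > 0:
        fixed_gv /= denom
        max_reachable /= denom
    return fixed_gv, max_reachable, float(fixed.mean())


def summarize_cycle(
    pop: Population,
    q: QTLModel,
    gebv_values: np.ndarray | None,
    cycle: int,
) -> CycleMetrics:
    """All per-cycle metrics of one breeding population.

    ``gebv_values`` may be None (cycle 0, before any model exists);
    accuracy is then missing.  Accuracy is also recorded as missing — not
    zero — when either vector has no variance.
    """
    if len(pop) < 10:
        raise ValueError("need at least 10 individuals for the top-10 summary")
    g = genetic_values(pop, q)
    denom = q.max_value
    g_norm = g / denom if denom > 0 else g
    top10 = float(np.sort(g_norm)[-10:].mean())
    fixed_gv, max_reachable, pct_fixed = fixation_report(pop, q)
    accuracy = float("nan")
    if gebv_values is not None:
        gh = np.asarray(gebv_values, dtype=np.float64)
        if np.std(gh) > 0 and np.std(g) > 0:
            accuracy = float(np.corrcoef(gh, g)[0, 1])
    return CycleMetrics(
        cycle=cycle,
        mean_gv=float(g_norm.mean()),
        top10_gv=top10,
        fixed_gv=fixed_gv,
        max_reachable_gv=max_reachable,
        pct_qtl_fixed=pct_fixed,
        genetic_variance=float(np.var(g, ddof=1)) if len(pop) > 1 else 0.0,
        accuracy=accuracy,
    )


def metrics_frame(records: list[tuple[int, str, CycleMetrics]]) -> pd.DataFrame:
    """Long-format table (rep, cycle, method, metric, value)."""
    rows = []
    for rep, method, m in records:
        for name in (
            "mean_gv",
            "top10_gv",
            "fixed_gv",
            "max_reachable_gv",
            "pct_qtl_fixed",
            "genetic_variance",
            "accuracy",
        ):
            rows.append(
                {"rep": rep, "cycle": m.cycle, "method": method, "metric": name,
                 "value": getattr(m, name)}
            )
    return pd.DataFrame(rows)
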