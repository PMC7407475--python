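"""Multi-environment phenotype simulation.

Phenotypes follow y_ij = g_i + e_j + eps_ij: the true genetic value of
individual i, plus an environment main effect shared by all individuals
in environment j, plus an individual-by-environment residual.  The
recorded phenotype is the mean over n_env environments (the entry mean).

Variances are calibrated once against the founder population and then
frozen for the whole simulation:

* sigma_E^2 = env_ratio * sigma_g^2  (environment effects dominate the
  genetic signal, default ratio 8);
* sigma_R^2 = n_env * sigma_g^2 * (1 - h2) / h2, so that the entry-mean
  heritability sigma_g^2 / (sigma_g^2 + sigma_R^2 / n_env) equals the
  target h2.

The environment shift e_j is common to every individual within a
phenotyping event, so it moves all entry means by the same amount and is
absorbed by the fixed intercept of the prediction model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founders import Population
from .genome import QTLModel, genetic_values

__all__ = [
    "VarianceSettings",
    "PhenotypeRecord",
    "calibrate_variances",
    "simulate_phenotypes",
    "phenotype_values",
]


@dataclass(frozen=True)
class VarianceSettings:
    sigma_E2: float  # environment main-effect variance
    sigma_R2: float  # residual variance per individual x environment
    h2: float  # target entry-mean heritability
    n_env: int
    sigma_g2_ref: float  # founder genetic variance used for calibration

    def __post_init__(self) -> None:
        if min(self.sigma_E2, self.sigma_R2, self.sigma_g2_ref) < 0:
            raise ValueError("variances must be nonnegative")
        if self.n_env < 1:
            raise ValueError("need at least one environment")


@dataclass(frozen=True)
class PhenotypeRecord:
    individual_id: str
    value: float  # mean over environments
    cycle: int


def calibrate_variances(
    base_pop: Population,
    q: QTLModel,
    h2: float = 0.5,
    env_ratio: float = 8.0,
    n_env: int = 3,
) -> VarianceSettings:
    """Freeze sigma_E^2 and sigma_R^2 against the founder genetic variance."""
    if not 0 < h2 < 1:
        raise ValueError("heritability must lie in (0, 1)")
    g = genetic_values(base_pop, q)
    sigma_g2 = float(np.var(g, ddof=1))
    if sigma_g2 == 0:
        raise ValueError("base population is monomorphic at all QTL (zero genetic variance)")
    sigma_E2 = env_ratio * sigma_g2
    sigma_R2 = n_env * sigma_g2 * (1.0 - h2) / h2
    return VarianceSettings(sigma_E2, sigma_R2, h2, n_env, sigma_g2)


def simulate_phenotypes(
    pop: Population,
    q: QTLModel,
    vs: VarianceSettings,
    rng: np.random.Generator,
    cycle: int = 0,
) -> list[PhenotypeRecord]:
    """One phenotyping event: n_env shared environment draws, iid residuals.

    Returns one record per individual holding the entry mean
    mean_j(g_i + e_j + eps_ij).
    """
    g = genetic_values(pop, q)
    e = rng.normal(0.0, np.sqrt(vs.sigma_E2), size=vs.n_env)
    eps = rng.normal(0.0, np.sqrt(vs.sigma_R2), size=(len(pop), vs.n_env))
    values = g + e.mean() + eps.mean(axis=1)
    return [PhenotypeRecord(pid, float(v), cycle) for pid, v in zip(pop.ids, values)]


def phenotype_values(pop, q, vs, rng, cycle=0) -> np.ndarray:
    """Entry-mean phenotypes as a plain array (same event semantics)."""
    return np.array([r.value for r in simulate_phenotypes(pop, q, vs, rng, cycle)])
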