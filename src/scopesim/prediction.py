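"""Genomic prediction: RR-BLUP fitted by REML, and the sliding training panel.

The mixed model is

    y = 1 beta + Z u + eps,   u ~ N(0, sigma_u^2 I_k),  eps ~ N(0, sigma_e^2 I_n)

with y the entry-mean phenotypes of the training panel (TP), Z the
(-1,0,+1)-coded marker incidence matrix restricted to markers passing
the minor-allele-frequency filter, and u the additive marker effects.
Variance components are estimated by restricted maximum likelihood,
profiled down to a one-dimensional search in the ratio
delta = sigma_e^2 / sigma_u^2 on the spectrum of Z Z' (the standard
spectral/EMMA formulation): after absorbing the intercept, the
restricted log-likelihood depends on delta only through the rotated
residuals, so a bracketed scalar optimization is exact, deterministic
and fast at TP sizes of a few hundred.

GEBVs are ghat = beta_hat + Z_bc u_hat; the intercept is a constant
shift and never affects rankings.

The TP is a fixed-capacity, age-ordered panel.  Each cycle the "tails"
rule phenotypes the n_new/2 highest- and n_new/2 lowest-GEBV individuals
of the breeding population, appends them, and evicts the n_new oldest
records, keeping the size constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "TrainingPanel",
    "PredictionModel",
    "GEBVTable",
    "maf_filter",
    "fit_rrblup",
    "predict_gebv",
    "tails_update",
]


# ---------------------------------------------------------------------------
# Training panel
# ---------------------------------------------------------------------------


@dataclass
class TrainingPanel:
    """Fixed-size, age-ordered set of (marker genotypes, phenotype) records.

    ``genotypes`` is (n, k) over the full prediction-marker set (the MAF
    filter is applied at fit time, not at storage time).  Records are
    stored oldest-first; eviction removes leading rows.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    cycle_added: np.ndarray
    capacity: int
    marker_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.float64)
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.float64)
        self.cycle_added = np.asarray(self.cycle_added, dtype=np.int64)
        if self.genotypes.shape[0] != self.phenotypes.size != self.cycle_added.size:
            raise ValueError("genotypes, phenotypes and cycle_added must align")
        if len(self) > self.capacity:
            raise ValueError("training panel exceeds capacity")
        order = np.argsort(self.cycle_added, kind="stable")
        self.genotypes = self.genotypes[order]
        self.phenotypes = self.phenotypes[order]
        self.cycle_added = self.cycle_added[order]

    def __len__(self) -> int:
        return int(self.phenotypes.size)


@dataclass(frozen=True)
class PredictionModel:
    beta: float  # fixed-effect intercept
    u_hat: np.ndarray  # BLUP marker effects over retained markers
    retained_markers: np.ndarray  # indices into the TP marker columns
    sigma_u2: float
    sigma_e2: float
    converged: bool = True
    n_markers_total: int = 0  # filtered markers predict with effect 0

    @property
    def lambda_ridge(self) -> float:
        return self.sigma_e2 / self.sigma_u2 if self.sigma_u2 > 0 else np.inf

    def full_effects(self) -> np.ndarray:
        """Effects over all marker columns, zero where MAF-filtered."""
        u = np.zeros(self.n_markers_total)
        u[self.retained_markers] = self.u_hat
        return u


@dataclass(frozen=True)
class GEBVTable:
    ids: list
    values: np.ndarray  # beta_hat + Z u_hat

    def ranking(self) -> np.ndarray:
        """Indices sorted by descending GEBV, stable in insertion order."""
        return np.argsort(-self.values, kind="stable")


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------


def maf_filter(tp_genotypes: np.ndarray, threshold: float = 0.03) -> np.ndarray:
    """Indices of markers whose minor allele frequency is >= threshold.

    Allele frequency of the +1-coded allele is counted over 2n gene
    copies (a heterozygote contributes one copy of each allele); markers
    with MAF strictly below the threshold are removed.
    """
    z = np.asarray(tp_genotypes, dtype=np.float64)
    if z.size == 0:
        raise ValueError("empty training panel")
    p = (z + 1.0).sum(axis=0) / (2.0 * z.shape[0])
    maf = np.minimum(p, 1.0 - p)
    return np.flatnonzero(maf >= threshold - 1e-12)


# ---------------------------------------------------------------------------
# REML / RR-BLUP
# ---------------------------------------------------------------------------


def _reml_delta(eigvals: np.ndarray, eta2: np.ndarray, n_rest: int):
    """Profiled restricted log-likelihood in delta = sigma_e^2/sigma_u^2.

    ``eigvals``/``eta2`` cover the full n-dim spectrum of the doubly
    centered kernel; the intercept direction carries eta2 = 0 exactly,
    so the quadratic form is basis-independent, and one log(delta) is
    subtracted from the determinant to account for that dropped
    restricted dimension.
    """

    def neg_restricted_ll(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = eigvals + d
        s = float(eta2 @ (1.0 / denom))
        return 0.5 * (n_rest * np.log(s) + np.log(denom).sum() - log_delta)

    # coarse deterministic grid, then bounded refinement around the best point
    grid = np.linspace(-10.0, 10.0, 81)
    vals = [neg_restricted_ll(g) for g in grid]
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    res = minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8, "maxiter": 200},
    )
    converged = bool(res.success)
    best = res.x if res.fun <= vals[j] else grid[j]
    return float(np.exp(best)), converged


def fit_rrblup(
    tp: TrainingPanel, maf_threshold: float = 0.03, min_markers: int = 1
) -> PredictionModel:
    """Fit the ridge-regression BLUP model on the training panel by REML.

    The MAF filter is recomputed on the current panel; retained markers
    enter the model, filtered ones predict with effect zero.  The
    variance ratio is estimated on the spectrum of Z Z' after absorbing
    the intercept; BLUPs are u_hat = sigma_u^2 Z' V^{-1} (y - 1 beta_hat).
    """
    n = len(tp)
    if n < 2:
        raise ValueError("need at least 2 training records")
    y = tp.phenotypes
    if np.ptp(y) == 0:
        raise ValueError("zero-variance phenotypes")
    retained = maf_filter(tp.genotypes, maf_threshold)
    if retained.size < min_markers:
        raise ValueError("no markers retained after MAF filtering")
    Z = tp.genotypes[:, retained]

    K = Z @ Z.T
    # absorb the intercept: P = I - 11'/n, work in the (n-1)-dim contrast space
    ybar = y.mean()
    Kc = K - K.mean(axis=0, keepdims=True) - K.mean(axis=1, keepdims=True) + K.mean()
    w, U = np.linalg.eigh(Kc)
    w = np.clip(w, 0.0, None)
    eta = U.T @ (y - ybar)  # component along 1 is zero by centering
    delta, converged = _reml_delta(w, eta**2, n - 1)

    sigma_u2 = float(eta**2 @ (1.0 / (w + delta)) / (n - 1))
    sigma_e2 = float(delta * sigma_u2)

    # GLS intercept and BLUP effects on the original scale
    wK, UK = np.linalg.eigh(K)
    wK = np.clip(wK, 0.0, None)
    inv_diag = 1.0 / (wK + delta)  # V/sigma_u2 = K + delta I
    ones = np.ones(n)
    Vi_y = UK @ (inv_diag * (UK.T @ y))
    Vi_1 = UK @ (inv_diag * (UK.T @ ones))
    beta = float(ones @ Vi_y) / float(ones @ Vi_1)
    resid = y - beta
    u_hat = Z.T @ (UK @ (inv_diag * (UK.T @ resid)))
    return PredictionModel(
        beta=beta,
        u_hat=u_hat,
        retained_markers=retained,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        converged=converged,
        n_markers_total=tp.genotypes.shape[1],
    )


def predict_gebv(marker_codes: np.ndarray, model: PredictionModel, ids=None) -> GEBVTable:
    """GEBVs ghat = beta_hat + Z u_hat over the retained markers.

    ``marker_codes`` is (n, k) over the same marker columns as the TP.
    """
    z = np.asarray(marker_codes, dtype=np.float64)
    if z.shape[1] != model.n_markers_total:
        raise ValueError(
            f"marker count mismatch: population has {z.shape[1]}, model expects {model.n_markers_total}"
        )
    values = model.beta + z[:, model.retained_markers] @ model.u_hat
    if ids is None:
        ids = list(range(z.shape[0]))
    return GEBVTable(list(ids), values)


# ---------------------------------------------------------------------------
# Training-panel update (tails rule)
# ---------------------------------------------------------------------------


def tails_select(gebvs: GEBVTable, n_new: int) -> np.ndarray:
    """Indices of the n_new/2 highest- plus n_new/2 lowest-GEBV individuals."""
    if n_new % 2:
        raise ValueError("n_new must be even")
    n_pop = gebvs.values.size
    if n_pop < n_new:
        raise ValueError("population smaller than the requested tails")
    order = gebvs.ranking()
    top = order[: n_new // 2]
    bottom = order[n_pop - n_new // 2 :]
    return np.concatenate([top, bottom])


def tails_update(
    tp: TrainingPanel,
    breeding_pop_markers: np.ndarray,
    gebvs: GEBVTable,
    phenotyper,
    cycle: int,
    n_new: int = 150,
) -> TrainingPanel:
    """Refresh the TP: phenotype both GEBV tails, evict the oldest records.

    ``phenotyper(indices) -> values`` phenotypes the chosen individuals
    (one phenotyping event).  The panel stays exactly at capacity.
    """
    chosen = tails_select(gebvs, n_new)
    new_y = np.asarray(phenotyper(chosen), dtype=np.float64)
    if new_y.size != chosen.size:
        raise ValueError("phenotyper must return one value per selected individual")
    new_Z = np.asarray(breeding_pop_markers, dtype=np.float64)[chosen]
    genotypes = np.concatenate([tp.genotypes[n_new:], new_Z], axis=0)
    phenotypes = np.concatenate([tp.phenotypes[n_new:], new_y])
    cycles = np.concatenate([tp.cycle_added[n_new:], np.full(chosen.size, cycle)])
    return TrainingPanel(genotypes, phenotypes, cycles, tp.capacity, tp.marker_ids)
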