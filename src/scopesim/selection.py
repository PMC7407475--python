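"""Parental selection and mating strategies.

Four strategies turn the GEBV-ranked breeding population into a crossing
block of couples:

* **truncation / baseline** — take the n highest-GEBV individuals and
  mate them randomly;
* **scoping** — pre-select the top SR fraction by GEBV, then build
  couples where P1 is the best remaining candidate by GEBV and P2 is the
  candidate that maximizes the marker-variance score
  ``F = sum_j var(Z_j,selection) p_j`` over the selected parents.  The
  Boolean vector p masks out markers whose two alleles are already both
  present among the selected parents, steering the selection toward
  rescuing rare marker alleles; when every marker is covered, p resets
  to all-ones;
* **population merit** — start from the truncation set and hill-climb
  the merit B = mean GEBV - c * mean genomic relationship, swapping
  parents against the rest of the breeding population;
* **maximum variance total (MVT)** — fix P1 = top n/2 by GEBV and
  hill-climb the P2 half within a pre-selected pool so as to maximize
  the genetic-variance criterion mean_i((1 + F_i) - 2 Gbar_p), with F_i
  the genomic inbreeding coefficient G_ii - 1 and Gbar_p the mean
  off-diagonal relationship of the parents.

Relationships use VanRaden's genomic relationship matrix computed from
the current breeding population's marker codes and allele frequencies.
All ties are broken by higher GEBV, then lower insertion index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Couple",
    "RelationshipMatrix",
    "truncation_select",
    "random_mating",
    "fscore",
    "scoping_select",
    "vanraden_G",
    "population_merit",
    "pm_select",
    "mvt_criterion",
    "mvt_select",
]


@dataclass(frozen=True)
class Couple:
    """One parental pairing, as indices into the breeding population."""

    p1: int
    p2: int

    def __post_init__(self) -> None:
        if self.p1 == self.p2:
            raise ValueError("parents of a couple must be distinct")


@dataclass(frozen=True)
class RelationshipMatrix:
    G: np.ndarray  # (n, n) symmetric
    allele_freqs: np.ndarray  # per-marker frequency of the +1 allele

    def inbreeding(self) -> np.ndarray:
        """Genomic inbreeding coefficients F_i = G_ii - 1."""
        return np.diag(self.G) - 1.0


def _rank_desc(gebv_values: np.ndarray) -> np.ndarray:
    """Indices sorted by descending GEBV; ties keep insertion order."""
    return np.argsort(-np.asarray(gebv_values, dtype=np.float64), kind="stable")


# ---------------------------------------------------------------------------
# Baseline: truncation selection + random mating
# ---------------------------------------------------------------------------


def truncation_select(gebv_values: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n highest-GEBV individuals (stable tie-breaking)."""
    g = np.asarray(gebv_values)
    if n > g.size:
        raise ValueError(f"cannot select {n} from {g.size} individuals")
    return _rank_desc(g)[:n]


def random_mating(parent_indices, rng: np.random.Generator) -> list[Couple]:
    """Uniform random perfect matching of an even set of parents."""
    parents = np.asarray(parent_indices)
    if parents.size % 2:
        raise ValueError("random mating needs an even number of parents")
    perm = rng.permutation(parents)
    return [Couple(int(perm[2 * i]), int(perm[2 * i + 1])) for i in range(parents.size // 2)]


# ---------------------------------------------------------------------------
# Scoping: truncation pre-selection + variance-maximizing pairing
# ---------------------------------------------------------------------------


def fscore(Z_selected: np.ndarray, p: np.ndarray) -> float:
    """Masked marker-variance score of a selected parental set.

    Sample variance (n-1 denominator) of the {-1,0,+1} codes per marker,
    summed over markers with p_j = 1.  Fewer than two parents give 0.
    """
    Z = np.atleast_2d(np.asarray(Z_selected, dtype=np.float64))
    p = np.asarray(p, dtype=np.float64)
    if p.size != Z.shape[1]:
        raise ValueError("mask length must equal marker count")
    if Z.shape[0] < 2:
        return 0.0
    return float(np.var(Z, axis=0, ddof=1) @ p)


def scoping_select(
    gebv_values: np.ndarray,
    Z: np.ndarray,
    SR: float,
    n_couples: int = 50,
) -> list[Couple]:
    """Scoping parental selection and mating.

    The top ``ceil(SR * n)`` individuals by GEBV form the candidate
    pool.  Couples are built sequentially: P1 is the best remaining
    candidate by GEBV; P2 is the remaining candidate that maximizes the
    masked variance score of the selected parents including itself.
    After each couple, markers with both alleles present among the
    selected parents are masked out; if every marker is masked, the mask
    resets to all-ones.
    """
    g = np.asarray(gebv_values, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    n_pop, k = Z.shape
    if not 0.1 - 1e-9 <= SR <= 1 + 1e-9:
        raise ValueError("scoping rate must lie in [0.1, 1]")
    m = math.ceil(SR * n_pop)
    if m < 2 * n_couples:
        raise ValueError(
            f"pre-selection of {m} cannot provide {2 * n_couples} distinct parents"
        )
    cand = _rank_desc(g)[:m]  # candidate pool, best GEBV first
    avail = np.ones(m, dtype=bool)  # positions into cand
    Zc = Z[cand]

    s1 = np.zeros(k)  # running sums over selected parents
    s2 = np.zeros(k)
    has_low = np.zeros(k, dtype=bool)  # first allele seen (code <= 0)
    has_high = np.zeros(k, dtype=bool)  # second allele seen (code >= 0)
    p_mask = np.ones(k, dtype=bool)
    n_sel = 0

    def add(pos: int) -> None:
        nonlocal n_sel
        z = Zc[pos]
        s1[:] += z
        s2[:] += z * z
        has_low[:] |= z <= 0
        has_high[:] |= z >= 0
        n_sel += 1
        avail[pos] = False

    couples: list[Couple] = []
    for _ in range(n_couples):
        pos1 = int(np.flatnonzero(avail)[0])  # best remaining GEBV
        add(pos1)
        rem = np.flatnonzero(avail)
        Zr = Zc[rem]
        # variance of selected + candidate, vectorized over candidates
        m1 = s1[None, :] + Zr
        m2 = s2[None, :] + Zr * Zr
        var = (m2 - m1 * m1 / (n_sel + 1)) / n_sel  # ddof=1 with n_sel+1 rows
        scores = var @ p_mask.astype(np.float64)
        pos2 = int(rem[np.argmax(scores)])  # ties -> best GEBV (rank order)
        add(pos2)
        couples.append(Couple(int(cand[pos1]), int(cand[pos2])))
        p_mask = ~(has_low & has_high)
        if not p_mask.any():
            p_mask = np.ones(k, dtype=bool)
    return couples


# ---------------------------------------------------------------------------
# Genomic relationships (VanRaden)
# ---------------------------------------------------------------------------


def vanraden_G(Z: np.ndarray, freq_source: np.ndarray | None = None) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = MM' / (2 sum P_i (1 - P_i)).

    Column i of M is Z_i - 2 (P_i - 0.5), with P_i the frequency of the
    +1-coded allele computed from ``freq_source`` (defaults to Z itself,
    i.e., the current breeding population).  Monomorphic markers
    contribute zero to both numerator and denominator.
    """
    Z = np.asarray(Z, dtype=np.float64)
    src = Z if freq_source is None else np.asarray(freq_source, dtype=np.float64)
    P = (src + 1.0).mean(axis=0) / 2.0
    denom = 2.0 * float(P @ (1.0 - P))
    if denom == 0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    M = Z - 2.0 * (P - 0.5)
    return RelationshipMatrix(G=(M @ M.T) / denom, allele_freqs=P)


def _offdiag_mean(G: np.ndarray, idx: np.ndarray) -> float:
    sub = G[np.ix_(idx, idx)]
    n = idx.size
    return float((sub.sum() - np.trace(sub)) / (n * (n - 1)))


def population_merit(mean_value: float, c: float, avg_relationship: float) -> float:
    """Population merit B = mean parental value - c * mean relationship."""
    return mean_value - c * avg_relationship


def pm_select(
    gebv_values: np.ndarray,
    Z: np.ndarray,
    rng: np.random.Generator,
    c: float = 20.0,
    n: int = 100,
    max_passes: int = 100,
    G: np.ndarray | None = None,
) -> list[Couple]:
    """Population-merit selection with random mating.

    Starts from the truncation set; in each pass every parent slot is
    offered its best strict-improvement swap against the non-selected
    part of the breeding population, where merit is mean selected GEBV
    minus c times mean off-diagonal genomic relationship.  Stops at a
    fixed point or after ``max_passes`` passes.
    """
    g = np.asarray(gebv_values, dtype=np.float64)
    n_pop = g.size
    if n_pop <= n:
        raise ValueError("breeding population must exceed the parental count")
    if G is None:
        G = vanraden_G(Z).G
    sel = truncation_select(g, n).tolist()
    in_sel = np.zeros(n_pop, dtype=bool)
    in_sel[sel] = True
    r = G[:, sel].sum(axis=1)  # relationship row-sums against selected set
    T = float(r[sel].sum() - G[np.array(sel), np.array(sel)].sum())  # off-diag sum
    gsum = float(g[sel].sum())
    denom = n * (n - 1)

    # candidate evaluation order implements the (higher GEBV, lower index) tie-break
    for _ in range(max_passes):
        changed = False
        for slot in range(n):
            p = sel[slot]
            cand = np.flatnonzero(~in_sel)
            cand = cand[np.argsort(-g[cand], kind="stable")]
            T_new = T - 2.0 * (r[p] - G[p, p]) + 2.0 * (r[cand] - G[cand, p])
            B_new = (gsum - g[p] + g[cand]) / n - c * T_new / denom
            B_cur = gsum / n - c * T / denom
            j = int(np.argmax(B_new))
            if B_new[j] > B_cur + 1e-12:
                q = int(cand[j])
                r += G[:, q] - G[:, p]
                T = float(T_new[j])
                gsum += g[q] - g[p]
                in_sel[p] = False
                in_sel[q] = True
                sel[slot] = q
                changed = True
        if not changed:
            break
    else:
        warnings.warn(f"population-merit optimizer hit the pass cap ({max_passes})")
    return random_mating(np.array(sel), rng)


# ---------------------------------------------------------------------------
# Maximum variance total
# ---------------------------------------------------------------------------


def mvt_criterion(G_sel: np.ndarray) -> float:
    """Genetic-variance criterion (1/n) sum_i ((1 + F_i) - 2 Gbar_p)."""
    G_sel = np.asarray(G_sel, dtype=np.float64)
    n = G_sel.shape[0]
    if n < 2:
        raise ValueError("criterion needs at least two parents")
    gbar = (G_sel.sum() - np.trace(G_sel)) / (n * (n - 1))
    return float(np.trace(G_sel) / n - 2.0 * gbar)


def mvt_select(
    gebv_values: np.ndarray,
    Z: np.ndarray,
    rng: np.random.Generator,
    pre_n: int = 300,
    n: int = 100,
    max_passes: int = 100,
    G: np.ndarray | None = None,
) -> list[Couple]:
    """Maximum-variance-total selection.

    300 individuals are pre-selected by truncation; P1 = the top n/2 by
    GEBV stay fixed, P2 starts as the next n/2 and its members are
    iteratively replaced from the unused pre-selected pool so as to
    maximize the variance criterion of the full parental set.  Each P1
    is paired with a random distinct P2.
    """
    g = np.asarray(gebv_values, dtype=np.float64)
    if not g.size >= pre_n >= n:
        raise ValueError("need population >= pre_n >= n")
    if n % 2:
        raise ValueError("parent count must be even")
    if G is None:
        G = vanraden_G(Z).G
    pre = truncation_select(g, pre_n)
    p1 = pre[: n // 2].tolist()
    p2 = pre[n // 2 : n].tolist()
    pool_mask = np.zeros(g.size, dtype=bool)
    pool_mask[pre[n:]] = True

    sel = np.array(p1 + p2)
    r = G[:, sel].sum(axis=1)
    T = float(r[sel].sum() - G[sel, sel].sum())
    diag_sum = float(G[sel, sel].sum())
    denom = n * (n - 1)

    def crit(T_: float, diag_: float) -> float:
        return diag_ / n - 2.0 * T_ / denom

    for _ in range(max_passes):
        changed = False
        for slot in range(len(p2)):
            pcur = p2[slot]
            cand = np.flatnonzero(pool_mask)
            if cand.size == 0:
                break
            cand = cand[np.argsort(-g[cand], kind="stable")]
            T_new = T - 2.0 * (r[pcur] - G[pcur, pcur]) + 2.0 * (r[cand] - G[cand, pcur])
            diag_new = diag_sum - G[pcur, pcur] + G[cand, cand]
            c_new = diag_new / n - 2.0 * T_new / denom
            j = int(np.argmax(c_new))
            if c_new[j] > crit(T, diag_sum) + 1e-12:
                q = int(cand[j])
                r += G[:, q] - G[:, pcur]
                T = float(T_new[j])
                diag_sum = float(diag_new[j])
                pool_mask[q] = False
                pool_mask[pcur] = True
                p2[slot] = q
                changed = True
        if not changed:
            break
    else:
        warnings.warn(f"MVT optimizer hit the pass cap ({max_passes})")
    perm = rng.permutation(len(p2))
    return [Couple(int(p1[i]), int(p2[perm[i]])) for i in range(len(p1))]
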