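"""Genetic architecture and reproduction: QTL effects, meiosis, crossing, SSD.

The simulated trait is purely additive.  L causal loci (QTL) are drawn
uniformly from the map; the k-th QTL (k = 1..L) carries an effect a^k
with a = (L-1)/(L+1), a geometric series giving a few large and many
small effects.  At each QTL one of the two alleles is designated
favorable: the favorable homozygote scores +a^k, the heterozygote 0 and
the unfavorable homozygote -a^k.  Dominance and epistasis are absent.
All loci that are not QTL form the marker set used for genomic
prediction — markers are never causal.

Meiosis follows the standard count-location model: per chromosome the
crossover count is Poisson with mean equal to the map length in Morgans,
crossover locations are uniform, and there is no interference or
mutation (Haldane's model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .founders import Individual, MarkerMap, Population

__all__ = [
    "QTLModel",
    "GeneticValueReport",
    "sample_qtl",
    "genetic_value",
    "genetic_values",
    "meiosis",
    "gametes",
    "cross",
    "cross_block",
    "single_seed_descent",
]


# ---------------------------------------------------------------------------
# QTL model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTLModel:
    """L causal loci with geometric effects a^k and favorable orientation.

    ``favorable_sign[k]`` is +1 if the +1-coded homozygote at the k-th
    QTL is the favorable one, else -1; so the raw genetic value of an
    individual with codes z is ``sum_k z[qtl_k] * favorable_sign[k] * a^k``.
    """

    qtl_indices: np.ndarray  # (L,) int locus indices, in effect order k=1..L
    effects: np.ndarray  # (L,) float, a^k
    favorable_sign: np.ndarray  # (L,) int8, +1 / -1
    marker_indices: np.ndarray  # remaining loci, for prediction

    def __post_init__(self) -> None:
        q = np.asarray(self.qtl_indices, dtype=np.int64)
        e = np.asarray(self.effects, dtype=np.float64)
        s = np.asarray(self.favorable_sign, dtype=np.int8)
        m = np.asarray(self.marker_indices, dtype=np.int64)
        if not (q.size == e.size == s.size):
            raise ValueError("qtl_indices, effects and favorable_sign must align")
        if q.size != np.unique(q).size:
            raise ValueError("QTL indices must be distinct")
        if np.intersect1d(q, m).size:
            raise ValueError("marker set must exclude QTL loci")
        if q.size > 1 and not (np.all(e > 0) and np.all(np.diff(e) < 0)):
            raise ValueError("effects must be strictly positive and decreasing for L > 1")
        for name, arr in (("qtl_indices", q), ("effects", e), ("favorable_sign", s), ("marker_indices", m)):
            object.__setattr__(self, name, arr)

    @property
    def L(self) -> int:
        return int(self.qtl_indices.size)

    @property
    def a(self) -> float:
        return (self.L - 1) / (self.L + 1)

    @property
    def max_value(self) -> float:
        """Sum of all favorable effects — the best attainable raw value."""
        return float(self.effects.sum())

    def to_tsv(self, path, marker_map: MarkerMap) -> None:
        pd.DataFrame(
            {
                "locus_id": marker_map.locus_id[self.qtl_indices],
                "k": np.arange(1, self.L + 1),
                "effect": self.effects,
                "favorable_allele": np.where(self.favorable_sign > 0, "+1", "-1"),
            }
        ).to_csv(path, sep="\t", index=False)


def sample_qtl(marker_map: MarkerMap, L: int, seed_or_rng) -> QTLModel:
    """Draw L distinct QTL uniformly from the map and orient them randomly.

    Effects follow the geometric series a^k, k = 1..L, with
    a = (L-1)/(L+1); the largest effect (k = 1) is assigned to the first
    sampled locus.  All remaining loci become prediction markers.
    """
    n_loci = marker_map.n_loci
    if L >= n_loci:
        raise ValueError(f"need L < n_loci, got L={L}, n_loci={n_loci}")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    qtl = rng.choice(n_loci, size=L, replace=False)
    sign = np.where(rng.random(L) < 0.5, 1, -1).astype(np.int8)
    a = (L - 1) / (L + 1)
    effects = a ** np.arange(1, L + 1, dtype=np.float64)
    markers = np.setdiff1d(np.arange(n_loci), qtl)
    return QTLModel(qtl, effects, sign, markers)


# ---------------------------------------------------------------------------
# Genetic values
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticValueReport:
    raw_value: float
    normalized_value: float  # raw / sum of effects, in [-1, 1]


def genetic_values(codes_or_pop, q: QTLModel) -> np.ndarray:
    """Raw genetic values of a population (vectorized).

    ``codes_or_pop`` may be a Population or an (n, n_loci) code matrix.
    """
    codes = codes_or_pop.genotype_codes if isinstance(codes_or_pop, Population) else np.asarray(codes_or_pop)
    z = codes[..., q.qtl_indices].astype(np.float64)
    return z @ (q.favorable_sign * q.effects)


def genetic_value(ind: Individual, q: QTLModel) -> GeneticValueReport:
    """Raw and normalized (fraction-of-maximum) genetic value of one line."""
    raw = float(genetic_values(ind.genotype_code[None, :], q)[0])
    denom = q.max_value
    if denom == 0:  # single QTL with L=1 has effect a=0
        return GeneticValueReport(raw, 0.0)
    return GeneticValueReport(raw, raw / denom)


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------


def gametes(haplotypes: np.ndarray, marker_map: MarkerMap, rng: np.random.Generator) -> np.ndarray:
    """Simulate one gamete per parent for a batch of parents (vectorized).

    ``haplotypes`` has shape (B, 2, n_loci).  Per chromosome the
    crossover count is Poisson(length in Morgans), crossover positions
    are uniform over the chromosome's map span, the starting haplotype is
    chosen with probability 1/2, and alleles switch source haplotype at
    each crossover (no interference, no mutation).  Returns (B, n_loci).
    """
    haps = np.asarray(haplotypes)
    B, _, n_loci = haps.shape
    out = np.empty((B, n_loci), dtype=np.uint8)
    for c in marker_map.chromosomes:
        idx = marker_map.chrom_indices(int(c))
        pos = marker_map.position_cM[idx]
        lo, hi = pos[0], pos[-1]
        length_m = (hi - lo) / 100.0  # cM -> Morgan
        start = rng.integers(0, 2, size=B)
        n_xo = rng.poisson(length_m, size=B)
        max_xo = int(n_xo.max(initial=0))
        if max_xo == 0:
            source = np.broadcast_to(start[:, None], (B, idx.size))
        else:
            xo = rng.uniform(lo, hi, size=(B, max_xo))
            xo[np.arange(max_xo)[None, :] >= n_xo[:, None]] = np.inf
            # crossovers strictly before a locus flip its source haplotype
            n_before = (xo[:, :, None] < pos[None, None, :]).sum(axis=1)
            source = (start[:, None] + n_before) % 2
        out[:, idx] = np.take_along_axis(haps[:, :, idx], source[:, None, :], axis=1)[:, 0, :]
    return out


def meiosis(parent: Individual, marker_map: MarkerMap, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete (0/1 allele vector) from a single parent."""
    return gametes(parent.haplotypes[None, :, :], marker_map, rng)[0]


# ---------------------------------------------------------------------------
# Crossing and single-seed descent
# ---------------------------------------------------------------------------


def cross(
    p1: Individual,
    p2: Individual,
    n_offspring: int,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    origin_cycle: int = 0,
    id_prefix: str = "F1",
) -> Population:
    """F1 family: each offspring receives one independent gamete per parent."""
    if p1.id == p2.id:
        raise ValueError("parents of a cross must be distinct")
    h1 = np.repeat(p1.haplotypes[None, :, :], n_offspring, axis=0)
    h2 = np.repeat(p2.haplotypes[None, :, :], n_offspring, axis=0)
    g1 = gametes(h1, marker_map, rng)
    g2 = gametes(h2, marker_map, rng)
    haps = np.stack([g1, g2], axis=1)
    ids = [f"{id_prefix}_{p1.id}x{p2.id}_{i}" for i in range(n_offspring)]
    return Population(ids, haps, marker_map, origin_cycle)


def cross_block(
    pop: Population,
    couples: list[tuple[int, int]],
    n_offspring: int,
    rng: np.random.Generator,
    origin_cycle: int = 0,
    id_prefix: str = "F1",
) -> Population:
    """All F1s of a crossing block in one vectorized batch.

    ``couples`` holds (index_p1, index_p2) pairs into ``pop``.
    """
    i1 = np.repeat([c[0] for c in couples], n_offspring)
    i2 = np.repeat([c[1] for c in couples], n_offspring)
    g1 = gametes(pop.haplotypes[i1], pop.map, rng)
    g2 = gametes(pop.haplotypes[i2], pop.map, rng)
    haps = np.stack([g1, g2], axis=1)
    ids = [
        f"{id_prefix}_c{ci}_{k}"
        for ci in range(len(couples))
        for k in range(n_offspring)
    ]
    return Population(ids, haps, pop.map, origin_cycle)


def single_seed_descent(
    f1: Population, generations: int, rng: np.random.Generator, id_suffix: str = "ssd"
) -> Population:
    """Advance every lineage by selfing, one random seed per plant per generation.

    1000 F1 in, ``generations`` rounds of selfing, 1000 F(1+generations)
    out; each selfed seed is formed from two independent gametes of its
    single parent.
    """
    if generations < 1:
        raise ValueError("need at least one generation of selfing")
    haps = f1.haplotypes
    for _ in range(generations):
        g1 = gametes(haps, f1.map, rng)
        g2 = gametes(haps, f1.map, rng)
        haps = np.stack([g1, g2], axis=1)
    ids = [f"{i}_{id_suffix}" for i in f1.ids]
    return Population(ids, haps, f1.map, f1.origin_cycle)
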