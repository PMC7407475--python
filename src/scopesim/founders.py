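"""Founder panels: file I/O and synthetic panel generation.

A breeding program starts from a base population of fully inbred
(homozygous) lines genotyped at biallelic SNP loci.  Genotypes are coded
-1 / 0 / +1 (homozygote first allele / heterozygote / homozygote second
allele); founders, being inbred, may only carry the two homozygous codes.

The canonical on-disk dialect is a tab-separated genotype matrix
(rows = lines, first column = line id, remaining columns = {-1,+1}
codes) together with a TSV marker map (locus_id, chromosome,
position_cM).  A minimal VCF reader is provided for interoperability:
REF/ALT homozygotes map to -1/+1 and heterozygous founder records are
rejected.

When no real panel is at hand, :func:`synth_founders` generates two
inbred panels with a multi-chromosome genetic map of the same broad
shape as a North American spring barley panel (7 chromosomes of 150 cM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "Individual",
    "Population",
    "load_founders",
    "load_founders_vcf",
    "write_founders",
    "synth_founders",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Genetic map: locus identifiers, chromosome assignment, cM positions.

    Positions must be non-decreasing within each chromosome; loci are
    stored in map order (chromosome blocks, ascending position), which is
    also the column order of every genotype matrix.
    """

    locus_id: np.ndarray  # str array, shape (n_loci,)
    chromosome: np.ndarray  # int array, shape (n_loci,)
    position_cM: np.ndarray  # float array, shape (n_loci,)

    def __post_init__(self) -> None:
        lid = np.asarray(self.locus_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position_cM, dtype=np.float64)
        if not (lid.shape == chrom.shape == pos.shape) or lid.ndim != 1:
            raise ValueError("locus_id, chromosome and position_cM must be 1-D and equal length")
        if lid.size == 0:
            raise ValueError("marker map is empty")
        if len(set(lid.tolist())) != lid.size:
            raise ValueError("duplicate locus ids in marker map")
        if np.any(pos < 0):
            raise ValueError("negative cM position in marker map")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not non-decreasing on chromosome {c}")
        object.__setattr__(self, "locus_id", lid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_cM", pos)

    @property
    def n_loci(self) -> int:
        return self.locus_id.size

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_indices(self, chrom: int) -> np.ndarray:
        """Locus indices belonging to one chromosome (map order)."""
        return np.flatnonzero(self.chromosome == chrom)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if df.shape[1] < 3:
            raise ValueError("map file needs columns locus_id, chromosome, position_cM")
        return cls(
            locus_id=df.iloc[:, 0].to_numpy(dtype=object),
            chromosome=df.iloc[:, 1].to_numpy(dtype=np.int64),
            position_cM=df.iloc[:, 2].to_numpy(dtype=np.float64),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "locus_id": self.locus_id,
                "chromosome": self.chromosome,
                "position_cM": self.position_cM,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Individual:
    """A single line: two phased haplotypes over all loci.

    ``genotype_code`` is the derived h1 + h2 - 1 coding in {-1, 0, +1}.
    """

    id: str
    haplotypes: np.ndarray  # uint8, shape (2, n_loci), entries 0/1
    origin_cycle: int = 0

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2 or h.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_loci)")
        if h.max(initial=0) > 1:
            raise ValueError("haplotype alleles must be 0/1")
        object.__setattr__(self, "haplotypes", h)

    @property
    def genotype_code(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int8) - 1

    @property
    def is_homozygous(self) -> bool:
        return bool(np.array_equal(self.haplotypes[0], self.haplotypes[1]))


class Population:
    """Ordered collection of individuals sharing one marker map.

    Haplotypes are stored as a dense ``(n, 2, n_loci)`` uint8 array so
    that meiosis, genotype coding and allele-frequency computations are
    vectorized; `Individual` objects are materialized on demand.
    """

    def __init__(
        self,
        ids,
        haplotypes: np.ndarray,
        marker_map: MarkerMap,
        origin_cycle=0,
        panel_label: str | None = None,
    ):
        self.ids = list(map(str, ids))
        haps = np.ascontiguousarray(haplotypes, dtype=np.uint8)
        if haps.ndim != 3 or haps.shape[0] != len(self.ids) or haps.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_individuals, 2, n_loci)")
        if haps.shape[2] != marker_map.n_loci:
            raise ValueError(
                f"haplotype locus count {haps.shape[2]} does not match map ({marker_map.n_loci})"
            )
        if haps.max(initial=0) > 1:
            raise ValueError("haplotype alleles must be 0/1")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in population")
        self.haplotypes = haps
        self.map = marker_map
        oc = np.broadcast_to(np.asarray(origin_cycle, dtype=np.int64), (len(self.ids),))
        self.origin_cycle = np.array(oc)
        self.panel_label = panel_label

    # -- container protocol ------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i: int) -> Individual:
        return Individual(self.ids[i], self.haplotypes[i], int(self.origin_cycle[i]))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    # -- derived views -----------------------------------------------------

    @property
    def n_loci(self) -> int:
        return self.map.n_loci

    @property
    def genotype_codes(self) -> np.ndarray:
        """(n, n_loci) int8 matrix of {-1, 0, +1} codes."""
        return self.haplotypes.sum(axis=1, dtype=np.int16).astype(np.int8) - 1

    def allele_freq(self) -> np.ndarray:
        """Per-locus frequency of the second (+1 coded) allele."""
        return self.haplotypes.mean(axis=(0, 1))

    def is_fully_homozygous(self) -> bool:
        return bool(np.array_equal(self.haplotypes[:, 0, :], self.haplotypes[:, 1, :]))

    def subset(self, indices, panel_label: str | None = None) -> "Population":
        idx = np.asarray(indices, dtype=np.int64)
        return Population(
            [self.ids[i] for i in idx],
            self.haplotypes[idx],
            self.map,
            self.origin_cycle[idx],
            panel_label or self.panel_label,
        )

    @staticmethod
    def concatenate(pops: list["Population"], panel_label: str | None = None) -> "Population":
        if not pops:
            raise ValueError("no populations to concatenate")
        m = pops[0].map
        if any(p.map is not m and p.map.n_loci != m.n_loci for p in pops):
            raise ValueError("populations must share a marker map")
        return Population(
            [i for p in pops for i in p.ids],
            np.concatenate([p.haplotypes for p in pops], axis=0),
            m,
            np.concatenate([p.origin_cycle for p in pops]),
            panel_label,
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _haps_from_codes(codes: np.ndarray) -> np.ndarray:
    """Homozygous {-1,+1} codes -> phased (n, 2, L) haplotypes."""
    allele = ((codes + 1) // 2).astype(np.uint8)  # -1 -> 0, +1 -> 1
    return np.repeat(allele[:, None, :], 2, axis=1)


def load_founders(genotype_file, map_file, panel_label: str | None = None) -> Population:
    """Read an inbred founder panel from the canonical TSV dialect.

    The genotype file has one row per line (first column = id) and one
    column per locus with entries in {-1, +1}; the marker map must cover
    exactly the genotype columns, in order.  Heterozygous codes (0) are
    rejected: founders are fully inbred lines.
    """
    marker_map = MarkerMap.from_tsv(map_file)
    df = pd.read_csv(genotype_file, sep="\t", dtype={0: str})
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in founder genotype file")
    geno = df.iloc[:, 1:]
    if geno.shape[1] != marker_map.n_loci:
        raise ValueError(
            f"genotype file has {geno.shape[1]} loci but map has {marker_map.n_loci}"
        )
    if list(geno.columns) != marker_map.locus_id.tolist():
        raise ValueError("genotype column order does not match marker map")
    codes = geno.to_numpy()
    try:
        codes = codes.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric genotype code in founder file: {exc}") from exc
    if np.any(codes == 0):
        raise ValueError("heterozygous founder: code 0 found, founders must be inbred lines")
    bad = set(np.unique(codes)) - {-1, 1}
    if bad:
        raise ValueError(f"unknown genotype code(s) {sorted(bad)}; expected -1/+1")
    return Population(ids, _haps_from_codes(codes), marker_map, 0, panel_label)


def write_founders(pop: Population, genotype_file, map_file) -> None:
    """Write a fully homozygous population in the canonical TSV dialect."""
    if not pop.is_fully_homozygous():
        raise ValueError("write_founders requires a fully homozygous population")
    df = pd.DataFrame(pop.genotype_codes, columns=pop.map.locus_id)
    df.insert(0, "id", pop.ids)
    df.to_csv(genotype_file, sep="\t", index=False)
    pop.map.to_tsv(map_file)


def load_founders_vcf(vcf_file, map_file, panel_label: str | None = None) -> Population:
    """Read founders from a VCF (v4.x): REF/REF -> -1, ALT/ALT -> +1.

    Heterozygous or missing genotypes are rejected (founders are inbred).
    Records must appear in marker-map order with matching ids.
    """
    marker_map = MarkerMap.from_tsv(map_file)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    with open(vcf_file) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                sample_ids = fields[9:]
                continue
            locus_ids.append(fields[2])
            calls = [f.split(":")[0].replace("|", "/") for f in fields[9:]]
            codes = np.empty(len(calls), dtype=np.int64)
            for i, c in enumerate(calls):
                if c == "0/0":
                    codes[i] = -1
                elif c == "1/1":
                    codes[i] = 1
                else:
                    raise ValueError(
                        f"heterozygous or missing founder genotype {c!r} at {fields[2]}"
                    )
            rows.append(codes)
    if locus_ids != marker_map.locus_id.tolist():
        raise ValueError("VCF records do not match marker map loci")
    codes = np.stack(rows, axis=1)  # (n_samples, n_loci)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in VCF")
    return Population(sample_ids, _haps_from_codes(codes), marker_map, 0, panel_label)


# ---------------------------------------------------------------------------
# Synthetic founders
# ---------------------------------------------------------------------------


def uniform_map(n_loci: int, n_chrom: int, chrom_length_cM: float) -> MarkerMap:
    """Loci split into contiguous chromosome blocks, uniformly spaced in cM."""
    if n_loci < n_chrom:
        raise ValueError("need at least one locus per chromosome")
    sizes = np.full(n_chrom, n_loci // n_chrom, dtype=np.int64)
    sizes[: n_loci % n_chrom] += 1
    chroms, positions, names = [], [], []
    for c, size in enumerate(sizes, start=1):
        pos = np.linspace(0.0, chrom_length_cM, size) if size > 1 else np.array([0.0])
        chroms.append(np.full(size, c))
        positions.append(pos)
        names.extend(f"M{c}_{j}" for j in range(size))
    return MarkerMap(
        locus_id=np.array(names, dtype=object),
        chromosome=np.concatenate(chroms),
        position_cM=np.concatenate(positions),
    )


def synth_founders(
    n_lines_per_panel: int = 380,
    n_loci: int = 1590,
    n_chrom: int = 7,
    chrom_length_cM: float = 150.0,
    allele_freq_spectrum=None,
    seed: int = 0,
) -> tuple[Population, Population]:
    """Generate two synthetic inbred founder panels sharing one genetic map.

    Per-locus allele frequencies are drawn once (default: uniform on
    [0.05, 0.95]) and each inbred line draws a single founder allele per
    locus (both haplotypes identical).  The two panels share the
    frequency spectrum but are sampled independently, giving mild
    between-panel differentiation from drift, as between two breeding
    programs drawing on common germplasm.

    ``allele_freq_spectrum`` may be a ``(low, high)`` tuple for a uniform
    spectrum or a callable ``f(rng, n_loci) -> frequencies``.
    """
    if n_lines_per_panel < 2:
        raise ValueError("need at least 2 lines per panel")
    rng = np.random.default_rng(seed)
    marker_map = uniform_map(n_loci, n_chrom, chrom_length_cM)
    if allele_freq_spectrum is None:
        allele_freq_spectrum = (0.05, 0.95)
    if callable(allele_freq_spectrum):
        freqs = np.asarray(allele_freq_spectrum(rng, n_loci), dtype=np.float64)
    else:
        low, high = allele_freq_spectrum
        freqs = rng.uniform(low, high, size=n_loci)

    panels = []
    for label in ("panel_A", "panel_B"):
        alleles = (rng.random((n_lines_per_panel, n_loci)) < freqs).astype(np.uint8)
        haps = np.repeat(alleles[:, None, :], 2, axis=1)
        ids = [f"{label}_{i:04d}" for i in range(n_lines_per_panel)]
        panels.append(Population(ids, haps, marker_map, 0, label))
    poly = [np.any(p.genotype_codes != p.genotype_codes[0], axis=0).any() for p in panels]
    if not all(poly):
        warnings.warn("degenerate allele-frequency spectrum: a panel is monomorphic at all loci")
    return panels[0], panels[1]
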