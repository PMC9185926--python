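"""Shared genomic data model: coordinate arithmetic, interval indexing, sequences.

All coordinates are 0-based half-open (BED convention) internally. VCF-style
1-based positions are converted at the I/O boundary (see :mod:`epmap.io`).
Chromosome names are compared by exact string match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

BASES = "ACGT"
_CODE = {c: i for i, c in enumerate(BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap: true iff same chrom and the spans share >=1 base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def assign_bin(pos: int, bin_size: int = 5000, chrom: str = "") -> GenomicInterval:
    """Bin containing ``pos``: left-closed tiles of ``bin_size`` from 0."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if pos < 0:
        raise ValueError("pos must be >= 0")
    lo = (pos // bin_size) * bin_size
    return GenomicInterval(chrom or "bin", lo, lo + bin_size)


@dataclass
class Gene:
    gene_id: str
    interval: GenomicInterval
    strand: str
    muscle_trait_related: bool = False
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.expression is not None and self.expression < 0:
            raise ValueError("expression must be >= 0")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


CRE_CLASSES = ("active_promoter", "enhancer", "super_enhancer")


@dataclass
class CisRegElement:
    interval: GenomicInterval
    cre_class: str
    id: str

    def __post_init__(self) -> None:
        if self.cre_class not in CRE_CLASSES:
            raise ValueError(f"unknown cre_class {self.cre_class!r}")

    @property
    def is_enhancer(self) -> bool:
        # super-enhancers count as enhancers for loop/gene classification
        return self.cre_class in ("enhancer", "super_enhancer")

    @property
    def is_promoter(self) -> bool:
        return self.cre_class == "active_promoter"


MIN_LOOP_DIST = 5_000
MAX_LOOP_DIST = 2_000_000


@dataclass
class ChromatinLoop:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    contact_count: int
    fdr: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loops must be intrachromosomal")
        if self.anchor1.start >= self.anchor2.start:
            raise ValueError("anchors must be ordered (anchor1 before anchor2)")
        if not (0 < self.fdr <= 1):
            raise ValueError(f"fdr must be in (0,1], got {self.fdr}")
        if self.contact_count < 0:
            raise ValueError("contact_count must be >= 0")
        d = self.distance
        if not (MIN_LOOP_DIST <= d <= MAX_LOOP_DIST):
            raise ValueError(f"loop distance {d} outside [{MIN_LOOP_DIST}, {MAX_LOOP_DIST}]")

    @property
    def distance(self) -> int:
        """Midpoint-to-midpoint anchor distance."""
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom


@dataclass
class Tad:
    interval: GenomicInterval


@dataclass
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    af_by_breed: dict[str, float] = field(default_factory=dict)
    breed_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.snp_id}: ref == alt")
        for breed, af in self.af_by_breed.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"{self.snp_id}: AF for {breed} outside [0,1]")


@dataclass
class GwasSignal:
    snp_id: str
    chrom: str
    pos: int
    trait: str
    source: str  # array -> TAD pooling, lcs -> LD pooling

    def __post_init__(self) -> None:
        if self.source not in ("array", "lcs"):
            raise ValueError(f"source must be array|lcs, got {self.source!r}")


@dataclass
class GenotypeMatrix:
    """Dosage (0/1/2 per diploid) or haplotype (0/1 per chromosome copy) matrix.

    Rows are SNPs, columns are samples (or haplotypes when ``haplotypes=True``).
    """

    snp_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    haplotypes: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("genotype matrix shape inconsistent with ids")
        hi = 1 if self.haplotypes else 2
        if self.values.size and (self.values.min() < 0 or self.values.max() > hi):
            raise ValueError(f"genotype values must lie in [0,{hi}]")

    def row(self, snp_id: str) -> np.ndarray:
        return self.values[self.snp_ids.index(snp_id)]

    @property
    def allele_freqs(self) -> np.ndarray:
        denom = self.values.shape[1] * (1 if self.haplotypes else 2)
        return self.values.sum(axis=1) / denom


@dataclass
class Pwm:
    motif_id: str
    matrix: np.ndarray  # shape (L, 4), probabilities over A,C,G,T per position
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (L, 4)")
        if len(self.matrix) < 4:
            raise ValueError("PWM length must be >= 4")
        if (self.matrix < 0).any():
            raise ValueError("PWM entries must be >= 0")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


class IntervalIndex:
    """Overlap index over a set of intervals (or objects carrying one).

    Queries return hits in deterministic (chrom, start, end, insertion-order)
    order, matching what a brute-force scan over the sorted input would give.
    """

    def __init__(self, items: Iterable, key=None):
        self._key = key or (lambda x: x)
        self._trees: dict[str, IntervalTree] = {}
        self._items = list(items)
        for i, item in enumerate(self._items):
            iv = self._key(item)
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start, iv.end, i)

    def __len__(self) -> int:
        return len(self._items)

    def _sorted(self, idxs) -> list:
        order = sorted(idxs, key=lambda i: (self._key(self._items[i]).start,
                                            self._key(self._items[i]).end, i))
        return [self._items[i] for i in order]

    def query(self, interval: GenomicInterval) -> list:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        return self._sorted(hit.data for hit in tree.overlap(interval.start, interval.end))

    def query_point(self, chrom: str, pos: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return self._sorted(hit.data for hit in tree.at(pos))

    def any_overlap(self, interval: GenomicInterval) -> bool:
        tree = self._trees.get(interval.chrom)
        return bool(tree is not None and tree.overlaps(interval.start, interval.end))


def build_interval_index(items: Iterable, key=None) -> IntervalIndex:
    return IntervalIndex(items, key=key)


class Genome:
    """In-memory genome: per-chromosome sequences stored as uint8 codes 0..3."""

    def __init__(self, seqs: Mapping[str, np.ndarray | str]):
        self.codes: dict[str, np.ndarray] = {}
        for chrom, s in seqs.items():
            if isinstance(s, str):
                arr = np.frombuffer(s.encode(), dtype=np.uint8)
                codes = np.zeros(arr.size, dtype=np.uint8)
                for base, code in _CODE.items():
                    codes[arr == ord(base)] = code
                self.codes[chrom] = codes
            else:
                self.codes[chrom] = np.asarray(s, dtype=np.uint8)

    @property
    def chroms(self) -> list[str]:
        return list(self.codes)

    def length(self, chrom: str) -> int:
        return len(self.codes[chrom])

    def seq(self, chrom: str, start: int, end: int) -> str:
        codes = self.codes[chrom][start:end]
        return "".join(BASES[c] for c in codes)

    def set_seq(self, chrom: str, start: int, seq: str) -> None:
        arr = np.array([_CODE[b] for b in seq], dtype=np.uint8)
        self.codes[chrom][start:start + len(arr)] = arr

    def base(self, chrom: str, pos: int) -> str:
        return BASES[self.codes[chrom][pos]]


def encode_seq(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.uint8)


class KmerLocator:
    """Exact substring locator over both strands of a genome.

    Anchored on a sorted k-mer code table (k = minimum query length); the
    remainder of a query is verified by direct comparison. Suitable for the
    short (17-23 bp) mates produced by bridge-linker RNA-DNA reads.
    """

    def __init__(self, genome: Genome, k: int = 17):
        self.genome = genome
        self.k = k
        codes_parts, pos_parts, chrom_ids = [], [], []
        self._chrom_names = list(genome.codes)
        for ci, chrom in enumerate(self._chrom_names):
            g = genome.codes[chrom].astype(np.int64)
            n = g.size - k + 1
            if n <= 0:
                continue
            code = np.zeros(n, dtype=np.int64)
            for j in range(k):
                code = code * 4 + g[j:j + n]
            codes_parts.append(code)
            pos_parts.append(np.arange(n, dtype=np.int64))
            chrom_ids.append(np.full(n, ci, dtype=np.int32))
        codes = np.concatenate(codes_parts)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = np.concatenate(pos_parts)[order]
        self._chrom_id = np.concatenate(chrom_ids)[order]

    def _hits_forward(self, seq: str) -> list[tuple[str, int]]:
        if len(seq) < self.k or any(b not in _CODE for b in seq):
            return []
        q = encode_seq(seq).astype(np.int64)
        code = 0
        for j in range(self.k):
            code = code * 4 + int(q[j])
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        out = []
        for idx in range(lo, hi):
            chrom = self._chrom_names[self._chrom_id[idx]]
            pos = int(self._pos[idx])
            rest = self.genome.codes[chrom][pos + self.k: pos + len(seq)]
            if rest.size == len(seq) - self.k and np.array_equal(rest, q[self.k:]):
                out.append((chrom, pos))
        return out

    def locate(self, seq: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of ``seq`` as (chrom, start, strand)."""
        hits = [(c, p, "+") for c, p in self._hits_forward(seq)]
        rc = revcomp(seq)
        if rc != seq:
            hits += [(c, p, "-") for c, p in self._hits_forward(rc)]
        return sorted(hits)

    def locate_unique(self, seq: str) -> tuple[str, int, str] | None:
        hits = self.locate(seq)
        return hits[0] if len(hits) == 1 else None
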