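"""GRID-seq style RNA-chromatin contact parsing and caRNA calling.

A raw bridge-linker read is cDNA(RNA-mate) + linker + DNA-mate. The linker
carries a 12 bp core seed flanked by MmeI recognition motifs; the seed locates
the linker, the motifs confirm its boundaries, and the linker orientation
tells which flank is the RNA mate. Parsed mates are located on the genome,
uniquely-mapped pairs become RNA-DNA contacts, and per-gene contacts are
classified local / cis / trans and tested for chromatin association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter, defaultdict

import numpy as np
from scipy import stats as sp_stats

from .core import Gene, Genome, IntervalIndex, KmerLocator, revcomp

MIN_READ_LEN = 79
MATE_MIN, MATE_MAX = 17, 23
LOCAL_FLANK = 10_000

_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "N": "ACGT"}


def _iupac_match(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(b in _IUPAC[p] for b, p in zip(seq, pattern))


@dataclass
class LinkerSpec:
    full_seq: str
    seed12: str
    mmel_motif: str = "TCCRAC"
    max_seed_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.seed12) != 12:
            raise ValueError("seed must be 12 bp")
        if self.full_seq.count(self.seed12) != 1:
            raise ValueError("seed must occur exactly once in the linker")
        self.seed_offset = self.full_seq.index(self.seed12)
        # MmeI motif occurrences (either orientation) define the boundary checks
        self.motif_sites = []
        m, n = self.mmel_motif, len(self.mmel_motif)
        rc = "".join({"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R"}[b] for b in reversed(m))
        for pat in (m, rc):
            for i in range(len(self.full_seq) - n + 1):
                if _iupac_match(self.full_seq[i:i + n], pat):
                    self.motif_sites.append((i, pat))
        if not self.motif_sites:
            raise ValueError("linker contains no MmeI motif")


def _find_seed(read: str, seed: str, max_mm: int) -> list[int]:
    if max_mm == 0:
        out, i = [], read.find(seed)
        while i != -1:
            out.append(i)
            i = read.find(seed, i + 1)
        return out
    k = len(seed)
    return [i for i in range(len(read) - k + 1)
            if sum(a != b for a, b in zip(read[i:i + k], seed)) <= max_mm]


@dataclass
class ParsedRead:
    read_id: str
    status: str                  # ok | min_length | no_seed | ambiguous_linker | linker_boundary | mate_length
    rna_seq: str | None = None   # formal RNA read (reverse complement of the cDNA mate)
    dna_seq: str | None = None
    orientation: str = "+"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


REJECT_REASONS = ("min_length", "no_seed", "ambiguous_linker", "linker_boundary", "mate_length")


def parse_grid_read(raw_seq: str, linker: LinkerSpec, read_id: str = "") -> ParsedRead:
    """Split a raw read into (RNA, DNA) mates, or reject with a reason code."""
    if len(raw_seq) < MIN_READ_LEN:
        return ParsedRead(read_id, "min_length")
    fwd = _find_seed(raw_seq, linker.seed12, linker.max_seed_mismatches)
    rc_read = revcomp(raw_seq)
    rev = _find_seed(rc_read, linker.seed12, linker.max_seed_mismatches)
    if len(fwd) + len(rev) == 0:
        return ParsedRead(read_id, "no_seed")
    if len(fwd) + len(rev) > 1:
        return ParsedRead(read_id, "ambiguous_linker")
    orientation = "+" if fwd else "-"
    read = raw_seq if fwd else rc_read
    seed_pos = (fwd or rev)[0]
    lstart = seed_pos - linker.seed_offset
    lend = lstart + len(linker.full_seq)
    if lstart < 0 or lend > len(read):
        return ParsedRead(read_id, "linker_boundary", orientation=orientation)
    for off, pat in linker.motif_sites:
        if not _iupac_match(read[lstart + off: lstart + off + len(pat)], pat):
            return ParsedRead(read_id, "linker_boundary", orientation=orientation)
    cdna, dna = read[:lstart], read[lend:]
    if not (MATE_MIN <= len(cdna) <= MATE_MAX) or not (MATE_MIN <= len(dna) <= MATE_MAX):
        return ParsedRead(read_id, "mate_length", orientation=orientation)
    return ParsedRead(read_id, "ok", rna_seq=revcomp(cdna), dna_seq=dna, orientation=orientation)


def parse_reads(reads: list[tuple[str, str]], linker: LinkerSpec):
    """Parse many reads; returns (parsed list, Counter of statuses)."""
    parsed = [parse_grid_read(seq, linker, read_id=rid) for rid, seq in reads]
    return parsed, Counter(p.status for p in parsed)


@dataclass
class ContactPair:
    read_id: str
    rna_chrom: str
    rna_pos: int
    rna_strand: str
    dna_chrom: str
    dna_pos: int
    source_gene: str | None = None
    mode: str | None = None


def assign_pairs(parsed: list[ParsedRead], locator: KmerLocator, genes: list[Gene],
                 ) -> tuple[list[ContactPair], dict]:
    """Locate mates on the genome; keep pairs where both mates map uniquely.

    The RNA mate is matched sense-aware: its source gene must lie on the
    strand the mate located to. The built-in locator is exact substring
    matching; a real aligner can be slotted in via the same interface.
    """
    gene_index = IntervalIndex(genes, key=lambda g: g.interval)
    pairs, n_nonunique = [], 0
    for p in parsed:
        if not p.ok:
            continue
        rna_hit = locator.locate_unique(p.rna_seq)
        dna_hit = locator.locate_unique(p.dna_seq)
        if rna_hit is None or dna_hit is None:
            n_nonunique += 1
            continue
        rchrom, rpos, rstrand = rna_hit
        hits = [g for g in gene_index.query_point(rchrom, rpos)
                if g.strand == rstrand]
        source = hits[0].gene_id if hits else None
        pairs.append(ContactPair(p.read_id, rchrom, rpos, rstrand,
                                 dna_hit[0], dna_hit[1], source_gene=source))
    return pairs, {"n_ok": sum(p.ok for p in parsed), "n_nonunique": n_nonunique,
                   "n_pairs": len(pairs)}


def classify_mode(pair: ContactPair, source_gene: Gene, local_flank: int = LOCAL_FLANK) -> str:
    """local: DNA end within +/-10 kb of the gene body; cis: same chromosome
    beyond that; trans: different chromosome."""
    if pair.source_gene is None:
        raise ValueError("pair has no assigned source gene")
    if pair.dna_chrom != source_gene.chrom:
        return "trans"
    iv = source_gene.interval
    if iv.start - local_flank <= pair.dna_pos < iv.end + local_flank:
        return "local"
    return "cis"


def classify_pairs(pairs: list[ContactPair], genes: list[Gene],
                   local_flank: int = LOCAL_FLANK) -> list[ContactPair]:
    by_id = {g.gene_id: g for g in genes}
    for p in pairs:
        if p.source_gene is not None:
            p.mode = classify_mode(p, by_id[p.source_gene], local_flank)
    return pairs


@dataclass
class CaRna:
    gene_id: str
    n_pairs: int
    mode_fractions: tuple[float, float, float]  # (local, cis, trans)
    p_value: float
    q_value: float = 1.0
    enriched: bool = False


def call_caRNAs(pairs: list[ContactPair], genes: list[Gene], min_pairs: int = 10,
                q_thresh: float = 0.05) -> list[CaRna]:
    """Chromatin-associated RNAs: genes whose contact support exceeds the
    uniform background expectation (one-sided Poisson, BH-corrected) with at
    least ``min_pairs`` uniquely-assigned pairs."""
    from statsmodels.stats.multitest import multipletests

    counts: dict[str, Counter] = defaultdict(Counter)
    for p in pairs:
        if p.source_gene is not None and p.mode is not None:
            counts[p.source_gene][p.mode] += 1
    if not counts:
        return []
    total = sum(sum(c.values()) for c in counts.values())
    lam = total / max(len(genes), 1)  # uniform-across-genes background rate
    out = []
    for gid in sorted(counts):
        c = counts[gid]
        n = sum(c.values())
        fr = (c["local"] / n, c["cis"] / n, c["trans"] / n)
        pval = float(sp_stats.poisson.sf(n - 1, lam))
        out.append(CaRna(gid, n, fr, pval))
    qs = multipletests([r.p_value for r in out], method="fdr_bh")[1]
    for r, q in zip(out, qs):
        r.q_value = float(q)
        r.enriched = r.n_pairs >= min_pairs and r.q_value < q_thresh
    return out


def bin_contact_counts(pairs: list[ContactPair], chrom_lengths: dict[str, int],
                       bin_size: int = 10_000, mode: str | None = None,
                       ) -> dict[str, np.ndarray]:
    """Per-bin DNA-end counts, optionally restricted to one interaction mode."""
    out = {c: np.zeros(int(np.ceil(n / bin_size)), dtype=float)
           for c, n in chrom_lengths.items()}
    for p in pairs:
        if mode is not None and p.mode != mode:
            continue
        if p.dna_chrom in out:
            out[p.dna_chrom][p.dna_pos // bin_size] += 1
    return out


def background_correct(observed: dict[str, np.ndarray], background: dict[str, np.ndarray],
                       smooth_bins: int = 5, eps: float = 1.0):
    """Ratio-correct binned contact density against a smoothed trans-contact
    background. Returns (corrected, warned): an all-zero background leaves
    the input unchanged and sets the warning flag."""
    total_bg = sum(float(b.sum()) for b in background.values())
    if total_bg == 0:
        return {c: v.copy() for c, v in observed.items()}, True
    corrected = {}
    kernel = np.ones(smooth_bins) / smooth_bins
    for chrom, obs in observed.items():
        bg = background.get(chrom, np.zeros_like(obs))
        smoothed = np.convolve(bg, kernel, mode="same")
        corrected[chrom] = obs / (smoothed + eps)
    return corrected, False


def differential_caRNA_genes(levels_a, levels_b, lfc_thresh: float = 2.0,
                             p_thresh: float = 0.05, pseudocount: float = 1.0):
    """Differentially caRNA-regulated genes; same moderated test as the loop
    score comparison but at the stricter |log2FC| > 2 decision rule."""
    from .loops import differential_genes

    return differential_genes(levels_a, levels_b, lfc_thresh=lfc_thresh,
                              p_thresh=p_thresh, pseudocount=pseudocount)
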