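"""GWAS fine-mapping through the 3D genome.

Candidate SNPs are pooled per leading signal — the TAD containing the signal
for array-based GWAS, an LD r^2 >= 0.5 neighborhood for sequencing-based
GWAS — then passed through a 5-step filter: (1) inside a loop-mediated
enhancer or active promoter; (2) inside an ATAC peak or footprint;
(3) |deltaAF| >= 0.5 between lean and local breed groups; (4) a loop-linked
target gene that is muscle-trait-related and has an intra-chromosomal
RNA-chromatin contact; (5) a predicted strong effect on TF binding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (Gene, GenomicInterval, GenotypeMatrix, GwasSignal,
                   IntervalIndex, SnpRecord, Tad, overlaps)
from .loops import promoter_region
from .motifs import AlleleEffect, best_effects

logger = logging.getLogger(__name__)

DAF_MIN = 0.5
R2_MIN = 0.5
LD_WINDOW = 2_000_000


@dataclass
class CandidatePool:
    signal: GwasSignal
    route: str  # tad | ld
    snp_ids: list[str]
    n_monomorphic_skipped: int = 0


def pool_by_tad(signal: GwasSignal, tads: list[Tad], snps: list[SnpRecord]) -> CandidatePool:
    """All SNPs inside the single TAD containing the signal (array route)."""
    if signal.source != "array":
        raise ValueError("TAD pooling applies to array-based signals")
    hits = [t for t in tads if t.interval.contains(signal.chrom, signal.pos)]
    if len(hits) > 1:
        raise ValueError(f"signal {signal.snp_id} covered by {len(hits)} overlapping TADs")
    if not hits:
        logger.warning("signal %s outside all TADs; empty pool", signal.snp_id)
        return CandidatePool(signal, "tad", [])
    tad = hits[0].interval
    ids = [s.snp_id for s in snps if tad.contains(s.chrom, s.pos)]
    return CandidatePool(signal, "tad", ids)


def ld_r2(x, y) -> float:
    """Squared Pearson correlation of genotype vectors (composite LD on
    dosages; haplotype r^2 when 0/1 haplotype columns are supplied)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("genotype vectors must have equal length")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("monomorphic")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pool_by_ld(signal: GwasSignal, genotypes: GenotypeMatrix, snps: list[SnpRecord],
               r2_min: float = R2_MIN, window: int = LD_WINDOW) -> CandidatePool:
    """SNPs within ``window`` of the signal with LD r^2 >= ``r2_min`` (LCS
    route); the signal SNP itself is always pooled."""
    if signal.source != "lcs":
        raise ValueError("LD pooling applies to LCS-based signals")
    if signal.snp_id not in genotypes.snp_ids:
        raise ValueError(f"signal SNP {signal.snp_id} absent from genotype matrix")
    sig_vec = genotypes.row(signal.snp_id)
    ids, n_mono = [], 0
    in_matrix = set(genotypes.snp_ids)
    for s in snps:
        if s.chrom != signal.chrom or abs(s.pos - signal.pos) > window:
            continue
        if s.snp_id not in in_matrix:
            continue
        if s.snp_id == signal.snp_id:
            ids.append(s.snp_id)
            continue
        vec = genotypes.row(s.snp_id)
        if np.var(vec) == 0:
            n_mono += 1
            continue
        try:
            if ld_r2(sig_vec, vec) >= r2_min:
                ids.append(s.snp_id)
        except ValueError:
            n_mono += 1
    return CandidatePool(signal, "ld", ids, n_monomorphic_skipped=n_mono)


def pool_candidates(signal: GwasSignal, tads, genotypes, snps, **kwargs) -> CandidatePool:
    if signal.source == "array":
        return pool_by_tad(signal, tads, snps)
    return pool_by_ld(signal, genotypes, snps, **kwargs)


def delta_af(snp: SnpRecord, lean_breeds: list[str], local_breeds: list[str]) -> float:
    """Mean alt AF over lean breeds minus mean over local breeds, in [-1, 1]."""
    for breed in list(lean_breeds) + list(local_breeds):
        if breed not in snp.af_by_breed:
            raise ValueError(f"{snp.snp_id}: no allele frequency for breed {breed!r}")
    lean = np.mean([snp.af_by_breed[b] for b in lean_breeds])
    local = np.mean([snp.af_by_breed[b] for b in local_breeds])
    return float(lean - local)


def assign_target_genes(snp: SnpRecord, cres, loops, genes,
                        cre_index: IntervalIndex | None = None) -> list[str]:
    """Genes whose promoter sits on the distal anchor of a loop whose
    proximal anchor overlaps the SNP's element; a SNP inside an active
    promoter additionally targets that promoter's own gene."""
    if cre_index is None:
        cre_index = IntervalIndex(cres, key=lambda c: c.interval)
    containing = [c for c in cre_index.query_point(snp.chrom, snp.pos)]
    proms = {g.gene_id: promoter_region(g, cre_index) for g in genes}
    targets: set[str] = set()
    for cre in containing:
        if cre.is_promoter:
            for g in genes:
                if overlaps(proms[g.gene_id], cre.interval):
                    targets.add(g.gene_id)
        for lp in loops:
            if lp.chrom != snp.chrom:
                continue
            distal = None
            if overlaps(lp.anchor1, cre.interval):
                distal = lp.anchor2
            elif overlaps(lp.anchor2, cre.interval):
                distal = lp.anchor1
            if distal is None:
                continue
            for g in genes:
                if g.chrom == distal.chrom and overlaps(proms[g.gene_id], distal):
                    targets.add(g.gene_id)
    return sorted(targets)


@dataclass
class CandidateVariant:
    snp_id: str
    trait: str
    route: str
    cre_id: str
    cre_class: str
    target_genes: list[str]
    delta_af: float
    motif_effects: list[AlleleEffect]
    steps_passed: tuple[bool, bool, bool, bool, bool]


@dataclass
class FilterAudit:
    pool_size: int
    dropped_at_step: dict[int, int] = field(default_factory=lambda: {k: 0 for k in range(1, 6)})
    emitted: int = 0
    verdicts: dict[str, list] = field(default_factory=dict)  # snp_id -> per-step bool/None

    def first_failed(self, snp_id: str) -> int | None:
        v = self.verdicts[snp_id]
        for k, ok in enumerate(v, 1):
            if ok is False:
                return k
        return None


class FilterContext:
    """Pre-indexed inputs shared across pools for the 5-step filter."""

    def __init__(self, cres, loops, atac_peaks, footprints, contacts, genes,
                 pwms, genome, lean_breeds, local_breeds):
        self.cres = cres
        self.loops = loops
        self.genes = genes
        self.pwms = pwms
        self.genome = genome
        self.lean_breeds = lean_breeds
        self.local_breeds = local_breeds
        self.cre_index = IntervalIndex(cres, key=lambda c: c.interval)
        anchors = []
        for lp in loops:
            anchors.append(lp.anchor1)
            anchors.append(lp.anchor2)
        self.anchor_index = IntervalIndex(anchors)
        self.open_index = IntervalIndex(list(atac_peaks) + list(footprints))
        self.gene_by_id = {g.gene_id: g for g in genes}
        # genes with >=1 intra-chromosomal (local or cis) RNA contact
        self.intra_contact_counts: dict[str, int] = {}
        for p in contacts:
            if p.source_gene is not None and p.mode in ("local", "cis"):
                self.intra_contact_counts[p.source_gene] = \
                    self.intra_contact_counts.get(p.source_gene, 0) + 1
        # loops bucketed by anchor overlap would be faster; pool sizes are
        # small enough that the per-CRE scan in assign_target_genes suffices


def five_step_filter(pool: CandidatePool, snps_by_id: dict[str, SnpRecord],
                     ctx: FilterContext, daf_min: float = DAF_MIN,
                     min_contacts: int = 1) -> tuple[list[CandidateVariant], FilterAudit]:
    """Apply the 5-step filter to a candidate pool.

    Steps short-circuit: verdicts after the first failure are None in the
    audit. Filters drop, never raise, except on malformed inputs.
    """
    audit = FilterAudit(pool_size=len(pool.snp_ids))
    out = []
    for snp_id in pool.snp_ids:
        snp = snps_by_id[snp_id]
        verdicts: list = [None] * 5
        # step 1: inside a CRE overlapping >=1 loop anchor ("loop-mediated")
        containing = [c for c in ctx.cre_index.query_point(snp.chrom, snp.pos)]
        mediated = [c for c in containing if ctx.anchor_index.any_overlap(c.interval)]
        verdicts[0] = bool(mediated)
        if not mediated:
            audit.dropped_at_step[1] += 1
            audit.verdicts[snp_id] = verdicts
            continue
        # step 2: open chromatin (ATAC peak or footprint)
        verdicts[1] = bool(ctx.open_index.query_point(snp.chrom, snp.pos))
        if not verdicts[1]:
            audit.dropped_at_step[2] += 1
            audit.verdicts[snp_id] = verdicts
            continue
        # step 3: breed-group allele-frequency divergence
        daf = delta_af(snp, ctx.lean_breeds, ctx.local_breeds)
        verdicts[2] = abs(daf) >= daf_min
        if not verdicts[2]:
            audit.dropped_at_step[3] += 1
            audit.verdicts[snp_id] = verdicts
            continue
        # step 4: muscle-trait target gene with intra-chromosomal RNA contact
        targets = assign_target_genes(snp, ctx.cres, ctx.loops, ctx.genes,
                                      cre_index=ctx.cre_index)
        qualifying = [
            gid for gid in targets
            if ctx.gene_by_id[gid].muscle_trait_related
            and ctx.intra_contact_counts.get(gid, 0) >= min_contacts]
        verdicts[3] = bool(qualifying)
        if not qualifying:
            audit.dropped_at_step[4] += 1
            audit.verdicts[snp_id] = verdicts
            continue
        # step 5: predicted strong effect on TF binding
        effects = best_effects(snp, ctx.pwms, ctx.genome)
        strong = [e for e in effects if e.classification == "strong"]
        verdicts[4] = bool(strong)
        if not strong:
            audit.dropped_at_step[5] += 1
            audit.verdicts[snp_id] = verdicts
            continue
        audit.verdicts[snp_id] = verdicts
        audit.emitted += 1
        # promoter precedence when the SNP sits in both CRE classes
        cre = sorted(mediated, key=lambda c: (not c.is_promoter, c.id))[0]
        out.append(CandidateVariant(
            snp_id=snp.snp_id, trait=pool.signal.trait, route=pool.route,
            cre_id=cre.id, cre_class=cre.cre_class, target_genes=qualifying,
            delta_af=daf, motif_effects=effects,
            steps_passed=(True, True, True, True, True)))
    return out, audit
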