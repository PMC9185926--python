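"""Synthetic dataset generator with planted ground truth.

Emulates the structure of a two-breed skeletal-muscle multi-omics study:
a random genome; genes and cis-regulatory elements; TADs; enhancer-promoter
loops whose targets skip the nearest gene at a configurable rate (default
0.75, with a log-normal loop-distance law peaking near 80 kb); two diverged
populations with Balding-Nichols allele frequencies (closed-form FST equal to
the divergence parameter F); planted selective-sweep windows; RNA-chromatin
contact pairs with a local/cis/trans mix; raw bridge-linker reads; and a set
of planted causal variants that pass the 5-step fine-mapping filter next to
decoys that each violate exactly one designated step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from functools import cached_property
from pathlib import Path

import numpy as np

from . import io as eio
from .core import (BASES, ChromatinLoop, CisRegElement, Gene, GenomicInterval,
                   Genome, GenotypeMatrix, GwasSignal, IntervalIndex,
                   KmerLocator, Pwm, SnpRecord, Tad, assign_bin, revcomp)
from .grid import ContactPair, LinkerSpec
from .motifs import best_effects

LEAN_BREEDS = ["LW", "LR", "DU", "PI"]
LOCAL_BREEDS = ["MS", "EH", "JH", "BX", "LC", "RT"]
TRAITS = ["FCR", "ADG", "AGE", "BW", "FCR_BV", "AGE_BV", "meat_color",
          "conductivity", "drip_loss", "marbling", "moisture", "pH",
          "IMF", "LMD", "LMP"]

DEFAULT_SEED12 = "ATCGCAGGTTAC"


def default_linker() -> LinkerSpec:
    """45 bp bridge linker: MmeI motifs at both ends, 12 bp core seed inside.

    45 bp keeps the shortest parseable read (17 + 45 + 17) at the 79 bp
    minimum-length cutoff.
    """
    full = "TCCGAC" + "GATTACAGGT" + DEFAULT_SEED12 + "CCATGATTAGG" + "GTCGGA"
    assert len(full) == 45
    assert DEFAULT_SEED12 not in revcomp(full)
    return LinkerSpec(full_seq=full, seed12=DEFAULT_SEED12)


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 500
    n_enhancers: int = 600
    n_tads: int = 40
    n_loops: int = 2000
    loop_distance_log_mean: float = float(np.log(80_000))
    loop_distance_log_sd: float = 0.8
    n_snps: int = 5000
    n_samples_per_pop: int = 50
    divergence_F: float = 0.2
    frac_skipping: float = 0.75
    n_causal: int = 10
    n_decoys: int = 50
    n_contact_pairs: int = 20_000
    mode_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_grid_reads: int = 10_000
    grid_corrupt_frac: float = 0.0
    n_sweep_windows: int = 3
    sweep_window_size: int = 50_000
    n_sweep_snps: int = 30
    n_atac_peaks: int = 300
    replicate_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.divergence_F < 1):
            raise ValueError("divergence_F must lie in (0,1)")
        if not (0 <= self.frac_skipping <= 1):
            raise ValueError("frac_skipping must lie in [0,1]")

    @property
    def linker(self) -> LinkerSpec:
        return default_linker()


@dataclass
class TruthTable:
    planted_causal: list[dict] = field(default_factory=list)
    planted_decoys: list[dict] = field(default_factory=list)
    contact_modes: dict[str, str] = field(default_factory=dict)
    read_truth: dict[str, dict] = field(default_factory=dict)
    sweep_windows: list[list] = field(default_factory=list)  # [chrom, start, end]
    reg_loops: list[dict] = field(default_factory=list)  # enhancer_id, gene_id, skip
    enhancer_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "TruthTable":
        return cls(**d)


@dataclass
class Bundle:
    config: SimConfig
    genome: Genome
    tads: list[Tad]
    genes: list[Gene]
    cres: list[CisRegElement]
    loops_by_sample: dict[str, list[ChromatinLoop]]
    snps: list[SnpRecord]
    haps: dict[str, GenotypeMatrix]      # pop -> phased haplotypes
    genotypes: dict[str, GenotypeMatrix]  # pop -> dosages
    signals: list[GwasSignal]
    atac_peaks: list[GenomicInterval]
    footprints: list[GenomicInterval]
    pwms: list[Pwm]
    contacts: list[ContactPair]
    grid_reads: list[tuple[str, str]]
    truth: TruthTable

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.genome.length(c) for c in self.genome.chroms}

    @cached_property
    def locator(self) -> KmerLocator:
        return KmerLocator(self.genome)

    @cached_property
    def snps_by_id(self) -> dict[str, SnpRecord]:
        return {s.snp_id: s for s in self.snps}

    @cached_property
    def combined_genotypes(self) -> GenotypeMatrix:
        a, b = self.genotypes["lean"], self.genotypes["local"]
        return GenotypeMatrix(a.snp_ids, a.sample_ids + b.sample_ids,
                              np.hstack([a.values, b.values]))


# ------------------------------------------------------------------ PWMs

def _pure_pwm(motif_id: str, consensus: str) -> Pwm:
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, BASES.index(b)] = 1.0
    return Pwm(motif_id, mat)


def _soft_pwm(motif_id: str, consensus: str, p_max: float = 0.85) -> Pwm:
    mat = np.full((len(consensus), 4), (1 - p_max) / 3)
    for i, b in enumerate(consensus):
        mat[i, BASES.index(b)] = p_max
    return Pwm(motif_id, mat)


def default_pwm_library() -> list[Pwm]:
    """Four sharp 6-mers (plantable single-base effects span 1/6 of the
    relative-score range) plus two softer 8-mers."""
    return [
        _pure_pwm("TF01", "ACGTCA"),
        _pure_pwm("TF02", "TGACGG"),
        _pure_pwm("TF03", "CATTGC"),
        _pure_pwm("TF04", "GGATAC"),
        _soft_pwm("TF05", "ACGTACGT"),
        _soft_pwm("TF06", "TTGACCAA"),
    ]


# ------------------------------------------------------------------ genotypes

def bn_af(rng: np.random.Generator, p, F: float):
    """Balding-Nichols subpopulation allele frequency around ancestral p."""
    p = np.asarray(p, dtype=float)
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(a, b)


@dataclass
class GenotypeSim:
    chroms: np.ndarray
    positions: np.ndarray
    hap_a: np.ndarray  # sites x 2n
    hap_b: np.ndarray
    sweep_windows: list[GenomicInterval]
    sweep_mask: np.ndarray


def simulate_genotypes(n_snps: int, n_samples_per_pop: int, divergence_F: float,
                       chrom_lengths: dict[str, int], seed: int = 0,
                       n_sweep_windows: int = 0, sweep_window_size: int = 50_000,
                       n_sweep_snps: int = 30, sweep_hap_frac: float = 0.9,
                       ) -> GenotypeSim:
    """Two diverged populations under Balding-Nichols drift, with optional
    planted hard sweeps in population A (a shared core haplotype at
    ``sweep_hap_frac`` pushing window AFs toward fixation)."""
    rng = np.random.default_rng(seed)
    names = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in names], dtype=float)
    ci = rng.choice(len(names), size=n_snps, p=lens / lens.sum())
    pos = np.array([rng.integers(0, chrom_lengths[names[c]]) for c in ci])
    chroms = np.array([names[c] for c in ci])
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    nh = 2 * n_samples_per_pop
    af_a = bn_af(rng, p_anc, divergence_F)
    af_b = bn_af(rng, p_anc, divergence_F)
    hap_a = (rng.random((n_snps, nh)) < af_a[:, None]).astype(np.int8)
    hap_b = (rng.random((n_snps, nh)) < af_b[:, None]).astype(np.int8)
    sweep_mask = np.zeros(n_snps, dtype=bool)

    sweeps = []
    if n_sweep_windows:
        chrom = names[0]
        L = chrom_lengths[chrom]
        span = L // (n_sweep_windows + 1)
        extra_c, extra_p, extra_a, extra_b = [], [], [], []
        for w in range(n_sweep_windows):
            start = ((w + 1) * span // sweep_window_size) * sweep_window_size
            win = GenomicInterval(chrom, start, start + sweep_window_size)
            sweeps.append(win)
            wpos = np.sort(rng.integers(win.start, win.end, size=n_sweep_snps))
            wp = rng.uniform(0.1, 0.4, size=n_sweep_snps)
            core = rng.random(nh) < sweep_hap_frac  # shared sweep haplotypes in A
            ha = (rng.random((n_sweep_snps, nh)) < wp[:, None]).astype(np.int8)
            ha[:, core] = 1
            hb = (rng.random((n_sweep_snps, nh)) <
                  bn_af(rng, wp, divergence_F)[:, None]).astype(np.int8)
            extra_c.append(np.full(n_sweep_snps, chrom))
            extra_p.append(wpos)
            extra_a.append(ha)
            extra_b.append(hb)
        chroms = np.concatenate([chroms] + extra_c)
        pos = np.concatenate([pos] + extra_p)
        hap_a = np.vstack([hap_a] + extra_a)
        hap_b = np.vstack([hap_b] + extra_b)
        sweep_mask = np.concatenate(
            [sweep_mask, np.ones(n_sweep_windows * n_sweep_snps, dtype=bool)])

    order = np.lexsort((pos, chroms))
    return GenotypeSim(chroms[order], pos[order], hap_a[order], hap_b[order],
                       sweeps, sweep_mask[order])


# ------------------------------------------------------------------ simulate

class _SnpSpec:
    """Mutable SNP under construction; ids are assigned after the final sort."""

    __slots__ = ("chrom", "pos", "ref", "alt", "afs", "hap_a", "hap_b", "tag")

    def __init__(self, chrom, pos, ref, alt, afs, hap_a, hap_b, tag="neutral"):
        self.chrom, self.pos, self.ref, self.alt = chrom, pos, ref, alt
        self.afs, self.hap_a, self.hap_b, self.tag = afs, hap_a, hap_b, tag


def _loop_key(chrom, p1, p2):
    b1 = assign_bin(min(p1, p2), 5000, chrom)
    b2 = assign_bin(max(p1, p2), 5000, chrom)
    return None if b1.start == b2.start else (chrom, b1.start, b2.start)


class _Simulator:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
        self.truth = TruthTable()
        self.cres: list[CisRegElement] = []
        self.loop_specs: dict[tuple, dict] = {}  # key -> {count, log10fdr}
        self.atac: list[GenomicInterval] = []
        self.footprints: list[GenomicInterval] = []
        self.snp_specs: list[_SnpSpec] = []
        self.planted_zones: list[GenomicInterval] = []
        self._cre_trees: dict[str, "object"] = {}
        self.contact_specs: list[dict] = []
        self.pwms = default_pwm_library()
        self._n_enh = 0

    # -- geography -------------------------------------------------

    def make_genome(self):
        self.genome = Genome({c: self.rng.integers(0, 4, self.cfg.chrom_length)
                              .astype(np.uint8) for c in self.chrom_names})

    def make_tads(self):
        per = max(1, self.cfg.n_tads // self.cfg.n_chroms)
        self.tads = []
        L = self.cfg.chrom_length
        for chrom in self.chrom_names:
            edges = np.linspace(0, L, per + 1)
            jitter = self.rng.uniform(-0.1, 0.1, per - 1) * (L / per)
            edges[1:-1] = edges[1:-1] + jitter
            edges = np.round(edges).astype(int)
            for a, b in zip(edges, edges[1:]):
                self.tads.append(Tad(GenomicInterval(chrom, int(a), int(b))))

    def make_genes(self):
        per = self.cfg.n_genes // self.cfg.n_chroms
        if per < 2:
            raise ValueError("infeasible config: need >=2 genes per chromosome")
        L = self.cfg.chrom_length
        pitch = L / per
        self.genes = []
        gi = 0
        for chrom in self.chrom_names:
            centers = (np.arange(per) + 0.5) * pitch \
                + self.rng.uniform(-0.3, 0.3, per) * pitch
            for c in centers:
                gi += 1
                length = int(self.rng.integers(5_000, 30_000))
                start = int(np.clip(c - length / 2, 0, L - length - 1))
                strand = "+" if self.rng.random() < 0.5 else "-"
                self.genes.append(Gene(f"g{gi:04d}",
                                       GenomicInterval(chrom, start, start + length),
                                       strand))
        self.tss_by_chrom = {
            c: sorted((g.tss, g) for g in self.genes if g.chrom == c)
            for c in self.chrom_names}

    def _register_cre(self, cre: CisRegElement) -> None:
        from intervaltree import IntervalTree
        tree = self._cre_trees.setdefault(cre.interval.chrom, IntervalTree())
        tree.addi(cre.interval.start, cre.interval.end)

    def _near_any_cre(self, chrom, mid, half=1000) -> bool:
        tree = self._cre_trees.get(chrom)
        return bool(tree is not None and tree.overlaps(max(0, mid - half), mid + half))

    def make_promoter_cres(self):
        self.prom_cre_of: dict[str, CisRegElement] = {}
        for g in self.genes:
            if self.rng.random() < 0.7:
                iv = GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 500)
                cre = CisRegElement(iv, "active_promoter", f"P_{g.gene_id}")
                self.cres.append(cre)
                self._register_cre(cre)
                self.prom_cre_of[g.gene_id] = cre

    def _new_enhancer(self, chrom, mid, length=1000, super_enh=False) -> CisRegElement:
        self._n_enh += 1
        iv = GenomicInterval(chrom, max(0, mid - length // 2), mid + length // 2)
        cre = CisRegElement(iv, "super_enhancer" if super_enh else "enhancer",
                            f"E{self._n_enh:04d}")
        self.cres.append(cre)
        self._register_cre(cre)
        return cre

    def _nearest_gene(self, chrom, mid) -> Gene:
        genes = [g for _, g in self.tss_by_chrom[chrom]]
        return min(genes, key=lambda g: (abs(g.tss - mid), g.tss, g.gene_id))

    def _tad_of(self, chrom, pos) -> Tad | None:
        for t in self.tads:
            if t.interval.contains(chrom, pos):
                return t
        return None

    def _add_loop(self, chrom, p1, p2, strong=False):
        key = _loop_key(chrom, p1, p2)
        if key is None or abs(key[2] - key[1]) > 2_000_000:
            return None
        if key not in self.loop_specs:
            lf = self.rng.uniform(2.5, 6.0) if strong else self.rng.uniform(1.5, 5.0)
            self.loop_specs[key] = {
                "count": int(self.rng.poisson(20)) + 1, "log10fdr": lf}
        return key

    def make_regulatory_loops(self):
        """Enhancer->promoter loops; the target skips the nearest gene with
        probability frac_skipping, staying within the enhancer's TAD."""
        per = self.cfg.n_enhancers // self.cfg.n_chroms
        L = self.cfg.chrom_length
        counts: dict[str, int] = {}
        for chrom in self.chrom_names:
            tss = np.array([t for t, _ in self.tss_by_chrom[chrom]])
            placed = 0
            tries = 0
            while placed < per and tries < per * 50:
                tries += 1
                mid = int(self.rng.integers(5_000, L - 5_000))
                if np.min(np.abs(tss - mid)) < 3_000:
                    continue
                tad = self._tad_of(chrom, mid)
                if tad is None:
                    continue
                enh = self._new_enhancer(chrom, mid,
                                         **({"length": 5000, "super_enh": True}
                                            if self.rng.random() < 0.05 else {}))
                placed += 1
                nearest = self._nearest_gene(chrom, mid)
                in_tad = [g for _, g in self.tss_by_chrom[chrom]
                          if tad.interval.contains(chrom, g.tss)
                          and abs(g.tss - mid) >= 10_000]
                skip_candidates = [g for g in in_tad if g.gene_id != nearest.gene_id]
                want_skip = self.rng.random() < self.cfg.frac_skipping
                if want_skip and skip_candidates:
                    target = skip_candidates[int(self.rng.integers(len(skip_candidates)))]
                else:
                    target = nearest
                if not self._add_loop(chrom, mid, target.tss):
                    continue
                skipped = target.gene_id != nearest.gene_id
                self.truth.reg_loops.append(
                    {"enhancer_id": enh.id, "gene_id": target.gene_id, "skip": skipped})
                counts[target.gene_id] = counts.get(target.gene_id, 0) + 1
        self.truth.enhancer_counts = counts

    def make_background_loops(self):
        need = self.cfg.n_loops - len(self.loop_specs)
        lengths = np.array([t.interval.length for t in self.tads], dtype=float)
        tries = 0
        while len(self.loop_specs) < self.cfg.n_loops and tries < need * 100:
            tries += 1
            t = self.tads[int(self.rng.choice(len(self.tads), p=lengths / lengths.sum()))]
            iv = t.interval
            p1 = int(self.rng.integers(iv.start, iv.end))
            d = int(np.exp(self.rng.normal(self.cfg.loop_distance_log_mean,
                                           self.cfg.loop_distance_log_sd)))
            if not (5_000 <= d <= 2_000_000):
                continue
            p2 = p1 + d
            if self.rng.random() < 0.95:  # stay within the TAD
                if p2 >= iv.end:
                    continue
            elif p2 >= self.cfg.chrom_length:
                continue
            self._add_loop(iv.chrom, p1, p2)

    # -- planting --------------------------------------------------

    def _reserve(self, iv: GenomicInterval):
        self.planted_zones.append(iv)

    def _clear_of_planted(self, chrom, mid, half=1500) -> bool:
        probe = GenomicInterval(chrom, max(0, mid - half), mid + half)
        from .core import overlaps as _ov
        return not any(_ov(probe, z) for z in self.planted_zones)

    def _divergent_afs(self, target_daf: float) -> dict[str, float]:
        """Breed AFs with |mean(lean) - mean(local)| close to ``target_daf``."""
        sign = 1 if self.rng.random() < 0.5 else -1
        hi = 0.5 + target_daf / 2
        lo = 0.5 - target_daf / 2
        jit = lambda c: float(np.clip(c + self.rng.uniform(-0.02, 0.02), 0, 1))
        afs = {}
        for b in LEAN_BREEDS:
            afs[b] = jit(hi) if sign > 0 else jit(lo)
        for b in LOCAL_BREEDS:
            afs[b] = jit(lo) if sign > 0 else jit(hi)
        return afs

    def _neutral_hap_cols(self):
        nh = 2 * self.cfg.n_samples_per_pop
        return ((self.rng.random(nh) < 0.5).astype(np.int8),
                (self.rng.random(nh) < 0.5).astype(np.int8))

    def _plant_motif_site(self, chrom, pos, pwm: Pwm, enhance: bool):
        """Write a consensus site so the SNP base is motif column 2; returns
        (ref, alt). ``enhance``: the genome carries a broken site the alt
        allele completes; otherwise ref is the consensus base alt breaks."""
        j_star = 2
        site_start = pos - j_star
        self.genome.set_seq(chrom, site_start, pwm.consensus)
        cons = pwm.consensus[j_star]
        others = [b for b in BASES if b != cons]
        other = others[int(self.rng.integers(3))]
        if enhance:
            self.genome.set_seq(chrom, pos, other)
            return other, cons
        return cons, other

    def _ensure_strong(self, chrom, pos, pwm: Pwm, enhance: bool,
                       max_tries: int = 50):
        """Plant a consensus site at the SNP and verify the predicted effect
        is classified strong; re-randomize the flank if a chance near-match
        elsewhere in the scan window masks the planted shift."""
        for _ in range(max_tries):
            ref, alt = self._plant_motif_site(chrom, pos, pwm, enhance)
            snp = SnpRecord("tmp", chrom, pos, ref, alt)
            effects = best_effects(snp, [pwm], self.genome)
            if effects[0].classification == "strong":
                return ref, alt
            flank = len(pwm) - 1
            start = max(0, pos - flank)
            w = self.rng.integers(0, 4, pos + flank + 1 - start).astype(np.uint8)
            self.genome.codes[chrom][start:pos + flank + 1] = w
        raise RuntimeError("could not plant a strong motif site")

    def _scrub_motifs(self, spec: _SnpSpec, max_tries: int = 50):
        """Re-randomize the SNP flank until no PWM calls a strong effect."""
        chrom, pos = spec.chrom, spec.pos
        for _ in range(max_tries):
            snp = SnpRecord("tmp", chrom, pos, spec.ref, spec.alt)
            effects = best_effects(snp, self.pwms, self.genome)
            if all(e.classification != "strong" for e in effects):
                return
            flank = max(len(p) for p in self.pwms)
            start = max(0, pos - flank)
            w = self.rng.integers(0, 4, pos + flank + 1 - start).astype(np.uint8)
            self.genome.codes[chrom][start:pos + flank + 1] = w
            spec.ref = self.genome.base(chrom, pos)
            spec.alt = [b for b in BASES if b != spec.ref][int(self.rng.integers(3))]
        raise RuntimeError("could not scrub accidental motif matches")

    def _plant_open_chromatin(self, chrom, pos):
        self.atac.append(GenomicInterval(chrom, max(0, pos - 250), pos + 250))
        self.footprints.append(GenomicInterval(chrom, max(0, pos - 25), pos + 25))

    def _plant_contacts(self, gene: Gene, n_local=5, n_cis=3):
        for _ in range(n_local):
            lo = max(0, gene.interval.start - 9_000)
            hi = min(self.cfg.chrom_length, gene.interval.end + 9_000)
            self.contact_specs.append(
                {"gene": gene, "mode": "local",
                 "dna_chrom": gene.chrom, "dna_pos": int(self.rng.integers(lo, hi))})
        for _ in range(n_cis):
            self.contact_specs.append(
                {"gene": gene, "mode": "cis",
                 "dna_chrom": gene.chrom, "dna_pos": self._cis_pos(gene)})

    def _cis_pos(self, gene: Gene) -> int:
        L = self.cfg.chrom_length
        for _ in range(100):
            p = int(self.rng.integers(0, L))
            if not (gene.interval.start - 10_000 <= p < gene.interval.end + 10_000):
                return p
        raise RuntimeError("could not place cis contact")

    def _pick_target(self, tad: Tad, exclude=()) -> tuple[Gene, int] | None:
        """A gene in the TAD and an enhancer midpoint 25-200 kb from its TSS,
        clear of other planted elements and >=3 kb from every TSS."""
        iv = tad.interval
        genes = [g for _, g in self.tss_by_chrom[iv.chrom]
                 if iv.contains(iv.chrom, g.tss) and g.gene_id not in exclude]
        self.rng.shuffle(genes)
        tss = np.array([t for t, _ in self.tss_by_chrom[iv.chrom]])
        hi_off = int(min(200_000, max(40_000, iv.length // 2 - 10_000)))
        for g in genes:
            for _ in range(50):
                off = int(self.rng.integers(25_000, hi_off))
                mid = g.tss + off * (1 if self.rng.random() < 0.5 else -1)
                if not iv.contains(iv.chrom, mid):
                    continue
                if np.min(np.abs(tss - mid)) < 3_000:
                    continue
                if not self._clear_of_planted(iv.chrom, mid):
                    continue
                if self._near_any_cre(iv.chrom, mid):
                    continue  # keep planted elements off background CREs
                return g, mid
        return None

    def plant_causal_and_signals(self):
        cfg = self.cfg
        usable_tads = [t for t in self.tads if t.interval.length >= 300_000]
        self.rng.shuffle(usable_tads)
        n_extra_signals = 5
        need = cfg.n_causal + n_extra_signals
        if len(usable_tads) < need:
            raise ValueError("infeasible config: not enough TADs to plant "
                             f"{need} independent signals")
        self.signal_tads: list[Tad] = []
        self.muscle_targets: set[str] = set()
        n_array = int(np.ceil(cfg.n_causal * 0.6))
        for i in range(cfg.n_causal):
            tad = usable_tads[i]
            picked = self._pick_target(tad)
            if picked is None:
                raise ValueError("infeasible config: gene density too low to "
                                 "plant a causal loop in a TAD")
            gene, mid = picked
            in_promoter = i % 5 == 4  # some causal variants sit in promoters
            if in_promoter:
                cre = self.prom_cre_of.get(gene.gene_id)
                if cre is None:
                    iv = GenomicInterval(gene.chrom, max(0, gene.tss - 500), gene.tss + 500)
                    cre = CisRegElement(iv, "active_promoter", f"P_{gene.gene_id}")
                    self.cres.append(cre)
                    self._register_cre(cre)
                    self.prom_cre_of[gene.gene_id] = cre
                pos = cre.interval.midpoint
                self._add_loop(gene.chrom, gene.tss, mid, strong=True)
            else:
                cre = self._new_enhancer(gene.chrom, mid)
                pos = mid
                self._add_loop(gene.chrom, mid, gene.tss, strong=True)
            self._reserve(cre.interval)
            gene.muscle_trait_related = True
            self.muscle_targets.add(gene.gene_id)
            self._plant_open_chromatin(gene.chrom, pos)
            self._plant_contacts(gene)
            pwm = self.pwms[i % 4]
            ref, alt = self._ensure_strong(gene.chrom, pos, pwm, enhance=(i < 2))
            hap_a, hap_b = self._neutral_hap_cols()
            spec = _SnpSpec(gene.chrom, pos, ref, alt,
                            self._divergent_afs(0.7), hap_a, hap_b, tag="causal")
            self.snp_specs.append(spec)
            route = "tad" if i < n_array else "ld"
            trait = TRAITS[i % len(TRAITS)]
            self.truth.planted_causal.append(
                {"snp": spec, "trait": trait, "target_gene": gene.gene_id,
                 "route": route, "motif_id": pwm.motif_id,
                 "direction": "enhance" if i < 2 else "disrupt"})
            # matching leading signal
            if route == "tad":
                self.signal_tads.append(tad)
                for _ in range(100):
                    sp = int(self.rng.integers(tad.interval.start, tad.interval.end))
                    if abs(sp - pos) > 2_000 and self._clear_of_planted(gene.chrom, sp):
                        break
                sig_hap = self._neutral_hap_cols()
                sig = _SnpSpec(gene.chrom, sp, None, None,
                               self._bn_breed_afs(), *sig_hap, tag="signal_array")
            else:
                lo = max(0, pos - 500_000)
                hi = min(cfg.chrom_length, pos + 500_000)
                for _ in range(100):
                    sp = int(self.rng.integers(lo, hi))
                    if abs(sp - pos) > 2_000 and self._clear_of_planted(gene.chrom, sp):
                        break
                # perfect LD with the causal site
                sig = _SnpSpec(gene.chrom, sp, None, None, self._bn_breed_afs(),
                               spec.hap_a.copy(), spec.hap_b.copy(), tag="signal_lcs")
            self.snp_specs.append(sig)
            self.truth.planted_causal[-1]["signal"] = sig
        # extra array signals with no causal variant, to host decoys
        for j in range(n_extra_signals):
            tad = usable_tads[cfg.n_causal + j]
            self.signal_tads.append(tad)
            sp = int(self.rng.integers(tad.interval.start, tad.interval.end))
            sig = _SnpSpec(tad.interval.chrom, sp, None, None,
                           self._bn_breed_afs(), *self._neutral_hap_cols(),
                           tag="signal_array")
            self.snp_specs.append(sig)
            self._extra_signal_specs = getattr(self, "_extra_signal_specs", [])
            self._extra_signal_specs.append((sig, TRAITS[(cfg.n_causal + j) % len(TRAITS)]))

    def _bn_breed_afs(self, p=None) -> dict[str, float]:
        if p is None:
            p = float(self.rng.uniform(0.05, 0.95))
        return {b: float(np.clip(bn_af(self.rng, p, self.cfg.divergence_F), 0, 1))
                for b in LEAN_BREEDS + LOCAL_BREEDS}

    def _anchor_overlaps(self, iv: GenomicInterval) -> bool:
        for chrom, s1, s2 in self.loop_specs:
            if chrom != iv.chrom:
                continue
            if (s1 < iv.end and iv.start < s1 + 5000) or \
               (s2 < iv.end and iv.start < s2 + 5000):
                return True
        return False

    def _muscle_partner_exists(self, cre_iv: GenomicInterval) -> bool:
        """True if any loop anchored on ``cre_iv`` has a partner bin touching
        the promoter of a muscle-trait gene (would leak through step 4)."""
        partner_bins = []
        for chrom, s1, s2 in self.loop_specs:
            if chrom != cre_iv.chrom:
                continue
            if s1 < cre_iv.end and cre_iv.start < s1 + 5000:
                partner_bins.append((chrom, s2))
            if s2 < cre_iv.end and cre_iv.start < s2 + 5000:
                partner_bins.append((chrom, s1))
        for chrom, s in partner_bins:
            for gid in self.muscle_targets:
                g = self._gene_by_id[gid]
                if g.chrom != chrom:
                    continue
                prom = self.prom_cre_of.get(gid)
                p_lo = prom.interval.start if prom else max(0, g.tss - 2_500)
                p_hi = prom.interval.end if prom else g.tss + 2_500
                if p_lo < s + 5000 and s < p_hi:
                    return True
        return False

    def plant_decoys(self):
        """Decoys each violate exactly one designated filter step; every other
        plantable step is satisfied so the violation is isolated.

        Placement order matters: loop-adding decoys first, then step-4 decoys
        (validated against the then-final loop set so no bin collision links
        them to a muscle gene), then loop-less step-1 decoys.
        """
        cfg = self.cfg
        self._gene_by_id = {g.gene_id: g for g in self.genes}
        self.decoy4_targets: set[str] = set()
        order = [2, 3, 5, 4, 1]
        per_step = {k: cfg.n_decoys // 5 for k in range(1, 6)}
        for k in range(1, 1 + cfg.n_decoys - 5 * (cfg.n_decoys // 5)):
            per_step[k] += 1
        decoy_specs = []
        ti = 0
        for step in order:
            placed, attempts = 0, 0
            while placed < per_step[step] and attempts < per_step[step] * 40:
                attempts += 1
                tad = self.signal_tads[ti % len(self.signal_tads)]
                ti += 1
                picked = self._pick_target(
                    tad, exclude=self.muscle_targets | self.decoy4_targets)
                if picked is None:
                    continue
                gene, mid = picked
                iv = GenomicInterval(gene.chrom, mid - 500, mid + 500)
                if step == 1 and self._anchor_overlaps(iv):
                    continue  # loop-less element must not touch any anchor
                loop_key = None
                if step != 1:
                    loop_key = self._add_loop(gene.chrom, mid, gene.tss, strong=True)
                    if loop_key is None:
                        continue
                if step == 4:
                    if self._muscle_partner_exists(iv):
                        if loop_key is not None:
                            del self.loop_specs[loop_key]
                        continue
                    self.decoy4_targets.add(gene.gene_id)
                cre = self._new_enhancer(gene.chrom, mid)
                self._reserve(cre.interval)
                if step != 2:
                    self._plant_open_chromatin(gene.chrom, mid)
                afs = (self._divergent_afs(0.3) if step == 3
                       else self._divergent_afs(0.7))
                if step not in (1, 4):
                    gene.muscle_trait_related = True
                    self.muscle_targets.add(gene.gene_id)
                    self._plant_contacts(gene, n_local=2, n_cis=1)
                spec = _SnpSpec(gene.chrom, mid, None, None, afs,
                                *self._neutral_hap_cols(), tag=f"decoy{step}")
                if step == 5:
                    spec.ref = self.genome.base(gene.chrom, mid)
                    spec.alt = [b for b in BASES if b != spec.ref][int(self.rng.integers(3))]
                    self._scrub_motifs(spec)
                else:
                    pwm = self.pwms[int(self.rng.integers(4))]
                    spec.ref, spec.alt = self._ensure_strong(
                        gene.chrom, mid, pwm, enhance=False)
                self.snp_specs.append(spec)
                decoy_specs.append((spec, step))
                placed += 1
            if placed < per_step[step]:
                raise ValueError(
                    f"infeasible config: could not place step-{step} decoys")
        self._decoy_specs = decoy_specs

    # -- background layers ----------------------------------------

    def make_background_atac(self):
        cre_index = IntervalIndex(self.cres, key=lambda c: c.interval)
        placed, tries = 0, 0
        L = self.cfg.chrom_length
        while placed < self.cfg.n_atac_peaks and tries < self.cfg.n_atac_peaks * 50:
            tries += 1
            chrom = self.chrom_names[int(self.rng.integers(self.cfg.n_chroms))]
            start = int(self.rng.integers(0, L - 500))
            iv = GenomicInterval(chrom, start, start + 500)
            probe = GenomicInterval(chrom, max(0, start - 100), start + 600)
            if cre_index.any_overlap(probe):
                continue  # background open chromatin stays off CREs
            self.atac.append(iv)
            if placed % 3 == 0:
                self.footprints.append(GenomicInterval(chrom, start + 200, start + 260))
            placed += 1

    def make_neutral_snps(self):
        n_planted = len(self.snp_specs)
        n_sweep = self.cfg.n_sweep_windows * self.cfg.n_sweep_snps
        n_neutral = max(0, self.cfg.n_snps - n_planted - n_sweep)
        zone_index = IntervalIndex(self.planted_zones)
        taken = {(s.chrom, s.pos) for s in self.snp_specs}
        placed, tries = 0, 0
        while placed < n_neutral and tries < n_neutral * 20:
            tries += 1
            chrom = self.chrom_names[int(self.rng.integers(self.cfg.n_chroms))]
            pos = int(self.rng.integers(0, self.cfg.chrom_length))
            if (chrom, pos) in taken or zone_index.query_point(chrom, pos):
                continue
            taken.add((chrom, pos))
            p = float(self.rng.uniform(0.05, 0.95))
            afs = self._bn_breed_afs(p)
            nh = 2 * self.cfg.n_samples_per_pop
            af_a = float(bn_af(self.rng, p, self.cfg.divergence_F))
            af_b = float(bn_af(self.rng, p, self.cfg.divergence_F))
            hap_a = (self.rng.random(nh) < af_a).astype(np.int8)
            hap_b = (self.rng.random(nh) < af_b).astype(np.int8)
            self.snp_specs.append(_SnpSpec(chrom, pos, None, None, afs,
                                           hap_a, hap_b))
            placed += 1

    def make_sweeps(self):
        cfg = self.cfg
        if not cfg.n_sweep_windows:
            return
        chrom = self.chrom_names[0]
        L = cfg.chrom_length
        span = L // (cfg.n_sweep_windows + 1)
        nh = 2 * cfg.n_samples_per_pop
        zone_index = IntervalIndex(self.planted_zones)
        for w in range(cfg.n_sweep_windows):
            start = ((w + 1) * span // cfg.sweep_window_size) * cfg.sweep_window_size
            win = GenomicInterval(chrom, start, start + cfg.sweep_window_size)
            self.truth.sweep_windows.append([chrom, win.start, win.end])
            core = self.rng.random(nh) < 0.9
            for _ in range(cfg.n_sweep_snps):
                pos = int(self.rng.integers(win.start, win.end))
                if zone_index.query_point(chrom, pos):
                    continue
                p = float(self.rng.uniform(0.1, 0.4))
                hap_a = (self.rng.random(nh) < p).astype(np.int8)
                hap_a[core] = 1
                hap_b = (self.rng.random(nh) <
                         float(bn_af(self.rng, p, cfg.divergence_F))).astype(np.int8)
                afs = {b: float(self.rng.uniform(0.85, 0.95)) for b in LEAN_BREEDS}
                afs.update({b: float(np.clip(bn_af(self.rng, p, cfg.divergence_F), 0, 1))
                            for b in LOCAL_BREEDS})
                self.snp_specs.append(_SnpSpec(chrom, pos, None, None, afs,
                                               hap_a, hap_b, tag="sweep"))

    # -- contacts & reads ------------------------------------------

    def make_background_contacts(self):
        cfg = self.cfg
        n_bg = max(0, cfg.n_contact_pairs - len(self.contact_specs))
        w = np.exp(self.rng.normal(0, 1, len(self.genes)))
        w /= w.sum()
        gene_idx = self.rng.choice(len(self.genes), size=n_bg, p=w)
        modes = self.rng.choice(["local", "cis", "trans"], size=n_bg,
                                p=cfg.mode_fractions)
        for gi, mode in zip(gene_idx, modes):
            gene = self.genes[gi]
            if mode == "local":
                lo = max(0, gene.interval.start - 9_500)
                hi = min(cfg.chrom_length, gene.interval.end + 9_500)
                dchrom, dpos = gene.chrom, int(self.rng.integers(lo, hi))
            elif mode == "cis":
                dchrom, dpos = gene.chrom, self._cis_pos(gene)
            else:
                others = [c for c in self.chrom_names if c != gene.chrom]
                dchrom = others[int(self.rng.integers(len(others)))]
                dpos = int(self.rng.integers(0, cfg.chrom_length))
            self.contact_specs.append(
                {"gene": gene, "mode": mode, "dna_chrom": dchrom, "dna_pos": dpos})

    def realize_contacts(self):
        self.contacts = []
        for i, cs in enumerate(self.contact_specs):
            gene = cs["gene"]
            rid = f"c{i:06d}"
            rna_pos = int(self.rng.integers(gene.interval.start,
                                            gene.interval.end - 23))
            self.contacts.append(ContactPair(
                rid, gene.chrom, rna_pos, gene.strand,
                cs["dna_chrom"], cs["dna_pos"],
                source_gene=gene.gene_id, mode=cs["mode"]))
            self.truth.contact_modes[rid] = cs["mode"]

    def make_grid_reads(self):
        cfg = self.cfg
        linker = cfg.linker
        n = min(cfg.n_grid_reads, len(self.contacts))
        n_corrupt = int(round(cfg.grid_corrupt_frac * n))
        corrupt_idx = set(self.rng.choice(n, size=n_corrupt, replace=False).tolist()) \
            if n_corrupt else set()
        self.grid_reads = []
        kinds = ["seed_mut", "truncate", "long_mate"]
        for i in range(n):
            c = self.contacts[i]
            gene_strand = c.rna_strand
            corrupt = kinds[i % 3] if i in corrupt_idx else None
            rna_len = int(self.rng.integers(17, 24))
            dna_len = 28 if corrupt == "long_mate" else int(self.rng.integers(17, 24))
            fwd = self.genome.seq(c.rna_chrom, c.rna_pos, c.rna_pos + rna_len)
            rna_read = fwd if gene_strand == "+" else revcomp(fwd)
            dna_read = self.genome.seq(c.dna_chrom, c.dna_pos, c.dna_pos + dna_len)
            seq = revcomp(rna_read) + linker.full_seq + dna_read
            if corrupt == "seed_mut":
                sstart = seq.index(linker.seed12)
                core = linker.seed12
                mutated = "".join(
                    {"A": "C", "C": "G", "G": "T", "T": "A"}[b] if j in (3, 6, 9) else b
                    for j, b in enumerate(core))
                seq = seq[:sstart] + mutated + seq[sstart + 12:]
            elif corrupt == "truncate":
                seq = seq[:70]
            if self.rng.random() < 0.5:
                seq = revcomp(seq)
            self.grid_reads.append((c.read_id, seq))
            self.truth.read_truth[c.read_id] = {
                "rna_chrom": c.rna_chrom, "rna_pos": c.rna_pos,
                "rna_strand": gene_strand, "rna_seq": rna_read,
                "dna_chrom": c.dna_chrom, "dna_pos": c.dna_pos,
                "dna_seq": dna_read, "corrupt": corrupt}

    # -- assembly --------------------------------------------------

    def realize_loops(self):
        samples = ["lean_rep1", "lean_rep2", "local_rep1", "local_rep2"]
        self.loops_by_sample = {s: [] for s in samples}
        for (chrom, s1, s2), spec in self.loop_specs.items():
            for s in samples:
                lf = spec["log10fdr"] + self.rng.normal(0, self.cfg.replicate_noise_sd)
                fdr = float(np.clip(10 ** (-lf), 1e-9, 0.05))
                count = int(self.rng.poisson(spec["count"])) + 1
                self.loops_by_sample[s].append(ChromatinLoop(
                    GenomicInterval(chrom, s1, s1 + 5000),
                    GenomicInterval(chrom, s2, s2 + 5000),
                    count, fdr, sample=s))

    def finalize_snps(self) -> tuple[list[SnpRecord], dict, dict]:
        for s in self.snp_specs:
            if s.ref is None:
                s.ref = self.genome.base(s.chrom, s.pos)
            if s.alt is None:
                s.alt = [b for b in BASES if b != s.ref][int(self.rng.integers(3))]
        self.snp_specs.sort(key=lambda s: (s.chrom, s.pos))
        groups = {b: "lean" for b in LEAN_BREEDS}
        groups.update({b: "local" for b in LOCAL_BREEDS})
        records, ids = [], {}
        for i, s in enumerate(self.snp_specs):
            sid = f"rs{i + 1:06d}"
            ids[id(s)] = sid
            records.append(SnpRecord(sid, s.chrom, s.pos, s.ref, s.alt,
                                     dict(s.afs), dict(groups)))
        hap_a = np.vstack([s.hap_a for s in self.snp_specs])
        hap_b = np.vstack([s.hap_b for s in self.snp_specs])
        snp_ids = [r.snp_id for r in records]
        nsp = self.cfg.n_samples_per_pop
        hapm = {
            "lean": GenotypeMatrix(snp_ids, [f"lean_h{i}" for i in range(2 * nsp)],
                                   hap_a, haplotypes=True),
            "local": GenotypeMatrix(snp_ids, [f"local_h{i}" for i in range(2 * nsp)],
                                    hap_b, haplotypes=True)}
        genm = {
            "lean": GenotypeMatrix(snp_ids, [f"lean_s{i}" for i in range(nsp)],
                                   hap_a[:, ::2] + hap_a[:, 1::2]),
            "local": GenotypeMatrix(snp_ids, [f"local_s{i}" for i in range(nsp)],
                                    hap_b[:, ::2] + hap_b[:, 1::2])}
        self._snp_ids = ids
        return records, hapm, genm

    def finalize_signals(self) -> list[GwasSignal]:
        signals = []
        for entry in self.truth.planted_causal:
            sig = entry.pop("signal")
            source = "array" if entry["route"] == "tad" else "lcs"
            signals.append(GwasSignal(self._snp_ids[id(sig)], sig.chrom, sig.pos,
                                      entry["trait"], source))
            entry["snp_id"] = self._snp_ids[id(entry.pop("snp"))]
            entry["signal_id"] = signals[-1].snp_id
        for sig, trait in getattr(self, "_extra_signal_specs", []):
            signals.append(GwasSignal(self._snp_ids[id(sig)], sig.chrom, sig.pos,
                                      trait, "array"))
        for spec, step in self._decoy_specs:
            self.truth.planted_decoys.append(
                {"snp_id": self._snp_ids[id(spec)], "failing_step": step})
        return signals

    def set_expression(self):
        counts = self.truth.enhancer_counts
        for g in self.genes:
            base = float(np.exp(self.rng.normal(2.0, 0.5)))
            g.expression = base * (1 + 0.6 * counts.get(g.gene_id, 0))

    def run(self) -> Bundle:
        self.make_genome()
        self.make_tads()
        self.make_genes()
        self.make_promoter_cres()
        self.make_regulatory_loops()
        self.make_background_loops()
        self.plant_causal_and_signals()
        self.plant_decoys()
        self.make_background_atac()
        self.make_neutral_snps()
        self.make_sweeps()
        self.make_background_contacts()
        self.realize_contacts()
        self.make_grid_reads()
        self.realize_loops()
        self.set_expression()
        records, hapm, genm = self.finalize_snps()
        signals = self.finalize_signals()
        cres = sorted(self.cres, key=lambda c: (c.interval, c.id))
        return Bundle(
            config=self.cfg, genome=self.genome, tads=self.tads,
            genes=self.genes, cres=cres,
            loops_by_sample=self.loops_by_sample, snps=records,
            haps=hapm, genotypes=genm, signals=signals,
            atac_peaks=sorted(self.atac), footprints=sorted(self.footprints),
            pwms=self.pwms, contacts=self.contacts,
            grid_reads=self.grid_reads, truth=self.truth)


def simulate(config: SimConfig | None = None) -> Bundle:
    """Generate the full dataset bundle plus its truth table.

    Deterministic given ``config.seed``.
    """
    return _Simulator(config or SimConfig()).run()


# ------------------------------------------------------------------ bundle I/O

def write_bundle(bundle: Bundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_fasta(out / "genome.fa",
                    {c: bundle.genome.seq(c, 0, bundle.genome.length(c))
                     for c in bundle.genome.chroms})
    eio.write_gtf_lite(out / "genes.gtf", bundle.genes)
    eio.write_bed(out / "cres.bed", bundle.cres)
    eio.write_bed(out / "tads.bed", [t.interval for t in bundle.tads])
    for sample, loops in bundle.loops_by_sample.items():
        eio.write_loops_bedpe(out / f"loops_{sample}.bedpe", loops)
    eio.write_vcf_lite(out / "snps.vcf", bundle.snps)
    for pop in bundle.haps:
        eio.write_genotypes(out / f"haps_{pop}.tsv", bundle.haps[pop])
        eio.write_genotypes(out / f"geno_{pop}.tsv", bundle.genotypes[pop])
    eio.write_signals(out / "signals.tsv", bundle.signals)
    eio.write_bed(out / "atac.bed", bundle.atac_peaks)
    eio.write_bed(out / "footprints.bed", bundle.footprints)
    eio.write_pwms(out / "pwms.txt", bundle.pwms)
    eio.write_contacts(out / "contacts.tsv", bundle.contacts)
    eio.write_fastq(out / "reads.fastq", bundle.grid_reads)
    with open(out / "chrom_sizes.tsv", "w") as fh:
        fh.write("#chrom\tlength\n")
        for c, n in bundle.chrom_lengths.items():
            fh.write(f"{c}\t{n}\n")
    eio.write_json(out / "truth.json", bundle.truth.to_json())
    eio.write_json(out / "config.json",
                   {k: v for k, v in asdict(bundle.config).items()})


def load_bundle(indir) -> Bundle:
    d = Path(indir)
    cfg_d = eio.read_json(d / "config.json")
    cfg_d["mode_fractions"] = tuple(cfg_d["mode_fractions"])
    cfg = SimConfig(**cfg_d)
    genome = Genome(eio.read_fasta(d / "genome.fa"))
    loops = {}
    for p in sorted(d.glob("loops_*.bedpe")):
        sample = p.stem[len("loops_"):]
        loops[sample] = eio.read_loops_bedpe(p, sample=sample).loops
    return Bundle(
        config=cfg, genome=genome,
        tads=eio.read_tads(d / "tads.bed"),
        genes=eio.read_gtf_lite(d / "genes.gtf"),
        cres=eio.read_bed(d / "cres.bed", class_column=True),
        loops_by_sample=loops,
        snps=eio.read_vcf_lite(d / "snps.vcf"),
        haps={p: eio.read_genotypes(d / f"haps_{p}.tsv", haplotypes=True)
              for p in ("lean", "local")},
        genotypes={p: eio.read_genotypes(d / f"geno_{p}.tsv")
                   for p in ("lean", "local")},
        signals=eio.read_signals(d / "signals.tsv"),
        atac_peaks=eio.read_bed(d / "atac.bed"),
        footprints=eio.read_bed(d / "footprints.bed"),
        pwms=eio.read_pwms(d / "pwms.txt"),
        contacts=eio.read_contacts(d / "contacts.tsv"),
        grid_reads=eio.read_fastq(d / "reads.fastq"),
        truth=TruthTable.from_json(eio.read_json(d / "truth.json")))
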