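"""Windowed selective-sweep scans: Hudson FST, XP-nSL, and their top-tail
intersection, plus a circular-permutation enrichment test of loop anchors in
the selected regions.

FST uses the Hudson estimator aggregated per window as a ratio of averages.
XP-nSL contrasts haplotype homozygosity tract lengths (counted in segregating
sites) between two populations and is standardized genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, GenotypeMatrix

WINDOW_SIZE = 50_000
WINDOW_STEP = 25_000
MIN_SNPS = 10


def hudson_fst(af_a, af_b, n_a: int, n_b: int):
    """Per-site Hudson FST components (numerator, denominator).

    ``n_a``/``n_b`` are sampled allele counts (2x diploids). The window or
    genome-wide estimate is sum(num)/sum(den) — a ratio of averages, which is
    not the average of per-site ratios.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need >=2 sampled alleles per population")
    pa = np.asarray(af_a, dtype=float)
    pb = np.asarray(af_b, dtype=float)
    num = (pa - pb) ** 2 - pa * (1 - pa) / (n_a - 1) - pb * (1 - pb) / (n_b - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return num, den


def fst_ratio(num, den) -> float:
    den_sum = float(np.sum(den))
    return float(np.sum(num)) / den_sum if den_sum > 0 else 0.0


def _pair_tract_lengths(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Per-site shared-haplotype tract length (in segregating sites) for one
    haplotype pair; 0 where the pair differs at the site itself."""
    n = h1.size
    mism = h1 != h2
    idx = np.arange(n)
    prev = np.where(mism, idx, -1)
    np.maximum.accumulate(prev, out=prev)
    # previous mismatch strictly before each site
    prev_excl = np.concatenate(([-1], prev[:-1]))
    nxt = np.where(mism, idx, n)
    nxt = np.minimum.accumulate(nxt[::-1])[::-1]
    nxt_excl = np.concatenate((nxt[1:], [n]))
    tract = nxt_excl - prev_excl - 1
    tract[mism] = 0
    return tract


def _nsl(haps: np.ndarray, max_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Mean pairwise tract length per site, log scale."""
    n_hap = haps.shape[1]
    pairs = [(i, j) for i in range(n_hap) for j in range(i + 1, n_hap)]
    if len(pairs) > max_pairs:
        sel = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(sel)]
    acc = np.zeros(haps.shape[0], dtype=float)
    for i, j in pairs:
        acc += _pair_tract_lengths(haps[:, i], haps[:, j])
    mean = acc / len(pairs)
    return np.log(np.maximum(mean, 1e-9))


def xp_nsl(haps_a: GenotypeMatrix | np.ndarray, haps_b, max_pairs: int = 300,
           seed: int = 0, standardize: bool = True) -> np.ndarray:
    """Per-site XP-nSL: nSL(A) - nSL(B), standardized genome-wide.

    Inputs are phased haplotype matrices (sites x haplotypes, 0/1 alleles).
    Pairs are subsampled deterministically when the population is large.
    """
    def _values(h):
        if isinstance(h, GenotypeMatrix):
            if not h.haplotypes:
                raise ValueError("XP-nSL requires phased haplotypes "
                                 "(load with haplotypes=True)")
            return h.values
        return np.asarray(h)

    ha, hb = _values(haps_a), _values(haps_b)
    if ha.shape[1] < 10 or hb.shape[1] < 10:
        raise ValueError("need >=10 haplotypes per population")
    rng = np.random.default_rng(seed)
    raw = _nsl(ha, max_pairs, rng) - _nsl(hb, max_pairs, rng)
    if not standardize:
        return raw
    sd = raw.std()
    return (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()


@dataclass
class WindowStat:
    window: GenomicInterval
    fst: float
    xpnsl: float
    n_snps: int


def window_scan(chroms, positions, num, den, xpnsl_scores,
                chrom_lengths: dict[str, int], window_size: int = WINDOW_SIZE,
                step: int = WINDOW_STEP, min_snps: int = MIN_SNPS) -> list[WindowStat]:
    """Aggregate per-site FST components and XP-nSL scores into sliding
    windows; windows with fewer than ``min_snps`` sites are not reported."""
    chroms = np.asarray(chroms)
    positions = np.asarray(positions)
    out = []
    for chrom in sorted(chrom_lengths):
        mask = chroms == chrom
        pos = positions[mask]
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        cn, cd, cx = num[mask][order], den[mask][order], xpnsl_scores[mask][order]
        L = chrom_lengths[chrom]
        for start in range(0, max(L - window_size + step, 1), step):
            end = min(start + window_size, L)
            lo = np.searchsorted(pos, start, "left")
            hi = np.searchsorted(pos, end, "left")
            if hi - lo < min_snps:
                continue
            out.append(WindowStat(
                GenomicInterval(chrom, start, end),
                fst=fst_ratio(cn[lo:hi], cd[lo:hi]),
                xpnsl=float(np.mean(cx[lo:hi])),
                n_snps=int(hi - lo)))
    return out


def select_regions(window_stats: list[WindowStat], q: float = 0.95) -> list[GenomicInterval]:
    """Merged windows in the top (1-q) tail of BOTH FST and XP-nSL."""
    if not window_stats:
        return []
    fst = np.array([w.fst for w in window_stats])
    xp = np.array([w.xpnsl for w in window_stats])
    fst_thr = np.quantile(fst, q)
    xp_thr = np.quantile(xp, q)
    chosen = [w.window for w in window_stats
              if w.fst >= fst_thr and w.xpnsl >= xp_thr]
    chosen.sort()
    merged: list[GenomicInterval] = []
    for iv in chosen:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            merged[-1] = GenomicInterval(iv.chrom, merged[-1].start,
                                         max(merged[-1].end, iv.end))
        else:
            merged.append(iv)
    return merged


@dataclass
class EnrichmentResult:
    observed_overlap: int
    expected_mean: float
    expected_sd: float
    fold: float
    p_perm: float


def _count_overlaps(anchors_by_chrom, regions_by_chrom) -> int:
    n = 0
    for chrom, spans in anchors_by_chrom.items():
        regs = regions_by_chrom.get(chrom)
        if regs is None:
            continue
        starts, ends = regs
        for a_start, a_end in spans:
            i = np.searchsorted(ends, a_start, "right")
            if i < len(starts) and starts[i] < a_end:
                n += 1
    return n


def anchor_enrichment(anchors: list[GenomicInterval], regions: list[GenomicInterval],
                      chrom_sizes: dict[str, int], n_perm: int = 1000,
                      seed: int = 0) -> EnrichmentResult:
    """Permutation enrichment of anchors in regions.

    The null circularly shifts all anchors on a chromosome by one uniform
    offset per permutation, preserving anchor spacing; p uses the +1
    correction and is therefore never 0.
    """
    if not regions:
        raise ValueError("region set is empty")
    regions_by_chrom: dict[str, tuple] = {}
    for chrom in {r.chrom for r in regions}:
        rs = sorted(r for r in regions if r.chrom == chrom)
        regions_by_chrom[chrom] = (np.array([r.start for r in rs]),
                                   np.array([r.end for r in rs]))
    anchors_by_chrom: dict[str, list] = {}
    for a in anchors:
        anchors_by_chrom.setdefault(a.chrom, []).append((a.start, a.end))

    observed = _count_overlaps(anchors_by_chrom, regions_by_chrom)
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=int)
    for t in range(n_perm):
        shifted = {}
        for chrom, spans in anchors_by_chrom.items():
            L = chrom_sizes[chrom]
            off = int(rng.integers(0, L))
            moved = []
            for s, e in spans:
                s2 = (s + off) % L
                e2 = s2 + (e - s)
                if e2 <= L:
                    moved.append((s2, e2))
                else:  # wrap: split across the origin
                    moved.append((s2, L))
                    moved.append((0, e2 - L))
            shifted[chrom] = moved
        null[t] = _count_overlaps(shifted, regions_by_chrom)
    exp_mean = float(null.mean())
    if exp_mean > 0:
        fold = observed / exp_mean
    else:
        fold = 0.0 if observed == 0 else float("inf")
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return EnrichmentResult(observed, exp_mean, float(null.std()), fold, p)
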