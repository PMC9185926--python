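"""Chromatin-loop annotation and differential loop-regulation of genes.

Loops and genes are classified by the cis-regulatory content of their
anchors; each active promoter gets a cumulative interaction score (the sum of
-log10 FDR over the loops touching it), scores are quantile-normalized across
samples, and genes are tested for differential loop regulation between two
conditions with a variance-shrunken two-sample test on log scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .core import (ChromatinLoop, CisRegElement, Gene, GenomicInterval,
                   IntervalIndex, overlaps)

PROMOTER_FLANK = 2_500
FDR_FLOOR = 1e-10

LOOP_CLASSES = ("PP", "PE", "EE", "P_none", "E_none", "unclear")
GENE_TYPES = ("I", "II", "III", "IV")


def promoter_region(gene: Gene, cre_index: IntervalIndex | None = None) -> GenomicInterval:
    """TSS +/- 2.5 kb, unless an annotated active-promoter element overlaps
    the TSS, in which case that element's interval is used."""
    if cre_index is not None:
        hits = [c for c in cre_index.query_point(gene.chrom, gene.tss) if c.is_promoter]
        if hits:
            return hits[0].interval
    return GenomicInterval(gene.chrom, max(0, gene.tss - PROMOTER_FLANK),
                           gene.tss + PROMOTER_FLANK)


def _anchor_content(anchor: GenomicInterval, cre_index: IntervalIndex) -> str:
    """'P', 'E' or 'none'; an anchor carrying both counts as P (promoter
    precedence, so promoter-involving classes are never understated)."""
    has_p = has_e = False
    for cre in cre_index.query(anchor):
        if cre.is_promoter:
            has_p = True
        elif cre.is_enhancer:
            has_e = True
    return "P" if has_p else ("E" if has_e else "none")


_LOOP_CLASS_TABLE = {
    ("P", "P"): "PP", ("P", "E"): "PE", ("E", "P"): "PE", ("E", "E"): "EE",
    ("P", "none"): "P_none", ("none", "P"): "P_none",
    ("E", "none"): "E_none", ("none", "E"): "E_none",
    ("none", "none"): "unclear",
}


def classify_loop(loop: ChromatinLoop, cre_index: IntervalIndex) -> str:
    a = _anchor_content(loop.anchor1, cre_index)
    b = _anchor_content(loop.anchor2, cre_index)
    return _LOOP_CLASS_TABLE[(a, b)]


def _partner_anchors(gene: Gene, loops, cre_index):
    prom = promoter_region(gene, cre_index)
    for lp in loops:
        if lp.chrom != gene.chrom:
            continue
        if overlaps(lp.anchor1, prom):
            yield lp, lp.anchor2
        if overlaps(lp.anchor2, prom):
            yield lp, lp.anchor1

def classify_gene(gene: Gene, loops, cre_index: IntervalIndex) -> str:
    """Regulation type: I no P and no E partner, II enhancers only,
    III promoters only, IV both."""
    has_p = has_e = False
    for _, other in _partner_anchors(gene, loops, cre_index):
        for cre in cre_index.query(other):
            if cre.is_promoter:
                has_p = True
            elif cre.is_enhancer:
                has_e = True
    return {(False, False): "I", (False, True): "II",
            (True, False): "III", (True, True): "IV"}[(has_p, has_e)]


def enhancers_per_promoter(gene: Gene, loops, cre_index: IntervalIndex) -> int:
    """Number of distinct enhancer elements looped to the gene's promoter."""
    seen = set()
    for _, other in _partner_anchors(gene, loops, cre_index):
        for cre in cre_index.query(other):
            if cre.is_enhancer:
                seen.add(cre.id)
    return len(seen)


def nearest_gene_skipping(enhancer, target_gene: Gene, genes: list[Gene]) -> bool:
    """Does the enhancer's loop target skip over the nearest-TSS gene?

    Ties on TSS distance break to the smaller TSS coordinate, then gene_id.
    """
    iv = enhancer.interval if isinstance(enhancer, CisRegElement) else enhancer
    if iv.chrom != target_gene.chrom:
        raise ValueError("enhancer and target gene on different chromosomes")
    mid = iv.midpoint
    same = [g for g in genes if g.chrom == iv.chrom]
    if not same:
        raise ValueError(f"no genes on chromosome {iv.chrom}")
    nearest = min(same, key=lambda g: (abs(g.tss - mid), g.tss, g.gene_id))
    return nearest.gene_id != target_gene.gene_id


@dataclass
class PromoterScore:
    gene_id: str
    sample: str
    score: float
    normalized_score: float | None = None


def promoter_interaction_score(gene: Gene, loops, cre_index: IntervalIndex | None = None,
                               sample: str = "", fdr_floor: float = FDR_FLOOR) -> PromoterScore:
    """Cumulative interaction score: sum of -log10(FDR) over loops with at
    least one anchor on the gene's active promoter."""
    prom = promoter_region(gene, cre_index)
    score = 0.0
    for lp in loops:
        if lp.chrom != gene.chrom:
            continue
        if overlaps(lp.anchor1, prom) or overlaps(lp.anchor2, prom):
            if lp.fdr == 0:
                raise ValueError("fdr=0 encountered; floor FDR upstream")
            score += -np.log10(max(lp.fdr, fdr_floor))
    return PromoterScore(gene.gene_id, sample, score)


def score_matrix(genes: list[Gene], loops_by_sample: dict[str, list],
                 cre_index: IntervalIndex | None = None) -> pd.DataFrame:
    """Genes x samples matrix of cumulative interaction scores.

    Loops are bucketed per promoter with an interval index, so the cost is
    loops + promoters rather than their product.
    """
    samples = list(loops_by_sample)
    gene_ids = [g.gene_id for g in genes]
    row_of = {gid: i for i, gid in enumerate(gene_ids)}
    proms = {g.gene_id: promoter_region(g, cre_index) for g in genes}
    prom_index = IntervalIndex(
        [(gid, iv) for gid, iv in proms.items()], key=lambda t: t[1])
    out = np.zeros((len(gene_ids), len(samples)))
    for j, sample in enumerate(samples):
        for lp in loops_by_sample[sample]:
            if lp.fdr == 0:
                raise ValueError("fdr=0 encountered; floor FDR upstream")
            val = -np.log10(max(lp.fdr, FDR_FLOOR))
            hit_genes = {gid for gid, _ in prom_index.query(lp.anchor1)}
            hit_genes |= {gid for gid, _ in prom_index.query(lp.anchor2)}
            for gid in hit_genes:
                out[row_of[gid], j] += val
    return pd.DataFrame(out, index=gene_ids, columns=samples)


def quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across columns.

    Each column's sorted values are replaced by the row-wise mean of the
    sorted columns; ties within a column receive the mean of the target
    values at the tied ranks.
    """
    arr = np.asarray(mat, dtype=float)
    if arr.shape[1] < 2:
        warnings.warn("quantile_normalize on a single sample is the identity")
        return mat.copy()
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(target)
        assigned[order] = target
        # average target values over tied input values
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


@dataclass
class DiffGeneResult:
    gene_id: str
    log2fc: float
    p_value: float
    q_value: float
    direction: str  # up_A | up_B | ns


def differential_genes(scores_a, scores_b, lfc_thresh: float = 1.5,
                       p_thresh: float = 0.05, pseudocount: float = 1.0,
                       prior_df: float = 4.0) -> list[DiffGeneResult]:
    """Moderated two-sample test on log2(score + pseudocount).

    Per-gene variances are shrunk toward the across-gene mean variance with
    ``prior_df`` pseudo-degrees of freedom (empirical-Bayes style); direction
    is called only when |log2FC| strictly exceeds ``lfc_thresh`` and
    p < ``p_thresh``. BH q-values are reported alongside.
    """
    from statsmodels.stats.multitest import multipletests

    a = pd.DataFrame(scores_a)
    b = pd.DataFrame(scores_b)
    if not a.index.equals(b.index):
        raise ValueError("condition matrices must share the same gene index")
    la = np.log2(np.asarray(a, dtype=float) + pseudocount)
    lb = np.log2(np.asarray(b, dtype=float) + pseudocount)
    na, nb = la.shape[1], lb.shape[1]
    if na < 1 or nb < 1:
        raise ValueError("need >=1 replicate per condition")
    lfc = la.mean(axis=1) - lb.mean(axis=1)
    df_resid = na + nb - 2
    if df_resid > 0:
        ss = la.var(axis=1, ddof=1) * (na - 1) if na > 1 else np.zeros(len(lfc))
        ss = ss + (lb.var(axis=1, ddof=1) * (nb - 1) if nb > 1 else 0.0)
        s2 = ss / df_resid
    else:
        s2 = np.zeros(len(lfc))
    s2_prior = float(np.mean(s2)) if df_resid > 0 else float(np.var(lfc, ddof=1))
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    se = np.sqrt(np.maximum(s2_mod, 1e-300) * (1 / na + 1 / nb))
    tstat = lfc / se
    pvals = 2 * sp_stats.t.sf(np.abs(tstat), df=df_resid + prior_df)
    allzero = (np.asarray(a).sum(axis=1) == 0) & (np.asarray(b).sum(axis=1) == 0)
    pvals = np.where(allzero, 1.0, pvals)
    lfc = np.where(allzero, 0.0, lfc)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = []
    for gid, fc, p, q in zip(a.index, lfc, pvals, qvals):
        if abs(fc) > lfc_thresh and p < p_thresh:
            direction = "up_A" if fc > 0 else "up_B"
        else:
            direction = "ns"
        out.append(DiffGeneResult(str(gid), float(fc), float(p), float(q), direction))
    return out


def correlate_level_changes(delta_chromatin, delta_rna):
    """Pearson correlation of per-promoter chromatin-level vs RNA-level changes."""
    x = np.asarray(delta_chromatin, dtype=float)
    y = np.asarray(delta_rna, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


def expression_by_enhancer_count(genes: list[Gene], counts: dict[str, int],
                                 max_count: int = 5):
    """Association between enhancer count category and mean expression.

    Returns (slope, r, p_kw): linear regression through the per-category mean
    expression, plus a Kruskal-Wallis p-value across the categories.
    """
    groups: dict[int, list[float]] = {}
    for g in genes:
        if g.expression is None:
            continue
        c = min(counts.get(g.gene_id, 0), max_count)
        groups.setdefault(c, []).append(g.expression)
    cats = sorted(groups)
    if len(cats) < 2:
        raise ValueError("need >=2 enhancer-count categories")
    means = [float(np.mean(groups[c])) for c in cats]
    fit = sp_stats.linregress(cats, means)
    kw = sp_stats.kruskal(*[groups[c] for c in cats])
    return float(fit.slope), float(fit.rvalue), float(kw.pvalue)
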