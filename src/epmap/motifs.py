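"""PWM allele-effect scoring: does a SNP strengthen or weaken a TF binding site?

Reference and alternate alleles are scored with a standard log2-odds PWM scan
over both strands; scores are mapped to the PWM's relative [0,1] scale
(score minus the worst attainable score, over the attainable range), and the
allele pair is classified by the shift in relative score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Genome, Pwm, SnpRecord, encode_seq, revcomp

PSEUDOCOUNT = 1e-3

# classification defaults: a "strong" effect needs a large relative-score shift
# and at least one allele close to a full-strength site
STRONG_DELTA = 0.15
STRONG_BEST = 0.85
WEAK_DELTA = 0.05


def log_odds_matrix(pwm: Pwm) -> np.ndarray:
    m = np.where(pwm.matrix == 0, PSEUDOCOUNT, pwm.matrix)
    return np.log2(m / pwm.background)


def _scan(window: str, lo: np.ndarray, offsets=None):
    """Best (score, offset, strand) over both strands.

    Offsets are window coordinates of the motif's left edge on the forward
    window; ``offsets`` restricts the scan (same restriction applies to the
    minus strand after coordinate reflection). Ties break to the lower
    offset, then the + strand. N bases contribute 0 log-odds.
    """
    L = lo.shape[0]
    W = len(window)
    if W < L:
        raise ValueError(f"window ({W}) shorter than motif ({L})")
    allowed = range(W - L + 1) if offsets is None else offsets
    best = None
    for strand in "+-":
        seq = window if strand == "+" else revcomp(window)
        for off in allowed:
            o = off if strand == "+" else W - L - off
            s = 0.0
            for j, base in enumerate(seq[o:o + L]):
                if base != "N":
                    s += lo[j, "ACGT".index(base)]
            key = (-s, off, strand)
            if best is None or key < best[0]:
                best = (key, (s, off, strand))
    return best[1]


def pwm_log_odds(window: str, pwm: Pwm):
    """Best log2-odds score of ``pwm`` over all offsets and both strands."""
    return _scan(window, log_odds_matrix(pwm))


@dataclass
class AlleleEffect:
    motif_id: str
    ref_best: float
    alt_best: float
    ref_rel: float
    alt_rel: float
    delta_rel: float
    classification: str  # strong | weak | neutral
    direction: str       # enhance | disrupt | none


def _classify(delta_rel: float, ref_rel: float, alt_rel: float,
              strong_delta: float, strong_best: float, weak_delta: float):
    ad = abs(delta_rel)
    if ad >= strong_delta and max(ref_rel, alt_rel) >= strong_best:
        cls = "strong"
    elif ad >= weak_delta:
        cls = "weak"
    else:
        cls = "neutral"
    if cls == "neutral" or delta_rel == 0:
        return cls, "none"
    return cls, ("enhance" if delta_rel > 0 else "disrupt")


def allele_effect(snp: SnpRecord, genome: Genome, pwm: Pwm, flank: int | None = None,
                  strong_delta: float = STRONG_DELTA, strong_best: float = STRONG_BEST,
                  weak_delta: float = WEAK_DELTA) -> AlleleEffect:
    """Score the ref vs alt allele of ``snp`` against ``pwm``.

    Only motif placements whose span covers the SNP base are scanned, so
    delta reflects the SNP and not flanking sequence.
    """
    L = len(pwm)
    if flank is None:
        flank = L - 1
    if flank < L - 1:
        raise ValueError("flank must be >= motif length - 1")
    if genome.base(snp.chrom, snp.pos) != snp.ref:
        raise ValueError(
            f"reference mismatch at {snp.chrom}:{snp.pos}: "
            f"genome {genome.base(snp.chrom, snp.pos)} != ref {snp.ref}")
    start = max(0, snp.pos - flank)
    end = min(genome.length(snp.chrom), snp.pos + flank + 1)
    window = genome.seq(snp.chrom, start, end)
    snp_idx = snp.pos - start
    lo = log_odds_matrix(pwm)
    offsets = [o for o in range(len(window) - L + 1) if o <= snp_idx <= o + L - 1]
    if not offsets:
        return AlleleEffect(pwm.motif_id, 0.0, 0.0, 0.0, 0.0, 0.0, "neutral", "none")

    alt_window = window[:snp_idx] + snp.alt + window[snp_idx + 1:]
    ref_best, _, _ = _scan(window, lo, offsets)
    alt_best, _, _ = _scan(alt_window, lo, offsets)
    smin, smax = lo.min(axis=1).sum(), lo.max(axis=1).sum()
    span = smax - smin
    if span <= 0:  # degenerate (uninformative) PWM
        return AlleleEffect(pwm.motif_id, float(ref_best), float(alt_best),
                            0.0, 0.0, 0.0, "neutral", "none")
    ref_rel = float(np.clip((ref_best - smin) / span, 0, 1))
    alt_rel = float(np.clip((alt_best - smin) / span, 0, 1))
    delta = alt_rel - ref_rel
    cls, direction = _classify(delta, ref_rel, alt_rel, strong_delta, strong_best, weak_delta)
    return AlleleEffect(pwm.motif_id, float(ref_best), float(alt_best),
                        ref_rel, alt_rel, delta, cls, direction)


def best_effects(snp: SnpRecord, pwm_library, genome: Genome, **kwargs) -> list[AlleleEffect]:
    """One AlleleEffect per PWM, sorted by |delta_rel| descending (ties by id)."""
    if not pwm_library:
        raise ValueError("PWM library is empty")
    effects = [allele_effect(snp, genome, p, **kwargs) for p in pwm_library]
    return sorted(effects, key=lambda e: (-abs(e.delta_rel), e.motif_id))
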