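"""Readers and writers for the plain-text formats the pipeline touches.

BED/BEDPE are 0-based half-open on disk and in memory. GTF-lite and VCF-lite
use 1-based coordinates on disk and are converted at this boundary. Every
writer emits a leading ``#`` header line naming its columns; readers skip
``#`` lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import (
    CRE_CLASSES,
    ChromatinLoop,
    CisRegElement,
    Gene,
    GenomicInterval,
    GenotypeMatrix,
    GwasSignal,
    Pwm,
    SnpRecord,
    Tad,
)


class ParseError(ValueError):
    pass


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------- BED

def read_bed(path, class_column: bool = False):
    """Read a 3+ column BED. With ``class_column``, column 4 is a CRE class
    and column 5 (optional) an element id; returns CisRegElement records."""
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
        try:
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: {e}") from e
        if class_column:
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: missing class column")
            if f[3] not in CRE_CLASSES:
                raise ParseError(f"{path}:{lineno}: unknown cre_class {f[3]!r}")
            cid = f[4] if len(f) > 4 else f"cre_{lineno}"
            out.append(CisRegElement(iv, f[3], cid))
        else:
            out.append(iv)
    return out


def write_bed(path, items) -> None:
    with open(path, "w") as fh:
        first = items[0] if items else None
        if isinstance(first, CisRegElement):
            fh.write("#chrom\tstart\tend\tcre_class\tid\n")
            for c in items:
                iv = c.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cre_class}\t{c.id}\n")
        else:
            fh.write("#chrom\tstart\tend\n")
            for iv in items:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_tads(path) -> list[Tad]:
    """Load TADs; within one set they must be non-overlapping after sorting."""
    ivs = sorted(read_bed(path))
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ParseError(f"{path}: overlapping TADs at {a} / {b}")
    return [Tad(iv) for iv in ivs]


# ---------------------------------------------------------------- BEDPE loops

@dataclass
class LoopLoadResult:
    loops: list[ChromatinLoop]
    n_rows: int
    n_interchromosomal: int
    n_distance_filtered: int

    @property
    def n_kept(self) -> int:
        return len(self.loops)


def read_loops_bedpe(path, sample: str = "") -> LoopLoadResult:
    """Load BEDPE loops: chrom1 start1 end1 chrom2 start2 end2 count fdr.

    Interchromosomal rows and rows outside the 5 kb - 2 Mb midpoint-distance
    band are dropped (tallied); anchors are reordered so anchor1 precedes
    anchor2 on the chromosome.
    """
    loops, n_rows, n_inter, n_dist = [], 0, 0, 0
    for lineno, f in _data_lines(path):
        if len(f) < 8:
            raise ParseError(f"{path}:{lineno}: expected 8 columns")
        n_rows += 1
        a = GenomicInterval(f[0], int(f[1]), int(f[2]))
        b = GenomicInterval(f[3], int(f[4]), int(f[5]))
        count, fdr = int(f[6]), float(f[7])
        if not (0 < fdr <= 1):
            raise ParseError(f"{path}:{lineno}: fdr {fdr} outside (0,1]")
        if a.chrom != b.chrom:
            n_inter += 1
            continue
        if a.start > b.start:
            a, b = b, a
        dist = abs(b.midpoint - a.midpoint)
        if not (5_000 <= dist <= 2_000_000):
            n_dist += 1
            continue
        loops.append(ChromatinLoop(a, b, count, fdr, sample=sample))
    return LoopLoadResult(loops, n_rows, n_inter, n_dist)


def write_loops_bedpe(path, loops) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tcount\tfdr\n")
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                     f"\t{lp.contact_count}\t{lp.fdr:.6g}\n")


# ---------------------------------------------------------------- GTF-lite

def read_gtf_lite(path) -> list[Gene]:
    """GTF-lite: feature=gene rows with gene_id and optional muscle_trait_related
    / expression attributes; 1-based inclusive coordinates on disk."""
    genes = []
    for lineno, f in _data_lines(path):
        if len(f) < 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
        if f[2] != "gene":
            continue
        attrs = {}
        for part in f[8].strip().split(";"):
            part = part.strip()
            if part:
                k, v = part.split(" ", 1)
                attrs[k] = v.strip('"')
        iv = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]))
        genes.append(Gene(
            gene_id=attrs["gene_id"], interval=iv, strand=f[6],
            muscle_trait_related=attrs.get("muscle_trait_related", "0") == "1",
            expression=float(attrs["expression"]) if "expression" in attrs else None,
        ))
    return genes


def write_gtf_lite(path, genes) -> None:
    with open(path, "w") as fh:
        fh.write("#seqname\tsource\tfeature\tstart\tend\tscore\tstrand\tframe\tattributes\n")
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; muscle_trait_related "{int(g.muscle_trait_related)}"'
            if g.expression is not None:
                attrs += f'; expression "{g.expression:.6g}"'
            fh.write(f"{g.chrom}\tepmap\tgene\t{g.interval.start + 1}\t{g.interval.end}"
                     f"\t.\t{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------- VCF-lite

def read_vcf_lite(path) -> list[SnpRecord]:
    """VCF-lite: CHROM POS ID REF ALT INFO with AF_<breed>=x and
    GRP_<breed>=lean|local INFO keys; POS is 1-based on disk."""
    snps = []
    for lineno, f in _data_lines(path):
        if len(f) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 VCF-lite columns")
        afs, groups = {}, {}
        for kv in f[5].split(";"):
            if not kv:
                continue
            k, v = kv.split("=", 1)
            if k.startswith("AF_"):
                afs[k[3:]] = float(v)
            elif k.startswith("GRP_"):
                groups[k[4:]] = v
        snps.append(SnpRecord(
            snp_id=f[2], chrom=f[0], pos=int(f[1]) - 1, ref=f[3], alt=f[4],
            af_by_breed=afs, breed_group=groups,
        ))
    return snps


def write_vcf_lite(path, snps) -> None:
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tINFO\n")
        for s in snps:
            info = ";".join(
                [f"AF_{b}={s.af_by_breed[b]:.6g}" for b in sorted(s.af_by_breed)]
                + [f"GRP_{b}={s.breed_group[b]}" for b in sorted(s.breed_group)]
            )
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.snp_id}\t{s.ref}\t{s.alt}\t{info or '.'}\n")


# ---------------------------------------------------------------- genotype TSV

def read_genotypes(path, haplotypes: bool = False, mean_impute: bool = False) -> GenotypeMatrix:
    """TSV genotype matrix: rows=SNPs, first column snp_id, header names samples.

    Missing entries (``NA``/``.``) fail the load unless ``mean_impute`` rounds
    them to the nearest integer of the row mean.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        snp_ids, rows = [], []
        for lineno, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(header):
                raise ParseError(f"{path}:{lineno}: ragged row")
            snp_ids.append(f[0])
            vals = []
            for v in f[1:]:
                vals.append(np.nan if v in ("NA", ".") else float(v))
            rows.append(vals)
    values = np.array(rows, dtype=float)
    if np.isnan(values).any():
        if not mean_impute:
            raise ParseError(f"{path}: missing genotype values (use mean_impute)")
        for i in range(values.shape[0]):
            row = values[i]
            row[np.isnan(row)] = np.round(np.nanmean(row))
    return GenotypeMatrix(snp_ids, sample_ids, values.astype(np.int64), haplotypes=haplotypes)


def write_genotypes(path, gm: GenotypeMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(gm.sample_ids) + "\n")
        for sid, row in zip(gm.snp_ids, gm.values):
            fh.write(sid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------- GWAS signals

def read_signals(path) -> list[GwasSignal]:
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 5:
            raise ParseError(f"{path}:{lineno}: expected 5 signal columns")
        out.append(GwasSignal(f[0], f[1], int(f[2]), f[3], f[4]))
    return out


def write_signals(path, signals) -> None:
    with open(path, "w") as fh:
        fh.write("#snp_id\tchrom\tpos\ttrait\tsource\n")
        for s in signals:
            fh.write(f"{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.trait}\t{s.source}\n")


# ---------------------------------------------------------------- JASPAR PWMs

def read_pwms(path) -> list[Pwm]:
    """JASPAR-style PWM text: ``>motif_id`` then four rows ``A [ 1 2 ... ]``.

    Count matrices are normalized to per-position probabilities.
    """
    pwms, motif_id, rows = [], None, {}

    def _flush():
        if motif_id is None:
            return
        mat = np.array([rows[b] for b in "ACGT"], dtype=float).T
        sums = mat.sum(axis=1, keepdims=True)
        pwms.append(Pwm(motif_id, mat / sums))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                motif_id = line[1:].split()[0]
                rows = {}
            else:
                base, rest = line.split(None, 1)
                rows[base] = [float(x) for x in rest.strip("[] \t").split()]
    _flush()
    return pwms


def write_pwms(path, pwms) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.6f}" for v in p.matrix[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path) -> dict[str, str]:
    seqs, name, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            out.append((head.rstrip("\n")[1:].split()[0], seq))
    return out


def write_fastq(path, reads: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------- contacts TSV

def read_contacts(path):
    from .grid import ContactPair
    out = []
    for lineno, f in _data_lines(path):
        if len(f) < 8:
            raise ParseError(f"{path}:{lineno}: expected 8 contact columns")
        out.append(ContactPair(
            read_id=f[0], rna_chrom=f[1], rna_pos=int(f[2]), rna_strand=f[3],
            dna_chrom=f[4], dna_pos=int(f[5]),
            source_gene=None if f[6] == "." else f[6],
            mode=None if f[7] == "." else f[7],
        ))
    return out


def write_contacts(path, pairs) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\trna_chrom\trna_pos\trna_strand\tdna_chrom\tdna_pos\tgene_id\tmode\n")
        for p in pairs:
            fh.write(f"{p.read_id}\t{p.rna_chrom}\t{p.rna_pos}\t{p.rna_strand}"
                     f"\t{p.dna_chrom}\t{p.dna_pos}\t{p.source_gene or '.'}\t{p.mode or '.'}\n")


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
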