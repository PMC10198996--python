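"""Readers and writers for the standard formats the pipeline consumes.

All coordinate conversion to the internal 0-based half-open forward-strand
convention happens here and only here: GFF3 and VCF are 1-based inclusive,
MAF minus-strand query rows count from the reverse-strand origin, SAM POS is
1-based. Downstream modules never see a 1-based coordinate.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import AlignIO, SeqIO
from cyvcf2 import VCF

from .models import (
    AlignedInterval,
    FootprintRead,
    Genome,
    GenomeSequence,
    PairwiseBlock,
    SnvRecord,
    TranscriptModel,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violates the dialect this pipeline expects."""


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str, species_tag: str = "") -> list[GenomeSequence]:
    """Read a FASTA file into upper-cased :class:`GenomeSequence` records.

    Order is preserved; duplicate contig names and empty files are errors.
    """
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate contig name {rec.id!r}")
        seen.add(rec.id)
        seqs.append(GenomeSequence(rec.id, str(rec.seq).upper(), species_tag))
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: Sequence[GenomeSequence], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.contig_name}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")


def read_genome(path: str, species_tag: str = "") -> Genome:
    return Genome.from_sequences(read_fasta(path, species_tag))


# ---------------------------------------------------------------- GFF3


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gff3(path: str, genome: Optional[Genome] = None) -> list[TranscriptModel]:
    """Assemble transcript models from GFF3 exon and CDS features.

    GFF3 1-based inclusive spans become 0-based half-open; minus-strand
    transcripts get their exon list reordered 5'->3' in transcript direction.
    CDS features must be contained in exons. If *genome* is given, contigs
    are checked to exist.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    strands: dict[str, str] = {}
    contigs: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}: malformed GFF3 line: {line[:80]!r}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = f
            if ftype not in ("exon", "CDS", "mRNA", "transcript"):
                continue
            a = _gff_attributes(attrs)
            if ftype in ("mRNA", "transcript"):
                tid = a.get("ID", "")
                meta.setdefault(tid, a)
                continue
            tid = a.get("Parent") or a.get("transcript_id")
            if not tid:
                raise FormatError(f"{path}: {ftype} without Parent attribute")
            if strand not in "+-":
                raise FormatError(f"{path}: missing strand for transcript {tid}")
            iv = (int(start) - 1, int(end))  # 1-based inclusive -> 0-based half-open
            strands[tid] = strand
            contigs[tid] = contig
            (exons if ftype == "exon" else cds).setdefault(tid, []).append(iv)

    models: list[TranscriptModel] = []
    for tid, exon_list in exons.items():
        strand = strands[tid]
        contig = contigs[tid]
        if genome is not None and contig not in genome:
            raise FormatError(f"{path}: contig {contig!r} not in genome")
        exon_list = sorted(exon_list, key=lambda x: x[0], reverse=(strand == "-"))
        attrs = meta.get(tid, {})
        cds_start = cds_end = None
        if tid in cds:
            spans = sorted(cds[tid])
            for cs, ce in spans:
                if not any(s <= cs and ce <= e for s, e in exon_list):
                    raise FormatError(f"{path}: CDS of {tid} not contained in exons")
            if strand == "+":
                cds_start, cds_end = spans[0][0], spans[-1][1] - 1
            else:
                cds_start, cds_end = spans[-1][1] - 1, spans[0][0]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=attrs.get("gene_id", attrs.get("Parent", tid)),
                contig=contig,
                strand=strand,
                exons=exon_list,
                cds_start_codon_pos=cds_start,
                cds_stop_codon_end=cds_end,
                biotype=attrs.get("biotype", "protein_coding"),
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


def write_gff3(models: Sequence[TranscriptModel], path: str) -> None:
    """Write transcript/exon/CDS features (inverse of :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            exon_spans = sorted(m.exons)
            t0 = exon_spans[0][0]
            t1 = exon_spans[-1][1]
            attrs = f"ID={m.transcript_id};gene_id={m.gene_id};biotype={m.biotype}"
            fh.write(
                f"{m.contig}\tnovostart\ttranscript\t{t0 + 1}\t{t1}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in exon_spans:
                fh.write(
                    f"{m.contig}\tnovostart\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={m.transcript_id}\n"
                )
            if m.cds_start_codon_pos is not None and m.cds_stop_codon_end is not None:
                lo = min(m.cds_start_codon_pos, m.cds_stop_codon_end)
                hi = max(m.cds_start_codon_pos, m.cds_stop_codon_end) + 1
                for s, e in exon_spans:
                    cs, ce = max(s, lo), min(e, hi)
                    if cs < ce:
                        fh.write(
                            f"{m.contig}\tnovostart\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t0\t"
                            f"Parent={m.transcript_id}\n"
                        )


# ---------------------------------------------------------------- VCF


def read_vcf(path: str) -> list[SnvRecord]:
    """Read biallelic SNVs from a VCF; multiallelic records are split into
    one :class:`SnvRecord` per alternate allele; indels are skipped (count
    logged)."""
    vcf = VCF(path)
    samples = list(vcf.samples)
    records: list[SnvRecord] = []
    n_indel = 0
    for var in vcf:
        ref = var.REF
        for alt_i, alt in enumerate(var.ALT):
            if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                n_indel += 1
                continue
            gts: list[tuple[Optional[int], Optional[int]]] = []
            for g in var.genotypes:  # [a0, a1, phased]
                if len(g) != 3:
                    raise FormatError(
                        f"{path}: genotype ploidy != 2 at {var.CHROM}:{var.POS}"
                    )
                pair = []
                for h in g[:2]:
                    if h < 0:
                        pair.append(None)
                    else:
                        # after splitting, this alt allele -> 1, others -> 0
                        pair.append(1 if h == alt_i + 1 else 0)
                gts.append((pair[0], pair[1]))
            vid = var.ID or f"{var.CHROM}_{var.POS}_{ref}_{alt}"
            if len(var.ALT) > 1:
                vid = f"{vid}_{alt}"
            records.append(
                SnvRecord(
                    contig=var.CHROM,
                    pos=var.POS - 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    genotypes=gts,
                    variant_id=vid,
                    samples=samples,
                )
            )
    if n_indel:
        log.info("read_vcf(%s): skipped %d non-SNV allele(s)", path, n_indel)
    return records


def write_vcf(
    records: Sequence[SnvRecord],
    samples: Sequence[str],
    contig_lengths: dict[str, int],
    path: str,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in sorted(records, key=lambda r: (r.contig, r.pos)):
            gt_strs = [
                "|".join("." if h is None else str(h) for h in gt) for gt in r.genotypes
            ]
            fh.write(
                f"{r.contig}\t{r.pos + 1}\t{r.variant_id}\t{r.ref_allele}\t"
                f"{r.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gt_strs) + "\n"
            )


# ---------------------------------------------------------------- MAF


def read_maf(path: str, target_species: str = "", query_species: str = "") -> list[PairwiseBlock]:
    """Read pairwise MAF blocks (first 's' row = target, second = query).

    Minus-strand rows (whose MAF start counts from the reverse-strand
    origin) are normalized to forward-strand intervals:
    ``fwd_start = srcSize - start - size``.
    """
    blocks: list[PairwiseBlock] = []
    for i, aln in enumerate(AlignIO.parse(path, "maf")):
        if len(aln) < 2:
            raise FormatError(f"{path}: MAF block {i} has fewer than 2 rows")
        rows = []
        for rec in list(aln)[:2]:
            ann = rec.annotations
            species, _, contig = rec.id.partition(".")
            start, size = int(ann["start"]), int(ann["size"])
            strand = "+" if ann["strand"] in (1, "+") else "-"
            src_size = int(ann["srcSize"])
            fwd_start = start if strand == "+" else src_size - start - size
            rows.append(
                (
                    species,
                    AlignedInterval(contig, fwd_start, fwd_start + size, strand),
                    str(rec.seq).upper(),
                )
            )
        blocks.append(
            PairwiseBlock(
                target_species=target_species or rows[0][0],
                query_species=query_species or rows[1][0],
                target_interval=rows[0][1],
                query_interval=rows[1][1],
                aligned_target=rows[0][2],
                aligned_query=rows[1][2],
                block_id=f"{os.path.basename(path)}:{i}",
            )
        )
    return blocks


def write_maf(blocks: Sequence[PairwiseBlock], path: str, src_sizes: dict[str, int]) -> None:
    """Write pairwise blocks as MAF (all rows forward-strand)."""

    def _row(species: str, iv: AlignedInterval, text: str) -> str:
        src = f"{species}.{iv.contig}"
        size = iv.end - iv.start
        total = src_sizes[f"{species}.{iv.contig}"]
        return f"s {src} {iv.start} {size} + {total} {text}\n"

    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("a\n")
            fh.write(_row(b.target_species, b.target_interval, b.aligned_target))
            fh.write(_row(b.query_species, b.query_interval, b.aligned_query))
            fh.write("\n")


# ---------------------------------------------------------------- SAM


def read_sam(
    path: str,
    sample_id: Optional[str] = None,
    blacklist: Optional[dict[str, list[tuple[int, int]]]] = None,
) -> list[FootprintRead]:
    """Read footprint reads from a SAM/BAM file.

    Uniqueness is the NH tag (NH==1) when present, else MAPQ>3. If a
    blacklist (contig -> interval list) is given, reads overlapping any
    interval get ``overlaps_ncrna_blacklist=True``.
    """
    sid = sample_id if sample_id is not None else os.path.splitext(os.path.basename(path))[0]
    reads: list[FootprintRead] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if aln.has_tag("NH"):
                unique = aln.get_tag("NH") == 1
            else:
                unique = aln.mapping_quality > 3
            start = aln.reference_start
            length = aln.query_length or aln.infer_read_length() or 0
            contig = aln.reference_name
            black = False
            if blacklist and contig in blacklist:
                end = start + length
                black = any(s < end and start < e for s, e in blacklist[contig])
            reads.append(
                FootprintRead(
                    sample_id=sid,
                    contig=contig,
                    leftmost_pos=start,
                    read_length=length,
                    strand="-" if aln.is_reverse else "+",
                    unique_flag=unique,
                    overlaps_ncrna_blacklist=black,
                )
            )
    return reads


def write_sam(
    reads: Sequence[FootprintRead],
    contig_lengths: dict[str, int],
    path: str,
    nh_override: Optional[Sequence[int]] = None,
) -> None:
    """Write footprint reads as plain-text SAM (no sequence/quality; CIGAR
    carries the read length). NH defaults to 1 for unique reads, 2 otherwise."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for i, r in enumerate(reads):
            flag = 16 if r.strand == "-" else 0
            nh = nh_override[i] if nh_override is not None else (1 if r.unique_flag else 2)
            fh.write(
                f"read{i}\t{flag}\t{r.contig}\t{r.leftmost_pos + 1}\t255\t"
                f"{r.read_length}M\t*\t0\t0\t*\t*\tNH:i:{nh}\n"
            )


def read_bed_intervals(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into contig -> sorted interval list (0-based half-open)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    for ivs in out.values():
        ivs.sort()
    return out


# ---------------------------------------------------------------- tabular


def write_bed(rows: Iterable[tuple], path: str) -> None:
    """Write BED6 rows: (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
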