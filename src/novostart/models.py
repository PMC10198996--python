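"""Core domain types shared across the pipeline.

All genomic coordinates held by these types are 0-based, half-open, on the
forward strand of the reference. Conversion from the 1-based conventions of
GFF3/VCF/MAF happens once, at the I/O boundary (:mod:`novostart.io`).

Transcript coordinates ("tpos") count exonic bases 5'->3' along the mature
transcript: tpos 0 is the transcript's first base, which for a minus-strand
transcript is the *highest* genomic coordinate of its first exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """A single contig of one species' genome."""

    contig_name: str
    sequence: str
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_name!r}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


class Genome(dict):
    """contig name -> GenomeSequence, with convenience slicing."""

    @classmethod
    def from_sequences(cls, seqs: Sequence[GenomeSequence]) -> "Genome":
        g = cls()
        for s in seqs:
            if s.contig_name in g:
                raise ValueError(f"duplicate contig name {s.contig_name!r}")
            g[s.contig_name] = s
        return g

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self[contig].sequence[start:end]

    def base(self, contig: str, pos: int) -> str:
        return self[contig].sequence[pos]


@dataclass
class TranscriptModel:
    """Exon structure of one transcript, with genome<->transcript mapping.

    ``exons`` are genomic intervals (0-based half-open, forward strand)
    ordered 5'->3' in *transcript* direction: ascending genomic start for
    plus-strand transcripts, descending for minus-strand ones.

    ``cds_start_codon_pos`` is the genomic position of the first CDS base in
    transcript orientation (for minus strand: the highest genomic coordinate
    of the start codon).  ``cds_stop_codon_end`` is the genomic position of
    the last CDS base in transcript orientation.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start_codon_pos: Optional[int] = None
    cds_stop_codon_end: Optional[int] = None
    biotype: str = "protein_coding"
    _g2t: dict[int, int] = field(default_factory=dict, repr=False)
    _t2g: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        starts = sorted(s for s, _ in self.exons)
        ends = sorted(e for _, e in self.exons)
        for (s1, e1), s2 in zip(zip(starts, ends), starts[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = sorted(self.exons, key=lambda x: x[0], reverse=(self.strand == "-"))
        if list(self.exons) != expected:
            raise ValueError(
                f"{self.transcript_id}: exons not in 5'->3' transcript order"
            )
        self._t2g = []
        for s, e in self.exons:
            rng = range(s, e) if self.strand == "+" else range(e - 1, s - 1, -1)
            self._t2g.extend(rng)
        self._g2t = {g: t for t, g in enumerate(self._t2g)}
        if self.cds_start_codon_pos is not None and self.cds_start_codon_pos not in self._g2t:
            raise ValueError(f"{self.transcript_id}: CDS start not inside an exon")

    def __len__(self) -> int:
        return len(self._t2g)

    def genome_to_transcript(self, gpos: int) -> Optional[int]:
        """Transcript coordinate of a genomic position, or None if intronic/outside."""
        return self._g2t.get(gpos)

    def transcript_to_genome(self, tpos: int) -> int:
        if not 0 <= tpos < len(self._t2g):
            raise IndexError(f"tpos {tpos} outside transcript {self.transcript_id}")
        return self._t2g[tpos]

    @property
    def cds_start_tpos(self) -> Optional[int]:
        if self.cds_start_codon_pos is None:
            return None
        return self._g2t[self.cds_start_codon_pos]

    @property
    def cds_stop_end_tpos(self) -> Optional[int]:
        if self.cds_stop_codon_end is None:
            return None
        return self._g2t.get(self.cds_stop_codon_end)

    def spliced_sequence(self, genome: Genome) -> str:
        """Mature transcript sequence (5'->3', exons joined, strand applied)."""
        contig = genome[self.contig].sequence
        parts = []
        for s, e in sorted(self.exons):
            parts.append(contig[s:e])
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)

    def junction_tpositions(self) -> list[int]:
        """Transcript coordinates of the first base of each non-first exon."""
        out, cum = [], 0
        for s, e in self.exons[:-1]:
            cum += e - s
            out.append(cum)
        return out


@dataclass
class SnvRecord:
    """A biallelic SNV with per-individual diploid genotypes.

    ``genotypes[i]`` is a pair of haplotype calls for individual
    ``samples[i]``; each call is 0 (ref), 1 (alt) or None (missing).
    """

    contig: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    genotypes: list[tuple[Optional[int], Optional[int]]]
    variant_id: str
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"{self.variant_id}: not a SNV")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref == alt")

    def allele_frequency(self) -> float:
        called = [h for gt in self.genotypes for h in gt if h is not None]
        if not called:
            return float("nan")
        return sum(called) / len(called)

    def carriers(self) -> set[str]:
        """Individuals with at least one alt haplotype."""
        out = set()
        for name, gt in zip(self.samples, self.genotypes):
            if any(h == 1 for h in gt):
                out.add(name)
        return out

    def is_monomorphic_ref(self) -> bool:
        """True if no called haplotype carries the alternate allele."""
        return all(h != 1 for gt in self.genotypes for h in gt)


@dataclass
class AlignedInterval:
    contig: str
    start: int  # 0-based half-open, forward strand
    end: int
    strand: str


@dataclass
class PairwiseBlock:
    """One gapped pairwise alignment block (MAF 's' line pair).

    ``aligned_target``/``aligned_query`` are equal-length gapped strings in
    target-forward orientation (the MAF convention: the query text of a
    minus-strand row is already reverse-complemented to match the target).
    Query intervals are normalized to forward-strand coordinates on load.
    """

    target_species: str
    query_species: str
    target_interval: AlignedInterval
    query_interval: AlignedInterval
    aligned_target: str
    aligned_query: str
    block_id: str = ""

    def __post_init__(self) -> None:
        if len(self.aligned_target) != len(self.aligned_query):
            raise ValueError(f"block {self.block_id}: row lengths differ")
        for a, b in zip(self.aligned_target, self.aligned_query):
            if a == "-" and b == "-":
                raise ValueError(f"block {self.block_id}: gap-gap column")
        t_len = len(self.aligned_target.replace("-", ""))
        q_len = len(self.aligned_query.replace("-", ""))
        ti, qi = self.target_interval, self.query_interval
        if t_len != ti.end - ti.start or q_len != qi.end - qi.start:
            raise ValueError(f"block {self.block_id}: interval/sequence length mismatch")


@dataclass
class FootprintRead:
    """A mapped ribosome footprint."""

    sample_id: str
    contig: str
    leftmost_pos: int  # 0-based
    read_length: int
    strand: str
    unique_flag: bool
    overlaps_ncrna_blacklist: bool = False

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
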