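"""Fixed human-specific start codons from pairwise whole-genome alignments.

The scan polarizes human-chimpanzee differences with two outgroups (gorilla,
orangutan) and a population fixation check:

1. keep only one-to-one alignment blocks (reciprocal single hit);
2. collect aligned columns where the human and chimp bases differ;
3. a divergent site is a candidate human-specific start codon (hSSC) iff it
   falls inside the annotated start codon of a human transcript while its
   chimp ortholog lies in the 5'UTR of a chimp transcript;
4. both outgroups must carry a non-human allele (a missing outgroup drops
   the candidate: polarization is impossible);
5. the site must be monomorphic (no alternate allele among called
   genotypes) in the population VCF.

Anchor vocabulary (ribosome-occupancy panel): hSSC = human-specific start
codon; hASC = the downstream human ancestral start (human ortholog of the
chimp start codon); cOSC = chimp ortholog of the hSSC; cSC = the chimp
start codon itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .models import Genome, PairwiseBlock, SnvRecord, TranscriptModel, revcomp

log = logging.getLogger(__name__)

# rejection reason codes, asserted by tests on planted distractors
REASON_CALLED = "called"
REASON_NOT_START = "not_in_start_codon"
REASON_CHIMP_NOT_5UTR = "chimp_ortholog_not_in_5utr"
REASON_OUTGROUP_SHARED = "outgroup_shares_human_allele"
REASON_MISSING_OUTGROUP = "missing_outgroup"
REASON_POLYMORPHIC = "polymorphic_in_population"
REASON_HASC_UNMAPPABLE = "ancestral_start_unmappable"


@dataclass
class OrthologSite:
    """A human position with a human/chimp allele difference, plus outgroup
    alleles looked up through their own one-to-one alignments. Alleles are
    alignment-column characters in human-forward orientation."""

    human_contig: str
    human_pos: int
    human_allele: str
    alleles: dict[str, Optional[str]]  # species -> allele or None
    positions: dict[str, Optional[tuple[str, int]]]  # species -> (contig, pos)
    block_ids: dict[str, str] = field(default_factory=dict)
    coverage: dict[str, int] = field(default_factory=dict)


@dataclass
class HssCall:
    """A fixed human-specific start codon."""

    site: OrthologSite
    transcript_id: str
    hssc_tpos: int
    hasc_tpos: int
    chimp_transcript_id: str
    chimp_ortholog_in_5utr: bool
    fixed_in_population: bool
    cug_origin: Optional[bool]
    novel_cds_len_nt: int
    divergent_offsets: list[int] = field(default_factory=list)  # within-codon, 0..2

    def __post_init__(self) -> None:
        gap = self.hasc_tpos - self.hssc_tpos
        assert gap % 3 == 0 and self.novel_cds_len_nt == gap - 3


class LiftMap:
    """Per-base coordinate + allele map through a set of pairwise blocks.

    Built from one-to-one blocks, so every target and query base appears in
    at most one block and the map is a partial bijection.
    """

    def __init__(self, blocks: Sequence[PairwiseBlock]):
        self.t2q: dict[tuple[str, int], tuple[str, int, str, str]] = {}
        self.q2t: dict[tuple[str, int], tuple[str, int]] = {}
        for b in blocks:
            ti, qi = b.target_interval, b.query_interval
            tpos = ti.start
            qpos = qi.start if qi.strand == "+" else qi.end - 1
            step = 1 if qi.strand == "+" else -1
            for tc, qc in zip(b.aligned_target, b.aligned_query):
                if tc != "-" and qc != "-":
                    key = (ti.contig, tpos)
                    self.t2q[key] = (qi.contig, qpos, qc, b.block_id)
                    self.q2t[(qi.contig, qpos)] = (ti.contig, tpos)
                if tc != "-":
                    tpos += 1
                if qc != "-":
                    qpos += step

    def query_allele(self, contig: str, pos: int) -> Optional[str]:
        hit = self.t2q.get((contig, pos))
        return hit[2] if hit else None

    def query_position(self, contig: str, pos: int) -> Optional[tuple[str, int]]:
        hit = self.t2q.get((contig, pos))
        return (hit[0], hit[1]) if hit else None

    def target_position(self, contig: str, pos: int) -> Optional[tuple[str, int]]:
        return self.q2t.get((contig, pos))


def filter_one_to_one(blocks: Sequence[PairwiseBlock]) -> list[PairwiseBlock]:
    """Keep blocks whose target and query spans are each covered by exactly
    one block genome-wide (reciprocal single hit).

    Equivalent to the per-base coverage-count rule: a block survives iff no
    other block overlaps its target interval on the target genome or its
    query interval on the query genome.
    """

    def _conflicted(key) -> set[int]:
        ivs = []
        for i, b in enumerate(blocks):
            iv = key(b)
            ivs.append((iv.contig, iv.start, iv.end, i))
        ivs.sort()
        bad: set[int] = set()
        # sweep keeping the farthest-reaching open interval: any overlap with
        # a prior block implies overlap with that one, and induction marks
        # every overlapped block (containment chains included)
        cur_contig, max_end, max_idx = None, -1, -1
        for c, s, e, i in ivs:
            if c != cur_contig:
                cur_contig, max_end, max_idx = c, e, i
                continue
            if s < max_end:
                bad.update((i, max_idx))
            if e > max_end:
                max_end, max_idx = e, i
        return bad

    bad = _conflicted(lambda b: b.target_interval) | _conflicted(lambda b: b.query_interval)
    kept = [b for i, b in enumerate(blocks) if i not in bad]
    log.info("one-to-one filter: %d -> %d blocks", len(blocks), len(kept))
    return kept


def find_divergent_sites(
    chimp_blocks: Sequence[PairwiseBlock],
    human_genome: Genome,
    chimp_genome: Optional[Genome] = None,
    outgroup_lifts: Optional[dict[str, LiftMap]] = None,
) -> list[OrthologSite]:
    """One OrthologSite per ungapped aligned column where human != chimp.

    Columns containing a gap or N are skipped. Outgroup alleles (gorilla,
    orangutan) are filled from their own one-to-one lift maps when given.
    *chimp_blocks* must already be one-to-one filtered. Block target rows
    are verified against the human genome.
    """
    outgroup_lifts = outgroup_lifts or {}
    sites: list[OrthologSite] = []
    chimp_lift = LiftMap(chimp_blocks)
    for b in chimp_blocks:
        ti = b.target_interval
        ungapped = b.aligned_target.replace("-", "")
        if human_genome.fetch(ti.contig, ti.start, ti.end) != ungapped:
            raise ValueError(f"block {b.block_id}: target row disagrees with genome FASTA")
        tpos = ti.start
        for tc, qc in zip(b.aligned_target, b.aligned_query):
            if tc != "-" and qc != "-" and "N" not in (tc, qc) and tc != qc:
                alleles: dict[str, Optional[str]] = {"chimp": qc}
                positions: dict[str, Optional[tuple[str, int]]] = {
                    "chimp": chimp_lift.query_position(ti.contig, tpos)
                }
                for sp, lift in outgroup_lifts.items():
                    alleles[sp] = lift.query_allele(ti.contig, tpos)
                    positions[sp] = lift.query_position(ti.contig, tpos)
                sites.append(
                    OrthologSite(
                        human_contig=ti.contig,
                        human_pos=tpos,
                        human_allele=tc,
                        alleles=alleles,
                        positions=positions,
                        block_ids={"chimp": b.block_id},
                    )
                )
            if tc != "-":
                tpos += 1
    log.info("divergent-site scan: %d sites", len(sites))
    return sites


def _start_codon_gpositions(t: TranscriptModel) -> list[int]:
    """Genomic positions of the start codon triplet, ascending."""
    cs = t.cds_start_tpos
    return sorted(t.transcript_to_genome(cs + i) for i in range(3))


def _chimp_triplet(
    human_t: TranscriptModel, chimp_lift: LiftMap
) -> Optional[str]:
    """Chimp orthologous start-codon triplet read in human-transcript
    orientation; None if any of the 3 columns is unaligned."""
    chars = []
    for g in _start_codon_gpositions(human_t):
        c = chimp_lift.query_allele(human_t.contig, g)
        if c is None:
            return None
        chars.append(c)
    trip = "".join(chars)
    return trip if human_t.strand == "+" else revcomp(trip)


def evaluate_site(
    site: OrthologSite,
    human_transcripts: Sequence[TranscriptModel],
    chimp_transcripts: Sequence[TranscriptModel],
    population: dict[tuple[str, int], SnvRecord],
    chimp_lift: LiftMap,
) -> tuple[Optional[HssCall], str]:
    """Apply the hSSC rules to one divergent site; return (call|None, reason)."""
    human_t = None
    for t in human_transcripts:
        if t.cds_start_tpos is None or t.contig != site.human_contig:
            continue
        if site.human_pos in _start_codon_gpositions(t):
            human_t = t
            break
    if human_t is None:
        return None, REASON_NOT_START

    # rule 2: chimp ortholog within a chimp transcript's 5'UTR
    chimp_loc = site.positions.get("chimp")
    chimp_t = None
    if chimp_loc is not None:
        for ct in chimp_transcripts:
            if ct.contig != chimp_loc[0] or ct.cds_start_tpos is None:
                continue
            tp = ct.genome_to_transcript(chimp_loc[1])
            if tp is not None and tp < ct.cds_start_tpos:
                chimp_t = ct
                break
    if chimp_t is None:
        return None, REASON_CHIMP_NOT_5UTR

    # rule 3: both outgroups must carry a non-human allele
    for sp in ("gorilla", "orangutan"):
        allele = site.alleles.get(sp)
        if allele is None:
            return None, REASON_MISSING_OUTGROUP
        if allele == site.human_allele:
            return None, REASON_OUTGROUP_SHARED

    # rule 4: fixed in the population
    rec = population.get((site.human_contig, site.human_pos))
    if rec is not None and not rec.is_monomorphic_ref():
        return None, REASON_POLYMORPHIC

    # ancestral start: human ortholog of the chimp start codon
    chimp_start_g = chimp_t.transcript_to_genome(chimp_t.cds_start_tpos)
    hasc_loc = chimp_lift.target_position(chimp_t.contig, chimp_start_g)
    hasc_tpos = None
    if hasc_loc is not None and hasc_loc[0] == human_t.contig:
        hasc_tpos = human_t.genome_to_transcript(hasc_loc[1])
    if hasc_tpos is None:
        return None, REASON_HASC_UNMAPPABLE

    hssc_tpos = human_t.cds_start_tpos
    triplet = _chimp_triplet(human_t, chimp_lift)
    trip_order = [human_t.transcript_to_genome(hssc_tpos + i) for i in range(3)]
    offsets = [trip_order.index(site.human_pos)]
    call = HssCall(
        site=site,
        transcript_id=human_t.transcript_id,
        hssc_tpos=hssc_tpos,
        hasc_tpos=hasc_tpos,
        chimp_transcript_id=chimp_t.transcript_id,
        chimp_ortholog_in_5utr=True,
        fixed_in_population=True,
        cug_origin=None if triplet is None else (triplet == "CTG"),
        novel_cds_len_nt=hasc_tpos - hssc_tpos - 3,
        divergent_offsets=offsets,
    )
    return call, REASON_CALLED


def call_hssc(
    site: OrthologSite,
    human_transcripts: Sequence[TranscriptModel],
    chimp_transcripts: Sequence[TranscriptModel],
    population: dict[tuple[str, int], SnvRecord],
    chimp_lift: LiftMap,
) -> Optional[HssCall]:
    call, _ = evaluate_site(site, human_transcripts, chimp_transcripts, population, chimp_lift)
    return call


def call_all(
    sites: Sequence[OrthologSite],
    human_transcripts: Sequence[TranscriptModel],
    chimp_transcripts: Sequence[TranscriptModel],
    population: dict[tuple[str, int], SnvRecord],
    chimp_lift: LiftMap,
) -> tuple[list[HssCall], dict[str, str]]:
    """Evaluate all sites; merge sites hitting the same start codon into one
    call (codons, not SNVs, are counted at species level). Returns the calls
    plus a reason code per site (keyed ``contig:pos``)."""
    reasons: dict[str, str] = {}
    by_transcript: dict[str, HssCall] = {}
    for site in sites:
        call, reason = evaluate_site(
            site, human_transcripts, chimp_transcripts, population, chimp_lift
        )
        reasons[f"{site.human_contig}:{site.human_pos}"] = reason
        if call is None:
            continue
        prev = by_transcript.get(call.transcript_id)
        if prev is None:
            by_transcript[call.transcript_id] = call
        else:
            prev.divergent_offsets = sorted(
                set(prev.divergent_offsets) | set(call.divergent_offsets)
            )
    calls = list(by_transcript.values())
    log.info("hSSC caller: %d divergent sites -> %d calls", len(sites), len(calls))
    return calls, reasons


def flag_cug_origin(
    call: HssCall,
    human_transcripts: dict[str, TranscriptModel],
    chimp_lift: LiftMap,
) -> HssCall:
    """(Re)compute the CUG-origin flag from the chimp orthologous triplet.

    A partially aligned triplet leaves ``cug_origin`` as None (unknown); the
    call is retained with the flag so downstream occupancy analyses can run
    in with-CUG and CUG-excluded modes.
    """
    t = human_transcripts[call.transcript_id]
    triplet = _chimp_triplet(t, chimp_lift)
    call.cug_origin = None if triplet is None else (triplet == "CTG")
    return call


def hssc_site_panel(
    calls: Sequence[HssCall],
    human_transcripts: dict[str, TranscriptModel],
    chimp_transcripts: dict[str, TranscriptModel],
    chimp_lift: LiftMap,
    min_codons: int = 5,
) -> pd.DataFrame:
    """Four occupancy anchors per call: hSSC, hASC (human genome), cOSC, cSC
    (chimp genome), each as the genomic position of the codon's first base
    in transcript orientation, plus the >= *min_codons* analyzability flag."""
    rows = []
    for c in calls:
        ht = human_transcripts[c.transcript_id]
        ct = chimp_transcripts[c.chimp_transcript_id]
        hssc_g = ht.transcript_to_genome(c.hssc_tpos)
        hasc_g = ht.transcript_to_genome(c.hasc_tpos)
        cosc = chimp_lift.query_position(ht.contig, hssc_g)
        csc_g = ct.transcript_to_genome(ct.cds_start_tpos)
        cosc_tpos = None if cosc is None else ct.genome_to_transcript(cosc[1])
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "chimp_transcript_id": c.chimp_transcript_id,
                "human_contig": ht.contig,
                "human_strand": ht.strand,
                "chimp_contig": ct.contig,
                "chimp_strand": ct.strand,
                "hssc_pos": hssc_g,
                "hssc_tpos": c.hssc_tpos,
                "hasc_pos": hasc_g,
                "hasc_tpos": c.hasc_tpos,
                "cosc_pos": None if cosc is None else cosc[1],
                "cosc_tpos": cosc_tpos,
                "csc_pos": csc_g,
                "csc_tpos": ct.cds_start_tpos,
                "novel_cds_len_nt": c.novel_cds_len_nt,
                "novel_cds_len_codons": c.novel_cds_len_nt // 3,
                "cug_origin": c.cug_origin,
                "analyzable": c.novel_cds_len_nt // 3 >= min_codons,
                "anchors_missing": cosc is None or cosc_tpos is None,
            }
        )
    return pd.DataFrame(rows)
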