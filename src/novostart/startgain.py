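"""Population-level start-gain SNV calling.

A start-gain SNV converts a non-AUG triplet in a transcript's 5'UTR into
AUG, in frame with the downstream canonical start codon and with no stop
codon in between, creating a candidate N-terminal extension. Calls are made
per (SNV, transcript) pair; population summaries deduplicate to SNV level.

Filtering rules applied by :func:`classify_snv`:

1. the SNV lies in the transcript's 5'UTR (exonic, upstream of the
   canonical start in transcript coordinates);
2. substituting the alternate allele creates an ATG triplet covering the
   variant base, where the reference triplet was not ATG;
3. the novel AUG is in frame with the canonical start codon;
4. no stop codon (TAA/TAG/TGA) lies in that frame strictly between the
   novel AUG and the canonical start;
5. the SNV's genomic position does not fall inside any annotated CDS of
   any transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import Genome, SnvRecord, TranscriptModel, revcomp

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: contigs treated as autosomes ("chr" prefix optional); configurable.
DEFAULT_AUTOSOMES = frozenset(
    {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}
)


@dataclass
class StartGainCall:
    """A validated start-gain SNV on one transcript."""

    snv: SnvRecord
    transcript_id: str
    novel_start_tpos: int
    canonical_start_tpos: int
    novel_cds_len_nt: int
    novel_cds_len_codons: int
    carrier_individuals: set[str]
    allele_frequency: float
    autosomal: bool

    def __post_init__(self) -> None:
        gap = self.canonical_start_tpos - self.novel_start_tpos
        assert gap % 3 == 0, "novel start out of frame"
        assert self.novel_cds_len_nt == gap - 3 and self.novel_cds_len_nt >= 0
        assert self.novel_cds_len_codons == self.novel_cds_len_nt // 3


@dataclass
class NmdCall:
    """Nonsense-mediated-decay prediction for one transcript (50-nt rule)."""

    transcript_id: str
    stop_codon_tpos: Optional[int]
    last_junction_tpos: Optional[int]
    distance_nt: Optional[int]
    nmd_predicted: bool
    single_exon: bool = False


def cds_interval_union(transcripts: Iterable[TranscriptModel]) -> dict[str, list[tuple[int, int]]]:
    """Union of annotated CDS genomic intervals per contig, merged and sorted.

    "Any known coding sequence" for rule 5: the per-exon CDS pieces of every
    transcript with an annotated CDS.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        if t.cds_start_tpos is None or t.cds_stop_end_tpos is None:
            continue
        lo_t, hi_t = t.cds_start_tpos, t.cds_stop_end_tpos
        for tpos in (lo_t, hi_t):
            assert 0 <= tpos < len(t)
        gpositions = [t.transcript_to_genome(tp) for tp in (lo_t, hi_t)]
        lo_g, hi_g = min(gpositions), max(gpositions)
        for s, e in t.exons:
            cs, ce = max(s, lo_g), min(e, hi_g + 1)
            if cs < ce:
                raw.setdefault(t.contig, []).append((cs, ce))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, ivs in raw.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[contig] = [(s, e) for s, e in out]
    return merged


def _in_intervals(ivs: Sequence[tuple[int, int]], pos: int) -> bool:
    import bisect

    i = bisect.bisect_right(ivs, (pos, float("inf"))) - 1
    return i >= 0 and ivs[i][0] <= pos < ivs[i][1]


def classify_snv(
    snv: SnvRecord,
    transcript: TranscriptModel,
    genome: Genome,
    cds_union: dict[str, list[tuple[int, int]]],
    autosomes: frozenset[str] = DEFAULT_AUTOSOMES,
) -> Optional[StartGainCall]:
    """Apply the five start-gain rules; return a call or None.

    *cds_union* is the output of :func:`cds_interval_union` over the entire
    annotation (rule 5). When a single substitution creates ATG at more than
    one covering triplet, the 5'-most in-frame AUG is reported (scanning-
    model default).
    """
    if transcript.cds_start_tpos is None:
        log.debug("%s: no annotated CDS, skipped", transcript.transcript_id)
        return None
    ref_base = genome.base(snv.contig, snv.pos)
    if ref_base != snv.ref_allele:
        raise ValueError(
            f"{snv.variant_id}: ref allele {snv.ref_allele} != genome {ref_base}"
        )
    if transcript.contig != snv.contig:
        return None
    tpos = transcript.genome_to_transcript(snv.pos)
    cds_start = transcript.cds_start_tpos
    if tpos is None or tpos >= cds_start:  # rule 1: exonic 5'UTR
        return None
    if _in_intervals(cds_union.get(snv.contig, ()), snv.pos):  # rule 5
        return None

    seq = transcript.spliced_sequence(genome)
    alt_base = snv.alt_allele if transcript.strand == "+" else revcomp(snv.alt_allele)
    alt_seq = seq[:tpos] + alt_base + seq[tpos + 1 :]

    # rule 2: scan the three triplets covering the variant base, 5'-most first
    for k in (tpos - 2, tpos - 1, tpos):
        if k < 0 or k + 3 > cds_start:
            continue
        if alt_seq[k : k + 3] != "ATG" or seq[k : k + 3] == "ATG":
            continue
        if (cds_start - k) % 3 != 0:  # rule 3
            continue
        between = alt_seq[k + 3 : cds_start]
        if any(between[i : i + 3] in STOP_CODONS for i in range(0, len(between), 3)):
            continue  # rule 4
        nt = cds_start - k - 3
        return StartGainCall(
            snv=snv,
            transcript_id=transcript.transcript_id,
            novel_start_tpos=k,
            canonical_start_tpos=cds_start,
            novel_cds_len_nt=nt,
            novel_cds_len_codons=nt // 3,
            carrier_individuals=snv.carriers(),
            allele_frequency=snv.allele_frequency(),
            autosomal=snv.contig in autosomes,
        )
    return None


def call_all(
    snvs: Sequence[SnvRecord],
    transcripts: Sequence[TranscriptModel],
    genome: Genome,
    autosomes: frozenset[str] = DEFAULT_AUTOSOMES,
) -> list[StartGainCall]:
    """Run :func:`classify_snv` over every (SNV, transcript) pair."""
    cds_union = cds_interval_union(transcripts)
    by_contig: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_contig.setdefault(t.contig, []).append(t)
    calls = []
    for snv in snvs:
        for t in by_contig.get(snv.contig, ()):
            call = classify_snv(snv, t, genome, cds_union, autosomes)
            if call is not None:
                calls.append(call)
    log.info("start-gain caller: %d SNVs -> %d calls", len(snvs), len(calls))
    return calls


def dedup_by_snv(calls: Sequence[StartGainCall]) -> list[StartGainCall]:
    """One call per SNV (first transcript wins) for SNV-level summaries."""
    seen: set[str] = set()
    out = []
    for c in calls:
        if c.snv.variant_id not in seen:
            seen.add(c.snv.variant_id)
            out.append(c)
    return out


def calls_table(calls: Sequence[StartGainCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": c.snv.variant_id,
                "transcript_id": c.transcript_id,
                "contig": c.snv.contig,
                "pos": c.snv.pos,
                "ref": c.snv.ref_allele,
                "alt": c.snv.alt_allele,
                "novel_start_tpos": c.novel_start_tpos,
                "canonical_start_tpos": c.canonical_start_tpos,
                "novel_cds_len_nt": c.novel_cds_len_nt,
                "novel_cds_len_codons": c.novel_cds_len_codons,
                "n_carriers": len(c.carrier_individuals),
                "allele_frequency": c.allele_frequency,
                "autosomal": c.autosomal,
            }
            for c in calls
        ],
        columns=[
            "variant_id",
            "transcript_id",
            "contig",
            "pos",
            "ref",
            "alt",
            "novel_start_tpos",
            "canonical_start_tpos",
            "novel_cds_len_nt",
            "novel_cds_len_codons",
            "n_carriers",
            "allele_frequency",
            "autosomal",
        ],
    )


def population_summary(calls: Sequence[StartGainCall]) -> dict[str, pd.DataFrame]:
    """Allele-frequency spectrum, per-individual burden and length quantiles.

    An individual "carries" a novel start codon if at least one of their
    haplotypes has the start-gain allele. Burden counts are over the
    SNV-deduplicated call set.
    """
    uniq = dedup_by_snv(calls)
    per_call = calls_table(uniq)
    if uniq:
        samples = uniq[0].snv.samples
        burden = {s: 0 for s in samples}
        for c in uniq:
            for s in c.carrier_individuals:
                burden[s] += 1
        per_ind = pd.DataFrame(
            {"individual": list(burden), "n_novel_start_codons": list(burden.values())}
        )
        lens = np.array([c.novel_cds_len_nt for c in uniq], dtype=float)
        qs = {
            f"q{int(q * 100)}": float(np.quantile(lens, q))
            for q in (0.0, 0.25, 0.5, 0.75, 1.0)
        }
        quant = pd.DataFrame([{"stat": k, "novel_cds_len_nt": v} for k, v in qs.items()])
    else:
        per_ind = pd.DataFrame(columns=["individual", "n_novel_start_codons"])
        quant = pd.DataFrame(columns=["stat", "novel_cds_len_nt"])
    return {"per_call": per_call, "per_individual": per_ind, "length_quantiles": quant}


def filter_for_occupancy(
    calls: Sequence[StartGainCall],
    min_codons: int = 5,
    min_carriers: int = 3,
) -> list[StartGainCall]:
    """Keep calls eligible for the ribosome-occupancy analysis: at least
    *min_codons* codons between the novel and canonical start, at least
    *min_carriers* carrier individuals, and an autosomal contig."""
    kept = [
        c
        for c in calls
        if c.novel_cds_len_codons >= min_codons
        and len(c.carrier_individuals) >= min_carriers
        and c.autosomal
    ]
    log.info("occupancy filter: %d -> %d calls", len(calls), len(kept))
    return kept


def nmd_classify(transcript: TranscriptModel, nmd_distance_nt: int = 50) -> NmdCall:
    """50-nt rule: predicted NMD target iff the stop codon's last base lies
    more than *nmd_distance_nt* nt upstream of the 3'-most exon-exon
    junction. Single-exon transcripts are never predicted targets."""
    if transcript.cds_stop_end_tpos is None:
        raise ValueError(f"{transcript.transcript_id}: no annotated stop codon")
    stop_tpos = transcript.cds_stop_end_tpos
    junctions = transcript.junction_tpositions()
    if not junctions:
        return NmdCall(transcript.transcript_id, stop_tpos, None, None, False, True)
    last_j = junctions[-1]
    dist = last_j - stop_tpos
    return NmdCall(transcript.transcript_id, stop_tpos, last_j, dist, dist > nmd_distance_nt)
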