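"""Synthetic multi-species fixture generator with planted ground truth.

Emulates, at toy scale, every input the pipeline consumes: a human genome
with GENCODE-style transcript annotation, a population VCF with planted
start-gain SNVs and one distractor family per rejection rule, chimpanzee/
gorilla/orangutan genomes with MAF pairwise alignments carrying planted
fixed human-specific start codons (plus rejection-class distractors),
ribosome-footprint SAM files with 3-nt periodicity and start-codon peaks,
an ncRNA blacklist BED, and codon alignments simulated under known
branch-specific omega. Every file is a deterministic function of the seed,
and a truth JSON records what was planted.

The default configuration mirrors the real study's design at small scale:
62 genotyped individuals; 10 true start-gain SNVs whose novel-CDS lengths
have median 48 nt and whose occupancy-filter partition exercises all three
filter rules; 26 fixed human-specific start codons with novel-CDS lengths
of median 30 nt, 16 of them analyzable (>= 5 codons) including 2 of
CUG origin, and 15 with novel CDS longer than 15 nt (the concatenation
set); a 4-fold carrier start-codon enrichment and a 4.9-fold hSSC/hASC
enrichment in the footprint model; and codon evolution with omega 0.36 on
the human branch against 2.74 on the others.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import io as nio
from .codon_evolution import (
    CodonAlignment,
    SENSE_CODONS,
    UNIFORM_PI,
    build_rate_matrix,
    transition_matrix,
)
from .models import FootprintRead, Genome, GenomeSequence, SnvRecord, TranscriptModel, revcomp
from .riboprofile import PSITE_OFFSETS

SPECIES = ("human", "chimpanzee", "gorilla", "orangutan")
FLANK = 30
SPACER = 300
MAIN_CDS_CODONS = 45
UTR3_LEN = 140
INTRON_LEN = 50


class ConfigError(ValueError):
    """The fixture configuration demands an impossible placement."""


# --------------------------------------------------------------- config


@dataclass
class PlantedStartGain:
    name: str
    gap_codons: int  # codons strictly between novel and canonical start
    carriers_total: int
    carriers_in_ribo: int
    contig: str = "chr1"
    strand: str = "+"
    kind: str = "true"  # true | out_of_frame | stop_interrupted | in_cds | no_atg
    intron: str = "cds"  # cds | utr3 | utr3_50 | none
    homozygous: bool = False


@dataclass
class PlantedHss:
    name: str
    gap_codons: int
    chimp_triplet: str = "ACG"
    strand: str = "+"
    kind: str = "true"  # true | polymorphic | outgroup_shared | not_5utr | gap_broken
    shared_outgroup: str = "gorilla"  # for outgroup_shared


def _default_startgain_events() -> list[PlantedStartGain]:
    ev = [
        PlantedStartGain("sg_true_01", 16, 6, 4, intron="utr3"),
        PlantedStartGain("sg_true_02", 16, 10, 5, strand="-"),
        PlantedStartGain("sg_true_03", 16, 4, 3),
        PlantedStartGain("sg_true_04", 20, 20, 6, homozygous=True),
        PlantedStartGain("sg_true_05", 8, 5, 3, intron="none"),
        PlantedStartGain("sg_true_06", 30, 8, 4, strand="-"),
        PlantedStartGain("sg_true_07", 3, 6, 3),
        PlantedStartGain("sg_true_08", 4, 5, 3, intron="utr3_50"),
        PlantedStartGain("sg_true_09", 16, 2, 2),
        PlantedStartGain("sg_true_10", 10, 6, 3, contig="chrX"),
    ]
    kinds = ("out_of_frame", "stop_interrupted", "in_cds", "no_atg")
    for kind in kinds:
        for i in range(3):
            ev.append(
                PlantedStartGain(
                    f"sg_{kind}_{i + 1:02d}", 12, 2, 1, kind=kind,
                    intron="none" if i == 2 else "cds",
                )
            )
    return ev


def _default_hss_events() -> list[PlantedHss]:
    non_analyzable = [1, 1, 2, 2, 3, 3, 4, 4, 4, 2]
    analyzable = [5, 8, 10, 10, 10, 10, 12, 14, 16, 18, 20, 24, 30, 36, 50, 62]
    triplets = ["ACG", "GTG", "ATA", "ATC", "AAG", "ATT"]
    ev: list[PlantedHss] = []
    for i, g in enumerate(non_analyzable):
        ev.append(
            PlantedHss(
                f"hss_true_{i + 1:02d}", g,
                chimp_triplet=triplets[i % len(triplets)],
                strand="-" if i == 4 else "+",
            )
        )
    for i, g in enumerate(analyzable):
        k = len(non_analyzable) + i + 1
        if g in (10, 16) and not any(
            e.chimp_triplet == "CTG" and e.gap_codons == g for e in ev
        ):
            trip = "CTG"  # the two CUG-origin codons
        elif g == 18:
            trip = "GCG"  # two divergent triplet positions, merged into one call
        else:
            trip = triplets[i % len(triplets)]
        ev.append(
            PlantedHss(
                f"hss_true_{k:02d}", g, chimp_triplet=trip,
                strand="-" if g == 12 else "+",
            )
        )
    ev += [
        PlantedHss("hss_poly_01", 8, kind="polymorphic"),
        PlantedHss("hss_poly_02", 10, kind="polymorphic", chimp_triplet="GTG"),
        PlantedHss("hss_outg_01", 8, kind="outgroup_shared", shared_outgroup="gorilla"),
        PlantedHss("hss_outg_02", 10, kind="outgroup_shared", shared_outgroup="orangutan"),
        PlantedHss("hss_not5utr_01", 8, kind="not_5utr"),
        PlantedHss("hss_not5utr_02", 10, kind="not_5utr", chimp_triplet="ATA"),
        PlantedHss("hss_gap_01", 8, kind="gap_broken"),
        PlantedHss("hss_gap_02", 10, kind="gap_broken", chimp_triplet="AAG"),
    ]
    return ev


@dataclass
class FixtureConfig:
    seed: int = 0
    n_individuals: int = 62
    n_ribo_human: int = 12
    n_chimp_samples: int = 5
    reads_per_human_sample: int = 40_000
    reads_per_chimp_sample: int = 30_000
    startgain_events: list[PlantedStartGain] = field(default_factory=_default_startgain_events)
    hss_events: list[PlantedHss] = field(default_factory=_default_hss_events)
    carrier_fold: float = 4.0  # start-gain anchor enrichment, carriers vs non-carriers
    hssc_fold: float = 4.9  # hSSC vs hASC enrichment
    hasc_peak: float = 2.0  # hASC anchor weight over background 1.0
    csc_peak: float = 5.0
    cosc_weight: float = 0.1  # non-CUG cOSC anchor weight
    cosc_cug_weight: float = 2.0
    upstream_noise: float = 0.05
    periodicity_amplitude: float = 0.6
    read_length_probs: dict[int, float] = field(
        default_factory=lambda: {26: 0.10, 27: 0.15, 28: 0.25, 29: 0.20, 30: 0.15, 31: 0.10, 32: 0.05}
    )
    # codon evolution of the novel CDS interiors
    kappa: float = 2.0
    omega_human: float = 0.36
    omega_background: float = 2.74
    branch_length: float = 0.06

    def __post_init__(self) -> None:
        if self.carrier_fold < 1 or self.hssc_fold < 1:
            raise ConfigError("enrichment folds must be >= 1")
        if abs(sum(self.read_length_probs.values()) - 1) > 1e-9:
            raise ConfigError("read length distribution must sum to 1")
        for ev in self.startgain_events:
            if ev.carriers_in_ribo > min(ev.carriers_total, self.n_ribo_human):
                raise ConfigError(f"{ev.name}: carriers_in_ribo too large")


# --------------------------------------------------------------- sequence helpers

_SAFE_CODONS = ["GCC", "GGC", "CTC", "CCG", "GCG", "TCC", "AGC", "CAG", "GTC", "CGG"]


def _bg(rng: np.random.Generator, n: int) -> str:
    """A/T-free background: can never contain ATG or a stop codon."""
    return "".join(np.array(list("CG"))[rng.integers(0, 2, n)])


def _safe_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(np.array(_SAFE_CODONS)[rng.integers(0, len(_SAFE_CODONS), n_codons)])


def _simulate_codon_rows(
    branch_lengths: dict[str, float],
    kappa: float,
    omegas: dict[str, float],
    pi: np.ndarray,
    n_codons: int,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Root codons from pi, then per-branch evolution by exp(Q_branch * t).

    Stop codons cannot arise: the state space is the 61 sense codons.
    Returns per-taxon codon lists plus the root under key ``'root'``.
    """
    root = rng.choice(len(SENSE_CODONS), size=n_codons, p=pi)
    out = {"root": [SENSE_CODONS[i] for i in root]}
    for taxon, t in branch_lengths.items():
        q = build_rate_matrix(kappa, omegas[taxon], pi)
        p = transition_matrix(q, t, pi)
        cdf = p[root].cumsum(axis=1)
        u = rng.random(n_codons)
        child = (u[:, None] > cdf).sum(axis=1)
        out[taxon] = [SENSE_CODONS[i] for i in child]
    return out


def simulate_codon_alignment(
    branch_lengths: dict[str, float],
    kappa: float,
    omegas: dict[str, float],
    pi: Optional[np.ndarray] = None,
    n_codons: int = 100,
    seed: int = 0,
) -> CodonAlignment:
    """Simulate a codon alignment on the star tree under branch-specific omega."""
    pi = UNIFORM_PI if pi is None else np.asarray(pi, dtype=float)
    rng = np.random.default_rng(seed)
    rows = _simulate_codon_rows(branch_lengths, kappa, omegas, pi, n_codons, rng)
    taxa = list(branch_lengths)
    return CodonAlignment(taxa=taxa, columns=list(zip(*[rows[t] for t in taxa])))


# --------------------------------------------------------------- cassettes


@dataclass
class _Transcript:
    tid: str
    exons_cols: list[tuple[int, int]]
    cds_start_col: int
    cds_stop_end_col: int


@dataclass
class _Cassette:
    name: str
    contig: str
    strand: str
    rows: dict[str, str]  # species -> gapped row, human row ungapped
    transcripts: list[_Transcript]  # human annotation
    chimp_transcripts: list[_Transcript] = field(default_factory=list)
    emit_maf: bool = False
    snv: Optional[dict] = None  # planted VCF record in column coordinates
    meta: dict = field(default_factory=dict)

    @property
    def n_cols(self) -> int:
        return len(self.rows["human"])


def _insert(base: str, pos: int, motif: str) -> str:
    return base[:pos] + motif + base[pos + len(motif) :]


def _build_startgain_cassette(ev: PlantedStartGain, rng: np.random.Generator) -> _Cassette:
    g = ev.gap_codons
    utr = 3 * (g + 2) + 24
    if utr < 3 * (g + 1) + 6:
        raise ConfigError(f"{ev.name}: 5'UTR too short for a {g}-codon gap")
    cds_col = FLANK + utr
    k = cds_col - 3 * (g + 1)
    if ev.kind == "out_of_frame":
        k -= 1
    utr_seq = _bg(rng, utr)
    motif = "ATG" if ev.kind == "no_atg" else "ACG"
    utr_seq = _insert(utr_seq, k - FLANK, motif)
    if ev.kind == "stop_interrupted":
        utr_seq = _insert(utr_seq, k - FLANK + 3, "TAA")

    body = "ATG" + _safe_cds(rng, MAIN_CDS_CODONS) + "TAA"
    stop_end_col = cds_col + len(body) - 1
    pre = _bg(rng, FLANK) + utr_seq + body + _bg(rng, UTR3_LEN + FLANK)

    intron_col = None
    if ev.intron == "cds":
        intron_col = cds_col + 3 + 20 * 3
    elif ev.intron == "utr3":
        intron_col = stop_end_col + 61
    elif ev.intron == "utr3_50":
        intron_col = stop_end_col + 50
    if intron_col is not None:
        pre = pre[:intron_col] + "GT" + _bg(rng, INTRON_LEN - 4) + "AG" + pre[intron_col:]
        stop_shift = INTRON_LEN if intron_col <= stop_end_col else 0
        exons = [(FLANK, intron_col), (intron_col + INTRON_LEN, len(pre) - FLANK)]
        stop_end_col += stop_shift
    else:
        exons = [(FLANK, len(pre) - FLANK)]

    transcripts = [_Transcript(ev.name + "_t", exons, cds_col, stop_end_col)]
    if ev.kind == "in_cds":
        b_stop = FLANK + 3 + ((utr - 8) // 3) * 3 - 1
        transcripts.append(_Transcript(ev.name + "_olap", [(FLANK, FLANK + utr)], FLANK + 3, b_stop))

    snv_col = k + 1
    ref_local, alt_local = ("T", "C") if ev.kind == "no_atg" else ("C", "T")
    assert pre[snv_col] == ref_local
    rows = {sp: pre for sp in SPECIES}
    return _Cassette(
        name=ev.name,
        contig=ev.contig,
        strand=ev.strand,
        rows=rows,
        transcripts=transcripts,
        snv={"col": snv_col, "ref_local": ref_local, "alt_local": alt_local, "event": ev},
        meta={
            "kind": ev.kind,
            "novel_start_col": k,
            "cds_start_col": cds_col,
            "stop_end_col": stop_end_col,
            "gap_codons": g,
            "intron": ev.intron,
        },
    )


def _build_hss_cassette(
    ev: PlantedHss, rng: np.random.Generator, cfg: FixtureConfig
) -> _Cassette:
    g = ev.gap_codons
    utr = 30
    hssc_col = FLANK + utr
    utr_seq = _bg(rng, utr)
    if ev.kind == "not_5utr":
        # upstream start codon annotated as the chimp CDS start, putting the
        # orthologous site inside chimp coding sequence
        utr_seq = _insert(utr_seq, 9, "ATG")

    interior = _simulate_codon_rows(
        {sp: cfg.branch_length for sp in ("human", "chimpanzee", "gorilla")},
        cfg.kappa,
        {
            "human": cfg.omega_human,
            "chimpanzee": cfg.omega_background,
            "gorilla": cfg.omega_background,
        },
        UNIFORM_PI,
        g,
        rng,
    )
    interior["orangutan"] = interior["root"]

    main = _safe_cds(rng, MAIN_CDS_CODONS) + "TAA"
    hasc_col = hssc_col + 3 + 3 * g
    stop_end_col = hasc_col + 3 + len(main) - 1
    intron_col = hasc_col + 3 + 20 * 3

    rows = {}
    for sp in SPECIES:
        trip = "ATG" if sp == "human" else ev.chimp_triplet
        if ev.kind == "outgroup_shared" and sp == ev.shared_outgroup:
            trip = "ATG"
        rows[sp] = trip + "".join(interior[sp]) + "ATG" + main
    pre = _bg(rng, FLANK) + utr_seq
    post = _bg(rng, UTR3_LEN + FLANK)
    intron = "GT" + _bg(rng, INTRON_LEN - 4) + "AG"
    full_rows = {}
    for sp in SPECIES:
        body = rows[sp]
        body = body[: intron_col - hssc_col] + intron + body[intron_col - hssc_col :]
        full_rows[sp] = pre + body + post
    stop_end_col += INTRON_LEN
    n_cols = len(full_rows["human"])
    exons = [(FLANK, intron_col), (intron_col + INTRON_LEN, n_cols - FLANK)]

    if ev.kind == "gap_broken":
        r = full_rows["gorilla"]
        full_rows["gorilla"] = r[:hssc_col] + "---" + r[hssc_col + 3 :]

    human_t = [_Transcript(ev.name + "_ht", exons, hssc_col, stop_end_col)]
    chimp_cds_start = FLANK + 9 if ev.kind == "not_5utr" else hasc_col
    chimp_t = [_Transcript(ev.name + "_ct", exons, chimp_cds_start, stop_end_col)]

    divergent_offsets = [i for i in range(3) if ev.chimp_triplet[i] != "ATG"[i]]
    snv = None
    if ev.kind == "polymorphic":
        # one heterozygous individual at the first divergent triplet position
        off = divergent_offsets[0]
        col = hssc_col + off
        ref_local = "ATG"[off]
        alt_local = next(b for b in "ACGT" if b != ref_local)
        snv = {"col": col, "ref_local": ref_local, "alt_local": alt_local, "event": ev}
    return _Cassette(
        name=ev.name,
        contig="chr1",
        strand=ev.strand,
        rows=full_rows,
        transcripts=human_t,
        chimp_transcripts=chimp_t,
        emit_maf=True,
        snv=snv,
        meta={
            "kind": ev.kind,
            "hssc_col": hssc_col,
            "hasc_col": hasc_col,
            "stop_end_col": stop_end_col,
            "gap_codons": g,
            "chimp_triplet": ev.chimp_triplet,
            "divergent_offsets": divergent_offsets,
            "cug_origin": ev.chimp_triplet == "CTG",
            "interior_human": "".join(interior["human"]),
        },
    )


# --------------------------------------------------------------- assembly


class _Assembly:
    """Concatenated per-species genomes with per-cassette offsets."""

    def __init__(self, cassettes: Sequence[_Cassette], rng: np.random.Generator):
        self.cassettes = list(cassettes)
        self.genomes: dict[str, dict[str, str]] = {sp: {} for sp in SPECIES}
        self.offsets: dict[tuple[str, str], int] = {}  # (cassette, species) -> start
        contigs = sorted({c.contig for c in cassettes})
        parts: dict[str, dict[str, list[str]]] = {
            sp: {c: [] for c in contigs} for sp in SPECIES
        }
        lengths: dict[str, dict[str, int]] = {sp: {c: 0 for c in contigs} for sp in SPECIES}
        for contig in contigs:
            spacer = _bg(rng, SPACER)
            for sp in SPECIES:
                parts[sp][contig].append(spacer)
                lengths[sp][contig] += SPACER
            for cas in self.cassettes:
                if cas.contig != contig:
                    continue
                spacer = _bg(rng, SPACER)
                for sp in SPECIES:
                    seq = cas.rows[sp].replace("-", "")
                    if cas.strand == "-":
                        seq = revcomp(seq)
                    self.offsets[(cas.name, sp)] = lengths[sp][contig]
                    parts[sp][contig].append(seq)
                    parts[sp][contig].append(spacer)
                    lengths[sp][contig] += len(seq) + SPACER
        for sp in SPECIES:
            for contig in contigs:
                self.genomes[sp][contig] = "".join(parts[sp][contig])

    def human_pos(self, cas: _Cassette, col: int) -> int:
        """Forward-strand human genomic position of a cassette column."""
        o = self.offsets[(cas.name, "human")]
        if cas.strand == "+":
            return o + col
        return o + cas.n_cols - 1 - col

    def species_pos(self, cas: _Cassette, sp: str, col: int) -> int:
        """Forward-strand genomic position of a column in species sp (the
        column must be ungapped in that species)."""
        row = cas.rows[sp]
        assert row[col] != "-"
        local = col - row[:col].count("-")
        length = len(row) - row.count("-")
        o = self.offsets[(cas.name, sp)]
        return o + local if cas.strand == "+" else o + length - 1 - local

    def transcript_model(self, cas: _Cassette, tr: _Transcript, sp: str = "human") -> TranscriptModel:
        def colpos(col: int) -> int:
            return self.human_pos(cas, col) if sp == "human" else self.species_pos(cas, sp, col)

        exons = []
        for s, e in tr.exons_cols:
            a, b = colpos(s), colpos(e - 1)
            exons.append((min(a, b), max(a, b) + 1))
        strand = cas.strand
        exons.sort(key=lambda x: x[0], reverse=(strand == "-"))
        return TranscriptModel(
            transcript_id=tr.tid,
            gene_id=tr.tid.rsplit("_", 1)[0],
            contig=cas.contig,
            strand=strand,
            exons=exons,
            cds_start_codon_pos=colpos(tr.cds_start_col),
            cds_stop_codon_end=colpos(tr.cds_stop_end_col),
        )

    def maf_blocks(self, query_species: str) -> list[dict]:
        """Per-cassette pairwise alignment rows (human-forward orientation)."""
        out = []
        for cas in self.cassettes:
            if not cas.emit_maf:
                continue
            trow, qrow = cas.rows["human"], cas.rows[query_species]
            if cas.strand == "-":
                trow, qrow = revcomp(trow), revcomp(qrow)
            q_len = len(cas.rows[query_species].replace("-", ""))
            out.append(
                {
                    "contig": cas.contig,
                    "t_start": self.offsets[(cas.name, "human")],
                    "t_len": cas.n_cols,
                    "q_start": self.offsets[(cas.name, query_species)],
                    "q_len": q_len,
                    "t_row": trow,
                    "q_row": qrow,
                }
            )
        return out


# --------------------------------------------------------------- genotypes


def _sample_names(n: int) -> list[str]:
    return [f"IND{i + 1:03d}" for i in range(n)]


def _assign_genotypes(
    ev: PlantedStartGain, n: int, n_ribo: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Carriers: the first carriers_in_ribo profiled individuals plus random
    non-profiled ones; heterozygous unless the event is marked homozygous."""
    gts = [(0, 0)] * n
    carrier_idx = list(range(ev.carriers_in_ribo))
    extra = ev.carriers_total - ev.carriers_in_ribo
    pool = list(range(n_ribo, n))
    carrier_idx += sorted(rng.choice(pool, size=extra, replace=False).tolist())
    gt = (1, 1) if ev.homozygous else (0, 1)
    for i in carrier_idx:
        gts[i] = gt
    return gts


# --------------------------------------------------------------- footprints


@dataclass
class RiboModel:
    """Per-sample P-site intensity over transcript space."""

    transcripts: list[TranscriptModel]
    weights: list[np.ndarray]  # aligned with transcripts

    def flatten(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
        gpos, w, strand_flags, contigs, t_ids = [], [], [], [], []
        for t, wt in zip(self.transcripts, self.weights):
            nz = np.flatnonzero(wt)
            t2g = np.asarray(t._t2g)
            gpos.append(t2g[nz])
            w.append(wt[nz])
            strand_flags.append(np.full(nz.size, t.strand == "-"))
            contigs.extend([t.contig] * nz.size)
            t_ids.extend([t.transcript_id] * nz.size)
        return (
            np.concatenate(gpos),
            np.concatenate(w),
            np.concatenate(strand_flags),
            contigs,
            t_ids,
        )


def _periodic(n_codons: int, amp: float) -> np.ndarray:
    codon = np.array([1 + amp, 1 - amp / 2, 1 - amp / 2])
    return np.tile(codon, n_codons)


def simulate_footprints(
    model: RiboModel,
    sample_id: str,
    n_reads: int,
    length_probs: dict[int, float],
    rng: np.random.Generator,
) -> list[FootprintRead]:
    """Draw P-sites from the intensity model, then back-compute each read's
    leftmost coordinate from its sampled length via the inverse offset rule,
    so re-running the P-site rule recovers the sampled positions exactly."""
    gpos, w, minus, contigs, _ = model.flatten()
    if n_reads == 0:
        return []
    p = w / w.sum()
    idx = rng.choice(gpos.size, size=n_reads, p=p)
    lens = np.array(list(length_probs))
    lprobs = np.array([length_probs[k] for k in lens])
    lengths = lens[rng.choice(lens.size, size=n_reads, p=lprobs)]
    offsets = np.array([PSITE_OFFSETS[int(l)] for l in lengths])
    psites = gpos[idx]
    is_minus = minus[idx]
    left = np.where(is_minus, psites + offsets - (lengths - 1), psites - offsets)
    reads = []
    for i in range(n_reads):
        reads.append(
            FootprintRead(
                sample_id=sample_id,
                contig=contigs[idx[i]],
                leftmost_pos=int(left[i]),
                read_length=int(lengths[i]),
                strand="-" if is_minus[i] else "+",
                unique_flag=True,
            )
        )
    return reads


def _junk_reads(sample_id: str, contig: str, rng: np.random.Generator) -> tuple[list[FootprintRead], list[int]]:
    """Reads that the filters must remove: multi-mapped, off-length, and
    blacklist-overlapping. Returns (reads, NH values)."""
    reads, nh = [], []
    for _ in range(20):
        reads.append(FootprintRead(sample_id, contig, int(rng.integers(400, 500)), 28, "+", False))
        nh.append(2)
    for ln in (22, 25, 33, 40):
        for _ in range(5):
            reads.append(FootprintRead(sample_id, contig, int(rng.integers(400, 500)), ln, "+", True))
            nh.append(1)
    for _ in range(15):  # inside the blacklist interval [10, 60)
        reads.append(FootprintRead(sample_id, contig, int(rng.integers(12, 30)), 28, "+", True))
        nh.append(1)
    return reads, nh


# --------------------------------------------------------------- fixture


def make_fixture(config: FixtureConfig, outdir: str) -> tuple[dict, dict]:
    """Write the full fixture into *outdir*; return (paths, truth)."""
    rng = np.random.default_rng(config.seed)
    os.makedirs(outdir, exist_ok=True)
    ribo_dir = os.path.join(outdir, "ribo")
    os.makedirs(ribo_dir, exist_ok=True)

    cassettes = [_build_startgain_cassette(ev, rng) for ev in config.startgain_events]
    hss_cassettes = [_build_hss_cassette(ev, rng, config) for ev in config.hss_events]
    cassettes += hss_cassettes
    asm = _Assembly(cassettes, rng)

    samples = _sample_names(config.n_individuals)
    ribo_samples = samples[: config.n_ribo_human]
    chimp_samples = [f"CHIMP{i + 1}" for i in range(config.n_chimp_samples)]

    # ---- transcripts
    human_models: dict[str, TranscriptModel] = {}
    chimp_models: dict[str, TranscriptModel] = {}
    cas_by_name = {c.name: c for c in cassettes}
    for cas in cassettes:
        for tr in cas.transcripts:
            human_models[tr.tid] = asm.transcript_model(cas, tr, "human")
        for tr in cas.chimp_transcripts:
            chimp_models[tr.tid] = asm.transcript_model(cas, tr, "chimpanzee")

    # ---- VCF records and truth
    vcf_records: list[SnvRecord] = []
    truth_sg: list[dict] = []
    sg_distractors: dict[str, str] = {}
    for cas in cassettes:
        if cas.snv is None:
            continue
        ev = cas.snv["event"]
        col = cas.snv["col"]
        pos = asm.human_pos(cas, col)
        if cas.strand == "+":
            ref, alt = cas.snv["ref_local"], cas.snv["alt_local"]
        else:
            ref, alt = revcomp(cas.snv["ref_local"]), revcomp(cas.snv["alt_local"])
        assert asm.genomes["human"][cas.contig][pos] == ref
        if isinstance(ev, PlantedHss):  # polymorphic hSSC distractor
            gts = [(0, 0)] * config.n_individuals
            gts[config.n_individuals // 2] = (0, 1)
            vcf_records.append(
                SnvRecord(cas.contig, pos, ref, alt, gts, ev.name, samples)
            )
            continue
        gts = _assign_genotypes(ev, config.n_individuals, config.n_ribo_human, rng)
        rec = SnvRecord(cas.contig, pos, ref, alt, gts, ev.name, samples)
        vcf_records.append(rec)
        if ev.kind == "true":
            model = human_models[ev.name + "_t"]
            novel_tpos = model.genome_to_transcript(asm.human_pos(cas, cas.meta["novel_start_col"]))
            canon_tpos = model.cds_start_tpos
            kept = (
                ev.gap_codons >= 5
                and ev.carriers_total >= 3
                and ev.contig != "chrX"
            )
            truth_sg.append(
                {
                    "variant_id": ev.name,
                    "transcript_id": ev.name + "_t",
                    "novel_start_tpos": novel_tpos,
                    "canonical_start_tpos": canon_tpos,
                    "novel_cds_len_nt": 3 * ev.gap_codons,
                    "novel_cds_len_codons": ev.gap_codons,
                    "n_carriers": ev.carriers_total,
                    "allele_frequency": rec.allele_frequency(),
                    "autosomal": ev.contig != "chrX",
                    "kept_by_occupancy_filter": kept,
                    "carriers": sorted(rec.carriers()),
                }
            )
        else:
            sg_distractors[ev.name] = ev.kind

    # ---- HSS truth
    truth_hss: list[dict] = []
    hss_distractors: dict[str, str] = {}
    for cas in hss_cassettes:
        ev = next(e for e in config.hss_events if e.name == cas.name)
        site_positions = sorted(
            asm.human_pos(cas, cas.meta["hssc_col"] + off)
            for off in cas.meta["divergent_offsets"]
        )
        if ev.kind == "true":
            truth_hss.append(
                {
                    "name": ev.name,
                    "transcript_id": ev.name + "_ht",
                    "chimp_transcript_id": ev.name + "_ct",
                    "novel_cds_len_nt": 3 * ev.gap_codons,
                    "gap_codons": ev.gap_codons,
                    "cug_origin": cas.meta["cug_origin"],
                    "analyzable": ev.gap_codons >= 5,
                    "site_positions": site_positions,
                    "strand": cas.strand,
                }
            )
        else:
            reason = {
                "polymorphic": "polymorphic_in_population",
                "outgroup_shared": "outgroup_shares_human_allele",
                "not_5utr": "chimp_ortholog_not_in_5utr",
                "gap_broken": "missing_outgroup",
            }[ev.kind]
            for p in site_positions:
                hss_distractors[f"chr1:{p}"] = reason

    # ---- write genomes / annotation / VCF / MAF / blacklist
    paths = {}
    contig_order = sorted(asm.genomes["human"])
    for sp in SPECIES:
        path = os.path.join(outdir, f"{sp}.fa")
        nio.write_fasta(
            [GenomeSequence(c, asm.genomes[sp][c], sp) for c in contig_order], path
        )
        paths[f"fasta_{sp}"] = path
    paths["gff_human"] = os.path.join(outdir, "human.gff3")
    nio.write_gff3(sorted(human_models.values(), key=lambda m: m.transcript_id), paths["gff_human"])
    paths["gff_chimp"] = os.path.join(outdir, "chimpanzee.gff3")
    nio.write_gff3(sorted(chimp_models.values(), key=lambda m: m.transcript_id), paths["gff_chimp"])
    paths["vcf"] = os.path.join(outdir, "population.vcf")
    nio.write_vcf(
        vcf_records,
        samples,
        {c: len(asm.genomes["human"][c]) for c in contig_order},
        paths["vcf"],
    )

    from .models import AlignedInterval, PairwiseBlock

    for sp in ("chimpanzee", "gorilla", "orangutan"):
        blocks = []
        for i, b in enumerate(asm.maf_blocks(sp)):
            blocks.append(
                PairwiseBlock(
                    target_species="human",
                    query_species=sp,
                    target_interval=AlignedInterval(b["contig"], b["t_start"], b["t_start"] + b["t_len"], "+"),
                    query_interval=AlignedInterval(b["contig"], b["q_start"], b["q_start"] + b["q_len"], "+"),
                    aligned_target=b["t_row"],
                    aligned_query=b["q_row"],
                    block_id=f"{sp}:{i}",
                )
            )
        if sp == "chimpanzee":
            # overlapping junk blocks on a spacer: dropped by the one-to-one filter
            a0 = 100
            t1 = asm.genomes["human"]["chr1"][a0 : a0 + 40]
            q1 = asm.genomes["chimpanzee"]["chr1"][a0 : a0 + 40]
            t2 = asm.genomes["human"]["chr1"][a0 + 20 : a0 + 60]
            q2 = asm.genomes["chimpanzee"]["chr1"][200:240]
            blocks.append(
                PairwiseBlock("human", sp, AlignedInterval("chr1", a0, a0 + 40, "+"),
                              AlignedInterval("chr1", a0, a0 + 40, "+"), t1, q1, "junk:0")
            )
            blocks.append(
                PairwiseBlock("human", sp, AlignedInterval("chr1", a0 + 20, a0 + 60, "+"),
                              AlignedInterval("chr1", 200, 240, "+"), t2, q2, "junk:1")
            )
        src_sizes = {
            f"human.{c}": len(asm.genomes["human"][c]) for c in contig_order
        } | {f"{sp}.{c}": len(asm.genomes[sp][c]) for c in contig_order}
        paths[f"maf_{sp}"] = os.path.join(outdir, f"human_{sp}.maf")
        nio.write_maf(blocks, paths[f"maf_{sp}"], src_sizes)

    paths["blacklist"] = os.path.join(outdir, "blacklist.bed")
    with open(paths["blacklist"], "w") as fh:
        fh.write("chr1\t10\t60\tncrna_cluster\t0\t+\n")

    # ---- ribosome footprints
    amp = config.periodicity_amplitude
    noise = config.upstream_noise

    def _sg_weights(cas: _Cassette, model: TranscriptModel, carrier: bool) -> np.ndarray:
        w = np.zeros(len(model))
        ns = model.genome_to_transcript(asm.human_pos(cas, cas.meta["novel_start_col"]))
        cs = model.cds_start_tpos
        stop = model.cds_stop_end_tpos
        if carrier:
            w[: max(ns - 1, 0)] = noise
            n_codons = (stop + 1 - ns) // 3
            w[ns : ns + 3 * n_codons] = _periodic(n_codons, amp)
            w[ns - 1 : ns + 2] = config.carrier_fold
        else:
            w[:cs] = 1.0
            n_codons = (stop + 1 - cs) // 3
            w[cs : cs + 3 * n_codons] = _periodic(n_codons, amp)
            w[ns - 1 : ns + 2] = 1.0
        return w

    def _hss_human_weights(cas: _Cassette, model: TranscriptModel) -> np.ndarray:
        w = np.zeros(len(model))
        hssc = model.cds_start_tpos
        hasc = model.genome_to_transcript(asm.human_pos(cas, cas.meta["hasc_col"]))
        stop = model.cds_stop_end_tpos
        w[: max(hssc - 1, 0)] = noise
        n_codons = (stop + 1 - hssc) // 3
        w[hssc : hssc + 3 * n_codons] = _periodic(n_codons, amp)
        w[hasc - 1 : hasc + 2] = config.hasc_peak
        w[hssc - 1 : hssc + 2] = config.hssc_fold * config.hasc_peak
        return w

    def _hss_chimp_weights(cas: _Cassette, model: TranscriptModel) -> np.ndarray:
        w = np.zeros(len(model))
        csc = model.cds_start_tpos
        cosc_g = asm.species_pos(cas, "chimpanzee", cas.meta["hssc_col"])
        cosc = model.genome_to_transcript(cosc_g)
        stop = model.cds_stop_end_tpos
        w[:csc] = noise
        n_codons = (stop + 1 - csc) // 3
        w[csc : csc + 3 * n_codons] = _periodic(n_codons, amp)
        w[csc - 1 : csc + 2] = config.csc_peak
        cosc_w = config.cosc_cug_weight if cas.meta["cug_origin"] else config.cosc_weight
        w[cosc - 1 : cosc + 2] = cosc_w
        return w

    sg_true_cassettes = [
        (cas_by_name[t["variant_id"]], human_models[t["transcript_id"]], set(t["carriers"]))
        for t in truth_sg
    ]
    hss_true = [t for t in truth_hss]

    contig_lengths_h = {c: len(asm.genomes["human"][c]) for c in contig_order}
    contig_lengths_c = {c: len(asm.genomes["chimpanzee"][c]) for c in contig_order}

    for sid in ribo_samples:
        transcripts, weights = [], []
        for cas, model, carriers in sg_true_cassettes:
            transcripts.append(model)
            weights.append(_sg_weights(cas, model, sid in carriers))
        for t in hss_true:
            cas = cas_by_name[t["name"]]
            model = human_models[t["transcript_id"]]
            transcripts.append(model)
            weights.append(_hss_human_weights(cas, model))
        reads = simulate_footprints(
            RiboModel(transcripts, weights), sid,
            config.reads_per_human_sample, config.read_length_probs, rng,
        )
        junk, junk_nh = _junk_reads(sid, "chr1", rng)
        path = os.path.join(ribo_dir, f"{sid}.sam")
        nio.write_sam(reads + junk, contig_lengths_h, path,
                      nh_override=[1] * len(reads) + junk_nh)
        paths[f"sam_{sid}"] = path

    for sid in chimp_samples:
        transcripts, weights = [], []
        for t in hss_true:
            cas = cas_by_name[t["name"]]
            model = chimp_models[t["chimp_transcript_id"]]
            transcripts.append(model)
            weights.append(_hss_chimp_weights(cas, model))
        reads = simulate_footprints(
            RiboModel(transcripts, weights), sid,
            config.reads_per_chimp_sample, config.read_length_probs, rng,
        )
        path = os.path.join(ribo_dir, f"{sid}.sam")
        nio.write_sam(reads, contig_lengths_c, path)
        paths[f"sam_{sid}"] = path

    # ---- NMD truth
    nmd_truth = {}
    for ev in config.startgain_events:
        if ev.kind != "true":
            continue
        nmd_truth[ev.name + "_t"] = ev.intron == "utr3"

    lens_sg = sorted(t["novel_cds_len_nt"] for t in truth_sg)
    lens_hss = sorted(t["novel_cds_len_nt"] for t in truth_hss)
    truth = {
        "samples": samples,
        "ribo_samples": ribo_samples,
        "chimp_samples": chimp_samples,
        "startgain": {
            "true_calls": truth_sg,
            "distractors": sg_distractors,
            "n_true": len(truth_sg),
            "n_kept_by_occupancy_filter": sum(t["kept_by_occupancy_filter"] for t in truth_sg),
            "median_novel_cds_len_nt": float(np.median(lens_sg)) if lens_sg else None,
        },
        "hss": {
            "true_calls": truth_hss,
            "distractors": hss_distractors,
            "n_true": len(truth_hss),
            "n_analyzable": sum(t["analyzable"] for t in truth_hss),
            "n_cug_origin": sum(t["cug_origin"] for t in truth_hss),
            "n_non_cug_analyzable": sum(
                t["analyzable"] and not t["cug_origin"] for t in truth_hss
            ),
            "n_concat_cds": sum(t["novel_cds_len_nt"] > 15 for t in truth_hss),
            "median_novel_cds_len_nt": float(np.median(lens_hss)) if lens_hss else None,
        },
        "ribo": {
            "carrier_fold": config.carrier_fold,
            "hssc_fold": config.hssc_fold,
            "periodicity_amplitude": config.periodicity_amplitude,
        },
        "codon_sim": {
            "kappa": config.kappa,
            "omega_human": config.omega_human,
            "omega_background": config.omega_background,
            "branch_length": config.branch_length,
        },
        "nmd": nmd_truth,
    }
    paths["truth"] = os.path.join(outdir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths, truth


# --------------------------------------------------------------- small experiments


def simulate_carrier_experiment(
    fold: float,
    n_samples: int = 8,
    n_anchors: int = 6,
    reads_per_sample: int = 3000,
    seed: int = 0,
    amp: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """A minimal carrier-vs-non-carrier occupancy experiment on a bare
    transcript set: returns (carrier_flags, occupancy) arrays over all
    (sample, anchor) units, computed through the footprint -> P-site ->
    RPM-track -> codon-occupancy machinery.

    Carrier status is Bernoulli(0.5) per (sample, anchor), mimicking
    genotype-driven grouping. Used for fold-recovery checks and null
    (fold = 1) calibration of the rank-sum test.
    """
    from .riboprofile import build_rpm_track, codon_occupancy, filter_reads

    rng = np.random.default_rng(seed)
    n_len = 240
    transcripts = [
        TranscriptModel(f"t{i}", f"g{i}", "c1", "+", [(1000 * i + 100, 1000 * i + 100 + n_len)],
                        cds_start_codon_pos=1000 * i + 100 + 60,
                        cds_stop_codon_end=1000 * i + 100 + n_len - 1)
        for i in range(n_anchors)
    ]
    anchor_tpos = 60
    carrier = rng.random((n_samples, n_anchors)) < 0.5
    occ = np.zeros((n_samples, n_anchors))
    lp = {26: 0.2, 28: 0.3, 29: 0.2, 30: 0.2, 32: 0.1}
    for s in range(n_samples):
        weights = []
        for a in range(n_anchors):
            w = np.zeros(n_len)
            w[:anchor_tpos] = 0.5
            w[anchor_tpos:] = _periodic((n_len - anchor_tpos) // 3, amp)
            w[anchor_tpos - 1 : anchor_tpos + 2] = fold if carrier[s, a] else 1.0
            weights.append(w)
        reads = simulate_footprints(
            RiboModel(transcripts, weights), f"s{s}", reads_per_sample, lp, rng
        )
        track = build_rpm_track(filter_reads(reads), f"s{s}")
        for a, t in enumerate(transcripts):
            occ[s, a] = codon_occupancy(
                track, "c1", t.transcript_to_genome(anchor_tpos), "+"
            )
    return carrier.ravel(), occ.ravel()
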