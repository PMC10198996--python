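"""Start-gain SNV calling: rule examples, the exhaustive substitution
oracle, population summaries, occupancy filtering and NMD classification."""

import numpy as np
import pytest

from novostart import startgain as sg
from novostart.models import Genome, GenomeSequence, SnvRecord, TranscriptModel, revcomp

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_calls(transcript, genome, cds_union):
    """Independent oracle: try every single-base substitution at every
    exonic 5'UTR position and decide start-gain status by direct simulation
    of the rules on the mutated transcript sequence."""
    seq = transcript.spliced_sequence(genome)
    cs = transcript.cds_start_tpos
    found = {}
    for tpos in range(cs):
        gpos = transcript.transcript_to_genome(tpos)
        in_cds = any(
            s <= gpos < e for s, e in cds_union.get(transcript.contig, ())
        )
        for alt in "ACGT":
            if alt == seq[tpos]:
                continue
            mutated = seq[:tpos] + alt + seq[tpos + 1 :]
            best = None
            for k in range(max(0, tpos - 2), tpos + 1):
                if k + 3 > cs:
                    continue
                if mutated[k : k + 3] != "ATG" or seq[k : k + 3] == "ATG":
                    continue
                if (cs - k) % 3 != 0:
                    continue
                codons = [mutated[i : i + 3] for i in range(k + 3, cs, 3)]
                if any(c in STOPS for c in codons):
                    continue
                best = k
                break
            if best is not None and not in_cds:
                found[(tpos, alt)] = best
    return found


def _make_transcript(strand, utr, cds_codons, contig="c1", offset=100):
    """Assemble a genome + transcript from a transcript-oriented sequence."""
    tx = utr + "ATG" + cds_codons + "TAA"
    flank = "G" * offset
    if strand == "+":
        contig_seq = flank + tx + flank
        exons = [(offset, offset + len(tx))]
    else:
        contig_seq = flank + revcomp(tx) + flank
        exons = [(offset, offset + len(tx))]
    t = TranscriptModel(
        "t1", "g1", contig, strand, exons,
        cds_start_codon_pos=offset + len(utr) if strand == "+" else offset + len(tx) - len(utr) - 1,
        cds_stop_codon_end=offset + len(tx) - 1 if strand == "+" else offset,
    )
    genome = Genome.from_sequences([GenomeSequence(contig, contig_seq)])
    assert t.spliced_sequence(genome) == tx
    return t, genome


def _snv_at(transcript, genome, tpos, alt_transcript_base, samples=("a", "b")):
    gpos = transcript.transcript_to_genome(tpos)
    ref = genome.base(transcript.contig, gpos)
    alt = alt_transcript_base if transcript.strand == "+" else revcomp(alt_transcript_base)
    return SnvRecord(
        transcript.contig, gpos, ref, alt,
        [(0, 1), (0, 0)], f"snv_{tpos}", list(samples),
    )


class TestClassifyRules:
    utr = "GC" * 12 + "ACG" + "GCC" * 4 + "GCG"  # ACG at tpos 24; UTR is 42 nt

    def test_in_frame_creation_called(self):
        # alt creates an in-frame AUG 18 nt upstream of the canonical start:
        # 5 full codons lie strictly between the two starts
        t, genome = _make_transcript("+", self.utr, "GCC" * 10)
        cds_union = sg.cds_interval_union([t])
        snv = _snv_at(t, genome, 25, "T")  # ACG -> ATG at tpos 24
        call = sg.classify_snv(snv, t, genome, cds_union)
        assert call is not None
        assert call.novel_start_tpos == 24
        assert call.canonical_start_tpos == 42
        assert call.novel_cds_len_nt == 15 and call.novel_cds_len_codons == 5
        assert call.carrier_individuals == {"a"}

    def test_out_of_frame_rejected(self):
        utr = "GC" * 12 + "ACG" + "GCC" * 4 + "GCGC"  # gap now 13 nt
        t, genome = _make_transcript("+", utr, "GCC" * 10)
        snv = _snv_at(t, genome, 25, "T")
        assert sg.classify_snv(snv, t, genome, sg.cds_interval_union([t])) is None

    def test_intervening_stop_rejected(self):
        utr = "GC" * 12 + "ACG" + "TGA" + "GCC" * 3 + "GCG"
        t, genome = _make_transcript("+", utr, "GCC" * 10)
        snv = _snv_at(t, genome, 25, "T")
        assert sg.classify_snv(snv, t, genome, sg.cds_interval_union([t])) is None

    def test_reference_atg_not_a_gain(self):
        utr = "GC" * 12 + "ATG" + "GCC" * 4 + "GCG"
        t, genome = _make_transcript("+", utr, "GCC" * 10)
        snv = _snv_at(t, genome, 25, "C")  # ATG -> ACG: destroys, not creates
        assert sg.classify_snv(snv, t, genome, sg.cds_interval_union([t])) is None

    def test_overlapping_cds_excluded(self):
        t, genome = _make_transcript("+", self.utr, "GCC" * 10)
        other = TranscriptModel(
            "t2", "g2", "c1", "+", [(100, 160)],
            cds_start_codon_pos=110, cds_stop_codon_end=145,
        )
        cds_union = sg.cds_interval_union([t, other])
        snv = _snv_at(t, genome, 25, "T")  # genomic pos 125: inside t2's CDS
        assert sg.classify_snv(snv, t, genome, cds_union) is None
        assert sg.classify_snv(snv, t, genome, sg.cds_interval_union([t])) is not None

    def test_ref_mismatch_is_data_error(self):
        t, genome = _make_transcript("+", self.utr, "GCC" * 10)
        snv = _snv_at(t, genome, 25, "T")
        snv.ref_allele = "T" if snv.ref_allele != "T" else "A"
        with pytest.raises(ValueError):
            sg.classify_snv(snv, t, genome, {})


@pytest.mark.parametrize("strand", ["+", "-"])
def test_exhaustive_substitution_oracle(strand):
    """classify_snv agrees with the brute-force oracle for every (position,
    alt allele) combination across the whole 5'UTR, both strands."""
    rng = np.random.default_rng(5)
    # random head, then a stop-free in-frame tail seeded with triplets one
    # substitution away from ATG so positives and negatives both occur
    utr = "".join(rng.choice(list("ACGT"), 39)) + "ACG" + "GCC" + "ATA" + "CCG" + "GTG"
    t, genome = _make_transcript(strand, utr, "GCCGGC" * 5)
    cds_union = sg.cds_interval_union([t])
    expected = brute_force_calls(t, genome, cds_union)
    got = {}
    for tpos in range(t.cds_start_tpos):
        for alt_t in "ACGT":
            seq = t.spliced_sequence(genome)
            if alt_t == seq[tpos]:
                continue
            snv = _snv_at(t, genome, tpos, alt_t)
            call = sg.classify_snv(snv, t, genome, cds_union)
            if call is not None:
                got[(tpos, alt_t)] = call.novel_start_tpos
    assert got == expected
    assert len(expected) > 0  # the random UTR must actually exercise the rules


def test_planted_truth_recovery(fixture, human_genome, human_transcripts, snvs):
    """On the synthetic genome the caller returns exactly the planted true
    start-gain SNVs: precision = recall = 1 over every distractor class."""
    calls = sg.call_all(snvs, human_transcripts, human_genome)
    truth = fixture["truth"]["startgain"]
    got = {c.snv.variant_id for c in calls}
    expected = {t["variant_id"] for t in truth["true_calls"]}
    assert got == expected
    assert set(truth["distractors"]) & got == set()
    by_id = {c.snv.variant_id: c for c in sg.dedup_by_snv(calls)}
    for t in truth["true_calls"]:
        c = by_id[t["variant_id"]]
        assert c.transcript_id == t["transcript_id"]
        assert c.novel_start_tpos == t["novel_start_tpos"]
        assert c.novel_cds_len_nt == t["novel_cds_len_nt"]
        assert len(c.carrier_individuals) == t["n_carriers"]
        assert c.allele_frequency == pytest.approx(t["allele_frequency"])


def test_population_summary_counting():
    """AF of 3/8 for genotypes 0|0,0|1,1|1,0|0 and burden (0,1,1,0)."""
    t, genome = _make_transcript("+", TestClassifyRules.utr, "GCC" * 10)
    samples = ["i1", "i2", "i3", "i4"]
    gpos = t.transcript_to_genome(25)
    snv = SnvRecord("c1", gpos, genome.base("c1", gpos), "T",
                    [(0, 0), (0, 1), (1, 1), (0, 0)], "v1", samples)
    call = sg.classify_snv(snv, t, genome, sg.cds_interval_union([t]))
    assert call.allele_frequency == pytest.approx(3 / 8)
    tables = sg.population_summary([call])
    burden = tables["per_individual"].set_index("individual")["n_novel_start_codons"]
    assert list(burden[samples]) == [0, 1, 1, 0]


def test_allele_frequency_matches_independent_tally(fixture, snvs):
    """AF from SnvRecord equals a recount from the raw VCF GT strings."""
    raw = {}
    with open(fixture["paths"]["vcf"]) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.split("\t")
            gts = "".join(f[9:])
            raw[f[2]] = (gts.count("1"), gts.count("0") + gts.count("1"))
    for r in snvs:
        alt, called = raw[r.variant_id]
        assert r.allele_frequency() == pytest.approx(alt / called)


def test_median_novel_cds_length_matches_planted(fixture, human_genome, human_transcripts, snvs):
    calls = sg.dedup_by_snv(sg.call_all(snvs, human_transcripts, human_genome))
    med = np.median([c.novel_cds_len_nt for c in calls])
    assert med == fixture["truth"]["startgain"]["median_novel_cds_len_nt"]


def _mk_call(codons, n_carriers, contig):
    t, genome = _make_transcript("+", "GC" * 3 * (codons + 3), "GCC" * 5, contig=contig)
    k = t.cds_start_tpos - 3 * (codons + 1)
    samples = [f"s{i}" for i in range(max(n_carriers, 1) + 1)]
    gpos = t.transcript_to_genome(k)
    gts = [(0, 1)] * n_carriers + [(0, 0)] * (len(samples) - n_carriers)
    snv = SnvRecord(contig, gpos, genome.base(contig, gpos), "T", gts, "v", samples)
    return sg.StartGainCall(
        snv=snv, transcript_id="t1", novel_start_tpos=k,
        canonical_start_tpos=t.cds_start_tpos, novel_cds_len_nt=3 * codons,
        novel_cds_len_codons=codons, carrier_individuals=snv.carriers(),
        allele_frequency=snv.allele_frequency(),
        autosomal=contig in sg.DEFAULT_AUTOSOMES,
    )


@pytest.mark.parametrize(
    "codons,carriers,contig,kept",
    [
        (4, 5, "chr7", False),  # one codon short
        (5, 3, "chr7", True),  # at every boundary
        (10, 2, "chr7", False),  # too few carriers
        (10, 10, "chrX", False),  # sex chromosome
    ],
)
def test_occupancy_filter_boundaries(codons, carriers, contig, kept):
    calls = sg.filter_for_occupancy([_mk_call(codons, carriers, contig)])
    assert (len(calls) == 1) == kept


class TestNmd:
    def _transcript(self, stop_to_junction):
        """Two-exon plus-strand transcript with a chosen stop->junction gap."""
        e1 = 200
        # distance = junction tpos - stop-end tpos, per the 50-nt rule
        t = TranscriptModel(
            "t", "g", "c1", "+", [(0, e1), (e1 + 50, e1 + 250)],
            cds_start_codon_pos=10,
            cds_stop_codon_end=e1 - stop_to_junction,
        )
        return t

    def test_beyond_50nt_is_predicted_target(self):
        n = sg.nmd_classify(self._transcript(60))
        assert n.distance_nt == 60 and n.nmd_predicted

    def test_exactly_50nt_is_not(self):
        """The rule is strictly 'more than 50'."""
        n = sg.nmd_classify(self._transcript(50))
        assert n.distance_nt == 50 and not n.nmd_predicted

    def test_single_exon_never_predicted(self):
        t = TranscriptModel("t", "g", "c1", "+", [(0, 300)],
                            cds_start_codon_pos=10, cds_stop_codon_end=100)
        n = sg.nmd_classify(t)
        assert not n.nmd_predicted and n.single_exon and n.distance_nt is None
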