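"""Human-specific start codon scan: one-to-one filtering against a
coverage-count oracle, divergent-site detection, planted-truth recovery
with rejection reasons, CUG flags and the four-anchor occupancy panel."""

import numpy as np
import pandas as pd
import pytest

from novostart import io as nio
from novostart import species_specific as ss
from novostart.models import AlignedInterval, Genome, PairwiseBlock


def _block(ts, te, qs, qe, t_contig="c1", q_contig="c1", bid=""):
    n = te - ts
    assert qe - qs == n
    seq = "A" * n
    return PairwiseBlock(
        "human", "chimp",
        AlignedInterval(t_contig, ts, te, "+"),
        AlignedInterval(q_contig, qs, qe, "+"),
        seq, seq, bid,
    )


def brute_force_one_to_one(blocks):
    """Coverage-count oracle: a block survives iff every base of its target
    interval and of its query interval is covered exactly once genome-wide."""
    from collections import Counter

    t_cov, q_cov = Counter(), Counter()
    for b in blocks:
        for p in range(b.target_interval.start, b.target_interval.end):
            t_cov[(b.target_interval.contig, p)] += 1
        for p in range(b.query_interval.start, b.query_interval.end):
            q_cov[(b.query_interval.contig, p)] += 1
    kept = []
    for b in blocks:
        ok_t = all(
            t_cov[(b.target_interval.contig, p)] == 1
            for p in range(b.target_interval.start, b.target_interval.end)
        )
        ok_q = all(
            q_cov[(b.query_interval.contig, p)] == 1
            for p in range(b.query_interval.start, b.query_interval.end)
        )
        if ok_t and ok_q:
            kept.append(b)
    return kept


class TestOneToOne:
    def test_overlapping_targets_both_dropped(self):
        blocks = [_block(0, 10, 100, 110), _block(5, 15, 200, 210)]
        assert ss.filter_one_to_one(blocks) == []

    def test_disjoint_blocks_all_kept(self):
        blocks = [_block(0, 10, 100, 110), _block(20, 30, 200, 210)]
        assert ss.filter_one_to_one(blocks) == blocks

    def test_query_side_conflict_drops_both(self):
        blocks = [_block(0, 10, 100, 110), _block(20, 30, 105, 115)]
        assert ss.filter_one_to_one(blocks) == []

    def test_containment_chain(self):
        """A long block containing two short ones: all three conflict."""
        blocks = [_block(0, 100, 0, 100), _block(10, 20, 200, 210), _block(30, 40, 300, 310)]
        assert ss.filter_one_to_one(blocks) == []

    def test_matches_coverage_oracle_on_random_block_sets(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            blocks = []
            for i in range(rng.integers(2, 12)):
                n = int(rng.integers(3, 20))
                ts = int(rng.integers(0, 80))
                qs = int(rng.integers(0, 80))
                blocks.append(
                    _block(ts, ts + n, qs, qs + n,
                           t_contig=f"c{rng.integers(1, 3)}",
                           q_contig=f"c{rng.integers(1, 3)}", bid=str(i))
                )
            got = [b.block_id for b in ss.filter_one_to_one(blocks)]
            want = [b.block_id for b in brute_force_one_to_one(blocks)]
            assert got == want, f"trial {trial}"


class TestDivergentSites:
    def _genome(self, seq):
        return Genome.from_sequences([nio.GenomeSequence("c1", seq)])

    def test_substitution_emitted_gap_skipped(self):
        human = self._genome("CCAACGGCC")
        b = PairwiseBlock(
            "human", "chimp",
            AlignedInterval("c1", 2, 7, "+"),
            AlignedInterval("c1", 0, 4, "+"),
            "AACGG", "AG-GG", "b0",
        )
        sites = ss.find_divergent_sites([b], human)
        assert [(s.human_pos, s.human_allele, s.alleles["chimp"]) for s in sites] == [
            (3, "A", "G")
        ]

    def test_genome_mismatch_is_data_error(self):
        human = self._genome("CCAACGGCC")
        b = PairwiseBlock(
            "human", "chimp",
            AlignedInterval("c1", 2, 7, "+"),
            AlignedInterval("c1", 0, 5, "+"),
            "TTTTT", "TTTTT", "b0",
        )
        with pytest.raises(ValueError):
            ss.find_divergent_sites([b], human)

    def test_planted_substitutions_recovered_exactly(self, fixture, human_genome):
        blocks = ss.filter_one_to_one(nio.read_maf(fixture["paths"]["maf_chimpanzee"]))
        sites = ss.find_divergent_sites(blocks, human_genome)
        got = {(s.human_contig, s.human_pos) for s in sites}
        # every planted hSSC divergent position must be among the sites
        truth = fixture["truth"]["hss"]
        for t in truth["true_calls"]:
            for p in t["site_positions"]:
                assert ("chr1", p) in got
        # and every site disagrees between the two emitted genomes
        chimp = nio.read_genome(fixture["paths"]["fasta_chimpanzee"])
        lift = ss.LiftMap(blocks)
        for s in sites:
            q = lift.query_position(s.human_contig, s.human_pos)
            assert chimp.base(q[0], q[1]) in "ACGT"


@pytest.fixture(scope="module")
def species_scan(fixture, human_genome, snvs):
    paths = fixture["paths"]
    chimp_genome = nio.read_genome(paths["fasta_chimpanzee"])
    human_transcripts = nio.read_gff3(paths["gff_human"])
    chimp_transcripts = nio.read_gff3(paths["gff_chimp"])
    one2one = {
        sp: ss.filter_one_to_one(nio.read_maf(paths[f"maf_{sp}"]))
        for sp in ("chimpanzee", "gorilla", "orangutan")
    }
    lifts = {sp: ss.LiftMap(b) for sp, b in one2one.items()}
    sites = ss.find_divergent_sites(
        one2one["chimpanzee"], human_genome, chimp_genome,
        outgroup_lifts={"gorilla": lifts["gorilla"], "orangutan": lifts["orangutan"]},
    )
    population = {(r.contig, r.pos): r for r in snvs}
    calls, reasons = ss.call_all(
        sites, human_transcripts, chimp_transcripts, population, lifts["chimpanzee"]
    )
    return {
        "calls": calls,
        "reasons": reasons,
        "lifts": lifts,
        "human_by_id": {t.transcript_id: t for t in human_transcripts},
        "chimp_by_id": {t.transcript_id: t for t in chimp_transcripts},
    }


class TestPlantedHssRecovery:
    def test_exact_recovery(self, fixture, species_scan):
        truth = fixture["truth"]["hss"]
        got = {c.transcript_id for c in species_scan["calls"]}
        want = {t["transcript_id"] for t in truth["true_calls"]}
        assert got == want  # precision = recall = 1

    def test_call_fields_match_truth(self, fixture, species_scan):
        truth = {t["transcript_id"]: t for t in fixture["truth"]["hss"]["true_calls"]}
        for c in species_scan["calls"]:
            t = truth[c.transcript_id]
            assert c.novel_cds_len_nt == t["novel_cds_len_nt"]
            assert c.cug_origin == t["cug_origin"]
            assert c.fixed_in_population and c.chimp_ortholog_in_5utr
            assert c.chimp_transcript_id == t["chimp_transcript_id"]

    def test_rejection_reason_codes(self, fixture, species_scan):
        """Each distractor class is rejected for exactly the planted reason."""
        reasons = species_scan["reasons"]
        expected = fixture["truth"]["hss"]["distractors"]
        assert expected  # all four classes planted
        for site_key, want in expected.items():
            assert reasons[site_key] == want, site_key

    def test_multi_divergent_triplet_merged_into_one_call(self, species_scan):
        """Human ATG vs chimp GCG differs at two positions: one call with
        both within-codon offsets recorded (codons are counted, not SNVs)."""
        multi = [c for c in species_scan["calls"] if len(c.divergent_offsets) > 1]
        assert len(multi) == 1
        assert multi[0].divergent_offsets == [0, 1]

    def test_strand_consistency(self, fixture, species_scan):
        """Events planted on minus-strand transcripts are recovered with
        identical novel-CDS lengths and flags after normalization."""
        truth = {t["transcript_id"]: t for t in fixture["truth"]["hss"]["true_calls"]}
        minus = [c for c in species_scan["calls"] if truth[c.transcript_id]["strand"] == "-"]
        assert len(minus) >= 2
        for c in minus:
            t = truth[c.transcript_id]
            assert c.novel_cds_len_nt == t["novel_cds_len_nt"]
            assert (c.hasc_tpos - c.hssc_tpos) % 3 == 0


class TestCugAndPanel:
    def test_cug_flags(self, fixture, species_scan):
        n_cug = sum(bool(c.cug_origin) for c in species_scan["calls"])
        assert n_cug == fixture["truth"]["hss"]["n_cug_origin"] == 2

    def test_cug_excluded_set_size(self, fixture, species_scan):
        """2 CUG-origin among 16 analyzable leaves 14 for the second-round
        occupancy analysis."""
        panel = ss.hssc_site_panel(
            species_scan["calls"], species_scan["human_by_id"],
            species_scan["chimp_by_id"], species_scan["lifts"]["chimpanzee"],
        )
        analyzable = panel[panel.analyzable]
        assert len(analyzable) == 16
        assert len(analyzable[~analyzable.cug_origin.astype(bool)]) == 14

    def test_gap_broken_triplet_leaves_flag_unknown(self, species_scan):
        """flag_cug_origin on a transcript whose chimp triplet is only
        partially aligned must keep the call with cug_origin None."""
        calls = species_scan["calls"]
        c = calls[0]
        lift = species_scan["lifts"]["chimpanzee"]
        t = species_scan["human_by_id"][c.transcript_id]
        # remove one aligned triplet column from a copy of the lift map
        import copy

        broken = copy.copy(lift)
        broken.t2q = dict(lift.t2q)
        gpos = t.transcript_to_genome(c.hssc_tpos + 1)
        del broken.t2q[(t.contig, gpos)]
        c2 = copy.copy(c)
        ss.flag_cug_origin(c2, species_scan["human_by_id"], broken)
        assert c2.cug_origin is None

    def test_anchor_positions_via_column_walk(self, fixture, species_scan):
        """All four anchors round-trip through a brute-force column walk of
        the MAF blocks: cOSC is the chimp base aligned to the hSSC column,
        and cSC lifts back to hASC."""
        blocks = ss.filter_one_to_one(
            nio.read_maf(fixture["paths"]["maf_chimpanzee"])
        )
        panel = ss.hssc_site_panel(
            species_scan["calls"], species_scan["human_by_id"],
            species_scan["chimp_by_id"], species_scan["lifts"]["chimpanzee"],
        )
        # independent column walk: human pos -> chimp pos for each block
        walk = {}
        for b in blocks:
            tp, qp = b.target_interval.start, b.query_interval.start
            for tc, qc in zip(b.aligned_target, b.aligned_query):
                if tc != "-" and qc != "-":
                    walk[(b.target_interval.contig, tp)] = qp
                if tc != "-":
                    tp += 1
                if qc != "-":
                    qp += 1
        for _, r in panel.iterrows():
            if r.anchors_missing:
                continue
            assert walk[(r.human_contig, r.hssc_pos)] == r.cosc_pos
            assert walk[(r.human_contig, r.hasc_pos)] == r.csc_pos
        assert not panel.anchors_missing.any()

    def test_analyzability_threshold(self, species_scan):
        panel = ss.hssc_site_panel(
            species_scan["calls"], species_scan["human_by_id"],
            species_scan["chimp_by_id"], species_scan["lifts"]["chimpanzee"],
        )
        for _, r in panel.iterrows():
            assert r.analyzable == (r.novel_cds_len_codons >= 5)
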