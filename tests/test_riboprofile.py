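"""P-site inference, RPM tracks, codon occupancy, metagene profiles and the
Wilcoxon machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from novostart import riboprofile as rp
from novostart.models import FootprintRead, TranscriptModel


def _read(left, length, strand="+", unique=True, black=False, contig="c1"):
    return FootprintRead("s", contig, left, length, strand, unique, black)


class TestFilterAndOffsets:
    @pytest.mark.parametrize(
        "length,unique,black,kept",
        [(25, True, False, False), (26, True, False, True), (32, True, False, True),
         (33, True, False, False), (30, False, False, False), (28, True, True, False)],
    )
    def test_filter_boundaries(self, length, unique, black, kept):
        out = rp.filter_reads([_read(100, length, unique=unique, black=black)])
        assert (len(out) == 1) == kept

    @pytest.mark.parametrize(
        "length,expected", [(26, 111), (28, 111), (29, 111), (30, 112), (31, 112), (32, 112)]
    )
    def test_plus_strand_offsets(self, length, expected):
        """12th nt for 26-29 nt reads, 13th for 30-32 nt reads."""
        assert rp.psite_position(_read(100, length)) == expected

    def test_minus_strand_mirrors_offset(self):
        # 5' end of a minus read is its rightmost base: (100+27) - 11 = 116
        assert rp.psite_position(_read(100, 28, "-")) == 116

    def test_out_of_range_length_rejected(self):
        with pytest.raises(ValueError):
            rp.psite_position(_read(100, 25))

    @pytest.mark.parametrize("length", range(26, 33))
    def test_strand_mirror_property(self, length):
        """Reverse-complementing the contig and flipping the read leaves the
        P-site at the mirrored coordinate for every read length."""
        contig_len = 1000
        left = 300
        fwd = rp.psite_position(_read(left, length, "+"))
        flipped_left = contig_len - (left + length)
        rev = rp.psite_position(_read(flipped_left, length, "-"))
        assert rev == contig_len - 1 - fwd


class TestTracks:
    def test_degenerate_all_reads_one_base(self):
        reads = [_read(100, 28) for _ in range(4)]
        track = rp.build_rpm_track(reads, "s")
        assert track.rpm("c1", 111) == pytest.approx(1e6)
        assert track.total_rpm() == pytest.approx(1e6)

    def test_ten_reads_ten_bases(self):
        reads = [_read(100 + 10 * i, 28) for i in range(10)]
        track = rp.build_rpm_track(reads, "s")
        for i in range(10):
            assert track.rpm("c1", 111 + 10 * i) == pytest.approx(1e5)

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError):
            rp.build_rpm_track([], "s")

    def test_fixture_tracks_sum_to_one_million_and_match_recount(self, fixture):
        """RPM conservation (rel tol 1e-6) plus a brute-force dictionary
        recount of per-base values, for every sample in the fixture."""
        from collections import Counter

        from novostart import io as nio

        paths = fixture["paths"]
        blacklist = nio.read_bed_intervals(paths["blacklist"])
        for sid in fixture["truth"]["ribo_samples"][:3] + fixture["truth"]["chimp_samples"][:2]:
            reads = rp.filter_reads(nio.read_sam(paths[f"sam_{sid}"], sid, blacklist))
            track = rp.build_rpm_track(reads, sid)
            assert track.total_rpm() == pytest.approx(1e6, rel=1e-6)
            recount = Counter()
            for r in reads:
                recount[(r.contig, rp.psite_position(r))] += 1
            scale = 1e6 / len(reads)
            for (contig, pos), n in recount.items():
                assert track.rpm(contig, pos) == pytest.approx(n * scale)
            assert sum(recount.values()) == track.total_retained_reads


class TestCodonOccupancy:
    def _track(self, values):
        from collections import Counter

        reads = []
        for pos, n in values.items():
            reads += [_read(pos - 11, 28) for _ in range(n)]
        return rp.build_rpm_track(reads, "s")

    def test_single_base_signal(self):
        track = self._track({50: 5, 300: 5})
        assert rp.codon_occupancy(track, "c1", 50, "+") == pytest.approx(5e5)

    def test_cleavage_slop_base_captured(self):
        """Signal landing one base before the codon is fully captured."""
        track = self._track({49: 10})
        assert rp.codon_occupancy(track, "c1", 50, "+") == pytest.approx(1e6)

    def test_three_term_sum_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = {int(p): int(n) for p, n in zip(rng.integers(40, 400, 50), rng.integers(1, 9, 50))}
        track = self._track(vals)
        for p in (50, 100, 150, 200):
            manual = sum(track.rpm("c1", p + d) for d in (-1, 0, 1))
            assert rp.codon_occupancy(track, "c1", p, "+") == pytest.approx(manual)
            assert rp.codon_occupancy(track, "c1", p, "-") == pytest.approx(manual)


class TestMetagene:
    def _setup(self, peak_offset0=True):
        t = TranscriptModel("t1", "g1", "c1", "+", [(100, 400)],
                            cds_start_codon_pos=160, cds_stop_codon_end=399)
        anchor = rp.Anchor("a1", t, 60)
        reads_peak = [_read(160 - 11 + d, 28) for d in (-1, 0, 1) for _ in range(20)]
        reads_flat = [_read(100 + 7 * i, 28) for i in range(40)]
        return t, anchor, reads_peak, reads_flat

    def test_planted_peak_maximal_at_offset_zero_for_carriers(self):
        t, anchor, peak, flat = self._setup()
        tracks = [rp.build_rpm_track(peak, "carrier_s"), rp.build_rpm_track(flat, "plain_s")]
        grouping = lambda sid, aid: "carrier" if sid.startswith("carrier") else "noncarrier"
        profiles, occ = rp.metagene(tracks, [anchor], 5, grouping)
        prof = profiles["carrier"]
        assert prof.mean_rpm[prof.offsets.index(0)] == max(prof.mean_rpm)
        flat_prof = profiles["noncarrier"]
        assert max(flat_prof.mean_rpm) < prof.mean_rpm[prof.offsets.index(0)]

    def test_zero_signal_elsewhere_gives_zero_profile(self):
        t, anchor, peak, _ = self._setup()
        far = [_read(2000, 28) for _ in range(10)]
        track = rp.build_rpm_track(far, "s")
        profiles, _ = rp.metagene([track], [anchor], 5, lambda s, a: "g")
        assert all(v == 0 for v in profiles["g"].mean_rpm)

    def test_profile_recomputable_from_occupancy_table(self, fixture):
        """Each profile mean equals the hand-computed two-stage mean (over
        anchors within sample, then over samples) of the occupancy table."""
        t, anchor, peak, flat = self._setup()
        t2 = TranscriptModel("t2", "g2", "c2", "+", [(100, 400)],
                             cds_start_codon_pos=160, cds_stop_codon_end=399)
        anchors = [anchor, rp.Anchor("a2", t2, 60)]
        reads = peak + [_read(150 + 3 * i, 28, contig="c2") for i in range(30)]
        tracks = [rp.build_rpm_track(reads, "s1"), rp.build_rpm_track(flat, "s2")]
        profiles, occ = rp.metagene(tracks, anchors, 4, lambda s, a: "g")
        for k, want in zip(profiles["g"].offsets, profiles["g"].mean_rpm):
            sub = occ[(occ.codon_offset == k)]
            manual = sub.groupby("sample_id")["rpm"].mean().mean()
            assert want == pytest.approx(manual)

    def test_splice_aware_window(self):
        """Anchors near a junction walk transcript space: the window skips
        the intron."""
        t = TranscriptModel("t1", "g1", "c1", "+", [(100, 200), (300, 400)],
                            cds_start_codon_pos=130, cds_stop_codon_end=399)
        # anchor at tpos 97; the offset +1 codon straddles the junction:
        # its slop base is the last base of exon 1 (g=199), its first two
        # bases are the first bases of exon 2 (g=300, 301)
        anchor = rp.Anchor("a", t, 97)
        reads = [_read(g - 11, 28) for g in (199, 300, 301) for _ in range(5)]
        track = rp.build_rpm_track(reads, "s")
        profiles, occ = rp.metagene([track], [anchor], 2, lambda s, a: "g")
        prof = profiles["g"]
        assert prof.mean_rpm[prof.offsets.index(1)] == pytest.approx(1e6)

    def test_window_beyond_transcript_end_excluded(self):
        t = TranscriptModel("t1", "g1", "c1", "+", [(100, 120)],
                            cds_start_codon_pos=103, cds_stop_codon_end=119)
        anchor = rp.Anchor("a", t, 3)
        track = rp.build_rpm_track([_read(100, 28)], "s")
        profiles, occ = rp.metagene([track], [anchor], 10, lambda s, a: "g")
        assert min(profiles["g"].offsets) == 0  # offset -1 needs tpos -1: excluded
        assert max(profiles["g"].offsets) == 5  # tpos 18 is the last codon that fits


def wilcoxon_enumeration(diffs):
    """Brute-force null: every sign assignment of the non-zero differences;
    two-sided p as twice the smaller tail (capped at 1)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    n = len(ws)
    p = 2 * min((ws <= w_obs + 1e-9).sum(), (ws >= w_obs - 1e-9).sum()) / n
    return w_obs, min(1.0, p)


class TestWilcoxon:
    def test_spec_example(self):
        """Pairs (2,1),(3,1),(4,2): all-positive differences, p = 0.25."""
        w, p = rp.wilcoxon_signed_rank([2, 3, 4], [1, 1, 2])
        assert p == pytest.approx(0.25)

    def test_identical_vectors(self):
        with pytest.warns(UserWarning):
            res = rp.compare_anchor_classes([1.0, 2.0], [1.0, 2.0], paired=True)
        assert res["p_value"] == 1.0 and res["fold_ratio"] == pytest.approx(1.0)

    def test_exact_matches_enumeration_randomized(self):
        """Exact p equals full sign-assignment enumeration for n <= 10,
        including tied and duplicated differences."""
        rng = np.random.default_rng(3)
        for trial in range(40):
            n = int(rng.integers(2, 11))
            d = rng.integers(-5, 6, size=n).astype(float)
            if not np.any(d):
                d[0] = 1.0
            w_mine, p_mine = rp.wilcoxon_signed_rank(d)
            w_enum, p_enum = wilcoxon_enumeration(d)
            assert w_mine == pytest.approx(w_enum)
            assert p_mine == pytest.approx(p_enum), f"trial {trial}: {d}"

    @given(st.lists(st.integers(-20, 20), min_size=2, max_size=10))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_matches_enumeration_property(self, diffs):
        if not any(diffs):
            diffs[0] = 1
        _, p_mine = rp.wilcoxon_signed_rank(np.asarray(diffs, float))
        _, p_enum = wilcoxon_enumeration(diffs)
        assert p_mine == pytest.approx(p_enum)

    def test_agrees_with_scipy_when_tie_free(self):
        """Cross-check against scipy's exact method on tie-free data."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            d = rng.permutation(np.arange(1, 13)) * rng.choice([-1, 1], 12)
            _, p_mine = rp.wilcoxon_signed_rank(d.astype(float))
            p_scipy = stats.wilcoxon(d, method="exact").pvalue
            assert p_mine == pytest.approx(p_scipy)

    def test_normal_branch_reasonable(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.5, 1.0, 60)
        _, p_big = rp.wilcoxon_signed_rank(d)
        p_scipy = stats.wilcoxon(d, method="approx", correction=True).pvalue
        assert p_big == pytest.approx(p_scipy, rel=1e-6)

    def test_unpaired_mode_is_rank_sum(self):
        a, b = [5.0, 6, 7, 8], [1.0, 2, 3, 4]
        res = rp.compare_anchor_classes(a, b, paired=False)
        assert res["test"] == "wilcoxon_rank_sum"
        assert res["fold_ratio"] == pytest.approx(np.mean(a) / np.mean(b))
        assert res["p_value"] == pytest.approx(
            stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        )
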