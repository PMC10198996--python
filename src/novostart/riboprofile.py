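"""Ribosome-footprint processing: P-site tracks, codon occupancy, metagene
profiles around anchor codons, and group comparisons.

Footprints are filtered to uniquely mapped reads of 26-32 nt that do not
overlap the non-coding-RNA blacklist. The P-site of a read is the 12th
nucleotide from the 5' end for 26-29 nt reads and the 13th for 30-32 nt
reads (0-based offsets 11 and 12). Per-base P-site counts are scaled to
reads per million (RPM) per sample. The occupancy of a codon is the RPM sum
over its first and second nucleotide plus the nucleotide before the first,
tolerating imprecise footprint cleavage; on the minus strand the same rule
is applied in transcript orientation.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import FootprintRead, TranscriptModel

log = logging.getLogger(__name__)

MIN_READ_LEN = 26
MAX_READ_LEN = 32
#: 0-based P-site offset from the 5' end, per read length
PSITE_OFFSETS = {n: (11 if n <= 29 else 12) for n in range(MIN_READ_LEN, MAX_READ_LEN + 1)}


def filter_reads(
    reads: Sequence[FootprintRead],
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
) -> list[FootprintRead]:
    """Keep uniquely mapped, non-blacklisted reads with min_len<=length<=max_len."""
    kept = [
        r
        for r in reads
        if r.unique_flag
        and not r.overlaps_ncrna_blacklist
        and min_len <= r.read_length <= max_len
    ]
    log.info("read filter: %d -> %d reads", len(reads), len(kept))
    return kept


def psite_position(read: FootprintRead) -> int:
    """Genomic position of the P-site. The 5' end of a minus-strand read is
    its rightmost aligned base, so the offset walks leftward."""
    try:
        o = PSITE_OFFSETS[read.read_length]
    except KeyError:
        raise ValueError(f"read length {read.read_length} outside {MIN_READ_LEN}-{MAX_READ_LEN}")
    if read.strand == "+":
        return read.leftmost_pos + o
    return (read.leftmost_pos + read.read_length - 1) - o


@dataclass
class PsiteTrack:
    """Sparse per-base P-site RPM signal for one sample."""

    sample_id: str
    counts: dict[str, Counter]  # contig -> {pos: P-site read count}
    total_retained_reads: int
    normalization_factor: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total_retained_reads <= 0:
            raise ValueError("cannot normalize a track with zero retained reads")
        self.normalization_factor = 1e6 / self.total_retained_reads

    def rpm(self, contig: str, pos: int) -> float:
        c = self.counts.get(contig)
        return 0.0 if c is None else c.get(pos, 0) * self.normalization_factor

    def total_rpm(self) -> float:
        return sum(sum(c.values()) for c in self.counts.values()) * self.normalization_factor

    def to_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.counts):
                for pos in sorted(self.counts[contig]):
                    v = self.counts[contig][pos] * self.normalization_factor
                    fh.write(f"{contig}\t{pos}\t{pos + 1}\t{v:.6g}\n")


def build_rpm_track(reads: Sequence[FootprintRead], sample_id: str) -> PsiteTrack:
    """Per-base P-site counts scaled by 1e6/total so the track sums to 1e6.

    *reads* must already be filtered; every read contributes one P-site.
    """
    counts: dict[str, Counter] = {}
    for r in reads:
        counts.setdefault(r.contig, Counter())[psite_position(r)] += 1
    return PsiteTrack(sample_id=sample_id, counts=counts, total_retained_reads=len(reads))


def codon_occupancy(track: PsiteTrack, contig: str, codon_first_base: int, strand: str) -> float:
    """RPM sum over {first nt, second nt, nt before first} of a codon.

    *codon_first_base* is the genomic position of the codon's first
    nucleotide in transcript orientation. On either strand the three
    contributing bases are the anchor base and its two genomic neighbours
    (the transcript-directional "before" and "second" mirror each other).
    """
    p = codon_first_base
    if p - 1 < 0:
        raise ValueError("codon at contig edge")
    return track.rpm(contig, p - 1) + track.rpm(contig, p) + track.rpm(contig, p + 1)


@dataclass
class Anchor:
    """A codon anchor for metagene profiling, in transcript space."""

    anchor_id: str
    transcript: TranscriptModel
    anchor_tpos: int  # transcript coordinate of the codon's first base


@dataclass
class CodonOccupancy:
    anchor_id: str
    sample_id: str
    codon_index: int
    rpm: float


@dataclass
class MetageneProfile:
    group_label: str
    offsets: list[int]
    mean_rpm: list[float]
    n_anchors: int
    n_samples: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_label,
                "codon_offset": self.offsets,
                "mean_rpm": self.mean_rpm,
                "n_anchors": self.n_anchors,
                "n_samples": self.n_samples,
            }
        )


def occupancy_records(
    track: PsiteTrack,
    anchor: Anchor,
    window_codons: int,
) -> list[CodonOccupancy]:
    """Per-codon occupancies in [-window, +window] around one anchor,
    walking transcript coordinates (introns skipped). Offsets whose codon
    (including the upstream slop base) leaves the transcript are omitted."""
    t = anchor.transcript
    out = []
    for k in range(-window_codons, window_codons + 1):
        tp = anchor.anchor_tpos + 3 * k
        if tp - 1 < 0 or tp + 1 >= len(t):
            continue
        rpm = sum(
            track.rpm(t.contig, t.transcript_to_genome(tp + d)) for d in (-1, 0, 1)
        )
        out.append(CodonOccupancy(anchor.anchor_id, track.sample_id, k, rpm))
    return out


def metagene(
    tracks: Sequence[PsiteTrack],
    anchors: Sequence[Anchor],
    window_codons: int,
    grouping: Callable[[str, str], Optional[str]],
) -> tuple[dict[str, MetageneProfile], pd.DataFrame]:
    """Mean RPM per codon offset, per group.

    *grouping* maps (sample_id, anchor_id) to a group label or None (pair
    excluded). Aggregation is mean over anchors within each sample, then
    mean over samples, so deeply sequenced samples do not dominate.
    Returns the per-group profiles and the raw per-(sample, anchor, offset)
    occupancy table.
    """
    rows = []
    for track in tracks:
        for anchor in anchors:
            group = grouping(track.sample_id, anchor.anchor_id)
            if group is None:
                continue
            for occ in occupancy_records(track, anchor, window_codons):
                rows.append(
                    {
                        "group": group,
                        "sample_id": occ.sample_id,
                        "anchor_id": occ.anchor_id,
                        "codon_offset": occ.codon_index,
                        "rpm": occ.rpm,
                    }
                )
    table = pd.DataFrame(
        rows, columns=["group", "sample_id", "anchor_id", "codon_offset", "rpm"]
    )
    profiles: dict[str, MetageneProfile] = {}
    for group, gdf in table.groupby("group"):
        per_sample = (
            gdf.groupby(["sample_id", "codon_offset"])["rpm"].mean().reset_index()
        )
        prof = per_sample.groupby("codon_offset")["rpm"].mean()
        profiles[group] = MetageneProfile(
            group_label=group,
            offsets=[int(k) for k in prof.index],
            mean_rpm=[float(v) for v in prof.values],
            n_anchors=gdf["anchor_id"].nunique(),
            n_samples=gdf["sample_id"].nunique(),
        )
    return profiles, table


# ---------------------------------------------------------------- tests


def _signed_rank_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Null distribution of W+ on the doubled-rank integer scale.

    counts[s] = number of sign assignments with doubled rank sum s; total
    2^n. Midranks from ties are half-integers, hence the doubling.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Optional[Sequence[float]] = None,
    exact_n: int = 25,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test; returns (W+, p).

    Zero differences are dropped (Wilcoxon's convention). The exact null is
    enumerated (tie-aware, via the doubled-midrank distribution) for up to
    *exact_n* non-zero differences; beyond that a normal approximation with
    tie correction and continuity correction is used. All differences zero
    gives p = 1 with a warning.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences zero; p = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_n:
        dr = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_null_counts(dr)
        total = counts.sum()
        w2 = int(round(2 * w))
        m2 = int(dr.sum())
        lo, hi = min(w2, m2 - w2), max(w2, m2 - w2)
        p = (counts[: lo + 1].sum() + counts[hi:].sum()) / total
        if lo == hi:  # both tails would double-count the center
            p = min(1.0, p - counts[lo] / total)
        return w, float(min(1.0, p))
    mu = n * (n + 1) / 4
    tie_sizes = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24 - (tie_sizes**3 - tie_sizes).sum() / 48
    z = (w - mu - 0.5 * np.sign(w - mu)) / np.sqrt(var)
    return w, float(min(1.0, 2 * stats.norm.sf(abs(z))))


def compare_anchor_classes(
    occ_a: Sequence[float],
    occ_b: Sequence[float],
    paired: bool,
) -> dict:
    """Compare two occupancy vectors (e.g. hSSC vs hASC, carrier vs
    non-carrier). Paired mode: Wilcoxon signed-rank over matched
    (sample, anchor) pairs. Unpaired mode: Wilcoxon rank-sum. The fold
    ratio is mean(a)/mean(b)."""
    a = np.asarray(occ_a, dtype=float)
    b = np.asarray(occ_b, dtype=float)
    mean_b = float(b.mean()) if b.size else float("nan")
    fold = float(a.mean()) / mean_b if mean_b else float("inf")
    if paired:
        if a.size != b.size:
            raise ValueError("paired mode requires matched vectors")
        stat, p = wilcoxon_signed_rank(a, b)
        test = "wilcoxon_signed_rank"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_rank_sum"
    return {
        "test": test,
        "statistic": stat,
        "p_value": p,
        "fold_ratio": fold,
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
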