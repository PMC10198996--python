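"""Codon substitution branch models and Ka/Ks likelihood-ratio tests.

The model is the Goldman-Yang-style 61-state codon model on an unrooted
3-taxon star tree (human, chimpanzee, gorilla). Instantaneous rates between
sense codons i != j differing at exactly one position are

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

with q_ij = 0 for multi-step changes, rows summing to zero, and the matrix
scaled so the expected number of substitutions per codon per unit branch
length is one. omega (Ka/Ks) may differ on a designated foreground branch
(omega1) from the shared background (omega0); nested model pairs are
compared by a chi-squared likelihood-ratio test with one degree of freedom.

The likelihood is Felsenstein pruning on the star tree: for each alignment
column, sum over the 61 root states of pi_r times the product over branches
of P(t_b)[r, observed codon]. Transition matrices come from the symmetrized
eigendecomposition of the reversible Q (stable and cheap to reuse across
branch lengths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

BASES = "TCAG"
STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

_GENETIC_CODE = {}


def _init_code() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _GENETIC_CODE.update(standard_dna_table.forward_table)


_init_code()

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(single_diff, transition, nonsynonymous) boolean matrices, 61x61."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ts = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = frozenset(diffs[0]) in _TRANSITIONS
            nonsyn[i, j] = _GENETIC_CODE[ci] != _GENETIC_CODE[cj]
    return single, ts, nonsyn


_SINGLE, _TS, _NONSYN = _pair_structure()

UNIFORM_PI = np.full(N_CODONS, 1.0 / N_CODONS)


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray, scale: bool = True) -> np.ndarray:
    """GY-style rate matrix over the 61 sense codons.

    Scaled (default) so -sum_i pi_i q_ii == 1. Codons with pi == 0 are
    isolated (zero flow in and out); the model is then restricted to the
    support of pi.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    q = np.where(_SINGLE, pi[None, :], 0.0)
    q = q * np.where(_TS, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    q[pi == 0.0, :] = 0.0
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        rate = -(pi * np.diag(q)).sum()
        if rate > 0:
            q = q / rate
    return q


def transition_matrix(q: np.ndarray, t: float, pi: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) via the symmetrized eigendecomposition (on the
    support of pi; zero-pi rows get identity)."""
    eig = _Spectral(q, pi)
    return eig.expm(t)


class _Spectral:
    """Reusable eigendecomposition of a reversible Q for fast exp(Qt)."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        self.n = q.shape[0]
        self.sup = np.flatnonzero(np.asarray(pi) > 0)
        ps = np.asarray(pi, dtype=float)[self.sup]
        qs = q[np.ix_(self.sup, self.sup)]
        d = np.sqrt(ps)
        sym = qs * d[:, None] / d[None, :]
        vals, vecs = np.linalg.eigh((sym + sym.T) / 2)
        self.vals = vals
        self.left = vecs / d[:, None]
        self.right = (vecs * d[:, None]).T

    def expm(self, t: float) -> np.ndarray:
        ps = self.left * np.exp(self.vals * t)[None, :]
        block = ps @ self.right
        np.clip(block, 0.0, None, out=block)
        out = np.eye(self.n)
        out[np.ix_(self.sup, self.sup)] = block
        return out


@dataclass
class CodonAlignment:
    """A gap- and stop-free codon alignment over an ordered taxon list."""

    taxa: list[str]
    columns: list[tuple[str, ...]]  # one tuple of codons (per taxon) per column
    source_cds_ids: list[str] = field(default_factory=list)
    source_cds_len_nt: int = 0  # nt length of the originating novel CDS
    n_dropped_columns: int = 0

    def __post_init__(self) -> None:
        for col in self.columns:
            if len(col) != len(self.taxa):
                raise ValueError("ragged alignment column")
            for codon in col:
                if codon in STOP_CODONS or codon not in CODON_INDEX:
                    raise ValueError(f"invalid codon {codon!r} in alignment")

    @property
    def n_codons(self) -> int:
        return len(self.columns)

    @classmethod
    def from_rows(
        cls,
        taxa: Sequence[str],
        rows: Sequence[Sequence[Optional[str]]],
        source_cds_ids: Sequence[str] = (),
        source_cds_len_nt: int = 0,
    ) -> "CodonAlignment":
        """Build from per-taxon codon lists, dropping columns containing a
        gap/None, an ambiguous base, or a stop codon in any taxon."""
        cols, dropped = [], 0
        for col in zip(*rows):
            ok = all(
                c is not None and c in CODON_INDEX for c in col
            )
            if ok:
                cols.append(tuple(col))
            else:
                dropped += 1
        return cls(
            taxa=list(taxa),
            columns=cols,
            source_cds_ids=list(source_cds_ids),
            source_cds_len_nt=source_cds_len_nt,
            n_dropped_columns=dropped,
        )

    def codon_indices(self) -> np.ndarray:
        """(n_taxa, n_codons) integer codon indices."""
        return np.array(
            [[CODON_INDEX[col[i]] for col in self.columns] for i in range(len(self.taxa))],
            dtype=int,
        )

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique column patterns and their counts (site independence)."""
        idx = self.codon_indices()
        pats, counts = np.unique(idx.T, axis=0, return_counts=True)
        return pats.T, counts.astype(float)


def concatenate(alignments: Sequence[CodonAlignment], min_len_nt: int = 15) -> CodonAlignment:
    """Concatenate alignments whose source CDS is strictly longer than
    *min_len_nt* (pools sparse per-CDS substitution counts into one
    estimable alignment)."""
    kept = [a for a in alignments if a.source_cds_len_nt > min_len_nt]
    if not kept:
        raise ValueError("no alignment survives the length threshold")
    taxa = kept[0].taxa
    cols, ids = [], []
    for a in kept:
        if a.taxa != taxa:
            raise ValueError("taxa ordering differs between alignments")
        cols.extend(a.columns)
        ids.extend(a.source_cds_ids)
    log.info("concatenate: %d/%d alignments kept, %d codons", len(kept), len(alignments), len(cols))
    return CodonAlignment(taxa=taxa, columns=cols, source_cds_ids=ids)


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies: product of per-codon-position nucleotide
    frequencies pooled over taxa, renormalized over the 61 sense codons."""
    pos_counts = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for col in alignment.columns:
        for codon in col:
            for k, b in enumerate(codon):
                pos_counts[k, base_idx[b]] += 1
    pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, base_idx[c[0]]] * pos_freq[1, base_idx[c[1]]] * pos_freq[2, base_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


@dataclass
class BranchModelSpec:
    """Parameterization of one branch model on the 3-taxon star tree."""

    taxa: tuple[str, str, str] = ("human", "chimpanzee", "gorilla")
    foreground_branch: Optional[str] = None
    kappa: float = 2.0
    pi: np.ndarray = field(default_factory=lambda: UNIFORM_PI.copy())
    omega0: float = 1.0
    omega1: Optional[float] = None
    branch_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.foreground_branch is not None and self.foreground_branch not in self.taxa:
            raise ValueError(f"foreground {self.foreground_branch!r} not in taxa")
        if not self.branch_lengths:
            self.branch_lengths = {t: 0.1 for t in self.taxa}
        if abs(float(np.sum(self.pi)) - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")

    def branch_omega(self, taxon: str) -> float:
        if taxon == self.foreground_branch:
            assert self.omega1 is not None
            return self.omega1
        return self.omega0


def log_likelihood(alignment: CodonAlignment, model: BranchModelSpec) -> float:
    """Pruning log-likelihood of the alignment under the branch model."""
    pats, counts = alignment.patterns()
    return _loglik_patterns(pats, counts, model)


def _loglik_patterns(pats: np.ndarray, counts: np.ndarray, model: BranchModelSpec) -> float:
    pi = np.asarray(model.pi, dtype=float)
    spectral: dict[float, _Spectral] = {}
    per_root = pi.copy()
    lik = np.broadcast_to(per_root[:, None], (N_CODONS, pats.shape[1])).copy()
    for b, taxon in enumerate(model.taxa):
        w = model.branch_omega(taxon)
        if w not in spectral:
            spectral[w] = _Spectral(build_rate_matrix(model.kappa, w, pi), pi)
        p = spectral[w].expm(model.branch_lengths[taxon])
        lik *= p[:, pats[b]]
    col_lik = lik.sum(axis=0)
    if np.any(col_lik <= 0):
        return -np.inf
    return float((np.log(col_lik) * counts).sum())


@dataclass
class KaKsFit:
    """A fitted branch model."""

    model: BranchModelSpec
    log_likelihood: float
    kappa: float
    omega0: float
    omega1: Optional[float]
    branch_lengths: dict[str, float]
    converged: bool
    n_starts_used: int

    @property
    def n_parameters(self) -> int:
        # kappa + omega0 [+ omega1] + branch lengths
        return 2 + (1 if self.omega1 is not None else 0) + len(self.branch_lengths)


@dataclass
class LrtResult:
    """Chi-squared LRT between nested branch models (df = 1)."""

    null_fit: KaKsFit
    alt_fit: KaKsFit
    statistic: float
    df: int
    p_value: float


_BOUNDS_LOG = {
    "kappa": (np.log(0.05), np.log(50.0)),
    "omega": (np.log(1e-4), np.log(50.0)),
    "t": (np.log(1e-6), np.log(20.0)),
}


def fit_model(
    alignment: CodonAlignment,
    foreground: Optional[str] = None,
    pi: Optional[np.ndarray] = None,
    frequencies: str = "f3x4",
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> KaKsFit:
    """Maximum-likelihood fit of (kappa, omega0[, omega1], branch lengths).

    Parameters are optimized on the log scale with L-BFGS-B from a default
    start plus *n_starts* seeded random restarts; codon frequencies are
    F3x4 from the data unless *pi* or ``frequencies='uniform'`` overrides.
    *foreground* names the taxon given its own omega1, or None for the
    single-omega model.
    """
    if alignment.n_codons < 2:
        raise ValueError("need at least 2 codon columns")
    taxa = tuple(alignment.taxa)
    if pi is None:
        pi = UNIFORM_PI.copy() if frequencies == "uniform" else f3x4_frequencies(alignment)
    pats, counts = alignment.patterns()
    has_fg = foreground is not None
    n_par = 2 + (1 if has_fg else 0) + 3  # kappa, omega0[, omega1], t x3

    def unpack(x: np.ndarray) -> BranchModelSpec:
        vals = np.exp(x)
        k = 2 + (1 if has_fg else 0)
        return BranchModelSpec(
            taxa=taxa,
            foreground_branch=foreground,
            kappa=vals[0],
            pi=pi,
            omega0=vals[1],
            omega1=vals[2] if has_fg else None,
            branch_lengths=dict(zip(taxa, vals[k : k + 3])),
        )

    def negloglik(x: np.ndarray) -> float:
        return -_loglik_patterns(pats, counts, unpack(x))

    lo = [_BOUNDS_LOG["kappa"][0], _BOUNDS_LOG["omega"][0]]
    hi = [_BOUNDS_LOG["kappa"][1], _BOUNDS_LOG["omega"][1]]
    if has_fg:
        lo.append(_BOUNDS_LOG["omega"][0])
        hi.append(_BOUNDS_LOG["omega"][1])
    lo += [_BOUNDS_LOG["t"][0]] * 3
    hi += [_BOUNDS_LOG["t"][1]] * 3
    bounds = list(zip(lo, hi))

    x0_default = np.log([2.0, 0.5] + ([0.5] if has_fg else []) + [0.1, 0.1, 0.1])
    rng = np.random.default_rng(seed)
    starts = [x0_default]
    for _ in range(n_starts):
        starts.append(
            np.array([rng.uniform(l, h) for l, h in zip(lo, hi)]) * 0.5 + x0_default * 0.5
        )

    best = None
    used = 0
    for x0 in starts:
        used += 1
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - tol:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("branch-model optimization failed to converge")
    spec = unpack(best.x)
    assert spec.foreground_branch == foreground and len(best.x) == n_par
    return KaKsFit(
        model=spec,
        log_likelihood=-float(best.fun),
        kappa=float(spec.kappa),
        omega0=float(spec.omega0),
        omega1=None if not has_fg else float(spec.omega1),
        branch_lengths={k: float(v) for k, v in spec.branch_lengths.items()},
        converged=bool(best.success),
        n_starts_used=used,
    )


def lrt(null_fit: KaKsFit, alt_fit: KaKsFit, tol: float = 1e-4) -> LrtResult:
    """2*(lnL_alt - lnL_null) against chi-squared with 1 df (one extra omega)."""
    stat = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if stat < -tol:
        raise RuntimeError(
            f"alternative fit worse than null (stat={stat:.6g}): optimizer failure"
        )
    stat = max(stat, 0.0)
    return LrtResult(
        null_fit=null_fit,
        alt_fit=alt_fit,
        statistic=stat,
        df=1,
        p_value=float(stats.chi2.sf(stat, df=1)),
    )


def extract_novel_cds_alignment(
    call,
    human_transcripts: dict,
    lifts: dict,
    human_genome,
    taxa: tuple[str, str, str] = ("human", "chimpanzee", "gorilla"),
) -> CodonAlignment:
    """Codon alignment of one novel CDS (between the human-specific start
    codon and the ancestral start, both excluded) with its chimp and gorilla
    orthologs read through the alignment lift maps.

    *lifts* maps 'chimpanzee'/'gorilla' to their :class:`LiftMap`. Codon
    columns with an unaligned base, N, or a stop in any taxon are dropped
    (the orthologous sequence need not be coding in the other species).
    """
    from .models import COMPLEMENT

    t = human_transcripts[call.transcript_id]
    start = call.hssc_tpos + 3
    end = call.hasc_tpos
    if end - start < 3:
        raise ValueError("novel CDS shorter than one codon")
    rows: dict[str, list[Optional[str]]] = {sp: [] for sp in taxa}
    for codon_start in range(start, end, 3):
        chars: dict[str, list[Optional[str]]] = {sp: [] for sp in taxa}
        for tp in (codon_start, codon_start + 1, codon_start + 2):
            g = t.transcript_to_genome(tp)
            hc = human_genome.base(t.contig, g)
            chars["human"].append(hc)
            for sp in taxa[1:]:
                chars[sp].append(lifts[sp].query_allele(t.contig, g))
        for sp in taxa:
            cs = chars[sp]
            if any(c is None or c not in "ACGT" for c in cs):
                rows[sp].append(None)
            else:
                codon = "".join(cs)
                if t.strand == "-":
                    codon = codon.translate(COMPLEMENT)  # order already 5'->3'
                rows[sp].append(codon)
    aln = CodonAlignment.from_rows(
        taxa,
        [rows[sp] for sp in taxa],
        source_cds_ids=[call.transcript_id],
        source_cds_len_nt=end - start,
    )
    if aln.n_codons < 1:
        raise ValueError(f"{call.transcript_id}: no complete codon column survives")
    return aln
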