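"""PWM scanning with exact P-value threshold calibration.

Motifs are position weight matrices scored as log2 odds against a
non-uniform i.i.d. background (the human genome is ~42% GC, so uniform
backgrounds misprice AT-rich words). A match cutoff is expressed as a
P-value alpha: the score threshold is calibrated so that a random
background word of the motif's length exceeds it with probability < alpha.
The tail probability is computed *exactly* by dynamic programming over the
per-position score distributions, never by sampling.

Dinucleotide repeat motifs (DRMs) — CACACA, GAGAGA, GCGCGC, TATATA — are
probability-one PWMs. Scanning covers both strands; GC and TA repeats are
their own reverse complements, so a single genomic occurrence of those is
reported once per strand (counted twice) unless deduplication is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .regions import GenomicRegion, fetch

__all__ = [
    "PWM",
    "ScanParams",
    "MotifHit",
    "NoThresholdError",
    "DRM_REPEATS",
    "drm_pwm",
    "background_from_gc",
    "log_odds",
    "score_distribution",
    "exact_tail_probability",
    "score_threshold",
    "scan",
    "count_hits",
    "count_per_bp",
    "read_jaspar_pfms",
    "read_meme_motifs",
    "write_hits_bed",
]

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
# reverse complement in code space: A<->T, C<->G
_COMP = np.array([3, 2, 1, 0])

DRM_REPEATS = ("CA", "GA", "GC", "TA")


class NoThresholdError(ValueError):
    """No achievable score satisfies the requested P-value bound."""


@dataclass(frozen=True)
class PWM:
    """Per-position nucleotide probabilities in A,C,G,T order."""

    name: str
    probs: np.ndarray  # shape (L, 4)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError(f"PWM probs must be (L, 4), got {p.shape}")
        if (p < 0).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name}: rows must be probabilities")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1])

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(name, counts / counts.sum(axis=1, keepdims=True))

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "PWM":
        p = np.zeros((len(sequence), 4))
        for i, b in enumerate(sequence.upper()):
            p[i, _CODE[b]] = 1.0
        return cls(name, p)


@dataclass(frozen=True)
class ScanParams:
    """Background model, regularization, and match cutoff for scanning."""

    background: np.ndarray = field(
        default_factory=lambda: background_from_gc(0.42)
    )
    pseudocount: float = 0.001
    alpha: float = 1 / 1024
    both_strands: bool = True
    dedupe_palindromes: bool = False

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        if (bg <= 0).any():
            raise ValueError("background frequencies must all be positive")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: int  # 0-based start within the scanned sequence
    strand: str  # "+" or "-"
    score: float  # log2 odds, bits
    site: str  # matched subsequence on the + strand of the input


def background_from_gc(gc: float) -> np.ndarray:
    """i.i.d. background with the given GC fraction (A=T, C=G)."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    at = (1 - gc) / 2
    return np.array([at, gc / 2, gc / 2, at])


def drm_pwm(repeat: str) -> PWM:
    """Invariant 6 bp dinucleotide-repeat PWM (CA, GA, GC, or TA)."""
    repeat = repeat.upper()
    if repeat not in DRM_REPEATS:
        raise ValueError(f"unsupported repeat {repeat!r}; one of {DRM_REPEATS}")
    return PWM.from_sequence(f"{repeat}_DRM", repeat * 3)


def log_odds(pwm: PWM, params: ScanParams) -> np.ndarray:
    """Log2-odds score matrix with background-proportional pseudocount.

    score(i, b) = log2(p'(i, b) / bg(b)) with
    p'(i, b) = (p(i, b) + c * bg(b)) / (1 + c).
    """
    bg = params.background
    reg = (pwm.probs + params.pseudocount * bg) / (1 + params.pseudocount)
    return np.log2(reg / bg)


def _lattice_distribution(
    M: np.ndarray, bg: np.ndarray, granularity: float
) -> tuple[np.ndarray, np.ndarray]:
    """Score distribution on an integer lattice of the given bit granularity
    (vectorized convolution of the per-position distributions)."""
    q = np.round(M / granularity).astype(np.int64)
    base = q.min(axis=1)
    offs = q - base[:, None]
    probs = np.array([1.0])
    for i in range(M.shape[0]):
        new = np.zeros(len(probs) + int(offs[i].max()))
        for b in range(4):
            o = int(offs[i, b])
            new[o : o + len(probs)] += probs * bg[b]
        probs = new
    scores = (np.arange(len(probs)) + base.sum()) * granularity
    keep = probs > 0
    return scores[keep], probs[keep]


def score_distribution(
    pwm: PWM,
    params: ScanParams,
    exact_words: int = 4**8,
    granularity: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the motif score of a random background word.

    For motifs up to 8 columns (word space <= ``exact_words``) the
    distribution is exact: dynamic programming over positions accumulates
    per-prefix score sums in left-to-right order, so the floats coincide
    bit-for-bit with a word-by-word enumeration. Longer matrices use a
    lattice convolution at 1e-3-bit granularity — far finer than any
    calibration decision depends on.

    Returns (scores ascending, probabilities).
    """
    M = log_odds(pwm, params)
    bg = params.background
    if 4 ** len(pwm) > exact_words:
        return _lattice_distribution(M, bg, granularity)
    dist: dict[float, float] = {0.0: 1.0}
    for i in range(len(pwm)):
        nxt: dict[float, float] = {}
        row = M[i]
        for s, p in dist.items():
            for b in range(4):
                ns = s + row[b]
                nxt[ns] = nxt.get(ns, 0.0) + p * bg[b]
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    return scores, probs


def exact_tail_probability(pwm: PWM, params: ScanParams, s: float) -> float:
    """P(score(W) >= s) for a random background word W, computed exactly."""
    scores, probs = score_distribution(pwm, params)
    return float(probs[scores >= s].sum())


_THRESHOLD_CACHE: dict[tuple, float] = {}


def score_threshold(pwm: PWM, params: ScanParams) -> float:
    """Smallest achievable score s* with P(score(W) >= s*) < alpha (strict).

    Raises :class:`NoThresholdError` when even the maximum achievable score
    is reached by background words with probability >= alpha; callers that
    scan treat that as "no hits possible". Calibrations are memoized: the
    same motif is typically scanned over thousands of regions.
    """
    key = (
        pwm.name,
        pwm.probs.tobytes(),
        params.background.tobytes(),
        params.pseudocount,
        params.alpha,
    )
    if key in _THRESHOLD_CACHE:
        cached = _THRESHOLD_CACHE[key]
        if np.isnan(cached):
            raise NoThresholdError(
                f"no score of {pwm.name} satisfies P < {params.alpha:g}"
            )
        return cached
    scores, probs = score_distribution(pwm, params)
    tails = probs[::-1].cumsum()[::-1]  # tails[i] = P(score >= scores[i])
    passing = np.nonzero(tails < params.alpha)[0]
    if len(passing) == 0:
        _THRESHOLD_CACHE[key] = float("nan")
        raise NoThresholdError(
            f"no score of {pwm.name} satisfies P < {params.alpha:g}"
        )
    result = float(scores[passing[0]])
    _THRESHOLD_CACHE[key] = result
    return result


def encode(sequence: str) -> np.ndarray:
    """Sequence to codes A=0 C=1 G=2 T=3; ambiguous bases get -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _CODE.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Score of every length-L window; NaN where a window contains N."""
    L = M.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    for i in range(L):
        scores += M[i, safe[i : i + n]]
        bad |= codes[i : i + n] < 0
    scores[bad] = np.nan
    return scores


def scan(
    sequence: str,
    pwm: PWM,
    params: ScanParams,
    region_id: str = "",
) -> list[MotifHit]:
    """All windows (both strands, if enabled) scoring at or above the
    calibrated threshold. A palindromic-consensus site therefore yields one
    hit per strand unless ``params.dedupe_palindromes`` collapses them.
    Sequences shorter than the motif return an empty list.

    The comparison allows a 1e-9-bit slack: window scores accumulate in
    strand-dependent order, so a word exactly at the threshold can differ
    from the calibrated value by a rounding ulp.
    """
    try:
        thr = score_threshold(pwm, params) - 1e-9
    except NoThresholdError:
        return []
    codes = encode(sequence)
    M = log_odds(pwm, params)
    hits: list[MotifHit] = []
    L = len(pwm)
    fwd = _window_scores(codes, M)
    for off in np.nonzero(fwd >= thr)[0]:
        hits.append(
            MotifHit(region_id, int(off), "+", float(fwd[off]), sequence[off : off + L])
        )
    if params.both_strands:
        # scoring the reverse strand == scoring the + strand with the
        # reverse-complemented matrix
        M_rc = M[::-1][:, _COMP]
        rev = _window_scores(codes, M_rc)
        for off in np.nonzero(rev >= thr)[0]:
            hits.append(
                MotifHit(
                    region_id, int(off), "-", float(rev[off]), sequence[off : off + L]
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    if params.dedupe_palindromes:
        seen = set()
        deduped = []
        for h in hits:
            if h.offset in seen:
                continue
            seen.add(h.offset)
            deduped.append(h)
        hits = deduped
    return hits


def _window_pass(mat: np.ndarray, M: np.ndarray, thr: float) -> np.ndarray:
    """Boolean (n_regions, n_windows) of windows scoring >= thr.

    ``mat`` holds per-region base codes padded with -1; padded or ambiguous
    windows never pass.
    """
    L = M.shape[0]
    n = mat.shape[1] - L + 1
    scores = np.zeros((mat.shape[0], n))
    bad = np.zeros((mat.shape[0], n), dtype=bool)
    safe = np.where(mat >= 0, mat, 0)
    for i in range(L):
        scores += M[i, safe[:, i : i + n]]
        bad |= mat[:, i : i + n] < 0
    return (scores >= thr) & ~bad


def count_hits(
    regions: Sequence[GenomicRegion],
    genome: Mapping[str, str],
    pwm: PWM,
    params: ScanParams,
) -> np.ndarray:
    """Hit count per region (vectorized over a padded region matrix;
    same match rule as :func:`scan`)."""
    if not regions:
        return np.zeros(0, dtype=np.int64)
    try:
        thr = score_threshold(pwm, params) - 1e-9
    except NoThresholdError:
        return np.zeros(len(regions), dtype=np.int64)
    L = len(pwm)
    seqs = [fetch(genome, r) for r in regions]
    maxlen = max(len(s) for s in seqs)
    if maxlen < L:
        return np.zeros(len(regions), dtype=np.int64)
    mat = np.full((len(seqs), maxlen), -1, dtype=np.int8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = encode(s)
    M = log_odds(pwm, params)
    fwd = _window_pass(mat, M, thr)
    if not params.both_strands:
        return fwd.sum(axis=1)
    rev = _window_pass(mat, M[::-1][:, _COMP], thr)
    if params.dedupe_palindromes:
        return (fwd | rev).sum(axis=1)
    return fwd.sum(axis=1) + rev.sum(axis=1)


def count_per_bp(
    regions: Sequence[GenomicRegion],
    genome: Mapping[str, str],
    pwm: PWM,
    params: ScanParams,
) -> np.ndarray:
    """Hit density (count / region length) per region."""
    counts = count_hits(regions, genome, pwm, params)
    lengths = np.array([r.length for r in regions], dtype=float)
    return counts / lengths


# ---------------------------------------------------------------------------
# motif file I/O (JASPAR PFM and minimal MEME, via Bio.motifs)


def _from_biomotif(m) -> PWM:
    counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T
    name = m.name or m.base_id if hasattr(m, "base_id") else m.name
    return PWM.from_counts(str(name or "motif"), counts)


def read_jaspar_pfms(path) -> list[PWM]:
    """JASPAR-style PFM text (``>ID name`` header + 4 count rows)."""
    from Bio import motifs

    with open(path) as fh:
        return [_from_biomotif(m) for m in motifs.parse(fh, "jaspar")]


def read_meme_motifs(path) -> list[PWM]:
    """Minimal MEME format (letter-probability matrices)."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        probs = np.array([m.pwm[b] for b in ALPHABET], dtype=float).T
        probs /= probs.sum(axis=1, keepdims=True)
        out.append(PWM(str(m.name), probs))
    return out


def write_hits_bed(
    hits: Iterable[MotifHit],
    regions_by_id: Mapping[str, GenomicRegion],
    pwm: PWM,
    path,
) -> None:
    """Hits as BED6 in genome coordinates (score = log2 odds, bits)."""
    with open(path, "w") as fh:
        for h in hits:
            r = regions_by_id[h.region_id]
            start = r.start + h.offset
            fh.write(
                f"{r.chrom}\t{start}\t{start + len(pwm)}\t{pwm.name}"
                f"\t{h.score:.4f}\t{h.strand}\n"
            )
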