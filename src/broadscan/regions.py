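"""Genomic intervals, breadth classes, and matched negative-set construction.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
The central objects are :class:`GenomicRegion` (an interval on a named
chromosome) and :class:`EnhancerRecord` (an interval plus the number of
cellular contexts in which the enhancer is active, its *breadth*).

Negative (non-enhancer) region sets are built either length-matched
(uniform placement anywhere outside an exclusion universe) or matched on
chromosome, length, and GC content by per-region rejection sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicRegion",
    "EnhancerRecord",
    "NegativeSetSpec",
    "RegionError",
    "PlacementError",
    "gc_content",
    "cpg_per_bp",
    "fetch",
    "chrom_sizes",
    "resize_centered",
    "split_by_breadth",
    "shuffle_length_matched",
    "sample_gc_matched",
    "read_bed",
    "write_bed",
    "read_enhancer_bed",
    "write_enhancer_bed",
]


class RegionError(ValueError):
    """Invalid interval arithmetic (e.g. a resized window leaving the chromosome)."""


class PlacementError(RuntimeError):
    """Negative-set placement failed after the retry cap."""


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise RegionError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class EnhancerRecord:
    """An enhancer interval plus its breadth of activity (contexts, >= 1)."""

    region: GenomicRegion
    breadth: int

    def __post_init__(self) -> None:
        if self.breadth < 1:
            raise ValueError(f"breadth must be >= 1, got {self.breadth}")


@dataclass
class NegativeSetSpec:
    """How to draw matched non-enhancer regions.

    mode
        ``"length"`` — length-matched placement anywhere outside the
        exclusions; ``"gc"`` — additionally same chromosome and GC content
        within ``gc_tolerance``.
    gc_tolerance
        Maximum |GC(out) - GC(in)| for ``"gc"`` mode. The matching criterion
        is a knob because "matched" is not a quantified notion; +/-0.02 keeps
        the residual GC signal below the per-region sampling noise of a
        600 bp window.
    exclusions
        Regions the negatives may not overlap by even 1 bp (the positive
        set, the full enhancer catalog, assembly gaps, blacklists, ...).
    """

    mode: str = "length"
    gc_tolerance: float = 0.02
    exclusions: Sequence[GenomicRegion] = field(default_factory=tuple)
    n_replicates: int = 4
    seed: int = 0
    max_tries: int = 10_000
    max_failure_frac: float = 0.01  # abort when more inputs are unmatchable

    def __post_init__(self) -> None:
        if self.mode not in ("length", "gc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "gc" and not self.gc_tolerance > 0:
            raise ValueError("gc_tolerance must be > 0 in gc mode")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# sequence composition

_GC_SET = frozenset("GCgc")
_UNAMBIG = frozenset("ACGTacgt")


def gc_content(sequence: str) -> float:
    """Fraction of G+C among unambiguous bases; NaN if none."""
    n_unambig = sum(1 for b in sequence if b in _UNAMBIG)
    if n_unambig == 0:
        return float("nan")
    n_gc = sum(1 for b in sequence if b in _GC_SET)
    return n_gc / n_unambig


def cpg_per_bp(sequence: str) -> float:
    """CG-dinucleotide rate: (# CpG) / (length - 1)."""
    if len(sequence) < 2:
        raise ValueError("cpg_per_bp needs a sequence of length >= 2")
    s = sequence.upper()
    return s.count("CG") / (len(s) - 1)


def fetch(genome: Mapping[str, str], region: GenomicRegion) -> str:
    """Extract a region's sequence from an in-memory genome mapping."""
    seq = genome[region.chrom]
    if region.end > len(seq):
        raise RegionError(
            f"{region.chrom}:{region.start}-{region.end} exceeds chromosome "
            f"length {len(seq)}"
        )
    return seq[region.start : region.end]


def chrom_sizes(genome: Mapping[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}


# ---------------------------------------------------------------------------
# interval operations


def resize_centered(
    regions: Iterable[GenomicRegion],
    target_len: int,
    sizes: Mapping[str, int],
    on_out_of_bounds: str = "error",
) -> list[GenomicRegion]:
    """Expand or contract every region to ``target_len`` about its center.

    The center ``(start + end) // 2`` is preserved; with an odd split the
    extra base goes rightward (``start = center - target_len // 2``).
    Regions whose resized window would leave the chromosome raise
    :class:`RegionError` (``on_out_of_bounds="error"``) or are clipped to the
    chromosome with a warning (``"clip"``).
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    if on_out_of_bounds not in ("error", "clip"):
        raise ValueError("on_out_of_bounds must be 'error' or 'clip'")
    out = []
    for r in regions:
        start = r.center - target_len // 2
        end = start + target_len
        limit = sizes[r.chrom]
        if start < 0 or end > limit:
            if on_out_of_bounds == "error":
                raise RegionError(
                    f"resized window [{start},{end}) for {r.id or r.chrom} "
                    f"exceeds chromosome bounds [0,{limit})"
                )
            warnings.warn(
                f"clipping resized window for {r.id or r.chrom}", stacklevel=2
            )
            start, end = max(start, 0), min(end, limit)
        out.append(replace(r, start=start, end=end))
    return out


def split_by_breadth(
    catalog: Sequence[EnhancerRecord],
    top_frac: float = 0.05,
    narrow_breadth: int = 1,
    seed: int = 0,
) -> tuple[list[EnhancerRecord], list[EnhancerRecord]]:
    """Build the broad and narrow enhancer classes.

    The broad set contains records whose breadth strictly exceeds the cutoff
    ``b*``, with ``b*`` the smallest breadth such that
    ``|{breadth > b*}| <= top_frac * n`` (the "active in greater than b*
    contexts" convention). The narrow set is a uniform random sample of
    records with breadth exactly ``narrow_breadth``, sized to match the broad
    set. Output is invariant to the order of ``catalog`` for a fixed seed.
    """
    if not catalog:
        raise ValueError("empty catalog")
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must be in (0, 1)")
    n = len(catalog)
    breadths = np.array([rec.breadth for rec in catalog])
    cutoff = 0
    while (breadths > cutoff).sum() > top_frac * n:
        cutoff += 1
    order = np.lexsort(
        (
            [rec.region.start for rec in catalog],
            [rec.region.chrom for rec in catalog],
            [rec.region.id for rec in catalog],
        )
    )
    ordered = [catalog[i] for i in order]
    broad = [rec for rec in ordered if rec.breadth > cutoff]
    candidates = [
        rec
        for rec in ordered
        if rec.breadth == narrow_breadth and rec.breadth <= cutoff
    ]
    if len(candidates) < len(broad):
        raise ValueError(
            f"only {len(candidates)} breadth-{narrow_breadth} records for a "
            f"broad set of {len(broad)}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(candidates), size=len(broad), replace=False)
    narrow = [candidates[i] for i in sorted(pick)]
    return broad, narrow


# ---------------------------------------------------------------------------
# negative sets


def _exclusion_trees(
    exclusions: Iterable[GenomicRegion],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in exclusions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def _overlaps(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlap(start, end))


def shuffle_length_matched(
    regions: Sequence[GenomicRegion],
    genome: Mapping[str, str],
    exclusions: Sequence[GenomicRegion] = (),
    seed: int = 0,
    same_chrom: bool = False,
    max_tries: int = 10_000,
) -> list[GenomicRegion]:
    """Place a length-matched random region for every input region.

    Placement is uniform over all feasible positions (rejection sampling):
    chromosomes are drawn proportionally to the number of start positions
    they offer unless ``same_chrom`` pins each output to its input's
    chromosome. Outputs overlap neither the exclusions nor each other.
    """
    sizes = chrom_sizes(genome)
    trees = _exclusion_trees(exclusions)
    rng = np.random.default_rng(seed)
    names = list(sizes)
    out: list[GenomicRegion] = []
    for i, r in enumerate(regions):
        L = r.length
        if same_chrom:
            pool = [r.chrom]
        else:
            pool = [c for c in names if sizes[c] >= L]
        weights = np.array([sizes[c] - L + 1 for c in pool], dtype=float)
        if not len(pool) or weights.sum() <= 0:
            raise PlacementError(f"no chromosome can host a region of length {L}")
        weights /= weights.sum()
        for _ in range(max_tries):
            chrom = pool[rng.choice(len(pool), p=weights)]
            start = int(rng.integers(0, sizes[chrom] - L + 1))
            if not _overlaps(trees, chrom, start, start + L):
                placed = GenomicRegion(chrom, start, start + L, id=f"shuf_{i}")
                out.append(placed)
                trees.setdefault(chrom, IntervalTree()).addi(start, start + L)
                break
        else:
            raise PlacementError(
                f"could not place a length-{L} region after {max_tries} tries"
            )
    return out


def _window_gc(genome: Mapping[str, str], chrom: str, L: int, cache: dict) -> np.ndarray:
    """GC fraction of every length-L window on a chromosome (prefix sums).

    Ambiguous bases count as non-GC; synthetic genomes contain none.
    """
    key = (chrom, L)
    if key not in cache:
        raw = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        is_gc = (
            (raw == ord("G")) | (raw == ord("C")) | (raw == ord("g")) | (raw == ord("c"))
        ).astype(np.int64)
        prefix = np.concatenate([[0], np.cumsum(is_gc)])
        cache[key] = (prefix[L:] - prefix[:-L]) / L
    return cache[key]


def sample_gc_matched(
    regions: Sequence[GenomicRegion],
    genome: Mapping[str, str],
    spec: NegativeSetSpec,
) -> list[GenomicRegion]:
    """Draw, per input region, a same-chromosome same-length region whose GC
    content matches within ``spec.gc_tolerance``, avoiding the exclusions.

    Candidate starts are enumerated exactly (per-window GC via prefix sums)
    and sampled uniformly; ``spec.max_tries`` bounds the redraws spent on
    overlap conflicts. Regions with no candidate at all (e.g. GC content
    unreachable on this genome) are per-region failures, tolerated up to 1%
    of the input; beyond that the run aborts with :class:`PlacementError`.
    """
    trees = _exclusion_trees(spec.exclusions)
    rng = np.random.default_rng(spec.seed)
    cache: dict = {}
    out: list[GenomicRegion] = []
    failures: list[str] = []
    for i, r in enumerate(regions):
        L = r.length
        target = gc_content(fetch(genome, r))
        wgc = _window_gc(genome, r.chrom, L, cache)
        candidates = np.nonzero(np.abs(wgc - target) <= spec.gc_tolerance)[0]
        placed = None
        if len(candidates):
            for _ in range(spec.max_tries):
                start = int(candidates[rng.integers(0, len(candidates))])
                if not _overlaps(trees, r.chrom, start, start + L):
                    placed = GenomicRegion(r.chrom, start, start + L, id=f"gcm_{i}")
                    break
        if placed is None:
            failures.append(r.id or f"{r.chrom}:{r.start}-{r.end}")
            continue
        out.append(placed)
        trees.setdefault(r.chrom, IntervalTree()).addi(placed.start, placed.end)
    if failures:
        if len(failures) > spec.max_failure_frac * len(regions):
            raise PlacementError(
                f"GC-matched sampling failed for {len(failures)}/{len(regions)} "
                f"regions (first: {failures[0]})"
            )
        warnings.warn(
            f"GC-matched sampling dropped {len(failures)} region(s)",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path) -> list[GenomicRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else ""
            regions.append(
                GenomicRegion(fields[0], int(fields[1]), int(fields[2]), id=name)
            )
    return regions


def write_bed(regions: Iterable[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


def read_enhancer_bed(path) -> list[EnhancerRecord]:
    """BED with 4th column id and 5th column breadth integer."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            records.append(
                EnhancerRecord(
                    GenomicRegion(f[0], int(f[1]), int(f[2]), id=f[3]),
                    breadth=int(f[4]),
                )
            )
    return records


def write_enhancer_bed(records: Iterable[EnhancerRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            r = rec.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t{rec.breadth}\n")
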