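"""Synthetic enhancer catalogs with known planted structure.

The generator emulates the statistical features the downstream analyses
assume about a genome-wide enhancer catalog scored for breadth of activity:

* an i.i.d. background genome at a configurable GC fraction (default 42%,
  the human genome-wide value);
* a breadth-of-activity distribution that is specific-heavy (15% of
  enhancers active in a single context) with a broad tail placing 5% of
  the mass above 45 contexts;
* positive length-breadth and GC-breadth couplings (broadly active
  enhancers are longer and more GC-rich);
* dinucleotide-repeat / arbitrary motif occurrences planted at
  class-dependent per-bp densities, recorded in a truth table;
* a TF table whose motif GC content differs between broadly expressed
  (TSPS < 1) and tissue-specific (TSPS >= 1) factors by a configurable
  effect size.

Everything is driven by one integer seed; each stage draws from its own
fixed substream so stages are independently reproducible and bit-identical
across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_scan import PWM, ALPHABET
from .regions import EnhancerRecord, GenomicRegion

__all__ = [
    "PlantedMotif",
    "SimulationConfig",
    "SyntheticCatalog",
    "SimulationInfeasibleError",
    "default_breadth_distribution",
    "default_planted_motifs",
    "breadth_class",
    "simulate_genome",
    "simulate_enhancers",
    "simulate_tf_table",
    "simulate_catalog",
    "random_regions",
    "gc_shifted_regions",
    "plant_in_regions",
    "simulate_semipartial_data",
    "write_catalog",
]

# fixed substream tags (SeedSequence entropy words)
_STREAM_GENOME = 0
_STREAM_ENHANCERS = 1
_STREAM_TF = 2

_CODES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


class SimulationInfeasibleError(RuntimeError):
    """Requested motif density/placement could not be realized."""


@dataclass(frozen=True)
class PlantedMotif:
    """A motif planted at class-dependent per-bp densities.

    ``densities`` maps breadth class ("narrow", "mid", "broad") to expected
    planted occurrences per base pair; missing classes get zero.
    """

    name: str
    sequence: str
    densities: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.densities.values()):
            raise ValueError(f"negative density for motif {self.name}")


def default_breadth_distribution(
    p_single: float = 0.15,
    top_mass: float = 0.05,
    top_min: int = 45,
    max_breadth: int = 60,
) -> dict[int, float]:
    """Breadth law: geometric body anchored at P(1)=0.15, 5% tail above 45.

    A single geometric law cannot satisfy both anchors (with P(1)=0.15 its
    mass above 45 contexts is ~7e-4), so the body over 1..top_min is
    geometric with its ratio solved so the body carries ``1 - top_mass``,
    and the tail spreads ``top_mass`` uniformly over top_min+1..max_breadth.
    """

    def body_mass(r: float) -> float:
        b = np.arange(top_min)
        return float(p_single * (r**b).sum())

    lo, hi = 1e-9, 1 - 1e-9
    for _ in range(200):
        mid = (lo + hi) / 2
        if body_mass(mid) < 1 - top_mass:
            lo = mid
        else:
            hi = mid
    r = (lo + hi) / 2
    dist = {b: p_single * r ** (b - 1) for b in range(1, top_min + 1)}
    scale = (1 - top_mass) / sum(dist.values())
    dist = {b: p * scale for b, p in dist.items()}
    n_tail = max_breadth - top_min
    for b in range(top_min + 1, max_breadth + 1):
        dist[b] = top_mass / n_tail
    return dist


def default_planted_motifs() -> tuple[PlantedMotif, ...]:
    """Class-dependent DRM densities mirroring the observed directionality:
    GC repeats enriched with breadth, TA repeats depleted, CA/GA flat.
    Densities are low enough that the median per-600-bp count stays 0."""
    return (
        PlantedMotif("GC_DRM", "GCGCGC", {"broad": 1.2e-3, "mid": 4.5e-4, "narrow": 3.0e-4}),
        PlantedMotif("TA_DRM", "TATATA", {"broad": 1.0e-4, "mid": 2.0e-4, "narrow": 2.7e-4}),
        PlantedMotif("CA_DRM", "CACACA", {"broad": 3.0e-4, "mid": 3.0e-4, "narrow": 3.0e-4}),
        PlantedMotif("GA_DRM", "GAGAGA", {"broad": 3.0e-4, "mid": 3.0e-4, "narrow": 3.0e-4}),
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic catalog generator (see module docstring)."""

    seed: int = 0
    # genome
    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    background_gc: float = 0.42
    # enhancer catalog
    n_enhancers: int = 4000
    breadth_distribution: Mapping[int, float] = field(
        default_factory=default_breadth_distribution
    )
    base_length: float = 280.0
    length_breadth_slope: float = 5.5  # bp per context
    length_noise_sd: float = 40.0
    min_length: int = 60
    gc_breadth_slope: float = 0.0012  # GC fraction per context
    broad_min_breadth: int = 45  # breadth > this => "broad" class
    planted_motifs: Sequence[PlantedMotif] = field(
        default_factory=default_planted_motifs
    )
    edge_margin: int = 500  # keep room for 600 bp recentered windows
    plant_guard: int = 2  # min gap between planted instances, bp
    max_plant_tries: int = 1000
    # TF table
    n_tfs: int = 563
    tf_broad_frac: float = 313 / 563
    tf_motif_gc_base: float = 0.455
    tsps_gc_association: float = 0.11  # broad-minus-specific mean motif GC
    tf_motif_gc_sd: float = 0.07
    tf_motifs_per_tf_mean: float = 3.3
    tf_motif_len_range: tuple[int, int] = (8, 14)
    tf_dirichlet_concentration: float = 10.0

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if not 0 < self.background_gc <= 1:
            raise ValueError("background_gc must be in (0, 1]")
        total = sum(self.breadth_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"breadth proportions sum to {total}, not 1")
        if any(p < 0 for p in self.breadth_distribution.values()):
            raise ValueError("breadth proportions must be nonnegative")
        max_len = self.base_length + self.length_breadth_slope * max(
            self.breadth_distribution
        )
        if self.chrom_length < max_len:
            raise ValueError("chrom_length below the longest enhancer")


@dataclass
class SyntheticCatalog:
    """A simulated genome + enhancer catalog + planted-motif truth table."""

    genome: dict[str, str]
    enhancers: list[EnhancerRecord]
    truth: pd.DataFrame  # enhancer_id, chrom, start, end, motif, breadth_class
    tf_table: pd.DataFrame | None = None
    tf_motifs: dict[str, PWM] | None = None
    config: SimulationConfig | None = None


def breadth_class(breadth: int, config: SimulationConfig) -> str:
    if breadth == 1:
        return "narrow"
    if breadth > config.broad_min_breadth:
        return "broad"
    return "mid"


# ---------------------------------------------------------------------------
# genome


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    idx = rng.choice(4, size=n, p=[at, gc / 2, gc / 2, at])
    return _CODES[idx]


def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """i.i.d. background genome: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    rng = np.random.default_rng([_STREAM_GENOME, config.seed])
    genome = {}
    for c in range(config.n_chromosomes):
        bases = _random_bases(rng, config.chrom_length, config.background_gc)
        genome[f"chr{c + 1}"] = bases.tobytes().decode("ascii")
    return genome


# ---------------------------------------------------------------------------
# enhancer catalog


def _place_nonoverlapping(
    rng: np.random.Generator,
    lengths: np.ndarray,
    sizes: Mapping[str, int],
    margin: int,
    max_tries: int = 1000,
) -> list[tuple[str, int]]:
    names = list(sizes)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    placements: list[tuple[str, int]] = []
    weights = np.array([sizes[c] for c in names], dtype=float)
    weights /= weights.sum()
    for L in lengths:
        for _ in range(max_tries):
            chrom = names[rng.choice(len(names), p=weights)]
            lo, hi = margin, sizes[chrom] - margin - int(L)
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + int(L)
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            placements.append((chrom, start))
            break
        else:
            raise SimulationInfeasibleError(
                f"could not place an enhancer of length {L}"
            )
    return placements


def _plant(
    rng: np.random.Generator,
    chrom_arr: np.ndarray,
    start: int,
    end: int,
    motif_codes: np.ndarray,
    n_instances: int,
    taken: list[tuple[int, int]],
    guard: int,
    max_tries: int,
) -> list[int]:
    """Overwrite background bases with a motif at random non-colliding
    offsets inside [start, end); returns genomic start positions."""
    L = len(motif_codes)
    placed = []
    for _ in range(n_instances):
        for _ in range(max_tries):
            pos = int(rng.integers(start, end - L + 1))
            a, b = pos - guard, pos + L + guard
            if any(s < b and a < e for s, e in taken):
                continue
            chrom_arr[pos : pos + L] = motif_codes
            taken.append((pos, pos + L))
            placed.append(pos)
            break
        else:
            raise SimulationInfeasibleError(
                "motif density too high: placement failed after "
                f"{max_tries} tries in [{start},{end})"
            )
    return placed


def simulate_enhancers(
    config: SimulationConfig, genome: Mapping[str, str]
) -> SyntheticCatalog:
    """Draw breadths, place enhancers, couple length/GC to breadth, plant
    motifs, and record the truth table.

    GC-breadth coupling is realized by resampling each enhancer's bases at
    GC = background + slope * breadth *before* motif planting, so
    compositional and motif effects stay separable. Planting replaces bases
    in place (no indels); instances are kept ``plant_guard`` bp apart so
    repeat-motif instances cannot chain into longer repeats with extra
    matching windows.
    """
    rng = np.random.default_rng([_STREAM_ENHANCERS, config.seed])
    arrs = {
        c: np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        for c, seq in genome.items()
    }
    sizes = {c: len(a) for c, a in arrs.items()}

    bvals = np.array(sorted(config.breadth_distribution))
    probs = np.array([config.breadth_distribution[b] for b in bvals], dtype=float)
    probs = probs / probs.sum()
    breadths = rng.choice(bvals, size=config.n_enhancers, p=probs)

    min_motif = max(
        (len(m.sequence) for m in config.planted_motifs), default=1
    )
    lengths = (
        config.base_length
        + config.length_breadth_slope * breadths
        + rng.normal(0, config.length_noise_sd, size=config.n_enhancers)
    )
    lengths = np.maximum(lengths, max(config.min_length, min_motif)).astype(int)

    placements = _place_nonoverlapping(
        rng, lengths, sizes, config.edge_margin
    )

    enhancers: list[EnhancerRecord] = []
    truth_rows: list[dict] = []
    motif_codes = {
        m.name: np.frombuffer(m.sequence.encode("ascii"), dtype=np.uint8)
        for m in config.planted_motifs
    }
    for i, ((chrom, start), L, breadth) in enumerate(
        zip(placements, lengths, breadths)
    ):
        end = start + int(L)
        rid = f"enh_{i:05d}"
        enhancers.append(
            EnhancerRecord(GenomicRegion(chrom, start, end, id=rid), int(breadth))
        )
        cls = breadth_class(int(breadth), config)
        gc_here = float(
            np.clip(
                config.background_gc + config.gc_breadth_slope * breadth,
                0.01,
                0.99,
            )
        )
        arrs[chrom][start:end] = _random_bases(rng, end - start, gc_here)
        taken: list[tuple[int, int]] = []
        for m in config.planted_motifs:
            density = m.densities.get(cls, 0.0)
            n_inst = int(rng.poisson(density * (end - start)))
            if n_inst == 0:
                continue
            positions = _plant(
                rng,
                arrs[chrom],
                start,
                end,
                motif_codes[m.name],
                n_inst,
                taken,
                config.plant_guard,
                config.max_plant_tries,
            )
            for pos in positions:
                truth_rows.append(
                    {
                        "enhancer_id": rid,
                        "chrom": chrom,
                        "start": pos,
                        "end": pos + len(m.sequence),
                        "motif": m.name,
                        "breadth_class": cls,
                    }
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=["enhancer_id", "chrom", "start", "end", "motif", "breadth_class"],
    )
    out_genome = {c: a.tobytes().decode("ascii") for c, a in arrs.items()}
    return SyntheticCatalog(
        genome=out_genome, enhancers=enhancers, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# TF table


def _tf_motif(
    rng: np.random.Generator, target_gc: float, length: int, conc: float
) -> PWM:
    at = (1 - target_gc) / 2
    alpha = conc * np.array([at, target_gc / 2, target_gc / 2, at])
    probs = rng.dirichlet(alpha, size=length)
    return PWM("tf_motif", probs)


def simulate_tf_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, PWM]]:
    """TF table (tf_name, tsps, breadth_class, motif_ids) plus PWMs.

    Broadly expressed TFs (TSPS < 1, drawn U(0,1)) receive motifs whose
    target GC is Normal(base + association/2, sd); specific TFs (TSPS in
    [1, 5]) get Normal(base - association/2, sd). Setting the association
    to zero gives the null configuration.
    """
    if config.n_tfs < 2:
        raise ValueError("n_tfs must be >= 2")
    rng = np.random.default_rng([_STREAM_TF, config.seed])
    n_broad = int(round(config.n_tfs * config.tf_broad_frac))
    n_broad = min(max(n_broad, 1), config.n_tfs - 1)
    rows = []
    motifs: dict[str, PWM] = {}
    lo, hi = config.tf_motif_len_range
    for i in range(config.n_tfs):
        is_broad = i < n_broad
        tsps = float(rng.uniform(0, 1) if is_broad else rng.uniform(1, 5))
        shift = config.tsps_gc_association / 2
        mean_gc = config.tf_motif_gc_base + (shift if is_broad else -shift)
        n_motifs = 1 + int(rng.poisson(max(config.tf_motifs_per_tf_mean - 1, 0)))
        ids = []
        for j in range(n_motifs):
            target = float(np.clip(rng.normal(mean_gc, config.tf_motif_gc_sd), 0.05, 0.95))
            L = int(rng.integers(lo, hi + 1))
            mid = f"TF{i:04d}_m{j}"
            pwm = _tf_motif(rng, target, L, config.tf_dirichlet_concentration)
            motifs[mid] = PWM(mid, pwm.probs)
            ids.append(mid)
        rows.append(
            {
                "tf_name": f"TF{i:04d}",
                "tsps": tsps,
                "breadth_class": "broad" if tsps < 1 else "specific",
                "motif_ids": ",".join(ids),
            }
        )
    return pd.DataFrame(rows), motifs


def simulate_catalog(config: SimulationConfig) -> SyntheticCatalog:
    """Genome + enhancers + TF table in one call."""
    genome = simulate_genome(config)
    catalog = simulate_enhancers(config, genome)
    catalog.tf_table, catalog.tf_motifs = simulate_tf_table(config)
    return catalog


# ---------------------------------------------------------------------------
# small free-standing generators used by analyses and tests


def random_regions(
    genome: Mapping[str, str],
    n: int,
    length: int,
    seed: int,
    margin: int = 0,
    prefix: str = "reg",
) -> list[GenomicRegion]:
    """n non-overlapping uniformly placed fixed-length regions."""
    rng = np.random.default_rng(seed)
    sizes = {c: len(s) for c, s in genome.items()}
    placements = _place_nonoverlapping(
        rng, np.full(n, length), sizes, margin
    )
    return [
        GenomicRegion(c, s, s + length, id=f"{prefix}_{i:05d}")
        for i, (c, s) in enumerate(placements)
    ]


def gc_shifted_regions(
    genome: Mapping[str, str],
    n: int,
    length: int,
    gc: float,
    seed: int,
    margin: int = 10,
    prefix: str = "pos",
) -> tuple[dict[str, str], list[GenomicRegion]]:
    """Place n fixed-length regions and resample their bases at the given
    GC fraction (a compositional class signal with no planted motifs).

    Returns the modified genome and the regions.
    """
    regions = random_regions(genome, n, length, seed, margin, prefix)
    rng = np.random.default_rng([3, seed])
    arrs = {
        c: np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
        for c, s in genome.items()
    }
    for r in regions:
        arrs[r.chrom][r.start : r.end] = _random_bases(rng, r.length, gc)
    return {c: a.tobytes().decode("ascii") for c, a in arrs.items()}, regions


def plant_in_regions(
    genome: Mapping[str, str],
    regions: Sequence[GenomicRegion],
    motif: str,
    density: float,
    seed: int,
    guard: int = 2,
    max_tries: int = 1000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant a motif at a per-bp density into existing regions.

    Returns the modified genome and a truth table of planted positions.
    Used to build controlled enrichment experiments outside the full
    catalog machinery.
    """
    rng = np.random.default_rng(seed)
    arrs = {
        c: np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
        for c, s in genome.items()
    }
    codes = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    rows = []
    for r in regions:
        n_inst = int(rng.poisson(density * r.length))
        if n_inst == 0:
            continue
        taken: list[tuple[int, int]] = []
        for pos in _plant(
            rng, arrs[r.chrom], r.start, r.end, codes, n_inst, taken, guard, max_tries
        ):
            rows.append(
                {"region_id": r.id, "chrom": r.chrom, "start": pos, "end": pos + len(motif)}
            )
    out = {c: a.tobytes().decode("ascii") for c, a in arrs.items()}
    return out, pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def simulate_semipartial_data(
    n: int,
    sr2: float,
    seed: int,
    r2_shared: float = 0.3,
    gc_cpg_r: float = 0.5,
) -> pd.DataFrame:
    """(gc, cpg, response) with a known population semipartial R^2.

    The response loads on standardized GC with variance share ``r2_shared``
    and on the GC-orthogonal component of CpG with share ``sr2``; the
    remainder is noise. CpG itself correlates with GC at ``gc_cpg_r``.
    """
    if not 0 <= sr2 < 1 or r2_shared + sr2 >= 1:
        raise ValueError("variance shares must be in [0,1) and sum below 1")
    rng = np.random.default_rng(seed)
    gc = rng.normal(size=n)
    z = rng.normal(size=n)  # GC-orthogonal CpG component
    cpg = gc_cpg_r * gc + np.sqrt(1 - gc_cpg_r**2) * z
    noise = rng.normal(size=n)
    response = (
        np.sqrt(r2_shared) * gc
        + np.sqrt(sr2) * z
        + np.sqrt(1 - r2_shared - sr2) * noise
    )
    return pd.DataFrame({"gc": gc, "cpg": cpg, "response": response})


# ---------------------------------------------------------------------------
# on-disk form: FASTA + BED + TSV + JASPAR PFM + JSON


def write_catalog(catalog: SyntheticCatalog, outdir) -> None:
    from pathlib import Path

    from .regions import write_enhancer_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for name, seq in catalog.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_enhancer_bed(catalog.enhancers, outdir / "enhancers.bed")
    catalog.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if catalog.tf_table is not None:
        catalog.tf_table.to_csv(outdir / "tf_table.tsv", sep="\t", index=False)
    if catalog.tf_motifs is not None:
        with open(outdir / "tf_motifs.pfm", "w") as fh:
            for name, pwm in catalog.tf_motifs.items():
                fh.write(f">{name}\t{name}\n")
                counts = np.round(pwm.probs * 1000).astype(int)
                for bi, base in enumerate(ALPHABET):
                    row = " ".join(str(c) for c in counts[:, bi])
                    fh.write(f"{base}  [ {row} ]\n")
    if catalog.config is not None:
        cfg = asdict(catalog.config)
        cfg["breadth_distribution"] = {
            str(k): v for k, v in catalog.config.breadth_distribution.items()
        }
        cfg["planted_motifs"] = [
            {"name": m.name, "sequence": m.sequence, "densities": dict(m.densities)}
            for m in catalog.config.planted_motifs
        ]
        with open(outdir / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1)
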