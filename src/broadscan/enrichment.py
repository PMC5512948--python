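"""Fold-enrichment statistics over enhancer classes and replicate negatives.

Fold enrichment (FE) of a motif is the ratio of its mean per-region count
in the positive set to that in a negative set; depletion is displayed as a
signed fold -1/FE. Significance comes from the two-sided Wilcoxon rank-sum
test on the two count distributions: exact enumeration when the smaller
sample has at most 8 observations, the tie- and continuity-corrected
normal approximation otherwise. Replicate analyses compute log2(FE)
against several independent negative sets and report their mean and spread.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import EnhancerRecord, GenomicRegion, fetch, gc_content
from .spectrum_classifier import enumerate_kmers, kmer_matrix

__all__ = [
    "EnrichmentResult",
    "fold_enrichment",
    "rank_sum_p",
    "replicate_enrichment",
    "all_kmer_enrichment",
    "density_breadth_correlation",
    "gc_breadth_correlation",
]

EXACT_MAX_N = 8


@dataclass
class EnrichmentResult:
    """FE of one motif; NaN fields mean the quantity was undefined
    (e.g. a zero mean in the negatives)."""

    motif: str
    fe: float
    log2_fe: float
    signed_fold: float
    p_value: float
    replicate_log2_fe: list[float] | None = None
    spread: float | None = None  # SD over replicates
    spread_se: float | None = None  # SE over replicates


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum P.

    Exact when min(len) <= EXACT_MAX_N: the null distribution of the
    rank-sum of the smaller sample is enumerated over all assignments of
    the pooled mid-ranks (valid with ties). Otherwise the normal
    approximation with tie and continuity correction (Mann-Whitney form).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if min(len(x), len(y)) <= EXACT_MAX_N:
        swap = len(y) < len(x)
        a, b = (y, x) if swap else (x, y)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        observed = ranks[: len(a)].sum()
        mean_null = len(a) * (len(pooled) + 1) / 2
        dev = abs(observed - mean_null)
        count = 0
        total = 0
        for idx in combinations(range(len(pooled)), len(a)):
            total += 1
            if abs(ranks[list(idx)].sum() - mean_null) >= dev - 1e-9:
                count += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _fe_fields(pos_mean: float, neg_mean: float) -> tuple[float, float, float]:
    if neg_mean == 0 and pos_mean == 0:
        return math.nan, math.nan, math.nan
    if neg_mean == 0:
        return math.inf, math.inf, math.inf
    if pos_mean == 0:
        return 0.0, -math.inf, -math.inf
    fe = pos_mean / neg_mean
    return fe, math.log2(fe), fe if fe >= 1 else -1 / fe


def fold_enrichment(
    pos_counts: Sequence[float],
    neg_counts: Sequence[float],
    motif: str = "",
    pseudocount: float = 0.0,
) -> EnrichmentResult:
    """FE = mean(pos) / mean(neg) with a rank-sum P on the distributions.

    ``pseudocount`` is added to both means before the ratio for small runs
    where a zero negative mean is plausible; by default nothing is added
    and degenerate means yield NaN/inf sentinels.
    """
    pos = np.asarray(pos_counts, dtype=float)
    neg = np.asarray(neg_counts, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both count vectors must be nonempty")
    fe, log2_fe, signed = _fe_fields(
        pos.mean() + pseudocount, neg.mean() + pseudocount
    )
    pooled = np.concatenate([pos, neg])
    p = 1.0 if np.ptp(pooled) == 0 else rank_sum_p(pos, neg)
    return EnrichmentResult(motif, fe, log2_fe, signed, p)


def replicate_enrichment(
    pos_counts: Sequence[float],
    neg_count_sets: Sequence[Sequence[float]],
    motif: str = "",
    pseudocount: float = 0.0,
) -> EnrichmentResult:
    """FE against several independent negative sets: per-replicate
    log2(FE), their mean, SD, and SE, and the rank-sum P against the
    pooled negatives."""
    if len(neg_count_sets) < 2:
        raise ValueError("need at least 2 replicate negative sets")
    reps = [
        fold_enrichment(pos_counts, neg, motif, pseudocount)
        for neg in neg_count_sets
    ]
    log2_vals = np.array([r.log2_fe for r in reps])
    if not np.isfinite(log2_vals).all():
        warnings.warn(
            f"undefined enrichment in a replicate for {motif!r}", stacklevel=2
        )
        mean_log2 = math.nan
        sd = math.nan
        se = math.nan
    else:
        mean_log2 = float(log2_vals.mean())
        sd = float(log2_vals.std(ddof=1))
        se = sd / math.sqrt(len(log2_vals))
    fe = 2**mean_log2 if np.isfinite(mean_log2) else math.nan
    signed = (fe if fe >= 1 else -1 / fe) if np.isfinite(fe) else math.nan
    pooled = np.concatenate([np.asarray(n, dtype=float) for n in neg_count_sets])
    everything = np.concatenate([np.asarray(pos_counts, dtype=float), pooled])
    p = 1.0 if np.ptp(everything) == 0 else rank_sum_p(pos_counts, pooled)
    return EnrichmentResult(
        motif,
        fe,
        mean_log2,
        signed,
        p,
        replicate_log2_fe=[float(v) for v in log2_vals],
        spread=sd,
        spread_se=se,
    )


def all_kmer_enrichment(
    pos_regions: Sequence[GenomicRegion],
    neg_regions: Sequence[GenomicRegion],
    genome: Mapping[str, str],
    k: int = 6,
    with_p_values: bool = False,
) -> pd.DataFrame:
    """log2(FE) of every k-mer between two region sets (sliding-window
    counts on the forward strand, matching the classifier features).

    Returns a frame indexed by k-mer with columns fe, log2_fe, gc,
    beyond_1sd, beyond_2sd (flags relative to the finite log2 FE
    distribution over all k-mers) and, optionally, a rank-sum p per k-mer.
    """
    kmers, gc = enumerate_kmers(k)
    pos = kmer_matrix([fetch(genome, r) for r in pos_regions], k)
    neg = kmer_matrix([fetch(genome, r) for r in neg_regions], k)
    pos_mean = pos.mean(axis=0)
    neg_mean = neg.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = pos_mean / neg_mean
        log2_fe = np.log2(fe)
    finite = np.isfinite(log2_fe)
    mu = log2_fe[finite].mean()
    sd = log2_fe[finite].std(ddof=1)
    df = pd.DataFrame(
        {
            "kmer": kmers,
            "fe": fe,
            "log2_fe": log2_fe,
            "gc": gc,
            "beyond_1sd": np.abs(log2_fe - mu) > sd,
            "beyond_2sd": np.abs(log2_fe - mu) > 2 * sd,
        }
    ).set_index("kmer")
    if with_p_values:
        res = stats.mannwhitneyu(
            pos, neg, alternative="two-sided", method="asymptotic", axis=0
        )
        df["p_value"] = res.pvalue
    return df


def density_breadth_correlation(
    densities: Sequence[float], breadths: Sequence[int]
) -> tuple[float, float]:
    """Spearman rank correlation of per-enhancer motif density vs breadth."""
    breadths = np.asarray(breadths)
    densities = np.asarray(densities, dtype=float)
    if len(np.unique(breadths)) < 3:
        raise ValueError("need >= 3 distinct breadth values")
    if np.ptp(densities) == 0:
        return math.nan, math.nan
    rho, p = stats.spearmanr(densities, breadths)
    return float(rho), float(p)


def gc_breadth_correlation(
    catalog: Sequence[EnhancerRecord],
    genome: Mapping[str, str],
    bin_edges: Sequence[int] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation of per-enhancer GC content vs breadth, plus a
    breadth-binned report (each bin labeled by the highest activity it
    contains, with its mean GC and size). Default edges aim for near-equal
    occupancy across six bins."""
    gcs = np.array([gc_content(fetch(genome, rec.region)) for rec in catalog])
    breadths = np.array([rec.breadth for rec in catalog])
    rho, p = density_breadth_correlation(gcs, breadths)
    if bin_edges is None:
        qs = np.quantile(breadths, np.linspace(0, 1, 7))
        bin_edges = np.unique(np.round(qs).astype(int))
        bin_edges[-1] = breadths.max()
    rows = []
    lo = int(np.min(breadths))
    for hi in bin_edges[1:]:
        mask = (breadths >= lo) & (breadths <= hi)
        if mask.sum() == 0:
            continue
        rows.append(
            {
                "max_breadth": int(breadths[mask].max()),
                "n": int(mask.sum()),
                "mean_gc": float(gcs[mask].mean()),
            }
        )
        lo = int(hi) + 1
    return float(rho), float(p), pd.DataFrame(rows)
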