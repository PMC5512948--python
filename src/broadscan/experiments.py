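"""Reusable study drivers: the controlled experiments the analyses run.

Each function sets up a synthetic experiment with known planted structure,
runs the relevant pipeline stage, and returns the measured quantities.
The numbered scripts under ``analysis/`` and the acceptance harness are
thin wrappers over these.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import all_kmer_enrichment, fold_enrichment, replicate_enrichment
from .motif_scan import (
    DRM_REPEATS,
    NoThresholdError,
    ScanParams,
    count_hits,
    drm_pwm,
    exact_tail_probability,
    log_odds,
    score_distribution,
    score_threshold,
)
from .regions import NegativeSetSpec, sample_gc_matched, shuffle_length_matched
from .spectrum_classifier import (
    FeatureMatrix,
    cross_validate,
    enrichment_gc_correlation,
    extract_weights,
    features_kmer,
    features_motif_density,
    train_linear,
    weight_gc_correlation,
)
from .synthetic_data import (
    SimulationConfig,
    gc_shifted_regions,
    plant_in_regions,
    random_regions,
    simulate_genome,
    simulate_semipartial_data,
    simulate_tf_table,
)
from .tf_expression import (
    compose,
    compare_composition,
    load_tf_table,
    semipartial_cpg_given_gc,
)

__all__ = [
    "drm_calibration_summary",
    "enrichment_recovery",
    "background_genome",
    "classifier_ordering",
    "weight_gc_experiment",
    "tf_composition_experiment",
    "semipartial_recovery",
]

# the exact-match regime for the GC repeat: at 1/4096 only the perfect word
# clears the cutoff, so planted-copy counts are not inflated by the halo of
# one-mismatch windows flanking each planted instance
EXACT_GC_ALPHA = 1 / 4096


def drm_calibration_summary() -> dict:
    """Threshold behavior of the four DRM PWMs on the 42% GC background.

    Reports the tail probability of each perfect repeat word and how many
    of the four pass at the 1/1024 and 1/4096 match cutoffs.
    """
    out: dict = {}
    for alpha, tag in ((1 / 1024, "1_in_1024"), (1 / 4096, "1_in_4096")):
        params = ScanParams(alpha=alpha)
        passing = 0
        for repeat in DRM_REPEATS:
            pwm = drm_pwm(repeat)
            M = log_odds(pwm, params)
            perfect = float(M.max(axis=1).sum())
            tail = exact_tail_probability(pwm, params, perfect)
            out[f"{repeat.lower()}_perfect_tail_p"] = tail
            try:
                passing += perfect >= score_threshold(pwm, params)
            except NoThresholdError:
                pass
        out[f"n_drm_words_passing_{tag}"] = passing
    return out


def enrichment_recovery(
    seed: int,
    ratios: Sequence[int] = (2, 4, 8),
    n_seeds: int = 20,
    n_regions: int = 200,
    region_len: int = 600,
    base_density: float = 0.004,
) -> pd.DataFrame:
    """Plant the GC repeat at density ratio r between positives and
    negatives and recover log2(FE) by scanning.

    One genome, positive set, and negative set per replicate seed; counts
    use the exact-match cutoff. Returns per-ratio mean/SD of log2(FE) over
    replicates next to the planted log2 r.
    """
    params = ScanParams(alpha=EXACT_GC_ALPHA)
    pwm = drm_pwm("GC")
    rows = []
    for r_true in ratios:
        vals = []
        for rep in range(n_seeds):
            s = seed + 1000 * rep
            cfg = SimulationConfig(
                seed=s, n_chromosomes=1, chrom_length=600_000,
                n_enhancers=0, planted_motifs=(),
            )
            genome = simulate_genome(cfg)
            regs = random_regions(genome, 2 * n_regions, region_len, seed=s)
            pos, neg = regs[:n_regions], regs[n_regions:]
            genome, _ = plant_in_regions(
                genome, pos, "GCGCGC", base_density * r_true, seed=s * 7 + 1
            )
            genome, _ = plant_in_regions(
                genome, neg, "GCGCGC", base_density, seed=s * 7 + 2
            )
            res = fold_enrichment(
                count_hits(pos, genome, pwm, params),
                count_hits(neg, genome, pwm, params),
                motif="GC_DRM",
            )
            vals.append(res.log2_fe)
        vals = np.asarray(vals)
        rows.append(
            {
                "ratio": r_true,
                "log2_ratio": np.log2(r_true),
                "mean_log2_fe": vals.mean(),
                "sd_log2_fe": vals.std(ddof=1),
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(rows)


def background_genome(seed: int, n_chromosomes: int = 4, chrom_length: int = 2_000_000):
    cfg = SimulationConfig(
        seed=seed, n_chromosomes=n_chromosomes, chrom_length=chrom_length,
        n_enhancers=0, planted_motifs=(),
    )
    return simulate_genome(cfg)


def classifier_ordering(
    seed: int,
    genome: Mapping[str, str] | None = None,
    n_per_class: int = 1000,
    region_len: int = 600,
    pos_gc: float = 0.46,
    folds: int = 10,
) -> dict:
    """The classifier comparison on a catalog whose positives differ only
    in GC composition (46% vs the 42% background).

    Measures ROC AUCs for: the 6-mer spectrum vs length-matched negatives,
    DRM densities vs length-matched negatives, DRM densities vs GC-matched
    negatives, and the 6-mer features with permuted labels (null).
    """
    if genome is None:
        genome = background_genome(seed)
    genome, pos = gc_shifted_regions(
        genome, n_per_class, region_len, pos_gc, seed=seed + 1
    )
    neg = shuffle_length_matched(pos, genome, exclusions=pos, seed=seed + 2)
    spec = NegativeSetSpec(mode="gc", exclusions=list(pos), seed=seed + 3)
    neg_gc = sample_gc_matched(pos, genome, spec)
    pos_gc_set = pos[: len(neg_gc)]  # in case of rare per-region failures

    params = ScanParams()
    drms = [drm_pwm(r) for r in DRM_REPEATS]
    fm_kmer = features_kmer(pos, neg, genome, k=6)
    fm_drm = features_motif_density(pos, neg, genome, drms, params)
    fm_drm_gc = features_motif_density(pos_gc_set, neg_gc, genome, drms, params)

    cv_kmer = cross_validate(fm_kmer, folds=folds, seed=seed + 4)
    cv_drm = cross_validate(fm_drm, folds=folds, seed=seed + 4)
    cv_drm_gc = cross_validate(fm_drm_gc, folds=folds, seed=seed + 4)

    rng = np.random.default_rng(seed + 5)
    fm_null = FeatureMatrix(
        fm_kmer.region_ids,
        fm_kmer.feature_names,
        fm_kmer.X,
        rng.permutation(fm_kmer.y),
    )
    cv_null = cross_validate(fm_null, folds=folds, seed=seed + 4)
    return {
        "kmer_auc": cv_kmer.mean_roc_auc,
        "kmer_pr_auc": cv_kmer.mean_pr_auc,
        "drm_auc": cv_drm.mean_roc_auc,
        "drm_gc_matched_auc": cv_drm_gc.mean_roc_auc,
        "null_auc": cv_null.mean_roc_auc,
        "n_per_class": n_per_class,
        "cv_results": {
            "kmer": cv_kmer,
            "drm": cv_drm,
            "drm_gc_matched": cv_drm_gc,
            "null": cv_null,
        },
    }


def weight_gc_experiment(
    seed: int,
    genome: Mapping[str, str] | None = None,
    n_per_class: int = 400,
    region_len: int = 600,
    pos_gc: float = 0.46,
    n_null_seeds: int = 10,
    n_replicate_negatives: int = 2,
) -> dict:
    """Spearman correlation between learned 6-mer weights and k-mer GC.

    Signal arm: GC-shifted positives vs length-matched negatives, weights
    averaged over replicate negative sets — the correlation should be
    strongly positive. Null arm: background positives vs GC-matched
    negatives with no planted signal, repeated over seeds — the
    correlation should vanish. Also reports the enrichment-based
    correlation on the signal arm.
    """
    if genome is None:
        genome = background_genome(seed)
    genome_sig, pos = gc_shifted_regions(
        genome, n_per_class, region_len, pos_gc, seed=seed + 11
    )
    weight_runs = []
    feature_names: list[str] = []
    for rep in range(n_replicate_negatives):
        neg = shuffle_length_matched(
            pos, genome_sig, exclusions=pos, seed=seed + 12 + rep
        )
        fm = features_kmer(pos, neg, genome_sig, k=6)
        feature_names = fm.feature_names
        w, _ = train_linear(fm.X, fm.y, seed=seed + rep)
        weight_runs.append(w)
    table = extract_weights(weight_runs, feature_names)
    rho_signal, _ = weight_gc_correlation(table)
    neg0 = shuffle_length_matched(pos, genome_sig, exclusions=pos, seed=seed + 12)
    kmer_fe = all_kmer_enrichment(pos, neg0, genome_sig, k=6)
    rho_fe, _ = enrichment_gc_correlation(kmer_fe)

    null_rhos = []
    for rep in range(n_null_seeds):
        s = seed + 100 * (rep + 1)
        pos_n = random_regions(genome, n_per_class, region_len, seed=s, prefix="np")
        spec = NegativeSetSpec(mode="gc", exclusions=list(pos_n), seed=s + 1)
        neg_n = sample_gc_matched(pos_n, genome, spec)
        fm = features_kmer(pos_n[: len(neg_n)], neg_n, genome, k=6)
        w, _ = train_linear(fm.X, fm.y, seed=s)
        t = extract_weights([w], fm.feature_names)
        null_rhos.append(weight_gc_correlation(t)[0])
    return {
        "weight_gc_rho_signal": rho_signal,
        "enrichment_gc_rho_signal": rho_fe,
        "weight_gc_rho_null": null_rhos,
        "n_per_class": n_per_class,
    }


def tf_composition_experiment(seed: int, n_tfs: int = 563) -> dict:
    """Simulate the TF table at the configured GC/TSPS association and
    compare motif composition between broad and specific TFs, plus the
    semipartial contribution of CpG beyond GC for both response codings."""
    cfg = SimulationConfig(seed=seed, n_tfs=n_tfs)
    table, motifs = simulate_tf_table(cfg)
    records = load_tf_table(table, motifs)
    res = compare_composition(records)
    df = compose(records)
    sr2_tsps, p_tsps = semipartial_cpg_given_gc(df.mean_gc, df.mean_cpg, df.tsps)
    dummy = (df.breadth_class == "broad").astype(float)
    sr2_dummy, p_dummy = semipartial_cpg_given_gc(df.mean_gc, df.mean_cpg, dummy)
    res.update(
        {
            "sr2_tsps": sr2_tsps,
            "sr2_tsps_p": p_tsps,
            "sr2_dummy": sr2_dummy,
            "sr2_dummy_p": p_dummy,
        }
    )
    return res


def semipartial_recovery(
    seed: int, n: int = 500, n_seeds: int = 50, sr2_true: float = 0.1
) -> dict:
    """Recover a planted semipartial R^2 from simulated (GC, CpG, response)
    triples; also the exact-collinear degenerate case."""
    vals = []
    for rep in range(n_seeds):
        df = simulate_semipartial_data(n, sr2=sr2_true, seed=seed + rep)
        vals.append(semipartial_cpg_given_gc(df.gc, df.cpg, df.response)[0])
    vals = np.asarray(vals)
    rng = np.random.default_rng(seed)
    gc = rng.normal(size=n)
    degenerate, _ = semipartial_cpg_given_gc(gc, 3 * gc - 1, rng.normal(size=n))
    return {
        "sr2_true": sr2_true,
        "sr2_mean": float(vals.mean()),
        "sr2_sd": float(vals.std(ddof=1)),
        "sr2_degenerate_collinear": float(degenerate),
        "n": n,
        "n_seeds": n_seeds,
    }
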