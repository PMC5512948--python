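"""PWM scoring, exact tail probabilities, threshold calibration, scanning."""

import itertools

import numpy as np
import pytest

from broadscan.motif_scan import (
    DRM_REPEATS,
    NoThresholdError,
    PWM,
    ScanParams,
    background_from_gc,
    count_per_bp,
    drm_pwm,
    exact_tail_probability,
    log_odds,
    read_jaspar_pfms,
    read_meme_motifs,
    scan,
    score_distribution,
    score_threshold,
)
from broadscan.regions import GenomicRegion

from conftest import random_pwm


def brute_force_tail(pwm: PWM, params: ScanParams, s: float) -> float:
    """Enumeration oracle: sum background probabilities of all 4^L words
    scoring >= s."""
    M = log_odds(pwm, params)
    bg = params.background
    total = 0.0
    for word in itertools.product(range(4), repeat=len(pwm)):
        score = 0.0
        prob = 1.0
        for i, b in enumerate(word):
            score += M[i, b]
            prob *= bg[b]
        if score >= s:
            total += prob
    return total


def naive_scan_offsets(seq: str, pwm: PWM, params: ScanParams) -> list:
    """Sliding-window rescoring oracle, independent of the vectorized path."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    M = log_odds(pwm, params)
    thr = score_threshold(pwm, params) - 1e-9  # same boundary rule as scan()
    L = len(pwm)
    idx = {b: i for i, b in enumerate("ACGT")}
    out = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L].upper()
        if any(b not in idx for b in window):
            continue
        fwd = sum(M[i, idx[b]] for i, b in enumerate(window))
        if fwd >= thr:
            out.append((off, "+"))
        if params.both_strands:
            rc = "".join(comp[b] for b in reversed(window))
            rev = sum(M[i, idx[b]] for i, b in enumerate(rc))
            if rev >= thr:
                out.append((off, "-"))
    return sorted(out)


class TestDrmPwm:
    @pytest.mark.parametrize("repeat", DRM_REPEATS)
    def test_consensus_is_triple_repeat(self, repeat):
        pwm = drm_pwm(repeat)
        assert len(pwm) == 6
        assert pwm.consensus == repeat * 3
        # probability-one columns
        assert np.all(pwm.probs.max(axis=1) == 1.0)

    def test_gc_and_ta_are_palindromic(self):
        for repeat in ("GC", "TA"):
            pwm = drm_pwm(repeat)
            assert pwm.reverse_complement().consensus == pwm.consensus

    def test_unsupported_repeat(self):
        with pytest.raises(ValueError, match="unsupported"):
            drm_pwm("AG")


class TestLogOdds:
    def test_background_pwm_scores_zero(self, default_params):
        bg = default_params.background
        pwm = PWM("bg", np.tile(bg, (5, 1)))
        assert np.allclose(log_odds(pwm, default_params), 0.0)

    def test_gc_column_value(self, default_params):
        # probability-1 column over background 0.21 with pseudocount 0.001
        M = log_odds(drm_pwm("GC"), default_params)
        expected = np.log2((1 + 0.001 * 0.21) / (1.001 * 0.21))
        assert M[0, 2] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(2.25, abs=5e-3)

    def test_monotone_in_probability(self, default_params):
        scores = []
        for p in (0.2, 0.5, 0.9):
            probs = np.array([[p, 1 - p, 0, 0]] * 3)
            scores.append(log_odds(PWM("m", probs), default_params)[0, 0])
        assert scores == sorted(scores)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ScanParams(background=np.array([0.5, 0.5, 0.0, 0.0]))


class TestExactTail:
    @pytest.mark.parametrize("repeat", DRM_REPEATS)
    def test_matches_enumeration_for_drms(self, repeat, default_params):
        pwm = drm_pwm(repeat)
        scores, _ = score_distribution(pwm, default_params)
        probe = np.concatenate([scores[:: max(len(scores) // 8, 1)], [scores[-1]]])
        for s in probe:
            assert exact_tail_probability(pwm, default_params, s) == pytest.approx(
                brute_force_tail(pwm, default_params, s), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_for_random_pwms(self, seed, default_params):
        rng = np.random.default_rng(seed)
        pwm = PWM(f"rand{seed}", random_pwm(rng, int(rng.integers(4, 8))))
        scores, _ = score_distribution(pwm, default_params)
        for s in scores[:: max(len(scores) // 6, 1)]:
            assert exact_tail_probability(pwm, default_params, s) == pytest.approx(
                brute_force_tail(pwm, default_params, s), abs=1e-12
            )

    def test_normalization_limits(self, default_params):
        pwm = drm_pwm("CA")
        assert exact_tail_probability(pwm, default_params, -np.inf) == 1.0
        scores, _ = score_distribution(pwm, default_params)
        assert exact_tail_probability(pwm, default_params, scores[-1] + 1e-6) == 0.0


class TestThresholdCalibration:
    """42% GC background: A=T=0.29, C=G=0.21."""

    def test_perfect_tatata_fails_1_in_4096(self):
        ta = drm_pwm("TA")
        params = ScanParams(alpha=1 / 4096)
        # the best achievable word is TATATA with tail probability 0.29^6
        scores, _ = score_distribution(ta, params)
        assert exact_tail_probability(ta, params, scores[-1]) == pytest.approx(
            0.29**6, abs=1e-12
        )
        assert 0.29**6 >= 1 / 4096  # hence nothing passes
        with pytest.raises(NoThresholdError):
            score_threshold(ta, params)
        assert scan("TATATA" * 3, ta, params) == []

    def test_all_perfect_drm_words_pass_1_in_1024(self):
        params = ScanParams(alpha=1 / 1024)
        for repeat in DRM_REPEATS:
            pwm = drm_pwm(repeat)
            thr = score_threshold(pwm, params)
            M = log_odds(pwm, params)
            perfect = M.max(axis=1).sum()
            assert perfect >= thr, f"perfect {repeat} word must pass"

    def test_alpha_one_returns_min_score(self, default_params):
        pwm = drm_pwm("GA")
        params = ScanParams(alpha=1.0)
        scores, _ = score_distribution(pwm, params)
        # P(score >= min) = 1 which is not < 1, so the threshold is the
        # smallest score whose tail drops below 1
        thr = score_threshold(pwm, params)
        assert thr == pytest.approx(scores[1])

    def test_threshold_tail_is_below_alpha(self, default_params):
        for repeat in DRM_REPEATS:
            pwm = drm_pwm(repeat)
            thr = score_threshold(pwm, default_params)
            assert exact_tail_probability(pwm, default_params, thr) < (
                default_params.alpha
            )


class TestScan:
    def test_palindrome_counted_once_per_strand(self, default_params):
        assert len(scan("GCGCGC", drm_pwm("GC"), default_params)) == 2
        assert len(scan("CACACA", drm_pwm("CA"), default_params)) == 1

    def test_dedupe_flag_collapses_palindromic_hits(self):
        params = ScanParams(dedupe_palindromes=True)
        assert len(scan("GCGCGC", drm_pwm("GC"), params)) == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_rescoring_oracle(self, seed, default_params):
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("ACGT"), p=[0.29, 0.21, 0.21, 0.29], size=1000))
        pwm = drm_pwm(DRM_REPEATS[seed % 4])
        params = ScanParams(alpha=1 / 64)  # loose cutoff: plenty of hits
        got = sorted((h.offset, h.strand) for h in scan(seq, pwm, params))
        assert got == naive_scan_offsets(seq, pwm, params)

    def test_revcomp_sequence_same_total_hits(self, default_params):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=2000)) + "GCGCGC" + "CACACA"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        for repeat in DRM_REPEATS:
            pwm = drm_pwm(repeat)
            assert len(scan(seq, pwm, default_params)) == len(
                scan(rc, pwm, default_params)
            )

    def test_lowering_alpha_never_adds_hits(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        pwm = drm_pwm("CA")
        counts = []
        for alpha in (1 / 16, 1 / 64, 1 / 256, 1 / 1024):
            try:
                counts.append(len(scan(seq, pwm, ScanParams(alpha=alpha))))
            except NoThresholdError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)

    def test_ambiguous_window_disqualified(self, default_params):
        assert scan("GCGNGC", drm_pwm("GC"), default_params) == []

    def test_sequence_shorter_than_motif(self, default_params):
        assert scan("GC", drm_pwm("GC"), default_params) == []

    def test_count_per_bp_arithmetic(self, default_params):
        genome = {"c": "A" * 100 + "GCGCGC" + "A" * 494}
        region = GenomicRegion("c", 0, 600, id="r")
        dens = count_per_bp([region], genome, drm_pwm("GC"), default_params)
        assert dens[0] == pytest.approx(2 / 600)  # palindrome: 2 hits
        empty = GenomicRegion("c", 300, 500, id="e")
        assert count_per_bp([empty], genome, drm_pwm("GC"), default_params)[0] == 0.0


class TestMotifIO:
    def test_jaspar_round_trip(self, tmp_path):
        path = tmp_path / "m.pfm"
        path.write_text(
            ">M001\ttest\n"
            "A  [ 10  0  0 ]\n"
            "C  [  0 10  0 ]\n"
            "G  [  0  0 10 ]\n"
            "T  [  0  0  0 ]\n"
        )
        pwms = read_jaspar_pfms(path)
        assert len(pwms) == 1
        assert pwms[0].consensus == "ACG"
        assert np.allclose(pwms[0].probs.sum(axis=1), 1.0)

    def test_meme_minimal(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
            "Background letter frequencies\nA 0.29 C 0.21 G 0.21 T 0.29\n\n"
            "MOTIF toy\nletter-probability matrix: alength= 4 w= 2 nsites= 10 E= 0\n"
            " 1.0 0.0 0.0 0.0\n 0.0 0.0 1.0 0.0\n"
        )
        pwms = read_meme_motifs(path)
        assert len(pwms) == 1 and pwms[0].consensus == "AG"
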