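"""Baseline, GC correction, MAPD, Viterbi decoding and score banding."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from poipanel import cnv, simulate
from poipanel.types import QpcrMeasurement, SVScoreSet


def make_panel(n: int, chrom: str = "1", start: int = 1000, spacing: int = 200):
    return pd.DataFrame(
        {
            "amplicon_id": [f"amp{i:03d}" for i in range(n)],
            "chrom": chrom,
            "start": [start + i * spacing for i in range(n)],
            "end": [start + i * spacing + 150 for i in range(n)],
            "gc_fraction": np.linspace(0.35, 0.65, n),
        }
    )


def series(values, panel):
    return pd.Series(np.asarray(values, dtype=float), index=panel["amplicon_id"].values)


class TestBaseline:
    def test_identical_controls_equal_normalized_profile(self):
        counts = pd.DataFrame({"c1": [100, 300, 600], "c2": [100, 300, 600]},
                              index=["a", "b", "c"])
        baseline, excluded = cnv.build_baseline(counts)
        np.testing.assert_allclose(baseline.values, [0.1, 0.3, 0.6])
        assert excluded == []

    def test_median_of_two_is_mean(self):
        counts = pd.DataFrame({"c1": [100, 900], "c2": [300, 700]}, index=["a", "b"])
        baseline, _ = cnv.build_baseline(counts)
        assert baseline["a"] == pytest.approx(0.2)

    def test_single_control_rejected(self):
        counts = pd.DataFrame({"c1": [100, 200]}, index=["a", "b"])
        with pytest.raises(ValueError):
            cnv.build_baseline(counts)

    def test_all_zero_amplicon_excluded_with_warning(self):
        counts = pd.DataFrame({"c1": [100, 0], "c2": [300, 0]}, index=["a", "b"])
        with pytest.warns(UserWarning):
            baseline, excluded = cnv.build_baseline(counts)
        assert excluded == ["b"]
        assert "b" not in baseline.index

    def test_simulated_controls_recover_truth_within_5pct(self):
        rng = np.random.default_rng(42)
        truth = rng.lognormal(0.0, 0.3, size=100)
        counts = pd.DataFrame(
            {f"c{i}": truth * rng.lognormal(0.0, 0.1, size=100) for i in range(20)},
            index=[f"amp{i}" for i in range(100)],
        )
        baseline, _ = cnv.build_baseline(counts)
        rel_err = np.abs(baseline.values / (truth / truth.sum()) - 1.0)
        # median-of-20 sampling noise: typical amplicon well inside 5%
        assert np.quantile(rel_err, 0.9) < 0.05
        assert np.median(rel_err) < 0.03


class TestGcCorrection:
    def test_sample_identical_to_baseline_gives_zero_ratios(self):
        panel = make_panel(40)
        baseline = pd.Series(1.0 / 40, index=panel["amplicon_id"].values)
        sample = pd.Series(500.0, index=panel["amplicon_id"].values)
        log2r = cnv.normalize_and_correct_gc(
            sample, baseline, panel.set_index("amplicon_id")["gc_fraction"]
        )
        np.testing.assert_allclose(log2r.values, 0.0, atol=1e-12)

    def test_imposed_linear_gc_bias_removed(self):
        rng = np.random.default_rng(5)
        panel = make_panel(300)
        gc = panel.set_index("amplicon_id")["gc_fraction"]
        baseline = pd.Series(1.0 / 300, index=panel["amplicon_id"].values)
        bias = 1.0 + 0.5 * (gc.values - 0.5)
        sample = pd.Series(500.0 * bias, index=panel["amplicon_id"].values)
        log2r = cnv.normalize_and_correct_gc(sample, baseline, gc)
        bins = np.floor(gc.values / 0.05)
        for b in np.unique(bins):
            assert abs(np.median(log2r.values[bins == b])) < 0.02

    def test_doubled_amplicon_has_log2_ratio_one(self):
        panel = make_panel(41)
        ids = panel["amplicon_id"].values
        baseline = pd.Series(1.0 / 41, index=ids)
        values = np.full(41, 500.0)
        values[0] = 1000.0
        log2r = cnv.normalize_and_correct_gc(
            pd.Series(values, index=ids),
            baseline,
            panel.set_index("amplicon_id")["gc_fraction"],
        )
        # total-count scaling and bin medians shift things slightly
        assert log2r.iloc[0] == pytest.approx(1.0, abs=0.1)
        assert abs(log2r.iloc[20]) < 0.1


class TestMapd:
    def test_constant_ratios_give_zero(self):
        panel = make_panel(10)
        noise = cnv.compute_mapd(series(np.zeros(10), panel), panel)
        assert noise.mapd == 0.0 and noise.eligible

    def test_alternating_ratios_give_one(self):
        panel = make_panel(10)
        noise = cnv.compute_mapd(series([0, 1] * 5, panel), panel)
        assert noise.mapd == 1.0 and not noise.eligible

    def test_fewer_than_two_amplicons_error(self):
        panel = make_panel(1)
        with pytest.raises(ValueError):
            cnv.compute_mapd(series([0.0], panel), panel)

    def test_shift_invariance_and_scaling(self):
        rng = np.random.default_rng(0)
        panel = make_panel(100)
        values = rng.normal(0, 0.2, 100)
        base = cnv.compute_mapd(series(values, panel), panel).mapd
        shifted = cnv.compute_mapd(series(values + 3.0, panel), panel).mapd
        scaled = cnv.compute_mapd(series(values * 2.0, panel), panel).mapd
        assert shifted == pytest.approx(base)
        assert scaled == pytest.approx(2.0 * base)

    def test_cross_chromosome_pairs_excluded(self):
        panel = make_panel(4)
        panel.loc[2:, "chrom"] = "2"
        # a huge jump between chromosomes must not enter the median
        noise = cnv.compute_mapd(series([0.0, 0.0, 10.0, 10.0], panel), panel)
        assert noise.mapd == 0.0

    def test_gaussian_closed_form(self):
        # for i.i.d. N(0, s) ratios, MAPD -> s * sqrt(2) * PHI^-1(0.75)
        rng = np.random.default_rng(123)
        panel = make_panel(2000)
        s = 0.2
        noise = cnv.compute_mapd(series(rng.normal(0, s, 2000), panel), panel)
        assert noise.mapd == pytest.approx(s * math.sqrt(2) * 0.67449, rel=0.05)


def brute_force_viterbi(obs, means, sigma, stay_prob):
    """Exhaustive most-likely-path search (oracle for small instances)."""
    n_states = len(means)
    log_stay = math.log(stay_prob)
    log_switch = math.log((1 - stay_prob) / (n_states - 1))

    def emit(x, k):
        return -0.5 * ((x - means[k]) / sigma) ** 2 - math.log(
            sigma * math.sqrt(2 * math.pi)
        )

    best_path, best_score = None, -math.inf
    for path in itertools.product(range(n_states), repeat=len(obs)):
        score = -math.log(n_states) + emit(obs[0], path[0])
        for t in range(1, len(obs)):
            score += log_stay if path[t] == path[t - 1] else log_switch
            score += emit(obs[t], path[t])
        if score > best_score:
            best_path, best_score = path, score
    return np.array(best_path), best_score


def path_score(path, obs, means, sigma, stay_prob):
    n_states = len(means)
    score = -math.log(n_states)
    for t, (x, k) in enumerate(zip(obs, path)):
        if t:
            score += (
                math.log(stay_prob)
                if path[t] == path[t - 1]
                else math.log((1 - stay_prob) / (n_states - 1))
            )
        score += -0.5 * ((x - means[k]) / sigma) ** 2 - math.log(
            sigma * math.sqrt(2 * math.pi)
        )
    return score


class TestViterbi:
    @pytest.mark.parametrize("n", [2, 4, 7, 10])
    def test_matches_brute_force_enumeration(self, n):
        means = np.array([-1.0, 0.0, 0.585])
        rng = np.random.default_rng(n)
        for _ in range(10):
            obs = rng.normal(0, 0.6, n)
            decoded = cnv.viterbi(obs, means, sigma=0.2, stay_prob=0.999)
            _, oracle_score = brute_force_viterbi(obs, means, 0.2, 0.999)
            assert path_score(decoded, obs, means, 0.2, 0.999) == pytest.approx(
                oracle_score
            )


class TestCaller:
    def test_flat_sample_single_diploid_segment(self):
        panel = make_panel(50)
        segments = cnv.call_cnv_hmm(series(np.zeros(50), panel), panel, sample_id="s")
        assert len(segments) == 1
        assert segments[0].ploidy == 2 and segments[0].change == "neutral"
        assert segments[0].n_amplicons == 50

    def test_planted_loss_recovered_with_breakpoints(self):
        rng = np.random.default_rng(17)
        panel = make_panel(200)
        values = rng.normal(0.0, 0.1, 200)
        values[80:100] += math.log2(0.5)
        segments = cnv.call_cnv_hmm(series(values, panel), panel, sample_id="s")
        losses = [s for s in segments if s.change == "loss"]
        assert len(losses) == 1
        assert losses[0].ploidy == 1
        assert losses[0].start == panel["start"].iloc[80]
        assert losses[0].end == panel["end"].iloc[99]

    def test_segments_partition_the_amplicons(self):
        rng = np.random.default_rng(3)
        panel = make_panel(120)
        values = rng.normal(0.0, 0.1, 120)
        values[30:50] += 0.58
        segments = cnv.call_cnv_hmm(series(values, panel), panel, sample_id="s")
        assert sum(s.n_amplicons for s in segments) == 120

    def test_ineligible_sample_refused_unless_forced(self):
        panel = make_panel(50)
        noisy = series([0, 1] * 25, panel)
        with pytest.raises(ValueError, match="ineligible"):
            cnv.call_cnv_hmm(noisy, panel, sample_id="s")
        segments = cnv.call_cnv_hmm(noisy, panel, sample_id="s", force=True)
        assert segments

    def test_single_amplicon_spike_confidence_gate(self):
        rng = np.random.default_rng(9)
        panel = make_panel(100)
        values = rng.normal(0.0, 0.1, 100)
        values[40] = 3.0
        segments = cnv.call_cnv_hmm(series(values, panel), panel, sample_id="s")
        gains = [s for s in segments if s.change == "gain"]
        kept = cnv.filter_and_flag(segments)
        kept_gains = [s for s in kept if s.change == "gain"]
        for seg in gains:
            assert (seg in kept_gains) == (seg.confidence > 10.0)


class TestFilterAndFlag:
    def _segment(self, confidence, length, ploidy=3):
        from poipanel.types import CNVSegment

        return CNVSegment(
            sample_id="s", chrom="1", start=0, end=length,
            ploidy=ploidy, confidence=confidence,
        )

    def test_confidence_boundary_is_strict(self):
        assert cnv.filter_and_flag([self._segment(10.0, 1000)]) == []
        kept = cnv.filter_and_flag([self._segment(10.01, 1000)])
        assert len(kept) == 1

    def test_focality_thresholds(self):
        focal = cnv.filter_and_flag([self._segment(20.0, 11_349)])[0]
        assert focal.focal is True
        broad = cnv.filter_and_flag([self._segment(20.0, 3_000_000)])[0]
        assert broad.focal is False

    def test_neutral_segments_kept_regardless_of_confidence(self):
        neutral = self._segment(0.0, 1000, ploidy=2)
        assert cnv.filter_and_flag([neutral]) == [neutral]


class TestTierSvScores:
    @pytest.mark.parametrize(
        "mvp, tier",
        [
            (0.700, "likely_pathogenic"),
            (0.187, "uncertain"),
            (0.227, "uncertain"),
            (0.154, "likely_benign"),
            (0.46, "likely_pathogenic"),
            (0.76, "likely_pathogenic"),
            (0.16, "uncertain"),
            (0.14, "likely_benign"),
            (0.05, "out_of_band"),
            (0.9, "out_of_band"),
        ],
    )
    def test_published_bands(self, mvp, tier):
        assert cnv.tier_sv_scores(SVScoreSet(mvp=mvp)) == tier

    def test_missing_mvp_undetermined(self):
        assert cnv.tier_sv_scores(SVScoreSet(cadd_sv_phred=13.86)) == "undetermined"


class TestQpcr:
    def _m(self, target, ref, cal_target, cal_ref):
        return QpcrMeasurement("s", target, ref, cal_target, cal_ref)

    def test_zero_ddct_is_unit_fold_change(self):
        assert cnv.qpcr_relative_quantity(self._m(24, 20, 24, 20)) == 1.0

    def test_one_cycle_doubling(self):
        assert cnv.qpcr_relative_quantity(self._m(23, 20, 24, 20)) == 2.0

    def test_hand_arithmetic(self):
        assert cnv.qpcr_relative_quantity(self._m(24, 20, 25, 20)) == 2.0

    def test_group_comparison_detects_shift(self):
        rng = np.random.default_rng(1)
        a = rng.normal(4.0, 0.1, 6)
        b = rng.normal(5.0, 0.1, 6)
        _, p = cnv.compare_qpcr_groups(a, b)
        assert p < 1e-4
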