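"""CRTD survival fitting, behavior tables, chi-square, co-localization."""

import numpy as np
import pytest

import tightropekit as tk
from tightropekit.errors import FitFailureError, InvalidParameterError
from tightropekit.residence import DwellRecord, ParticleDetection


def _dwells(durations, censored=None, motile=None):
    censored = censored or [False] * len(durations)
    motile = motile or [False] * len(durations)
    return [DwellRecord(f"p{i}", d, c, m)
            for i, (d, c, m) in enumerate(zip(durations, censored, motile))]


class TestBuildCRTD:
    def test_uncensored_counting(self):
        crtd = tk.build_crtd(_dwells([1, 2, 3, 4, 5]))
        # S(t) = #{duration >= t}/n at each observed duration
        assert list(crtd["t_s"]) == [0, 1, 2, 3, 4, 5]
        assert np.allclose(crtd["survival"], [1, 1, 4 / 5, 3 / 5, 2 / 5, 1 / 5])

    def test_three_point_fractions(self):
        crtd = tk.build_crtd(_dwells([1, 2, 3, 1.5, 2.5]))
        at = dict(zip(crtd["t_s"], crtd["survival"]))
        assert at[1.0] == pytest.approx(1.0)       # 5/5 still bound at t=1
        assert at[2.0] == pytest.approx(3 / 5)
        assert at[3.0] == pytest.approx(1 / 5)

    def test_monotone_and_bounded(self):
        dwells = tk.simulate_dwell_times(0.02, 500, window=np.inf, seed=4)
        crtd = tk.build_crtd(dwells)
        s = crtd["survival"].to_numpy()
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 0)
        assert np.all((s >= 0) & (s <= 1))

    def test_all_censored_flat_and_fit_refused(self):
        crtd = tk.build_crtd(_dwells([300] * 6, censored=[True] * 6))
        assert np.allclose(crtd["survival"], 1.0)
        with pytest.raises(FitFailureError):
            tk.fit_crtd(crtd)

    def test_requires_five_records(self):
        with pytest.raises(InvalidParameterError):
            tk.build_crtd(_dwells([1, 2, 3]))

    def test_empirical_survival_within_ks_band(self):
        k, n = 0.01, 2000
        dwells = tk.simulate_dwell_times(k, n, window=np.inf, seed=8)
        crtd = tk.build_crtd(dwells)
        t = crtd["t_s"].to_numpy()[1:]
        s = crtd["survival"].to_numpy()[1:]
        band = 1.628 / np.sqrt(n)  # 1% KS critical value
        assert np.max(np.abs(s - np.exp(-k * t))) < band + 1 / n

    def test_censored_mode_matches_kaplan_meier_oracle(self):
        """The at-risk accounting agrees with an independent Kaplan-Meier
        implementation (left-limit convention) on a censored sample."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(21)
        durations = rng.exponential(100, 200)
        cens_at = rng.uniform(20, 250, 200)
        observed = durations <= cens_at
        recorded = np.minimum(durations, cens_at)
        dwells = _dwells(list(recorded), censored=list(~observed))
        crtd = tk.build_crtd(dwells, mode="censored")

        km = lifelines.KaplanMeierFitter().fit(recorded, observed)
        for t, s in zip(crtd["t_s"][1:], crtd["survival"][1:]):
            # lifelines S is right-continuous P(T > t); ours is P(T >= t)
            s_km = float(km.survival_function_at_times(t - 1e-9).iloc[0])
            assert s == pytest.approx(s_km, abs=1e-9)


class TestFitCRTD:
    def test_closed_form_exponential(self):
        import pandas as pd

        t = np.linspace(0, 400, 60)
        crtd = pd.DataFrame({"t_s": t, "survival": np.exp(-0.01 * t)})
        fit = tk.fit_crtd(crtd)
        assert fit.half_life == pytest.approx(69.31, abs=0.01)
        assert fit.rate == pytest.approx(0.01, rel=1e-6)

    @pytest.mark.parametrize("rate,expected", [
        (1.400e-4, 4950.0),   # dissociation rate without competitor
        (1.195e-3, 580.0),    # with equimolar competitor
    ])
    def test_recovery_at_measured_rates(self, rate, expected):
        dwells = tk.simulate_dwell_times(rate, 1000, window=np.inf,
                                         seed=1 if rate < 1e-3 else 2)
        fit = tk.fit_crtd(tk.build_crtd(dwells))
        assert fit.half_life == pytest.approx(expected, rel=0.10)

    def test_unbiased_on_uncensored_samples(self):
        """Median relative half-life error < 5% at n=1000 over 200 seeds."""
        truth = 100.0
        k = np.log(2) / truth
        rel = []
        for i in range(200):
            dwells = tk.simulate_dwell_times(k, 1000, window=np.inf,
                                             seed=500 + i)
            fit = tk.fit_crtd(tk.build_crtd(dwells))
            rel.append(abs(fit.half_life - truth) / truth)
        assert np.median(rel) < 0.05

    def test_censoring_aware_reduces_bias(self):
        """With a 300 s movie and a 4950 s true half-life most dwells are
        censored; dropping them wrecks the estimate, at-risk accounting
        largely repairs it."""
        truth = 4950.0
        dwells = tk.simulate_dwell_times(np.log(2) / truth, 2000,
                                         window=300.0, seed=42)
        assert sum(d.censored for d in dwells) > 1500
        t_cens = tk.fit_crtd(tk.build_crtd(dwells, mode="censored")).half_life
        t_naive = tk.fit_crtd(tk.build_crtd(dwells, mode="naive")).half_life
        assert t_naive < truth * 0.2           # documented underestimate
        assert abs(t_cens - truth) < abs(t_naive - truth)
        assert t_cens == pytest.approx(truth, rel=0.25)


class TestHalfLifeFold:
    def test_measured_half_lives_give_8_5_fold(self):
        assert tk.half_life_fold(4950.0, 580.0) == pytest.approx(8.53, abs=0.01)

    @pytest.mark.parametrize("a,b,expected", [(100, 50, 2.0), (70, 70, 1.0)])
    def test_simple_ratios(self, a, b, expected):
        assert tk.half_life_fold(a, b) == pytest.approx(expected)

    def test_simulated_fold_in_range(self):
        """Fold of half-lives recovered from seeded simulations at the two
        measured rates lands in [7, 10] (~8-fold facilitated dissociation)."""
        f1 = tk.fit_crtd(tk.build_crtd(
            tk.simulate_dwell_times(1.400e-4, 1000, np.inf, seed=1)))
        f2 = tk.fit_crtd(tk.build_crtd(
            tk.simulate_dwell_times(1.195e-3, 1000, np.inf, seed=2)))
        assert 7.0 <= tk.half_life_fold(f1, f2) <= 10.0


class TestBehaviorTable:
    def _particles(self, lasts, motile=None, n_frames=3750):
        motile = motile or [False] * len(lasts)
        return [ParticleDetection(f"p{i}", "605", 2.0, 0, last, m)
                for i, (last, m) in enumerate(zip(lasts, motile))]

    def test_full_window_all_persistent(self):
        parts = self._particles([3749] * 8)
        out = tk.behavior_table(parts, window_s=300.0, frame_interval=0.08)
        assert out["counts"].loc["stationary", "persistent"] == 8
        assert out["fractions"].to_numpy().sum() == pytest.approx(1.0)

    def test_uniform_counts_quarter_fractions(self):
        parts = (self._particles([3749] * 10 + [100] * 10)
                 + self._particles([3749] * 10 + [100] * 10,
                                   motile=[True] * 20))
        out = tk.behavior_table(parts, window_s=300.0, frame_interval=0.08)
        assert np.allclose(out["fractions"].to_numpy(), 0.25)

    def test_dissociation_frequency_ratio(self):
        """Conditions with a 3-fold dissociation-rate difference produce an
        observed dissociation-frequency ratio within binomial error."""
        window, n = 300.0, 400
        k_slow = 8e-4  # P(dissociate) = 1 - exp(-k*300) = 0.213
        k_fast = 3 * k_slow                   # 0.513
        freqs = []
        for k, seed in [(k_slow, 5), (k_fast, 6)]:
            dwells = tk.simulate_dwell_times(k, n, window=window, seed=seed)
            p_true = 1 - np.exp(-k * window)
            freq = np.mean([not d.censored for d in dwells])
            assert abs(freq - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)
            freqs.append(freq)
        expected_ratio = (1 - np.exp(-k_fast * window)) / (1 - np.exp(-k_slow * window))
        assert freqs[1] / freqs[0] == pytest.approx(expected_ratio, rel=0.25)


class TestChiSquare:
    def test_identical_tables(self):
        chi2, df, p = tk.compare_conditions_chi2([50, 50], [50, 50])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        chi2, df, p = tk.compare_conditions_chi2([10, 90], [40, 60])
        assert chi2 == pytest.approx(24.0)
        assert df == 1
        assert p < 1e-5

    def test_zero_expected_cell(self):
        with pytest.raises(InvalidParameterError, match="exact"):
            tk.compare_conditions_chi2([0, 100], [0, 50])

    def test_type_one_error_calibrated(self):
        """Simulated null (equal dissociation probability, n=100/arm):
        rejection rate at alpha=0.05 lies in [0.03, 0.07]."""
        rng = np.random.default_rng(11)
        rejects = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.binomial(100, 0.3)
            b = rng.binomial(100, 0.3)
            _, _, p = tk.compare_conditions_chi2([100 - a, a], [100 - b, b])
            rejects += p < 0.05
        assert 0.03 <= rejects / n_rep <= 0.07


class TestColocalization:
    def _pd(self, pid, ch, pos, first=0, last=1000):
        return ParticleDetection(pid, ch, pos, first, last)

    def test_disjoint_positions_no_pairs(self):
        a = [self._pd("a0", "605", 2.0)]
        b = [self._pd("b0", "705", 10.0)]
        out = tk.pair_colocalized(a, b, max_distance_kb=1.5)
        assert out["colocalized"] == 0

    def test_toy_venn_fraction(self):
        a = [self._pd(f"a{i}", "605", 2.0 * i) for i in range(5)]
        b = ([self._pd("b0", "705", 0.1), self._pd("b1", "705", 2.1)]
             + [self._pd(f"b{i}", "705", 50.0 + 3 * i) for i in range(2, 7)])
        out = tk.pair_colocalized(a, b, max_distance_kb=0.5)
        assert out["colocalized"] == 2
        assert out["a_only"] == 3 and out["b_only"] == 5
        assert out["fraction_colocalized"] == pytest.approx(0.2)

    def test_temporal_overlap_required(self):
        a = [self._pd("a0", "605", 2.0, first=0, last=20)]
        b = [self._pd("b0", "705", 2.0, first=15, last=40)]
        assert tk.pair_colocalized(a, b, min_overlap_frames=6)["colocalized"] == 1
        assert tk.pair_colocalized(a, b, min_overlap_frames=7)["colocalized"] == 0

    def test_symmetric_under_label_swap(self, cfg):
        a, b, _ = tk.simulate_two_color_particles(6, 9, 4, cfg=cfg, seed=3)
        ab = tk.pair_colocalized(a, b)
        ba = tk.pair_colocalized(b, a)
        assert ab["colocalized"] == ba["colocalized"]
        assert ab["a_only"] == ba["b_only"]

    def test_perfect_recovery_on_simulated_truth(self, cfg):
        """Lesion spacing (2 kb) is >= 2x the pairing radius, so pairing
        recovers the ground truth with precision = recall = 1."""
        a, b, truth = tk.simulate_two_color_particles(8, 8, 3, cfg=cfg, seed=9)
        out = tk.pair_colocalized(a, b, max_distance_kb=1.0)
        assert out["colocalized"] == len(truth)
        found = {(pa.particle_id, pb.particle_id) for pa, pb in out["pairs"]}
        expected = {(pa.particle_id, pb.particle_id) for pa, pb in truth}
        assert found == expected
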