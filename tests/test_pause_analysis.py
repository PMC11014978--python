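import numpy as np
import pytest
from scipy import stats

from helpers import censored_exp_mle
from rbtransit.pause_analysis import (PauseSample, ccdf, extract_pauses,
                                      fit_exp_ccdf_lsq, fit_exp_double,
                                      fit_exp_single, passage_fraction,
                                      records_to_sample, select_model,
                                      PauseRecord)
from rbtransit.synthetic_data import default_geometry

GEO = default_geometry("opposing")
OP = GEO.operator_pos


def trace_with_dwell(duration, offset_bp=0.0, v=10.0, pre=30, post=30):
    """Aligned positions: ramp, plateau near the operator, ramp out."""
    level = OP + offset_bp
    ramp_in = level - v * np.arange(pre, 0, -1)
    ramp_out = level + v * np.arange(1, post + 1)
    return np.concatenate([ramp_in, np.full(int(duration), level), ramp_out])


class TestExtractPauses:
    def test_thirty_second_dwell_one_record(self):
        recs = extract_pauses(trace_with_dwell(30), GEO)
        assert len(recs) == 1
        assert recs[0].duration == 30.0
        assert abs(recs[0].position - OP) < 1e-9
        assert recs[0].outcome == "transited"

    def test_short_dwell_excluded(self):
        assert extract_pauses(trace_with_dwell(15), GEO) == []

    def test_outside_window_excluded(self):
        recs = extract_pauses(trace_with_dwell(100, offset_bp=80.0), GEO)
        assert recs == []

    def test_sub_steps_merged(self):
        y = np.concatenate([trace_with_dwell(0, offset_bp=0.0)[:30],
                            np.full(15, OP - 2.0), np.full(15, OP + 2.0),
                            trace_with_dwell(0)[-30:]])
        recs = extract_pauses(y, GEO)
        assert len(recs) == 1
        assert recs[0].duration == 30.0

    def test_threshold_monotonicity(self, rng):
        y = trace_with_dwell(40)
        base = extract_pauses(y, GEO, min_pause_s=30.0)
        lower = extract_pauses(y, GEO, min_pause_s=20.0)
        ids = {(r.start, r.position) for r in base}
        assert ids <= {(r.start, r.position) for r in lower}

    def test_window_monotonicity(self):
        y = trace_with_dwell(50, offset_bp=40.0)
        narrow = extract_pauses(y, GEO, window_bp=45.0)
        wide = extract_pauses(y, GEO, window_bp=60.0)
        assert len(wide) >= len(narrow)

    def test_trace_ending_in_window_censored(self):
        y = np.concatenate([trace_with_dwell(25)[:55],
                            np.full(40, OP)])  # ends at the roadblock
        recs = extract_pauses(y, GEO)
        assert recs and recs[0].outcome == "stalled_censored"

    def test_terminated_end_state_label(self):
        y = np.concatenate([trace_with_dwell(25)[:55], np.full(40, OP)])
        recs = extract_pauses(y, GEO, end_state="terminated_at_roadblock")
        assert recs[0].outcome == "terminated_at_roadblock"

    def test_empty_positions(self):
        assert extract_pauses(np.full(10, np.nan), GEO) == []

    def test_boundary_bias_correction(self):
        recs = extract_pauses(trace_with_dwell(30), GEO,
                              boundary_bias_samples=1.0)
        assert recs[0].duration == 29.0


class TestCCDF:
    def test_simple_empirical(self):
        s = PauseSample([10.0, 20.0, 30.0], [False, False, False])
        t, frac = ccdf(s)
        # right-continuous step function: value just after 20 is 1/3
        assert frac[np.searchsorted(t, 25.0, side="right") - 1] == \
            pytest.approx(1 / 3)

    def test_all_censored_flat_one(self):
        s = PauseSample([50.0, 50.0], [True, True])
        t, frac = ccdf(s)
        assert np.all(frac == 1.0)

    def test_monotone_bounded(self, rng):
        s = PauseSample(rng.exponential(100, 200),
                        rng.random(200) < 0.3)
        _, frac = ccdf(s)
        assert np.all(np.diff(frac) <= 1e-12)
        assert np.all((frac >= 0) & (frac <= 1))

    def test_km_equals_naive_without_censoring(self, rng):
        d = rng.exponential(50, 100)
        s = PauseSample(d, np.zeros(100, dtype=bool))
        t1, f1 = ccdf(s, method="km")
        t2, f2 = ccdf(s, method="naive")
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_km_matches_manual_product_limit(self):
        # durations 10, 20+, 30 (censored at 20): S(30-) = 2/3, S(30) = 0
        s = PauseSample([10.0, 20.0, 30.0], [False, True, False])
        t, frac = ccdf(s, method="km")
        assert frac[list(t).index(10.0)] == pytest.approx(2 / 3)
        assert frac[list(t).index(30.0)] == pytest.approx(0.0, abs=1e-12)

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            ccdf(PauseSample([], []))


class TestFitExpSingle:
    def test_single_duration_mle(self):
        s = PauseSample([37.0], [False])
        assert fit_exp_single(s, n_boot=0).tau[0] == pytest.approx(37.0)

    def test_mle_matches_independent_formula(self, rng):
        d = rng.exponential(80, 500)
        c = d > 150
        d[c] = 150.0
        s = PauseSample(d, c)
        fit = fit_exp_single(s, n_boot=0)
        assert fit.tau[0] == pytest.approx(censored_exp_mle(d, c))

    def test_uncensored_recovery(self, rng):
        s = PauseSample(rng.exponential(100.0, 1000), np.zeros(1000, bool))
        fit = fit_exp_single(s, seed=1)
        assert 93.0 <= fit.tau[0] <= 107.0
        lo, hi = fit.ci90[0]
        assert lo <= fit.tau[0] <= hi

    def test_censoring_consistency(self, rng):
        tau = 100.0
        d = rng.exponential(tau, 2000)
        c = d >= 70.0
        d[c] = 70.0
        s = PauseSample(d, c)
        s.meta["obs_window"] = 70.0
        fit = fit_exp_single(s, seed=2)
        se = tau / np.sqrt((~c).sum())
        assert abs(fit.tau[0] - tau) < 3 * se

    def test_all_censored_unidentifiable(self):
        with pytest.raises(ValueError):
            fit_exp_single(PauseSample([5.0, 5.0], [True, True]))

    def test_agreement_with_ccdf_backend(self, rng):
        s = PauseSample(rng.exponential(120.0, 2000), np.zeros(2000, bool))
        mle = fit_exp_single(s, n_boot=0).tau[0]
        lsq = fit_exp_ccdf_lsq(s).tau[0]
        assert abs(mle - lsq) / mle < 0.10

    def test_dkw_style_ccdf_agreement(self, rng):
        n = 2000
        s = PauseSample(rng.exponential(60.0, n), np.zeros(n, bool))
        tau = fit_exp_single(s, n_boot=0).tau[0]
        t, frac = ccdf(s)
        assert np.max(np.abs(frac - np.exp(-t / tau))) < 3 / np.sqrt(n)

    def test_ci_calibration_quick(self, rng):
        """~90% bootstrap CI covers tau in a loose band (small replicate
        count here; the acceptance suite runs the full 500)."""
        tau, n, cover = 150.0, 50, 0
        for i in range(100):
            s = PauseSample(rng.exponential(tau, n), np.zeros(n, bool))
            lo, hi = fit_exp_single(s, n_boot=400, seed=i).ci90[0]
            cover += lo <= tau <= hi
        assert 78 <= cover <= 99


class TestFitExpDouble:
    def test_mixture_recovery(self, rng):
        d = np.concatenate([rng.exponential(50.0, 2500),
                            rng.exponential(1000.0, 2500)])
        s = PauseSample(d, np.zeros(5000, bool))
        fit = fit_exp_double(s, seed=3)
        assert fit.model == "double"
        assert abs(fit.tau[0] - 50.0) / 50.0 < 0.15
        assert abs(fit.tau[1] - 1000.0) / 1000.0 < 0.15
        assert fit.tau[0] < fit.tau[1]
        assert 0.4 < fit.weight < 0.6

    def test_single_exponential_data_degenerates(self, rng):
        s = PauseSample(rng.exponential(100.0, 2000), np.zeros(2000, bool))
        fit = fit_exp_double(s, seed=4)
        if fit.model == "double":
            assert fit.tau[1] / fit.tau[0] < 1.6
        else:
            assert fit.meta.get("degenerate_double")

    def test_censored_mixture_loglik_finite(self, rng):
        d = np.concatenate([rng.exponential(50.0, 500),
                            rng.exponential(600.0, 500)])
        c = d > 1500.0
        d[c] = 1500.0
        fit = fit_exp_double(PauseSample(d, c), seed=5)
        assert np.isfinite(fit.loglik)


class TestSelectModel:
    def _fit(self, model, loglik):
        from rbtransit.pause_analysis import ExpFit

        return ExpFit(model=model, tau=(1.0,) if model == "single"
                      else (1.0, 2.0),
                      weight=None if model == "single" else 0.5,
                      ci90=None, loglik=loglik, n_used=100)

    def test_equal_loglik_prefers_single(self):
        choice = select_model(self._fit("single", -500.0),
                              self._fit("double", -500.0))
        assert choice.model == "single"
        assert choice.delta_aic == pytest.approx(4.0)

    def test_tie_at_zero_delta_goes_single(self):
        choice = select_model(self._fit("single", -500.0),
                              self._fit("double", -498.0))
        assert choice.delta_aic == pytest.approx(0.0)
        assert choice.model == "single"

    def test_bimodal_sample_chooses_double(self, rng):
        wins = 0
        for i in range(20):
            d = np.concatenate([rng.exponential(30.0, 200),
                                rng.exponential(900.0, 200)])
            s = PauseSample(d, np.zeros(400, bool))
            single = fit_exp_single(s, n_boot=0)
            double = fit_exp_double(s, seed=i)
            wins += select_model(single, double).model == "double"
        assert wins >= 19


class TestPassageFraction:
    def _records(self, outcomes):
        return [PauseRecord(start=0, duration=30, position=OP, outcome=o)
                for o in outcomes]

    def test_all_transited(self):
        frac, (lo, hi) = passage_fraction(self._records(["transited"] * 8))
        assert frac == 1.0 and hi == 1.0

    def test_zero_of_n_interval_excludes_half(self):
        frac, (lo, hi) = passage_fraction(
            self._records(["stalled_censored"] * 8))
        assert frac == 0.0
        assert hi < 0.5

    def test_terminated_counts_as_non_passage(self):
        frac, _ = passage_fraction(self._records(
            ["transited", "terminated_at_roadblock"]))
        assert frac == 0.5

    def test_empty_error(self):
        with pytest.raises(ValueError):
            passage_fraction([])

    def test_dislodging_raises_passage(self):
        from rbtransit.kinetics_sim import KineticParams
        from rbtransit.synthetic_data import generate_pause_sample

        base = dict(k1=0.02, k2=0.02, k3=1e-4, dt=1.0, t_max=5000.0)
        with_p1 = generate_pause_sample(KineticParams(p1=0.3, **base),
                                        2000, 3600.0, seed=8)
        without = generate_pause_sample(KineticParams(p1=0.0, **base),
                                        2000, 3600.0, seed=8)
        assert (1 - with_p1.censored_fraction) > (1 - without.censored_fraction)


def test_records_to_sample_roundtrip():
    recs = [PauseRecord(start=10, duration=40, position=OP,
                        outcome="transited"),
            PauseRecord(start=99, duration=70, position=OP,
                        outcome="stalled_censored")]
    s = records_to_sample(recs)
    np.testing.assert_array_equal(s.durations, [40.0, 70.0])
    np.testing.assert_array_equal(s.censored, [False, True])
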