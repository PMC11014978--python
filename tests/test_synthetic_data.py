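import numpy as np
import pytest

from rbtransit.kinetics_sim import KineticParams
from rbtransit.synthetic_data import (CohortRow, Condition, TemplateGeometry,
                                      TraceGenConfig, default_geometry,
                                      default_obs_window, generate_cohort,
                                      generate_pause_sample, generate_trace)


class TestTypes:
    def test_geometry_defaults_match_template(self):
        g = default_geometry("opposing")
        assert g.operator_pos == 709.0
        assert g.terminator_pos == 709.0 + 612.0
        assert g.anchor_offset == 1021.0
        assert default_geometry("assisting").anchor_offset == 2014.0

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            TemplateGeometry(operator_pos=0.0)
        with pytest.raises(ValueError):
            TemplateGeometry(operator_pos=800.0, terminator_pos=700.0)
        with pytest.raises(ValueError):
            TemplateGeometry(anchor_offset=-1.0)

    def test_condition_zero_force_consistency(self):
        Condition(roadblock="LacI-O2", force_direction="zero", force_pN=0.0)
        with pytest.raises(ValueError):
            Condition(roadblock="LacI-O2", force_direction="zero",
                      force_pN=0.2)
        with pytest.raises(ValueError):
            Condition(roadblock="LacI-O2", force_direction="opposing",
                      force_pN=0.0)

    def test_condition_enums(self):
        with pytest.raises(ValueError):
            Condition(roadblock="TetR", force_direction="opposing")
        with pytest.raises(ValueError):
            Condition(roadblock="LacI-O1", force_direction="opposing",
                      force_pN=0.2, grea_uM=-1.0)

    def test_obs_window_defaults(self):
        assert default_obs_window("LacI-O1") == 1800.0
        assert default_obs_window("LacI-Os") == 3600.0
        assert default_obs_window("EcoRI-Q111") == 3600.0

    def test_gen_config_validation(self):
        with pytest.raises(ValueError):
            TraceGenConfig(velocity=0.0)
        with pytest.raises(ValueError):
            TraceGenConfig(a_true=1.5)
        with pytest.raises(ValueError):
            TraceGenConfig(noise_sd=-1.0)


class TestGeneratePauseSample:
    def test_p1_one_all_two_seconds(self):
        p = KineticParams(k1=0.1, k2=0.1, k3=0.0, p1=1.0)
        s = generate_pause_sample(p, 100, 3600.0, seed=0)
        assert np.all(s.durations == 2.0)
        assert not s.censored.any()

    def test_locked_roadblock_all_censored_at_window(self):
        p = KineticParams(k1=0.0, k2=0.1, k3=0.0, p1=0.0)
        s = generate_pause_sample(p, 50, 3600.0, seed=1)
        assert np.all(s.durations == 3600.0)
        assert s.censored.all()

    def test_passive_mean_matches_closed_form(self):
        from rbtransit.kinetics_sim import passive_limit_mean

        p = KineticParams(k1=0.0, k2=0.1, k3=0.01, p1=0.0)
        s = generate_pause_sample(p, 100000, 5000.0, seed=2)
        se = s.durations.std() / np.sqrt(len(s))
        assert abs(s.durations.mean() - passive_limit_mean(0.01)) < 3 * se

    def test_reproducible(self):
        p = KineticParams(k1=0.01, k2=0.01, k3=0.01, p1=0.1)
        a = generate_pause_sample(p, 200, 3600.0, seed=5)
        b = generate_pause_sample(p, 200, 3600.0, seed=5)
        np.testing.assert_array_equal(a.durations, b.durations)

    def test_errors(self):
        p = KineticParams(k1=0.01, k2=0.01, k3=0.01, p1=0.1)
        with pytest.raises(ValueError):
            generate_pause_sample(p, 0, 3600.0, seed=0)
        with pytest.raises(ValueError):
            generate_pause_sample(p, 10, 0.0, seed=0)
        with pytest.raises(ValueError):
            generate_pause_sample(p, 10, 6000.0, seed=0)


class TestGenerateTrace:
    def test_noiseless_single_plateau(self, geometry, condition, quiet_gen):
        p = KineticParams(k1=0.1, k2=0.1, k3=0.0, p1=1.0)
        trace = generate_trace(geometry, condition, quiet_gen, p)
        truth = trace.meta["truth"]
        assert truth["roadblock_duration_s"] == 2.0
        # extension is exactly the latent trajectory
        np.testing.assert_allclose(trace.extension, truth["latent_nm"])
        # exactly one interior pause event: the roadblock
        kinds = [e[3] for e in truth["events"]]
        assert kinds == ["roadblock"]

    def test_a_true_scales_plateaus(self, geometry, condition, quiet_gen):
        p = KineticParams(k1=0.0, k2=0.01, k3=0.01, p1=0.0)
        t1 = generate_trace(geometry, condition, quiet_gen, p)
        t2 = generate_trace(geometry, condition,
                            quiet_gen.replace(a_true=0.8), p)
        np.testing.assert_allclose(t2.extension, 0.8 * t1.extension,
                                   atol=1e-9)

    def test_scaling_equivariance_of_latent(self, geometry, condition,
                                            quiet_gen):
        p = KineticParams(k1=0.0, k2=0.01, k3=0.01, p1=0.0)
        t1 = generate_trace(geometry, condition, quiet_gen, p)
        t2 = generate_trace(geometry, condition,
                            quiet_gen.replace(a_true=0.75), p)
        np.testing.assert_allclose(t2.meta["truth"]["latent_nm"] / 0.75,
                                   t1.meta["truth"]["latent_nm"], atol=1e-9)

    def test_stalled_trace_ends_at_operator(self, geometry, condition,
                                            quiet_gen):
        p = KineticParams(k1=0.0, k2=0.1, k3=0.0, p1=0.0)  # never transits
        trace = generate_trace(geometry, condition, quiet_gen, p)
        truth = trace.meta["truth"]
        assert truth["outcome"] == "stalled_censored"
        level = quiet_gen.nm_per_bp * geometry.operator_pos
        assert trace.extension[-1] == pytest.approx(level)
        assert trace.t.size == int(quiet_gen.obs_window)

    def test_window_truncation(self, geometry, condition, quiet_gen):
        p = KineticParams(k1=0.0, k2=0.01, k3=0.5, p1=0.0)
        trace = generate_trace(geometry, condition, quiet_gen, p)
        assert trace.t[-1] < quiet_gen.obs_window

    def test_gap_insertion(self, geometry, condition, quiet_gen):
        p = KineticParams(k1=0.0, k2=0.01, k3=0.5, p1=0.0)
        gen = quiet_gen.replace(gap_after_dwell_s=10.0, noise_sd=1.0)
        trace = generate_trace(geometry, condition, gen, p)
        gaps = np.isnan(trace.extension)
        assert gaps.sum() == 10
        start = int(gen.initial_dwell_s)
        assert gaps[start:start + 10].all()

    def test_ec_dissociation_truncates(self, geometry, condition, quiet_gen):
        p = KineticParams(k1=0.0, k2=0.1, k3=0.0, p1=0.0)
        gen = quiet_gen.replace(ec_dissociation_prob=1.0)
        trace = generate_trace(geometry, condition, gen, p)
        assert trace.meta["truth"]["outcome"] == "terminated_at_roadblock"
        assert trace.t.size < int(gen.obs_window)

    def test_censoring_annotation_consistency(self, geometry, condition):
        p = KineticParams(k1=0.0, k2=0.01, k3=0.002, p1=0.0)
        stalled = 0
        censored = 0
        for i in range(40):
            gen = TraceGenConfig(noise_sd=0.0, ubiquitous_pause_rate=0.0,
                                 obs_window=600.0, seed=i)
            trace = generate_trace(geometry, condition, gen, p)
            truth = trace.meta["truth"]
            stalled += truth["outcome"] == "stalled_censored"
            censored += truth["roadblock_censored"]
        assert stalled == censored


class TestGenerateCohort:
    def _row(self, label="a", n=3):
        return CohortRow(
            label=label,
            condition=Condition(roadblock="LacI-O1",
                                force_direction="opposing", force_pN=0.2),
            n_traces=n,
            params=KineticParams(k1=0.0, k2=0.01, k3=0.05, p1=0.0),
            gen=TraceGenConfig(noise_sd=1.0, obs_window=400.0))

    def test_counts_and_distinct_seeds(self):
        cohort = generate_cohort([self._row()], master_seed=3)
        traces = cohort["a"]
        assert len(traces) == 3
        seeds = {t.meta["gen"].seed for t in traces}
        assert len(seeds) == 3
        assert all(t.meta["condition"] == traces[0].meta["condition"]
                   for t in traces)

    def test_deterministic_under_master_seed(self):
        a = generate_cohort([self._row()], master_seed=11)["a"]
        b = generate_cohort([self._row()], master_seed=11)["a"]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.extension, y.extension)

    def test_count_conservation_many_rows(self):
        rows = [self._row(label=f"r{i}", n=5) for i in range(4)]
        cohort = generate_cohort(rows, master_seed=0)
        assert sum(len(v) for v in cohort.values()) == 20
        assert all(t.meta["trace_id"] for v in cohort.values() for t in v)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort([self._row(), self._row()], master_seed=0)


def test_roundtrip_single_trace(geometry, condition):
    """Full pipeline recovers one injected pause within 2 s (defaults-like
    config; the acceptance suite runs the 100-trace version)."""
    from rbtransit.pipeline_io import process_trace

    p = KineticParams(k1=0.0, k2=0.01, k3=0.01, p1=0.0)
    gen = TraceGenConfig(noise_sd=2.0, obs_window=1800.0, seed=7)
    trace = generate_trace(geometry, condition, gen, p)
    d_true = trace.meta["truth"]["roadblock_duration_s"]
    assert d_true >= 20.0
    out = process_trace(trace, geometry, refine=True)
    assert any(abs(r.duration - d_true) <= 2.0 for r in out["records"])
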