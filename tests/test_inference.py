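"""Initial-velocity estimation, two-term fitting and regime classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autocyclase import (RateParams, TimeCourse, VelocityRecord,
                         bootstrap_confidence, build_network, classify_regime,
                         estimate_initial_velocity, fit_velocity_model)


def _toy_timecourse(t, conc_of_t, c0):
    """Minimal single-species time course for velocity estimation."""
    return TimeCourse(times=np.asarray(t, float), species=("E",),
                      conc=np.asarray(conc_of_t, float)[None, :], c0=c0,
                      params=RateParams(), provenance="synthetic")


class TestInitialVelocity:
    def test_noise_free_line_recovered_exactly(self):
        t = np.linspace(0, 5, 11)
        tc = _toy_timecourse(t, 0.05e-6 * t, c0=5e-6)
        v = estimate_initial_velocity(tc)
        assert v.v0 == pytest.approx(0.05e-6, rel=1e-12)
        assert v.se == pytest.approx(0.0, abs=1e-18)

    def test_first_order_curve_within_2p5_percent(self):
        # truncated at 5% conversion the OLS slope stays within 2.5% of k*C0
        k, c0 = 0.01, 5e-6
        t = np.linspace(0, 4.8, 12)          # last point at 4.7% conversion
        tc = _toy_timecourse(t, c0 * (1 - np.exp(-k * t)), c0)
        v = estimate_initial_velocity(tc, max_conversion=0.05)
        # series expansion: OLS slope ~ k*C0*(1 - k*T/2), a ~2.4% shortfall
        assert v.v0 == pytest.approx(k * c0, rel=0.025)

    def test_sparse_early_sampling_advises_denser(self):
        t = np.array([0.0, 4.0, 8.0, 12.0, 16.0])
        tc = _toy_timecourse(t, 5e-6 * (1 - np.exp(-0.1 * t)), 5e-6)
        with pytest.raises(ValueError, match="densely"):
            estimate_initial_velocity(tc, max_conversion=0.10)

    def test_synthetic_triplicates_within_two_sd(self, study_params):
        from autocyclase import NoiseModel, generate_timecourses

        net = build_network(4, study_params, "drop")
        c0 = 5e-6
        data = generate_timecourses(net, study_params, [c0],
                                    np.linspace(0, 6, 13),
                                    NoiseModel(relative_sd=0.02, seed=3))
        v0s = [estimate_initial_velocity(tc).v0 for tc in data[c0]]
        truth = study_params.k_uni * c0 + study_params.k_bi * c0 ** 2
        sd = np.std(v0s, ddof=1)
        assert abs(np.mean(v0s) - truth) <= max(2 * sd, 0.05 * truth)


class TestVelocityFit:
    def test_pure_first_order(self):
        recs = [VelocityRecord(c, 0.01 * c) for c in (2.5e-6, 3.75e-6, 5e-6)]
        fit = fit_velocity_model(recs)
        assert fit.k1_hat == pytest.approx(0.01, rel=1e-9)
        assert fit.k2_hat == pytest.approx(0.0, abs=1e-6)

    def test_pure_second_order(self):
        recs = [VelocityRecord(c, 130.0 * c ** 2) for c in (10e-6, 15e-6, 20e-6)]
        fit = fit_velocity_model(recs)
        assert fit.k2_hat == pytest.approx(130.0, rel=1e-9)
        assert fit.k1_hat == pytest.approx(0.0, abs=1e-9)

    def test_null_data(self):
        fit = fit_velocity_model([VelocityRecord(c, 0.0) for c in (1e-6, 2e-6)])
        assert fit.k1_hat == 0.0 and fit.k2_hat == 0.0

    def test_identical_c0_ill_posed(self):
        with pytest.raises(ValueError, match="identifiable"):
            fit_velocity_model([VelocityRecord(5e-6, 1e-8),
                                VelocityRecord(5e-6, 2e-8)])

    @settings(derandomize=True, max_examples=60)
    @given(k1=st.floats(0.0, 1.0), k2=st.floats(0.0, 1e4))
    def test_noise_free_recovery_over_a_decade(self, k1, k2):
        grid = np.array([2e-6, 5e-6, 1e-5, 2e-5])
        recs = [VelocityRecord(c, k1 * c + k2 * c ** 2) for c in grid]
        fit = fit_velocity_model(recs)
        scale = max(k1, 1e-3)
        assert fit.k1_hat == pytest.approx(k1, rel=1e-6, abs=1e-6 * scale)
        assert fit.k2_hat == pytest.approx(k2, rel=1e-6, abs=1e-6 * max(k2, 1.0))


class TestRegime:
    @pytest.fixture()
    def study_fit(self):
        recs = [VelocityRecord(c, 0.01 * c + 130.0 * c ** 2)
                for c in (2.5e-6, 5e-6, 10e-6, 20e-6)]
        return fit_velocity_model(recs)

    def test_study_constants_regimes(self, study_fit):
        assert classify_regime(study_fit, 2.5e-6) == "unimolecular"
        assert classify_regime(study_fit, 5e-6) == "unimolecular"
        # 0.01 / (0.01 + 130 * 5e-6) = 0.9390
        assert study_fit.linear_fraction(5e-6) == pytest.approx(0.939, abs=1e-3)
        assert study_fit.linear_fraction(2.5e-6) >= 0.94
        # 0.01 / (0.01 + 130e-5) = 0.885
        assert study_fit.linear_fraction(10e-6) == pytest.approx(0.885, abs=1e-3)
        assert classify_regime(study_fit, 10e-6) == "mixed"

    def test_dilution_limit_is_unimolecular(self, study_fit):
        assert study_fit.linear_fraction(1e-12) > 0.999999
        assert classify_regime(study_fit, 1e-12) == "unimolecular"

    def test_labels_invariant_under_unit_rescaling(self, study_fit):
        # refit with concentrations expressed in mM instead of M
        recs = [VelocityRecord(r.c0 * 1e3, r.v0 * 1e3) for r in study_fit.records]
        refit = fit_velocity_model(recs)
        for r, s in zip(study_fit.records, refit.records):
            assert classify_regime(study_fit, r.c0) == classify_regime(refit, s.c0)


class TestBootstrap:
    def test_zero_noise_zero_width(self):
        recs = [VelocityRecord(c, 0.01 * c, replicates=(0.01 * c,) * 3)
                for c in (2.5e-6, 5e-6, 10e-6)]
        fit = bootstrap_confidence(recs, n_boot=200, seed=1)
        assert fit.ci_k1[0] == pytest.approx(fit.ci_k1[1], abs=1e-15)
        assert fit.ci_k1[0] == pytest.approx(fit.k1_hat, rel=1e-9)

    def test_coverage_at_two_percent_noise(self):
        """95% intervals cover the generating k1 in >= 90% of seeded
        synthetic experiments (ten replicates per concentration; with only
        three, percentile intervals undercover as expected for case
        resampling of tiny samples)."""
        rng = np.random.default_rng(12345)
        k1, k2 = 0.01, 130.0
        grid = np.array([2.5e-6, 5e-6, 10e-6, 20e-6])
        hits = 0
        n_exp = 200
        for _ in range(n_exp):
            recs = []
            for c in grid:
                truth = k1 * c + k2 * c ** 2
                reps = truth * rng.normal(1.0, 0.02, size=10)
                recs.append(VelocityRecord(c, float(np.mean(reps)),
                                           replicates=tuple(reps)))
            fit = bootstrap_confidence(recs, n_boot=300,
                                       seed=int(rng.integers(2 ** 31)))
            if fit.ci_k1[0] <= k1 <= fit.ci_k1[1]:
                hits += 1
        assert hits / n_exp >= 0.90

    def test_interval_width_shrinks_with_replicates(self):
        rng = np.random.default_rng(777)
        grid = np.array([2.5e-6, 5e-6, 10e-6, 20e-6])
        widths = []
        for n_rep in (3, 12):
            w = []
            for _ in range(25):
                recs = []
                for c in grid:
                    truth = 0.01 * c + 130.0 * c ** 2
                    reps = truth * rng.normal(1.0, 0.05, size=n_rep)
                    recs.append(VelocityRecord(c, float(np.mean(reps)),
                                               replicates=tuple(reps)))
                fit = bootstrap_confidence(recs, n_boot=200,
                                           seed=int(rng.integers(2 ** 31)))
                w.append(fit.ci_k1[1] - fit.ci_k1[0])
            widths.append(np.mean(w))
        assert widths[1] < widths[0]

    def test_too_few_draws_rejected(self):
        recs = [VelocityRecord(c, 0.01 * c) for c in (2e-6, 4e-6)]
        with pytest.raises(ValueError):
            bootstrap_confidence(recs, n_boot=1)
        with pytest.warns(UserWarning):
            bootstrap_confidence(recs, n_boot=50, seed=0)
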