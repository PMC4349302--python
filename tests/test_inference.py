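"""Prior, likelihood and MAP machinery."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from tgnkin.inference import (GaussianLikelihood, PriorSpec,
                              default_prior_box, initial_search_box,
                              log_likelihood, log_prior, log_tempered,
                              multistart_map, validate_dataset,
                              TemperedTarget)
from tgnkin.synth import NoiseSpec, generate_dataset


@pytest.fixture(scope="module")
def lik_a(model_a, dataset_a, protocol_map):
    data, _ = dataset_a
    return GaussianLikelihood(model_a, data, protocol_map)


@pytest.fixture(scope="module")
def x_truth(model_a, truth_a):
    return np.log10([truth_a[n] for n in model_a.parameter_names])


class TestLogPrior:
    def test_normalized_uniform_density(self):
        prior = PriorSpec({"a": (-3.0, 3.0)})
        assert log_prior([0.0], prior) == pytest.approx(-np.log(6.0))
        assert log_prior([2.9], prior) == pytest.approx(-np.log(6.0))

    def test_outside_box_is_minus_infinity(self):
        prior = PriorSpec({"a": (-3.0, 3.0), "b": (0.0, 1.0)})
        assert log_prior([0.0, 1.5], prior) == -np.inf
        assert log_prior([-4.0, 0.5], prior) == -np.inf

    def test_product_of_widths(self):
        prior = PriorSpec({"a": (0.0, 1.0), "b": (0.0, 2.0)})
        assert log_prior([0.5, 1.0], prior) == pytest.approx(-np.log(2.0))

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="lo < hi"):
            PriorSpec({"a": (1.0, 1.0)})


class TestLogLikelihood:
    def test_exact_predictions_leave_only_normalization(self, model_a, truth_a,
                                                        protocols,
                                                        protocol_map):
        """Zero-noise data are reproduced exactly, so logL is the Gaussian
        normalization sum alone (SDs supplied independently)."""
        noise = NoiseSpec(cv_absolute=0.0, rel_sd_frac=0.0, replicates=1,
                          allow_out_of_band_cv=True)
        data, _ = generate_dataset("A", truth_a, protocols, noise)
        data = data.assign(sd=1000.0)
        lik = GaussianLikelihood(model_a, data, protocol_map,
                                 rtol=1e-10, atol=1e-4)
        x = np.log10([truth_a[n] for n in model_a.parameter_names])
        expected = len(data) * (-0.5 * np.log(2 * np.pi * 1000.0 ** 2))
        assert lik(x) == pytest.approx(expected, abs=1e-2)

    def test_single_standard_normal_record(self):
        # one record, d=1, m=0, sigma=1 -> -0.5 log(2 pi) - 0.5
        const = -0.5 * np.log(2 * np.pi)
        assert const - 0.5 == pytest.approx(-1.41894, abs=1e-4)

    def test_profiled_scale_matches_grid_search(self, model_a, truth_a,
                                                protocol_map):
        """Profiling the blot gain in closed form equals brute-force
        optimization over the gain on a 3-point course."""
        from tgnkin.protocols import simulate
        times = [24.0, 24.5, 25.0]
        raw = simulate(model_a, truth_a,
                       protocol_map["E2"]).series("pPKD", times)
        d = raw * 1.8 + np.array([2e3, -3e3, 1e3])  # gain 1.8 plus noise
        sd = np.full(3, 5e3)
        course = pd.DataFrame({
            "experiment_id": "E2", "protocol_id": "E2", "observable": "pPKD",
            "mode": "relative", "time_h": times, "value": d, "sd": sd})
        lik = GaussianLikelihood(model_a, course, protocol_map)
        x = np.log10([truth_a[n] for n in model_a.parameter_names])
        ll_profiled = lik(x)
        scales = np.linspace(1.0, 3.0, 200001)
        grid = [np.sum(-0.5 * np.log(2 * np.pi * sd ** 2)
                       - (d - s * raw) ** 2 / (2 * sd ** 2)) for s in scales]
        assert ll_profiled == pytest.approx(max(grid), abs=1e-6)

    def test_duplicated_record_doubles_residual_contribution(
            self, model_a, x_truth, protocol_map, dataset_a):
        data, _ = dataset_a
        absolute = data[data["mode"] == "absolute"].reset_index(drop=True)
        lik1 = GaussianLikelihood(model_a, absolute, protocol_map)
        lik2 = GaussianLikelihood(
            model_a, pd.concat([absolute, absolute.iloc[[0]]],
                               ignore_index=True), protocol_map)
        row = absolute.iloc[0]
        pred = lik1.predict(x_truth)[0]
        contrib = (-0.5 * np.log(2 * np.pi * row.sd ** 2)
                   - (row.value - pred) ** 2 / (2 * row.sd ** 2))
        assert lik2(x_truth) - lik1(x_truth) == pytest.approx(contrib, rel=1e-6)

    def test_relative_course_gain_invariance(self, model_a, x_truth,
                                             protocol_map, dataset_a):
        """Rescaling a relative course's values and SDs together leaves the
        likelihood unchanged: profiling absorbs the gain."""
        data, _ = dataset_a
        rel = data[data["mode"] == "relative"].reset_index(drop=True)
        lik1 = GaussianLikelihood(model_a, rel, protocol_map)
        scaled = rel.assign(value=rel.value * 7.5, sd=rel.sd * 7.5)
        lik2 = GaussianLikelihood(model_a, scaled, protocol_map)
        # normalization shifts by -n log(7.5); the residual part is invariant
        shift = -len(rel) * np.log(7.5)
        assert lik2(x_truth) - lik1(x_truth) == pytest.approx(shift, rel=1e-9)

    def test_failed_simulation_returns_minus_inf(self, lik_a, model_a):
        wild = np.full(model_a.n_parameters, 8.0)  # absurdly fast everything
        assert lik_a(wild) == -np.inf
        assert lik_a.n_failed >= 1

    def test_sd_contract_enforced(self, model_a, dataset_a, protocol_map):
        data, _ = dataset_a
        bad = data.copy()
        bad.loc[0, "sd"] = 0.0
        with pytest.raises(ValueError, match="standard deviation"):
            validate_dataset(bad)

    def test_wrapper_equals_evaluator(self, model_a, dataset_a, protocols,
                                      x_truth, lik_a):
        data, _ = dataset_a
        assert log_likelihood(x_truth, data, model_a, protocols) == \
            pytest.approx(lik_a(x_truth))


class TestTempered:
    def test_beta_endpoints(self, lik_a, model_a, x_truth):
        prior = default_prior_box(model_a, x_truth)
        t0 = TemperedTarget(lik_a, prior, 0.0)
        t1 = TemperedTarget(lik_a, prior, 1.0)
        lp = log_prior(x_truth, prior, model_a.parameter_names)
        assert log_tempered(x_truth, t0) == pytest.approx(lp)
        assert log_tempered(x_truth, t1) == \
            pytest.approx(lp + lik_a(x_truth))

    def test_linear_in_beta(self, lik_a, model_a, x_truth):
        prior = default_prior_box(model_a, x_truth)
        lp = log_prior(x_truth, prior, model_a.parameter_names)
        ll = lik_a(x_truth)
        for beta in (0.25, 0.5, 0.75):
            t = TemperedTarget(lik_a, prior, beta)
            assert log_tempered(x_truth, t) == pytest.approx(lp + beta * ll)

    def test_invalid_beta_rejected(self, lik_a, model_a, x_truth):
        prior = default_prior_box(model_a, x_truth)
        with pytest.raises(ValueError, match="beta"):
            TemperedTarget(lik_a, prior, 1.5)


class TestPriorBoxes:
    def test_default_box_centered_with_physical_clamps(self, model_a, x_truth):
        prior = default_prior_box(model_a, x_truth)
        lo, hi = prior.arrays(model_a.parameter_names)
        assert np.all(lo < hi)
        for name, l, h in zip(model_a.parameter_names, lo, hi):
            if name.startswith("d_"):
                # half-lives within 1-100 h
                assert 10 ** l >= np.log(2) / 100 - 1e-12
                assert 10 ** h <= np.log(2) / 1 + 1e-12
            else:
                c = x_truth[list(model_a.parameter_names).index(name)]
                assert l >= c - 3 - 1e-12 and h <= c + 3 + 1e-12

    def test_search_box_covers_ground_truth(self, model_a, model_b, truth_a,
                                            truth_b):
        for m, gt in ((model_a, truth_a), (model_b, truth_b)):
            lo, hi = initial_search_box(m).arrays(m.parameter_names)
            x = np.log10([gt[n] for n in m.parameter_names])
            assert np.all(x >= lo) and np.all(x <= hi)


class TestMultistartMap:
    def _quadratic_setup(self):
        center = np.array([0.7, -1.2])
        prior = PriorSpec({"a": (-3.0, 3.0), "b": (-3.0, 3.0)})
        lik = lambda x: -0.5 * float(np.sum((np.asarray(x) - center) ** 2))
        model = SimpleNamespace(parameter_names=("a", "b"))
        return model, prior, lik, center

    def test_finds_analytic_optimum(self):
        model, prior, lik, center = self._quadratic_setup()
        ranked = multistart_map(model, None, prior, n_starts=5, seed=2,
                                likelihood=lik)
        np.testing.assert_allclose(ranked[0][0], center, atol=1e-4)

    def test_start_at_optimum_is_fixed_point(self):
        model, _, lik, center = self._quadratic_setup()
        # a vanishingly tight box pins the single start to the optimum
        tight = PriorSpec({"a": (center[0] - 1e-9, center[0] + 1e-9),
                           "b": (center[1] - 1e-9, center[1] + 1e-9)})
        ranked = multistart_map(model, None, tight, n_starts=1, seed=0,
                                likelihood=lik)
        np.testing.assert_allclose(ranked[0][0], center, atol=1e-6)

    def test_deterministic_given_seed(self):
        model, prior, lik, _ = self._quadratic_setup()
        r1 = multistart_map(model, None, prior, n_starts=4, seed=9,
                            likelihood=lik)
        r2 = multistart_map(model, None, prior, n_starts=4, seed=9,
                            likelihood=lik)
        for (x1, l1), (x2, l2) in zip(r1, r2):
            assert np.array_equal(x1, x2) and l1 == l2

    def test_results_sorted_descending(self):
        model, prior, lik, _ = self._quadratic_setup()
        ranked = multistart_map(model, None, prior, n_starts=6, seed=1,
                                likelihood=lik)
        lps = [lp for _, lp in ranked]
        assert lps == sorted(lps, reverse=True)
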