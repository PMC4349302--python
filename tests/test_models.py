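"""Structure and dynamics of the two kinetic model variants."""

import numpy as np
import pytest
import scipy.integrate

from tgnkin import _ode
from tgnkin.models import (build_model, reaction_fluxes, rhs,
                           steady_state, transfer_flux, model_to_json,
                           model_from_json)

from conftest import tiny_params


def hand_balance(variant, x, p, u):
    """Independent flux-balance oracle: every reaction written out symbol by
    symbol, separately from the package's reaction table."""
    PKD, PKDp, PI4K, PI4Kp, c4, c5, c6 = x
    g = 1.0 / (1.0 + p["k_inh"] * u[1])
    J = p["k10"] * c6
    r1 = g * p["vmax1"] * PKDp / (p["K1E"] + PKDp) * PI4K / (p["K1S"] + PI4K)
    dp = p["kdp_PI4K"] * PI4Kp
    r3 = g * p["vmax3"] * PKDp / (p["K3E"] + PKDp) * c6 / (p["K3S"] + c6)
    r9 = p["k9"] * c4
    r5 = p["vmax5"] * PI4Kp / (p["K5E"] + PI4Kp) * c5 / (p["K5S"] + c5)
    ab = g * p["k_act"] * PKD
    ac = p["vmax_cer"] * J / (p["K_cer"] + J)
    ap = g * u[0] * p["k_pdbu"] * PKD
    de = p["k_deact"] * PKDp
    sC = p["s_CERT"] + u[3] * p["s_ect_CERT"]
    d = [p["d_PKD"], p["d_PI4K"], p["d_CERT"]]
    out = np.empty(7)
    out[0] = p["s_PKD"] + de - ab - ac - ap - d[0] * PKD
    out[1] = ab + ac + ap - de - d[0] * PKDp
    out[2] = p["s_PI4K"] + u[2] * p["s_ect_PI4K"] + dp - r1 - d[1] * PI4K
    out[3] = r1 - dp - d[1] * PI4Kp
    if variant == "A":
        out[4] = r3 - r9 - d[2] * c4
        out[5] = sC + r9 - r5 - d[2] * c5
        out[6] = r5 - r3 - d[2] * c6
    else:
        pf = g * p["k_phos_free"] * PKDp * c5
        out[4] = r3 + pf - r9 - d[2] * c4
        out[5] = sC + r9 - r5 - pf - d[2] * c5
        out[6] = r5 - r3 - d[2] * c6
    return out


class TestStructure:
    def test_seven_species_both_variants(self, model_a, model_b):
        assert model_a.n_species == 7
        assert model_b.n_species == 7

    def test_parameter_counts(self, model_a, model_b):
        assert model_a.n_parameters == 26
        assert model_b.n_parameters == 27

    def test_species_differ_exactly_in_cert_states(self, model_a, model_b):
        a, b = set(model_a.species_names), set(model_b.species_names)
        assert a - b == {"CERTpER", "CERTaER", "CERTaTGN"}
        assert b - a == {"CERTp", "CERTa", "CERTaERTGN"}
        assert a & b == {"PKD", "PKDpDAG", "PI4K", "PI4Kp"}

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown model variant"):
            build_model("C")

    def test_every_parameter_used(self, model_a, model_b):
        for m in (model_a, model_b):
            used = set()
            for r in m.reaction_specs:
                used.update(r.parameters)
            assert used == set(m.parameter_names)

    def test_json_round_trip(self, model_a):
        doc = model_to_json(model_a)
        again = model_from_json(doc)
        assert again.species_names == model_a.species_names
        assert again.parameter_names == model_a.parameter_names


class TestRhs:
    def test_empty_system_is_static(self, model_a):
        p = tiny_params(model_a)
        dx = rhs(model_a, np.zeros(7), 0.0, p)
        assert np.all(np.abs(dx) < 1e-290)

    def test_pure_decay_term(self, model_a):
        p = tiny_params(model_a, d_PKD=0.07)
        x = np.zeros(7)
        x[0] = 1234.5
        dx = rhs(model_a, x, 0.0, p)
        assert dx[0] == pytest.approx(-0.07 * 1234.5, rel=1e-12)

    @pytest.mark.parametrize("variant", ["A", "B"])
    @pytest.mark.parametrize("u", [np.zeros(4), np.array([1.0, 0.5, 1.0, 0.3])])
    def test_matches_hand_summed_flux_balance(self, variant, u, truth_a, truth_b):
        model = build_model(variant)
        p = dict(truth_a if variant == "A" else truth_b)
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.uniform(0, 1e6, 7)
            got = rhs(model, x, 0.0, p, u)
            want = hand_balance(variant, x, p, u)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_fast_kernel_agrees_with_reaction_table(self, variant, truth_a,
                                                    truth_b):
        model = build_model(variant)
        gt = truth_a if variant == "A" else truth_b
        theta = model.params_array(gt)
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.uniform(0, 1e6, 7)
            u = rng.uniform(0, 1, 4)
            got = _ode.rhs_kernel(model._variant_id, x, theta, u)
            want = rhs(model, x, 0.0, gt, u)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-10)

    def test_negative_state_rejected(self, model_a, truth_a):
        x = np.zeros(7)
        x[2] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            rhs(model_a, x, 0.0, truth_a)


class TestReactionFluxes:
    def test_zero_regulator_silences_regulated_reaction(self, model_a, truth_a):
        x = np.full(7, 1e5)
        x[1] = 0.0  # no active PKD
        fluxes = reaction_fluxes(model_a, x, truth_a)
        assert fluxes["R1"] == 0.0
        assert fluxes["R3"] == 0.0

    def test_saturation_limit_is_vmax(self, model_a, truth_a):
        x = np.full(7, 1e14)  # everything far above every K
        fluxes = reaction_fluxes(model_a, x, truth_a)
        assert fluxes["R1"] == pytest.approx(truth_a["vmax1"], rel=1e-6)
        assert fluxes["R5"] == pytest.approx(truth_a["vmax5"], rel=1e-6)

    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_all_fluxes_nonnegative_and_bounded(self, variant, truth_a, truth_b):
        model = build_model(variant)
        gt = truth_a if variant == "A" else truth_b
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.uniform(0, 1e7, 7)
            fluxes = reaction_fluxes(model, x, gt, rng.uniform(0, 1, 4))
            assert all(v >= 0 for v in fluxes.values())
            for rid, pname in [("R1", "vmax1"), ("R3", "vmax3"),
                               ("R5", "vmax5"), ("PKD_act_cer", "vmax_cer")]:
                assert fluxes[rid] <= gt[pname] * (1 + 1e-12)

    def test_stoichiometric_reassembly_equals_rhs(self, model_a, truth_a):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1e6, 7)
        fluxes = reaction_fluxes(model_a, x, truth_a)
        idx = {n: i for i, n in enumerate(model_a.species_names)}
        dx = np.zeros(7)
        for r in model_a.reaction_specs:
            if r.substrate is not None:
                dx[idx[r.substrate]] -= fluxes[r.rid]
            if r.product is not None:
                dx[idx[r.product]] += fluxes[r.rid]
        np.testing.assert_allclose(dx, rhs(model_a, x, 0.0, truth_a),
                                   rtol=1e-12, atol=1e-12)


class TestTransferFlux:
    def test_linear_law(self, model_a, truth_a):
        x = np.zeros(7)
        x[6] = 100.0  # CERTaTGN
        p = dict(truth_a, k10=2.0)
        assert transfer_flux(model_a, x, p) == pytest.approx(200.0)
        x[6] = 0.0
        assert transfer_flux(model_a, x, p) == 0.0

    def test_variant_b_uses_double_bound_pool(self, model_b, truth_b):
        x = np.zeros(7)
        x[6] = 50.0  # CERTaERTGN
        p = dict(truth_b, k10=0.5)
        assert transfer_flux(model_b, x, p) == pytest.approx(25.0)


class TestIntegratorAgainstScipy:
    """Dual-route check: the jitted stepper versus scipy.integrate."""

    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_transient_states_match_solve_ivp(self, variant, truth_a, truth_b):
        model = build_model(variant)
        gt = truth_a if variant == "A" else truth_b
        theta = model.params_array(gt)
        u = np.array([0.0, 0.0, 1.0, 0.0])  # ectopic expression transient
        x0 = steady_state(model, gt)
        t_eval = np.array([0.5, 2.0, 8.0, 24.0])
        out, _, status = _ode.integrate_segment(
            model._variant_id, x0, theta, u, 0.0, 24.0, t_eval, 1e-10, 1e-6,
            200_000)
        assert status == _ode.OK
        sol = scipy.integrate.solve_ivp(
            lambda t, x: _ode.rhs_kernel(model._variant_id, x, theta, u),
            (0.0, 24.0), x0, t_eval=t_eval, method="LSODA", rtol=1e-10,
            atol=1e-6)
        np.testing.assert_allclose(out, sol.y.T, rtol=1e-5, atol=1e-3)


class TestSteadyState:
    def test_turnover_only_balance(self, model_a):
        p = tiny_params(model_a, s_PKD=2.5e4, d_PKD=0.05,
                        s_PI4K=1e5, d_PI4K=0.1, s_CERT=1e4, d_CERT=0.02)
        x = steady_state(model_a, p)
        assert x[0] == pytest.approx(2.5e4 / 0.05, rel=1e-6)
        assert x[2] == pytest.approx(1e5 / 0.1, rel=1e-6)
        assert x[4] + x[5] + x[6] == pytest.approx(1e4 / 0.02, rel=1e-6)

    def test_doubling_synthesis_doubles_turnover_totals(self, model_a):
        base = dict(s_PKD=2.5e4, d_PKD=0.05, s_PI4K=1e5, d_PI4K=0.1,
                    s_CERT=1e4, d_CERT=0.02)
        x1 = steady_state(model_a, tiny_params(model_a, **base))
        doubled = dict(base, s_PKD=5e4, s_PI4K=2e5, s_CERT=2e4)
        x2 = steady_state(model_a, tiny_params(model_a, **doubled))
        np.testing.assert_allclose(x2[:4], 2 * x1[:4], rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_residual_below_tolerance_at_ground_truth(self, variant, truth_a,
                                                      truth_b):
        model = build_model(variant)
        gt = truth_a if variant == "A" else truth_b
        x = steady_state(model, gt, tol_ss=1e-6)
        dx = rhs(model, x, 0.0, gt)
        assert np.max(np.abs(dx)) <= 1e-6

    def test_nonconvergence_raises_with_residual(self, model_a, truth_a):
        with pytest.raises(RuntimeError, match="residual"):
            steady_state(model_a, truth_a, t_relax=1e-9, polish=False)


class TestConservationAndSigns:
    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_totals_conserved_without_turnover(self, variant, truth_a, truth_b):
        """With synthesis and degradation off, each protein's total is a
        conserved quantity along any trajectory."""
        model = build_model(variant)
        gt = dict(truth_a if variant == "A" else truth_b)
        for name in ("s_PKD", "s_PI4K", "s_CERT", "s_ect_PI4K", "s_ect_CERT",
                     "d_PKD", "d_PI4K", "d_CERT"):
            gt[name] = 1e-300
        theta = model.params_array(gt)
        rng = np.random.default_rng(5)
        x0 = rng.uniform(1e4, 1e6, 7)
        out, _, status = _ode.integrate_segment(
            model._variant_id, x0, theta, np.zeros(4), 0.0, 50.0,
            np.array([10.0, 50.0]), 1e-10, 1e-6, 200_000)
        assert status == _ode.OK
        for x in out:
            assert x[0] + x[1] == pytest.approx(x0[0] + x0[1], rel=1e-8)
            assert x[2] + x[3] == pytest.approx(x0[2] + x0[3], rel=1e-8)
            assert x[4:].sum() == pytest.approx(x0[4:].sum(), rel=1e-8)

    def test_trajectories_stay_nonnegative(self, model_a, truth_a):
        theta = model_a.params_array(truth_a)
        rng = np.random.default_rng(9)
        for _ in range(5):
            x0 = rng.uniform(0, 1e6, 7)
            out, _, status = _ode.integrate_segment(
                model_a._variant_id, x0, theta,
                np.array([1.0, 0.0, 1.0, 1.0]), 0.0, 30.0,
                np.linspace(1, 30, 10), 1e-8, 0.1, 100_000)
            assert status == _ode.OK
            assert np.all(out >= -1e-9)

    def test_positive_feedback_sign_variant_a(self, model_a, truth_a):
        """Raising the transfer rate constant raises steady-state active PKD."""
        x0 = steady_state(model_a, truth_a)
        up = dict(truth_a, k10=truth_a["k10"] * 1.2)
        x1 = steady_state(model_a, up)
        assert x1[1] > x0[1]

    def test_negative_feedback_sign_variant_b(self, model_b, truth_b):
        """Raising basal PKD activation lowers steady-state ceramide transfer."""
        x0 = steady_state(model_b, truth_b)
        up = dict(truth_b, k_act=truth_b["k_act"] * 1.2)
        x1 = steady_state(model_b, up)
        assert transfer_flux(model_b, x1, up) < transfer_flux(model_b, x0, truth_b)
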