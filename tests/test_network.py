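"""Unit and property tests for the single-cell metabolic-redox network."""

import copy
import math

import numpy as np
import pytest

from biosos.network import (
    CultureCondition,
    GrowthRate,
    MetaboliteSpec,
    NetworkModel,
    NetworkValidationError,
    RateLaw,
    Reaction,
    Trajectory,
    apply_perturbation,
    default_network_config,
    evaluate_all_fluxes,
    glns_flux,
    ldh_flux,
    load_network,
    redox_ratio,
    save_network,
    simulate_monolayer,
    specific_rate,
)

# ---------------------------------------------------------------------------
# network loading and validation
# ---------------------------------------------------------------------------


class TestLoadNetwork:
    def test_default_network_has_29_reactions(self, model):
        assert len(model.reactions) == 29
        assert sum(1 for r in model.reactions if r.tag == "biomass") == 1

    def test_all_schematic_metabolites_present(self, model):
        expected = {
            "EGLC", "ELAC", "EPYR", "EGLN", "EGLU", "EALA", "ENH4", "ESER",
            "EVAL", "ELEU", "EILE", "EPRO", "PYR", "LAC", "CIT", "AKG",
            "NAD", "NADH", "FAD", "FADH2",
        }
        assert expected <= set(model.species_ids)

    def test_cofactor_creation_without_consumption_rejected(self):
        cfg = default_network_config()
        bad = {
            "id": "BADRX",
            "stoichiometry": {"NADH": 1, "PYR": -1, "LAC": 1},
            "rate_law": {"vmax_f": 1.0},
        }
        cfg["reactions"].insert(0, bad)
        with pytest.raises(NetworkValidationError, match="NAD/NADH"):
            load_network(cfg)

    def test_carbon_unbalanced_reaction_named_in_error(self):
        cfg = default_network_config()
        bad = {
            "id": "LEAKY",
            "stoichiometry": {"PYR": -1, "LAC": 1, "CO2": 1},
            "rate_law": {"vmax_f": 1.0},
        }
        cfg["reactions"].insert(0, bad)
        with pytest.raises(NetworkValidationError, match="LEAKY"):
            load_network(cfg)

    def test_unknown_metabolite_rejected(self):
        cfg = default_network_config()
        cfg["reactions"][0]["stoichiometry"]["XYZZY"] = 1.0
        with pytest.raises(NetworkValidationError, match="XYZZY"):
            load_network(cfg)

    def test_empty_reaction_list_means_no_biomass(self):
        cfg = default_network_config()
        cfg["reactions"] = []
        with pytest.raises(NetworkValidationError, match="no biomass reaction"):
            load_network(cfg)

    def test_yaml_round_trip(self, model, tmp_path):
        path = str(tmp_path / "net.yaml")
        save_network(model, path)
        again = load_network(path)
        assert again.reaction_ids == model.reaction_ids
        assert again.species_ids == model.species_ids
        np.testing.assert_allclose(
            again.stoichiometric_matrix(), model.stoichiometric_matrix()
        )
        for a, b in zip(again.reactions, model.reactions):
            assert a.rate_law.vmax_f == pytest.approx(b.rate_law.vmax_f)
            assert a.rate_law.saturation_factors == list(
                map(tuple, b.rate_law.saturation_factors)
            )


# ---------------------------------------------------------------------------
# printed rate laws
# ---------------------------------------------------------------------------


def _ldh_params(vf=2.0, vr=0.5):
    return RateLaw(
        vmax_f=vf,
        vmax_r=vr,
        saturation_factors=[("PYR", 0.25)],
        ratio_factors=[(("NADH", "NAD"), 0.15)],
        inhibition_factors=[("EPYR", 2.0)],
        rev_saturation_factors=[("LAC", 1.5)],
        rev_ratio_factors=[(("NAD", "NADH"), 3.0)],
    )


class TestLdhFlux:
    def test_zero_substrates_zero_flux(self):
        state = {"PYR": 0.0, "LAC": 0.0, "NAD": 0.5, "NADH": 0.5, "EPYR": 0.0}
        assert ldh_flux(state, _ldh_params()) == pytest.approx(0.0)

    def test_infinite_pyruvate_kills_forward_component(self):
        p = _ldh_params()
        state = {"PYR": 1.0, "LAC": 1.0, "NAD": 0.5, "NADH": 0.5, "EPYR": 1e12}
        rev_only = {"PYR": 0.0, "LAC": 1.0, "NAD": 0.5, "NADH": 0.5, "EPYR": 0.0}
        assert ldh_flux(state, p) == pytest.approx(ldh_flux(rev_only, p), rel=1e-6)

    def test_half_saturation_hand_value(self):
        # every factor at its half-saturation point: vf/8 - vr/4
        p = _ldh_params(vf=2.0, vr=0.5)
        state = {
            "PYR": 0.25,
            "LAC": 1.5,
            "NADH": 0.15,
            "NAD": 1.0,  # NADH/NAD = 0.15 = its Km
            "EPYR": 2.0,
        }
        # reverse ratio NAD/NADH = 1/0.15 != its Km: rebuild so both ratios sit
        # at half saturation simultaneously via the ratio Kms
        p.ratio_factors = [(("NADH", "NAD"), 0.15)]
        p.rev_ratio_factors = [(("NAD", "NADH"), 1.0 / 0.15)]
        expected = 2.0 / 8 - 0.5 / 4
        assert ldh_flux(state, p) == pytest.approx(expected, rel=1e-12)

    def test_forward_strictly_decreasing_in_epyr(self):
        p = _ldh_params(vr=0.0)
        vals = [
            ldh_flux({"PYR": 1.0, "LAC": 0.0, "NAD": 0.5, "NADH": 0.5, "EPYR": e}, p)
            for e in (0.0, 1.0, 4.0, 20.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_zero_cofactor_raises(self):
        with pytest.raises(ValueError, match="NAD"):
            ldh_flux({"PYR": 1, "LAC": 1, "NAD": 0.0, "NADH": 0.5, "EPYR": 0}, _ldh_params())


def _glns_params(vf=1.0, vr=0.4):
    return RateLaw(
        vmax_f=vf,
        vmax_r=vr,
        saturation_factors=[("GLN", 1.0)],
        inhibition_factors=[("EPYR", 2.0)],
        rev_saturation_factors=[("GLU", 4.0), ("NH4", 1.0)],
    )


class TestGlnsFlux:
    def test_zero_substrates_zero_flux(self):
        state = {"GLN": 0.0, "GLU": 0.0, "NH4": 1.0, "EPYR": 0.0}
        assert glns_flux(state, _glns_params()) == pytest.approx(0.0)

    def test_half_saturation_no_inhibition(self):
        p = _glns_params(vf=1.0, vr=0.0)
        state = {"GLN": 1.0, "GLU": 0.0, "NH4": 0.0, "EPYR": 0.0}
        assert glns_flux(state, p) == pytest.approx(0.5)

    def test_all_half_saturated_hand_value(self):
        p = _glns_params(vf=1.0, vr=0.4)
        state = {"GLN": 1.0, "EPYR": 2.0, "GLU": 4.0, "NH4": 1.0}
        assert glns_flux(state, p) == pytest.approx(1.0 / 4 - 0.4 / 4, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            glns_flux({"GLN": -1.0, "GLU": 0, "NH4": 0, "EPYR": 0}, _glns_params())


# ---------------------------------------------------------------------------
# whole-network flux evaluation
# ---------------------------------------------------------------------------


class TestEvaluateAllFluxes:
    def _state(self, model, **overrides):
        s = {k: 0.0 for k in model.species_ids}
        s.update(model.initial_intracellular)
        s.update(overrides)
        return s

    def test_zero_intracellular_pools_zero_internal_fluxes(self, model):
        state = {k: 0.0 for k in model.species_ids}
        state.update({"EGLC": 10.0, "EGLN": 2.0, "EPYR": 1.0, "EVAL": 0.4})
        v = evaluate_all_fluxes(model, state)
        for r in model.reactions:
            if r.tag not in ("transport",):
                assert v[r.id] == pytest.approx(0.0), r.id

    def test_anoxia_zeroes_oxphos(self, model):
        state = self._state(model, EGLC=10.0, EGLN=2.0)
        v = evaluate_all_fluxes(model, state, oxygen_level=0.0)
        assert v["OXPHOS_NADH"] == 0.0
        assert v["OXPHOS_FADH2"] == 0.0
        v1 = evaluate_all_fluxes(model, state, oxygen_level=1.0)
        assert v1["OXPHOS_NADH"] > 0.0

    def test_lactate_inhibits_glucose_uptake(self, model):
        lo = evaluate_all_fluxes(model, self._state(model, EGLC=10.0, ELAC=0.0))
        hi = evaluate_all_fluxes(model, self._state(model, EGLC=10.0, ELAC=20.0))
        assert hi["GLYC"] < lo["GLYC"]

    def test_missing_species_raises(self, model):
        with pytest.raises(KeyError):
            evaluate_all_fluxes(model, {"EGLC": 1.0})

    def test_vectorized_matches_scalar(self, model):
        rng = np.random.default_rng(0)
        states = rng.uniform(0.01, 2.0, size=(len(model.species_ids), 5))
        vec = evaluate_all_fluxes(model, states)
        for k in range(5):
            one = evaluate_all_fluxes(model, states[:, k])
            np.testing.assert_allclose(vec[:, k], one, rtol=1e-12)


# ---------------------------------------------------------------------------
# monolayer simulation
# ---------------------------------------------------------------------------


class TestSimulateMonolayer:
    def test_no_cells_no_change(self, model):
        cond = CultureCondition(
            initial_concentrations={"EGLC": 10.0, "EGLN": 2.0},
            initial_vcd=0.0,
        )
        traj = simulate_monolayer(model, cond, np.linspace(0, 48, 5))
        drift = np.abs(traj.extracellular - traj.extracellular[0]).max()
        assert drift < 1e-7

    def test_deterministic(self, model, hgll_condition):
        t = np.linspace(0, 48, 5)
        a = simulate_monolayer(model, hgll_condition, t)
        b = simulate_monolayer(model, hgll_condition, t)
        assert np.array_equal(a.extracellular, b.extracellular)
        assert np.array_equal(a.vcd, b.vcd)

    def test_pyruvate_lowers_glucose_and_glutamine_consumption(
        self, model, hgll_condition, hgll_trajectory
    ):
        cond = copy.deepcopy(hgll_condition)
        cond.initial_concentrations["EPYR"] += 4.0
        traj_p = simulate_monolayer(model, cond, hgll_trajectory.times)
        dglc = lambda tr: tr.conc("EGLC")[0] - tr.conc("EGLC")[-1]
        dgln = lambda tr: tr.conc("EGLN")[0] - tr.conc("EGLN")[-1]
        assert dglc(traj_p) < dglc(hgll_trajectory)
        assert dgln(traj_p) < dgln(hgll_trajectory)

    def test_cofactor_totals_conserved(self, hgll_trajectory):
        nad = hgll_trajectory.conc("NAD") + hgll_trajectory.conc("NADH")
        fad = hgll_trajectory.conc("FAD") + hgll_trajectory.conc("FADH2")
        np.testing.assert_allclose(nad, nad[0], rtol=1e-5)
        np.testing.assert_allclose(fad, fad[0], rtol=1e-5)

    def test_concentrations_stay_nonnegative(self, hgll_trajectory):
        assert hgll_trajectory.extracellular.min() >= -1e-7
        assert hgll_trajectory.intracellular.min() >= -1e-7

    def test_times_outside_duration_rejected(self, model, hgll_condition):
        with pytest.raises(ValueError):
            simulate_monolayer(model, hgll_condition, [0, 47, 72])


class TestOdeOracle:
    """Stiff-solver trajectory vs Richardson-extrapolated fixed-step RK4."""

    @staticmethod
    def _toy_model():
        mets = [
            MetaboliteSpec("EA", "extracellular", 1),
            MetaboliteSpec("A", "intracellular", 1),
            MetaboliteSpec("B", "intracellular", 1),
        ]
        rxns = [
            Reaction(
                "T1",
                {"EA": -1, "A": 1},
                RateLaw(vmax_f=0.5, saturation_factors=[("EA", 1.0)]),
                tag="transport",
            ),
            Reaction(
                "R2",
                {"A": -1, "B": 1},
                RateLaw(vmax_f=0.8, saturation_factors=[("A", 0.5)]),
            ),
            Reaction(
                "BIO",
                {"B": -1},
                RateLaw(vmax_f=1.0, saturation_factors=[("B", 0.01)]),
                tag="biomass",
            ),
        ]
        m = NetworkModel(
            metabolites=mets,
            reactions=rxns,
            biomass={"B": 1.0},
            growth=GrowthRate(mu_max=0.05, monod=[("EA", 1.0)]),
            initial_intracellular={"A": 0.2, "B": 0.1},
        )
        m.validate()
        return m

    def test_solver_matches_rk4_richardson(self):
        model = self._toy_model()
        cond = CultureCondition(
            initial_concentrations={"EA": 5.0}, initial_vcd=1e5, duration_h=24
        )
        traj = simulate_monolayer(
            model, cond, np.linspace(0, 24, 7), rtol=1e-10, atol=1e-12
        )

        ck = model.compiled()
        S_ext = ck.S[ck.ext_rows, :]
        S_int = ck.S[ck.int_rows, :]

        def rhs(y):
            full = np.empty(3)
            full[ck.ext_rows] = y[1:2]
            full[ck.int_rows] = y[2:]
            v = ck.fluxes(full)
            return np.concatenate(
                (
                    [ck.growth_rate(full) * y[0]],
                    S_ext @ v * y[0] * 1e-6,
                    S_int @ v,
                )
            )

        def rk4(y0, t_end, n):
            h = t_end / n
            y = np.array(y0, dtype=float)
            for _ in range(n):
                k1 = rhs(y)
                k2 = rhs(y + h / 2 * k1)
                k3 = rhs(y + h / 2 * k2)
                k4 = rhs(y + h * k3)
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            return y

        y0 = np.array([1e5, 5.0, 0.2, 0.1])
        coarse = rk4(y0, 24.0, 400)
        fine = rk4(y0, 24.0, 800)
        richardson = (16 * fine - coarse) / 15.0
        solver_end = np.concatenate(
            ([traj.vcd[-1]], traj.extracellular[-1], traj.intracellular[-1])
        )
        np.testing.assert_allclose(solver_end, richardson, rtol=1e-6)


# ---------------------------------------------------------------------------
# redox ratio and specific rates
# ---------------------------------------------------------------------------


class TestRedoxRatio:
    def test_fully_oxidized(self):
        assert redox_ratio({"NAD": 1.0, "NADH": 0.0}) == 1.0

    def test_balanced(self):
        assert redox_ratio({"NAD": 0.3, "NADH": 0.3}) == pytest.approx(0.5)

    def test_optical_arithmetic(self):
        assert redox_ratio({"FAD": 2.0, "NADH": 6.0}, "optical") == pytest.approx(0.25)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            redox_ratio({"NAD": 0.0, "NADH": 0.0})

    def test_unknown_modality(self):
        with pytest.raises(ValueError):
            redox_ratio({"NAD": 1, "NADH": 1}, "impedance")


def _make_traj(times, vcd, conc, species="EGLC"):
    times = np.asarray(times, dtype=float)
    return Trajectory(
        times=times,
        vcd=np.asarray(vcd, dtype=float),
        ext_ids=[species],
        extracellular=np.asarray(conc, dtype=float).reshape(-1, 1),
        int_ids=[],
        intracellular=np.zeros((len(times), 0)),
        reaction_ids=[],
        fluxes=np.zeros((len(times), 0)),
    )


class TestSpecificRate:
    def test_constant_concentration_zero_rate(self):
        traj = _make_traj([0, 24, 48], [1e5, 2e5, 4e5], [5, 5, 5])
        assert specific_rate(traj, "EGLC") == pytest.approx(0.0)

    def test_constant_vcd_collapses_to_linear_form(self):
        X0, dC, dt = 2e5, 1.2, 24.0
        traj = _make_traj([0, dt], [X0, X0], [5.0, 5.0 - dC])
        expected = dC / (X0 * dt * 1e-6)
        assert specific_rate(traj, "EGLC") == pytest.approx(expected, rel=1e-9)

    def test_exponential_vcd_log_mean_form(self):
        X0, dt = 1e5, 24.0
        mu = math.log(2) / dt  # one doubling
        dC = 0.9
        traj = _make_traj([0, dt], [X0, 2 * X0], [4.0, 4.0 - dC])
        expected = dC * mu / (X0 * (math.exp(mu * dt) - 1) * 1e-6)
        assert specific_rate(traj, "EGLC") == pytest.approx(expected, rel=1e-9)

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            _make_traj([0, 10, 5], [1, 1, 1], [1, 1, 1])


# ---------------------------------------------------------------------------
# perturbations and redox dynamics
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def perturb_base():
    return CultureCondition(
        initial_concentrations={"EGLC": 18.3, "EGLN": 2.7},
        initial_vcd=3.2e4,
        duration_h=48.0,
    )


class TestPerturbations:
    def test_normal_is_identity(self, perturb_base):
        out = apply_perturbation(perturb_base, "normal")
        assert out.initial_concentrations == perturb_base.initial_concentrations
        assert out.oxygen_schedule is None

    def test_hypoxia_schedule_piecewise(self, perturb_base):
        out = apply_perturbation(perturb_base, "hypoxia", (8.0, 24.0))
        assert out.oxygen_at(4.0) == 1.0
        assert out.oxygen_at(10.0) == 0.0
        assert out.oxygen_at(30.0) == 1.0

    def test_unknown_kind(self, perturb_base):
        with pytest.raises(ValueError):
            apply_perturbation(perturb_base, "caffeine")

    def test_starvation_raises_redox_ratio(self, model, perturb_base):
        times = np.linspace(0, 48, 25)
        normal = simulate_monolayer(model, perturb_base, times)
        starved = simulate_monolayer(
            model, apply_perturbation(perturb_base, "glucose_starvation"), times
        )
        base = redox_ratio(normal.state_at(0.0))
        end = redox_ratio(starved.state_at(48.0))
        assert end > base

    def test_hypoxia_sharp_decline_and_recovery(self, model, perturb_base):
        cond = apply_perturbation(perturb_base, "hypoxia", (8.0, 24.0))
        times = np.linspace(0, 48, 97)
        traj = simulate_monolayer(model, cond, times)
        rr = np.array([redox_ratio(traj.state_at(t)) for t in times])
        i_on = np.searchsorted(times, 8.0)
        i_off = np.searchsorted(times, 24.0)
        baseline = rr[i_on - 1]
        assert rr[i_on : i_off + 1].min() <= 0.8 * baseline  # >= 20% decline
        assert abs(rr[-1] - baseline) <= 0.05 * baseline  # recovery within 5%
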