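"""Kinetic Monte Carlo simulation of slip and catch bonds, with the
deterministic master-equation twin as oracle."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from catchslip.elasticity import EnergyProfile, WLCParameters, bell_off_rate
from catchslip.kinetics import (
    EXPERIMENT_SPEEDS,
    STRONG,
    WEAK,
    BondModel,
    PullProtocol,
    bond_model_for_geometry,
    build_force_schedule,
    master_equation_eta,
    pathway_fraction,
    simulate_constant_speed,
    simulate_force_clamp,
)
from catchslip.pathways import bell_evans_regression  # noqa: F401  (integration)
from catchslip.elasticity import bell_evans_modal_force

NEGLIGIBLE = EnergyProfile(1e-300, 0.5)


def catch_with_transition(transition: EnergyProfile) -> BondModel:
    base = bond_model_for_geometry("NN-C")
    return BondModel.catch(weak=base.weak, strong=base.strong, transition=transition)


class TestForceSchedule:
    def test_stiff_cantilever_head_equals_extension(self, ctx):
        prot = PullProtocol(V=800.0, k=1e9)
        s = build_force_schedule(prot, ctx)
        assert np.allclose(s.H, s.X, atol=1e-6)

    def test_time_steps_follow_head_height(self, ctx):
        s = build_force_schedule(PullProtocol(V=400.0), ctx)
        assert np.allclose(np.diff(s.t), np.diff(s.H) / 400.0)
        assert s.t[0] == 0.0
        assert np.all(np.diff(s.t) > 0)

    def test_loading_rate_is_series_spring_stiffness_times_speed(self, ctx):
        """(F_{i+1}-F_i)/Δt equals k_eff·V with 1/k_eff = 1/k + 1/k_wlc."""
        prot = PullProtocol(V=800.0, k=100.0)
        s = build_force_schedule(prot, ctx)
        inst = np.diff(s.F) / np.diff(s.t)
        k_wlc = np.gradient(s.F, s.X)
        k_eff = 1.0 / (1.0 / prot.k + 1.0 / k_wlc)
        mid = slice(100, -100)
        rel = np.abs(inst - (k_eff * prot.V)[:-1])[mid] / (k_eff[:-1] * prot.V)[mid]
        assert np.max(rel) < 0.01

    def test_grid_must_stay_below_contour_length(self):
        with pytest.raises(ValueError):
            PullProtocol(V=100.0, wlc=WLCParameters(Lc=124.0),
                         extension_grid=(1.0, 130.0, 100))


class TestConstantSpeedSlip:
    def test_mode_matches_analytic_modal_force(self, ctx, nnb_profile):
        model = BondModel.slip([(STRONG, nnb_profile, 1.0)])
        rec = simulate_constant_speed(model, PullProtocol(V=800.0), 5000,
                                      seed=11, ctx=ctx)
        counts, edges = np.histogram(rec["force_pN"], bins=40)
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        expected = bell_evans_modal_force(rec["loading_rate_pN_s"].mean(),
                                          nnb_profile, ctx)
        assert abs(mode - expected) < 5.0

    def test_rupture_forces_within_schedule(self, ctx, native_records_by_speed):
        s = build_force_schedule(PullProtocol(V=100.0), ctx)
        rec = native_records_by_speed[100.0]
        assert (rec["force_pN"] > 0).all()
        assert (rec["force_pN"] <= s.F.max()).all()
        assert rec.attrs["n_censored"] == 0

    def test_pathway_assignment_independent_of_speed(self, native_records_by_speed):
        table = []
        for V, rec in native_records_by_speed.items():
            n_strong = int((rec["pathway"] == STRONG).sum())
            table.append([n_strong, len(rec) - n_strong])
        _, p, *_ = chi2_contingency(np.array(table))
        assert p > 0.01

    def test_native_strong_fraction_near_assignment_probability(
        self, native_records_by_speed
    ):
        for rec in native_records_by_speed.values():
            eta, sd = pathway_fraction(rec)
            assert abs(eta - 0.64) < 3 * sd + 1e-9

    def test_deterministic_given_seed(self, ctx, native_model):
        a = simulate_constant_speed(native_model, PullProtocol(V=400.0), 200,
                                    seed=5, ctx=ctx)
        b = simulate_constant_speed(native_model, PullProtocol(V=400.0), 200,
                                    seed=5, ctx=ctx)
        assert a.equals(b)

    def test_grid_refinement_convergence(self, ctx, nnb_profile):
        model = BondModel.slip([(STRONG, nnb_profile, 1.0)])
        means = []
        for n_points in (10_000, 20_000):
            prot = PullProtocol(V=800.0,
                                extension_grid=(1.0, 0.995 * 124.0, n_points))
            rec = simulate_constant_speed(model, prot, 4000, seed=21, ctx=ctx)
            means.append(rec["force_pN"].mean())
        assert abs(means[1] - means[0]) / means[0] < 0.005


class TestConstantSpeedCatch:
    def test_no_transition_all_weak(self, ctx):
        model = catch_with_transition(NEGLIGIBLE)
        rec = simulate_constant_speed(model, PullProtocol(V=400.0), 300,
                                      seed=3, ctx=ctx)
        assert (rec["pathway"] == WEAK).all()

    def test_instant_transition_all_strong(self, ctx):
        model = catch_with_transition(EnergyProfile(1e6, 0.83))
        rec = simulate_constant_speed(model, PullProtocol(V=400.0), 300,
                                      seed=4, ctx=ctx)
        assert (rec["pathway"] == STRONG).all()

    def test_mc_matches_master_equation(self, ctx, catch_model):
        for V in (100.0, 3200.0):
            prot = PullProtocol(V=V)
            eta_star = master_equation_eta(catch_model, prot, ctx)
            rec = simulate_constant_speed(catch_model, prot, 4000, seed=31, ctx=ctx)
            eta, sd = pathway_fraction(rec)
            assert abs(eta - eta_star) < 3 * max(sd, 1e-3)

    def test_sequential_step_rule_agrees_with_competing(self, ctx, catch_model):
        prot = PullProtocol(V=800.0)
        eta_star = master_equation_eta(catch_model, prot, ctx)
        rec = simulate_constant_speed(catch_model, prot, 4000, seed=32, ctx=ctx,
                                      catch_step_rule="sequential")
        eta, sd = pathway_fraction(rec)
        assert abs(eta - eta_star) < 3 * max(sd, 1e-3)

    def test_prevalence_increases_with_speed(self, ctx, catch_model):
        etas = [master_equation_eta(catch_model, PullProtocol(V=V), ctx)
                for V in EXPERIMENT_SPEEDS]
        assert all(b > a for a, b in zip(etas, etas[1:]))


class TestMasterEquation:
    def test_limits(self, ctx):
        prot = PullProtocol(V=400.0)
        assert master_equation_eta(catch_with_transition(NEGLIGIBLE), prot, ctx) \
            == pytest.approx(0.0, abs=1e-10)
        assert master_equation_eta(
            catch_with_transition(EnergyProfile(1e6, 0.83)), prot, ctx
        ) == pytest.approx(1.0, abs=1e-6)

    def test_requires_catch_topology(self, ctx, native_model):
        with pytest.raises(TypeError):
            master_equation_eta(native_model, PullProtocol(V=100.0), ctx)


class TestForceClamp:
    def test_slip_median_is_log2_over_rate(self, ctx, nnb_profile):
        model = BondModel.slip([(STRONG, nnb_profile, 1.0)])
        F = 30.0
        lt = simulate_force_clamp(model, F, 1000, seed=9, ctx=ctx)
        med = np.median(lt["lifetime_s"])
        expected = np.log(2.0) / bell_off_rate(F, nnb_profile, ctx)
        # binomial CI on the sample median of an exponential at n=1000
        assert abs(med - expected) / expected < 0.15

    def test_native_lifetime_monotone_decreasing(self, ctx, native_model):
        meds = [
            np.median(simulate_force_clamp(native_model, F, 1000,
                                           seed=40 + int(F), ctx=ctx)["lifetime_s"])
            for F in (10.0, 20.0, 30.0, 40.0, 50.0)
        ]
        assert all(b < a for a, b in zip(meds, meds[1:]))

    def test_catch_lifetime_rises_between_20_and_30_pN(self, ctx, catch_model):
        med20 = np.median(simulate_force_clamp(catch_model, 20.0, 4000,
                                               seed=51, ctx=ctx)["lifetime_s"])
        med30 = np.median(simulate_force_clamp(catch_model, 30.0, 4000,
                                               seed=52, ctx=ctx)["lifetime_s"])
        assert med30 > med20

    def test_catch_strong_fraction_increases_with_clamp_force(self, ctx, catch_model):
        etas = []
        for i, F in enumerate((10.0, 30.0, 50.0)):
            lt = simulate_force_clamp(catch_model, F, 4000, seed=60 + i, ctx=ctx)
            etas.append(pathway_fraction(lt)[0])
        assert etas[0] < etas[1] < etas[2]
        # closed-form competing-risks check: eta = k12/(k12 + k_weak)
        k12 = bell_off_rate(50.0, catch_model.transition, ctx)
        kw = bell_off_rate(50.0, catch_model.weak, ctx)
        assert etas[2] == pytest.approx(k12 / (k12 + kw), abs=0.03)


class TestPathwayFraction:
    def test_all_strong(self):
        import pandas as pd

        rec = pd.DataFrame({"pathway": [STRONG] * 10})
        assert pathway_fraction(rec) == (1.0, 0.0)

    def test_half_and_half(self):
        import pandas as pd

        rec = pd.DataFrame({"pathway": [STRONG] * 50 + [WEAK] * 50})
        eta, sd = pathway_fraction(rec)
        assert eta == 0.5
        assert sd == pytest.approx(0.05)

    def test_empty_errors(self):
        import pandas as pd

        with pytest.raises(ValueError):
            pathway_fraction(pd.DataFrame({"pathway": []}))


class TestBondModelValidation:
    def test_slip_probabilities_must_sum_to_one(self, nnb_profile):
        with pytest.raises(ValueError):
            BondModel.slip([(STRONG, nnb_profile, 0.7), (WEAK, nnb_profile, 0.7)])

    def test_catch_requires_three_profiles(self, nnb_profile):
        with pytest.raises(ValueError):
            BondModel(topology="catch", weak=nnb_profile, strong=nnb_profile)

    def test_geometry_table_codes(self):
        for code in ("native", "NN-A", "NN-B", "NN-C", "NN-D"):
            bond_model_for_geometry(code)
        with pytest.raises(KeyError):
            bond_model_for_geometry("NN-X")
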