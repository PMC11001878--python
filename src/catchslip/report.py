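"""End-to-end round-trip report: recompute the headline quantities.

Every number here is produced by running the pipeline — simulating rupture
events or curves, fitting them, and reading the result — so the report
doubles as a self-check of the whole package against the published
landscape parameters it was built around.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import analyze_curve
from .elasticity import ThermalContext
from .kinetics import (
    EXPERIMENT_SPEEDS,
    STRONG,
    PullProtocol,
    bond_model_for_geometry,
    pathway_fraction,
    simulate_constant_speed,
)
from .pathways import bell_evans_regression, fit_force_histogram
from .synthetic import (
    CurveScenario,
    elp_linker_contour_length,
    generate_pull_curves,
)
from .transition import EtaObservation, fit_transition_profile, predict_eta


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def _simulate_and_regress(geometry: str, n_components: int, n_per_speed: int,
                          seed: int, ctx: ThermalContext):
    """Simulate all four speeds, Gaussian-fit each histogram and run the
    Bell–Evans regression on the high-force population."""
    model = bond_model_for_geometry(geometry)
    rates, modes = [], []
    frames = []
    for i, V in enumerate(EXPERIMENT_SPEEDS):
        rec = simulate_constant_speed(model, PullProtocol(V=V), n_per_speed,
                                      seed=_subseed(seed, 10 + i), ctx=ctx)
        frames.append(rec)
        fit = fit_force_histogram(rec["force_pN"], n_components,
                                  speed=V, loading_rates=rec["loading_rate_pN_s"])
        rates.append(fit.mean_loading_rate["high"])
        modes.append(fit.components[0].mean)
    be = bell_evans_regression(rates, modes, ctx)
    return be, pd.concat(frames, ignore_index=True)


def run_report(seed: int = 1) -> dict:
    """Compute all report quantities; returns {name: {value, n}}."""
    ctx = ThermalContext()
    out: dict[str, dict] = {}

    # --- printed arithmetic: two fully stretched ELP linkers -------------
    out["t1"] = {"value": float(elp_linker_contour_length(2)), "n": 340}

    # --- k12 round trip (deterministic, ODE mode) ------------------------
    model_c = bond_model_for_geometry("NN-C")
    protocols = [PullProtocol(V=v) for v in EXPERIMENT_SPEEDS]
    eta_star = predict_eta(model_c.transition, model_c.weak, model_c.strong,
                           protocols, mode="ode", ctx=ctx)
    observations = [EtaObservation(v, e, 0.02)
                    for v, e in zip(EXPERIMENT_SPEEDS, eta_star)]
    fit12 = fit_transition_profile(observations, model_c.weak, model_c.strong,
                                   protocols, ctx=ctx)
    out["t2"] = {"value": float(fit12.k12_0), "n": len(observations)}
    out["t3"] = {"value": float(fit12.dx12), "n": len(observations)}

    # --- native slip: pooled high-force rupture fraction (percent) -------
    model_n = bond_model_for_geometry("native")
    frames = []
    for i, V in enumerate(EXPERIMENT_SPEEDS):
        frames.append(
            simulate_constant_speed(model_n, PullProtocol(V=V), 1000,
                                    seed=_subseed(seed, i), ctx=ctx)
        )
    pooled = pd.concat(frames, ignore_index=True)
    eta, _ = pathway_fraction(pooled)
    out["t4"] = {"value": float(100.0 * eta), "n": len(pooled)}

    # --- NN-B single-pathway Bell-Evans round trip -----------------------
    be_b, rec_b = _simulate_and_regress("NN-B", 1, 1000, seed, ctx)
    out["t5"] = {"value": float(be_b.log10_k0), "n": len(rec_b)}
    out["t6"] = {"value": float(be_b.dx), "n": len(rec_b)}

    # --- synthetic curves: fingerprint contour-length increment ----------
    scenario = CurveScenario(force_noise_sd=0.0)
    curves = generate_pull_curves(scenario, 80, seed=_subseed(seed, 40), ctx=ctx)
    increments = []
    for c in curves:
        _, events, summary = analyze_curve(c, ctx=ctx)
        if len(events) == scenario.fln_count and summary.accepted:
            increments.append(summary.total_Lc_at_rupture - events[0].Lc_before)
    out["t7"] = {"value": float(np.mean(increments)), "n": len(increments)}

    # --- NN-C catch: strong-pathway Bell-Evans round trip ----------------
    be_c, rec_c = _simulate_and_regress("NN-C", 2, 1000, seed + 1, ctx)
    out["t8"] = {"value": float(be_c.log10_k0), "n": len(rec_c)}
    out["t9"] = {"value": float(be_c.dx), "n": len(rec_c)}

    return out
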