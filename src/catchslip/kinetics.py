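"""Stochastic simulation of slip and two-state catch bonds.

Two pulling protocols are covered:

* **constant speed** — the cantilever base retracts at speed V; the force
  follows a worm-like-chain schedule built on an even molecular-extension
  grid, with the cantilever bending correction H = X + F/k and time steps
  Δt = ΔH/V. Rupture (and, for catch bonds, the weak→strong transition)
  is sampled per step from the Bell hazard.
* **force clamp** — the force is constant, so waiting times are exactly
  exponential and are sampled in closed form without time discretization.

A deterministic master-equation twin of the catch model integrates the
two-state occupancies along the same force schedule and predicts the
strong-pathway prevalence η* without Monte Carlo noise; it doubles as an
oracle for the stochastic sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elasticity import (
    EnergyProfile,
    ThermalContext,
    WLCParameters,
    bell_off_rate,
    wlc_force,
)

WEAK = "weak"
STRONG = "strong"


@dataclass(frozen=True)
class SlipPathway:
    """One parallel dissociation pathway with its entry probability."""

    label: str
    profile: EnergyProfile
    probability: float


@dataclass(frozen=True)
class BondModel:
    """Kinetic topology of the receptor–ligand bond.

    ``slip``: the complex is assigned one of several non-interchangeable
    pathways at binding and ruptures along it.  ``catch``: the complex
    starts in a weak state and either ruptures from it or transitions
    irreversibly (rate ``transition``) to a strong state with higher
    mechanostability.
    """

    topology: str
    pathways: tuple[SlipPathway, ...] = ()
    weak: EnergyProfile | None = None
    strong: EnergyProfile | None = None
    transition: EnergyProfile | None = None

    def __post_init__(self) -> None:
        if self.topology == "slip":
            if not self.pathways:
                raise ValueError("slip model requires at least one pathway")
            probs = np.array([p.probability for p in self.pathways])
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValueError("pathway probabilities must lie in [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("pathway probabilities must sum to 1")
        elif self.topology == "catch":
            if self.weak is None or self.strong is None or self.transition is None:
                raise ValueError("catch model requires weak, strong and transition profiles")
        else:
            raise ValueError(f"unknown topology {self.topology!r}")

    @classmethod
    def slip(cls, pathways) -> "BondModel":
        return cls(topology="slip", pathways=tuple(SlipPathway(*p) for p in pathways))

    @classmethod
    def catch(cls, weak, strong, transition) -> "BondModel":
        return cls(topology="catch", weak=weak, strong=strong, transition=transition)


#: Bell–Evans landscape parameters per anchor geometry (log10 k0 [s⁻¹], Δx‡ [nm]).
#: "native" pulls N-terminus of Doc / C-terminus of Coh; NN-A..NN-D are the
#: non-native anchor geometries. NN-C (Coh residue F13) is the catch geometry;
#: its weak→strong transition profile was obtained from prevalence fitting.
GEOMETRY_TABLE = {
    "native": {
        "topology": "slip",
        "pathways": [
            (STRONG, (-7.0, 0.73), 0.64),
            (WEAK, (-9.0, 1.3), 0.36),
        ],
    },
    "NN-A": {
        "topology": "slip",
        "pathways": [
            (STRONG, (-7.0, 1.1), 0.5),
            (WEAK, (-31.0, 10.0), 0.5),
        ],
    },
    "NN-B": {
        "topology": "slip",
        "pathways": [(STRONG, (-4.2, 0.65), 1.0)],
    },
    "NN-C": {
        "topology": "catch",
        "weak": (-0.8, 0.51),
        "strong": (-2.5, 0.37),
        "transition_k0": 0.019,
        "transition_dx": 0.83,
    },
    "NN-D": {
        "topology": "slip",
        "pathways": [
            (STRONG, (-4.8, 0.58), 0.5),
            (WEAK, (-0.7, 0.41), 0.5),
        ],
    },
}

#: Pulling speeds used throughout (nm/s).
EXPERIMENT_SPEEDS = (100.0, 400.0, 800.0, 3200.0)


def bond_model_for_geometry(code: str) -> BondModel:
    """Bond model for an anchor-geometry code (native, NN-A … NN-D)."""
    try:
        entry = GEOMETRY_TABLE[code]
    except KeyError:
        raise KeyError(
            f"unknown anchor geometry {code!r}; expected one of {sorted(GEOMETRY_TABLE)}"
        ) from None
    if entry["topology"] == "slip":
        return BondModel.slip(
            (label, EnergyProfile.from_log10_k0(*params), prob)
            for label, params, prob in entry["pathways"]
        )
    return BondModel.catch(
        weak=EnergyProfile.from_log10_k0(*entry["weak"]),
        strong=EnergyProfile.from_log10_k0(*entry["strong"]),
        transition=EnergyProfile(entry["transition_k0"], entry["transition_dx"]),
    )


@dataclass(frozen=True)
class PullProtocol:
    """Constant-speed retraction protocol.

    V: pulling speed (nm/s); k: cantilever spring constant (pN/nm); wlc:
    tether elasticity; extension_grid: (x_min, x_max, n_points) molecular
    extension grid in nm, with x_max < Lc.
    """

    V: float
    k: float = 100.0
    wlc: WLCParameters = field(default_factory=WLCParameters)
    extension_grid: tuple[float, float, int] | None = None

    def __post_init__(self) -> None:
        if self.V <= 0 or self.k <= 0:
            raise ValueError("pulling speed and spring constant must be positive")
        grid = self.extension_grid or (1.0, 0.995 * self.wlc.Lc, 10_000)
        x_min, x_max, n = grid
        if not (0 <= x_min < x_max < self.wlc.Lc):
            raise ValueError("extension grid must satisfy 0 <= x_min < x_max < Lc")
        object.__setattr__(self, "extension_grid", (x_min, x_max, int(n)))


@dataclass(frozen=True)
class ForceSchedule:
    """Deterministic force/extension/head-height/time arrays for one pull."""

    X: np.ndarray
    F: np.ndarray
    H: np.ndarray
    t: np.ndarray

    def __len__(self) -> int:
        return len(self.X)


def build_force_schedule(
    protocol: PullProtocol, ctx: ThermalContext | None = None
) -> ForceSchedule:
    """WLC force schedule on an even extension grid with bending correction.

    H(t_i) = X(t_i) + F(t_i)/k converts molecular extension to head height;
    the time axis follows from the constant speed, t_{i+1} − t_i = ΔH/V
    with t_0 = 0.
    """
    ctx = ctx or ThermalContext()
    x_min, x_max, n = protocol.extension_grid
    X = np.linspace(x_min, x_max, n)
    F = wlc_force(X, protocol.wlc, ctx)
    H = X + F / protocol.k
    t = np.concatenate([[0.0], np.cumsum(np.diff(H)) / protocol.V])
    return ForceSchedule(X=X, F=F, H=H, t=t)


def _step_hazards(profile: EnergyProfile, schedule: ForceSchedule, ctx) -> np.ndarray:
    """Per-step integrated hazard k(F_i)·Δt_i for steps i = 0..m−2."""
    rates = bell_off_rate(schedule.F[:-1], profile, ctx)
    return rates * np.diff(schedule.t)


def _trailing_slopes(schedule: ForceSchedule, idx: np.ndarray, tail_fraction=0.05,
                     min_points=10) -> np.ndarray:
    """Least-squares slope of F(t) over the trailing window before each rupture index.

    Windows are ``max(min_points, tail_fraction·idx)`` samples ending at the
    rupture index; prefix sums make the per-replicate cost O(1).
    """
    t, F = schedule.t, schedule.F
    ones = np.concatenate([[0.0], np.cumsum(np.ones_like(t))])
    St = np.concatenate([[0.0], np.cumsum(t)])
    SF = np.concatenate([[0.0], np.cumsum(F)])
    Stt = np.concatenate([[0.0], np.cumsum(t * t)])
    StF = np.concatenate([[0.0], np.cumsum(t * F)])

    idx = np.asarray(idx)
    w = np.maximum(min_points, np.ceil(tail_fraction * (idx + 1)).astype(int))
    w = np.minimum(w, idx + 1)
    w = np.maximum(w, 2)
    lo = idx + 1 - w
    hi = idx + 1
    n = ones[hi] - ones[lo]
    st = St[hi] - St[lo]
    sf = SF[hi] - SF[lo]
    stt = Stt[hi] - Stt[lo]
    stf = StF[hi] - StF[lo]
    denom = n * stt - st * st
    return (n * stf - st * sf) / denom


def simulate_constant_speed(
    model: BondModel,
    protocol: PullProtocol,
    n: int,
    seed,
    ctx: ThermalContext | None = None,
    catch_step_rule: str = "competing",
):
    """Monte Carlo rupture events for ``n`` constant-speed pulls.

    Each replicate is stepped along the force schedule; the per-step event
    probability 1 − exp(−k(F)Δt) is realized by comparing the cumulative
    hazard against an Exp(1) draw (exactly equivalent to per-step uniform
    checks, but vectorized). For the catch model the weak-state step carries
    two competing hazards (rupture, weak→strong transition); the event type
    is split proportionally to the rates (``competing``) or by checking
    rupture first within the step (``sequential``) — the two rules coincide
    as Δt → 0.

    Returns
    -------
    pandas.DataFrame
        Columns force_pN, loading_rate_pN_s, pathway, time_s, speed_nm_s —
        one row per ruptured replicate — plus ``attrs['n_censored']`` for
        replicates that survived the whole ramp.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    if catch_step_rule not in ("competing", "sequential"):
        raise ValueError("catch_step_rule must be 'competing' or 'sequential'")
    ctx = ctx or ThermalContext()
    rng = np.random.default_rng(seed)
    schedule = build_force_schedule(protocol, ctx)
    m = len(schedule)

    idx = np.empty(n, dtype=int)
    labels = np.empty(n, dtype=object)

    if model.topology == "slip":
        probs = np.array([p.probability for p in model.pathways])
        assignment = rng.choice(len(model.pathways), size=n, p=probs)
        E = rng.exponential(size=n)
        cumhaz = {
            j: np.cumsum(_step_hazards(p.profile, schedule, ctx))
            for j, p in enumerate(model.pathways)
        }
        for j, p in enumerate(model.pathways):
            sel = assignment == j
            idx[sel] = np.searchsorted(cumhaz[j], E[sel])
            labels[sel] = p.label
    else:
        hw = _step_hazards(model.weak, schedule, ctx)
        h12 = _step_hazards(model.transition, schedule, ctx)
        cum_weak_total = np.cumsum(hw + h12)
        cumhaz_strong = np.cumsum(_step_hazards(model.strong, schedule, ctx))

        E1 = rng.exponential(size=n)
        j1 = np.searchsorted(cum_weak_total, E1)
        u = rng.uniform(size=n)
        jj = np.minimum(j1, m - 2)
        if catch_step_rule == "competing":
            p_rupt = hw[jj] / (hw[jj] + h12[jj])
        else:
            p_w = -np.expm1(-hw[jj])
            p_any = -np.expm1(-(hw[jj] + h12[jj]))
            p_rupt = p_w / p_any
        ruptured_weak = u < p_rupt
        weak_done = ruptured_weak & (j1 <= m - 2)

        idx[:] = j1
        labels[:] = WEAK
        to_strong = ~ruptured_weak & (j1 <= m - 2)
        if np.any(to_strong):
            j_tr = j1[to_strong]
            E2 = rng.exponential(size=j_tr.size)
            target = cumhaz_strong[j_tr] + E2
            j2 = np.searchsorted(cumhaz_strong, target)
            idx[to_strong] = j2
            labels[to_strong] = STRONG
        idx[weak_done] = j1[weak_done]

    censored = idx > m - 2
    kept = ~censored
    idx_k = idx[kept]
    slopes = _trailing_slopes(schedule, idx_k)
    df = pd.DataFrame(
        {
            "force_pN": schedule.F[idx_k],
            "loading_rate_pN_s": slopes,
            "pathway": labels[kept],
            "time_s": schedule.t[idx_k],
            "speed_nm_s": protocol.V,
        }
    )
    df.attrs["n_censored"] = int(censored.sum())
    return df


def simulate_force_clamp(
    model: BondModel,
    F: float,
    n: int,
    seed,
    ctx: ThermalContext | None = None,
):
    """Bond lifetimes under a constant clamping force.

    At constant force all rates are constant, so lifetimes are sampled from
    exact exponential waiting times: slip replicates draw Exp(k(F)) on their
    assigned pathway; catch replicates draw the weak-state dwell from
    Exp(k_weak + k12), branch to the strong state with probability
    k12/(k_weak + k12), and add an Exp(k_strong) dwell if they do.

    Returns a DataFrame with columns lifetime_s, pathway, clamp_force_pN.
    """
    import pandas as pd

    if F < 0:
        raise ValueError("clamp force must be nonnegative")
    if n < 1:
        raise ValueError("n must be >= 1")
    ctx = ctx or ThermalContext()
    rng = np.random.default_rng(seed)

    if model.topology == "slip":
        probs = np.array([p.probability for p in model.pathways])
        assignment = rng.choice(len(model.pathways), size=n, p=probs)
        lifetimes = np.empty(n)
        labels = np.empty(n, dtype=object)
        for j, p in enumerate(model.pathways):
            sel = assignment == j
            rate = bell_off_rate(F, p.profile, ctx)
            lifetimes[sel] = rng.exponential(1.0 / rate, size=sel.sum())
            labels[sel] = p.label
    else:
        kw = bell_off_rate(F, model.weak, ctx)
        k12 = bell_off_rate(F, model.transition, ctx)
        ks = bell_off_rate(F, model.strong, ctx)
        dwell_weak = rng.exponential(1.0 / (kw + k12), size=n)
        go_strong = rng.uniform(size=n) < k12 / (kw + k12)
        lifetimes = dwell_weak.copy()
        lifetimes[go_strong] += rng.exponential(1.0 / ks, size=int(go_strong.sum()))
        labels = np.where(go_strong, STRONG, WEAK).astype(object)

    return pd.DataFrame(
        {"lifetime_s": lifetimes, "pathway": labels, "clamp_force_pN": F}
    )


def master_equation_eta(
    model: BondModel,
    protocol: PullProtocol,
    ctx: ThermalContext | None = None,
) -> float:
    """Deterministic strong-pathway prevalence η* for the catch model.

    Integrates the two-state occupancies along the force schedule,

        dS1/dt = −(k_weak + k12)·S1
        dS2/dt = k12·S1 − k_strong·S2,

    with piecewise-constant rates per step (exact per-step updates), and
    returns the strong-pathway share of total rupture probability.
    """
    if model.topology != "catch":
        raise TypeError("master_equation_eta requires a catch-topology model")
    ctx = ctx or ThermalContext()
    schedule = build_force_schedule(protocol, ctx)
    F = schedule.F[:-1]
    dt = np.diff(schedule.t)
    kw = bell_off_rate(F, model.weak, ctx)
    k12 = bell_off_rate(F, model.transition, ctx)
    ks = bell_off_rate(F, model.strong, ctx)
    a = kw + k12

    # scalar loop on Python floats: this sits inside the prevalence-fit
    # objective, so per-step cost matters
    from math import exp

    a_l, ks_l, kw_l, k12_l, dt_l = (
        a.tolist(), ks.tolist(), kw.tolist(), k12.tolist(), dt.tolist()
    )
    s1, s2 = 1.0, 0.0
    weak_rupt, strong_rupt = 0.0, 0.0
    for ai, ki, kwi, k12i, h in zip(a_l, ks_l, kw_l, k12_l, dt_l):
        ea = exp(-ai * h)
        ek = exp(-ki * h)
        # weak-state rupture over the step
        weak_rupt += (kwi / ai) * s1 * (1.0 - ea)
        if abs(ai - ki) > 1e-12 * max(ai, ki, 1e-300):
            c = k12i * s1 / (ai - ki)
            # S2(τ) = (s2 + c) e^{−ks τ} − c e^{−a τ}
            strong_rupt += (s2 + c) * (1.0 - ek) - c * (ki / ai) * (1.0 - ea)
            s2 = (s2 + c) * ek - c * ea
        else:  # degenerate a == ks: S2(τ) = (s2 + k12 s1 τ) e^{−a τ}
            strong_rupt += ki * (
                s2 * (1.0 - ea) / ai
                + k12i * s1 * (1.0 - ea * (1.0 + ai * h)) / ai**2
            )
            s2 = (s2 + k12i * s1 * h) * ea
        s1 *= ea
        if s1 + s2 < 1e-14:
            break
    total = weak_rupt + strong_rupt
    if total <= 0:
        return 0.0
    return float(strong_rupt / total)


def pathway_fraction(records) -> tuple[float, float]:
    """Strong-pathway fraction η and its binomial standard error.

    ``records`` is any DataFrame with a ``pathway`` column (labels "weak"
    / "strong").
    """
    n = len(records)
    if n == 0:
        raise ValueError("no rupture records")
    eta = float((records["pathway"] == STRONG).sum()) / n
    sigma = float(np.sqrt(eta * (1.0 - eta) / n))
    return eta, sigma
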