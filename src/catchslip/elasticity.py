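"""Polymer elasticity and Bell-kinetics primitives.

Closed-form building blocks shared by the simulation and analysis layers:

* freely rotating chain (FRC) force–extension inversion used to transform
  AFM force curves into contour-length space,
* the interpolated worm-like chain (WLC) force law used to build the
  constant-pulling-speed force schedule,
* Bell's force-dependent off-rate and the Bell–Evans most-probable rupture
  force for a constant loading rate.

Units throughout: force in pN, length in nm, time in s, energy in pN·nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant in pN·nm/K.
KB_PN_NM = 1.380649e-2


@dataclass(frozen=True)
class ThermalContext:
    """Temperature and the thermal energy scale kBT.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin. Default 298 K (room-temperature
        AFM in aqueous buffer, kBT ≈ 4.114 pN·nm).
    """

    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def kBT(self) -> float:
        """Thermal energy in pN·nm (≈ 4.114 pN·nm at 298.15 K)."""
        return KB_PN_NM * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kBT in (pN·nm)⁻¹."""
        return 1.0 / self.kBT


def frc_derived_lengths(b: float, gamma_bond: float) -> tuple[float, float]:
    """Kuhn length and persistence length of a freely rotating chain.

    Parameters
    ----------
    b : float
        Segment (backbone bond) length in nm.
    gamma_bond : float
        Bond angle in degrees, in the open interval (0, 90).

    Returns
    -------
    (a, l) : tuple of float
        Kuhn length ``a = b(1+cosγ)/((1−cosγ)cos(γ/2))`` and persistence
        length ``l = b·cos(γ/2)/|ln cos γ|``, both in nm.
    """
    if b <= 0:
        raise ValueError("segment length b must be positive")
    if not 0.0 < gamma_bond < 90.0:
        raise ValueError("bond angle must lie strictly between 0 and 90 degrees")
    g = math.radians(gamma_bond)
    cg, ch = math.cos(g), math.cos(g / 2.0)
    a = b * (1.0 + cg) / ((1.0 - cg) * ch)
    l = b * ch / abs(math.log(cg))
    return a, l


@dataclass(frozen=True)
class FRCParameters:
    """Freely-rotating-chain geometry.

    Defaults are the polypeptide backbone values ``b = 0.11 nm`` and
    ``γ = 41°``; the Kuhn length ``a`` and persistence length ``l`` are
    derived, not free.
    """

    b: float = 0.11
    gamma_bond: float = 41.0
    a: float = field(init=False)
    l: float = field(init=False)

    def __post_init__(self) -> None:
        a, l = frc_derived_lengths(self.b, self.gamma_bond)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "l", l)


@dataclass(frozen=True)
class WLCParameters:
    """Worm-like chain with contour length ``Lc`` and persistence length ``p`` (nm)."""

    Lc: float = 124.0
    p: float = 0.4

    def __post_init__(self) -> None:
        if self.Lc <= 0 or self.p <= 0:
            raise ValueError("WLC contour and persistence lengths must be positive")


@dataclass(frozen=True)
class EnergyProfile:
    """One-barrier Bell energy landscape: zero-force off-rate and barrier distance.

    Parameters
    ----------
    k0 : float
        Zero-force off-rate in s⁻¹ (must be > 0; pass a tiny value such as
        1e-300 to effectively disable a pathway).
    dx : float
        Distance from the bound state to the transition state along the
        pulling coordinate, in nm.
    """

    k0: float
    dx: float

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise ValueError("k0 must be nonnegative")
        if self.dx < 0:
            raise ValueError("dx must be nonnegative")

    @classmethod
    def from_log10_k0(cls, log10_k0: float, dx: float) -> "EnergyProfile":
        return cls(k0=10.0 ** log10_k0, dx=dx)


def frc_contour_length(
    x,
    F,
    params: FRCParameters | None = None,
    ctx: ThermalContext | None = None,
):
    """Transform extension/force points to FRC contour length.

    The FRC inversion is piecewise in the reduced force ``Fb/kBT``:

    * low branch (``Fb/kBT < b/l``): linear-response form ``L = 3·kBT·x/(F·a)``
    * mid branch (``b/l ≤ Fb/kBT ≤ l/b``): ``L = x/(1 − (4Fl/kBT)^−1/2)``
    * high branch (``Fb/kBT > l/b``): ``L = x/(1 − (2Fb/kBT)^−1)``

    Boundary equality is assigned to the higher-force branch. Points where a
    branch denominator is nonpositive (force too low for the branch to
    invert) come back as NaN rather than raising.

    Parameters
    ----------
    x, F : array_like
        Extension (nm, ≥ 0) and force (pN, > 0); broadcast together.

    Returns
    -------
    numpy.ndarray
        Contour length in nm; NaN where the transform is invalid.
    """
    params = params or FRCParameters()
    ctx = ctx or ThermalContext()
    x = np.asarray(x, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0):
        raise ValueError("force must be strictly positive for the FRC transform")
    if np.any(x < 0):
        raise ValueError("extension must be nonnegative")

    kBT = ctx.kBT
    b, a, l = params.b, params.a, params.l
    fb = F * b / kBT

    L = np.empty(np.broadcast(x, F).shape, dtype=float)
    x, F, fb = np.broadcast_arrays(x, F, fb)

    low = fb < b / l
    high = fb > l / b
    mid = ~(low | high)

    with np.errstate(divide="ignore", invalid="ignore"):
        L_low = 3.0 * kBT * x / (F * a)
        denom_mid = 1.0 - (4.0 * F * l / kBT) ** -0.5
        L_mid = np.where(denom_mid > 0, x / denom_mid, np.nan)
        denom_high = 1.0 - (2.0 * F * b / kBT) ** -1
        L_high = np.where(denom_high > 0, x / denom_high, np.nan)

    L[low] = L_low[low]
    L[mid] = L_mid[mid]
    L[high] = L_high[high]
    return L if L.ndim else float(L)


def wlc_force(x, params: WLCParameters, ctx: ThermalContext | None = None):
    """Interpolated (Marko–Siggia) worm-like chain force at extension ``x``.

    ``F = (kBT/p)·[1/(4(1−x/Lc)²) − 1/4 + x/Lc]`` — strictly increasing in
    x, diverging as x → Lc.
    """
    ctx = ctx or ThermalContext()
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= params.Lc):
        raise ValueError("extension must satisfy 0 <= x < Lc")
    u = x / params.Lc
    F = (ctx.kBT / params.p) * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
    return F if F.ndim else float(F)


def wlc_extension(F, params: WLCParameters, ctx: ThermalContext | None = None):
    """Numerically invert :func:`wlc_force` (monotone bisection)."""
    ctx = ctx or ThermalContext()
    F = np.asarray(F, dtype=float)
    lo = np.zeros_like(F)
    hi = np.full_like(F, params.Lc * (1.0 - 1e-12))
    for _ in range(100):
        midx = 0.5 * (lo + hi)
        u = midx / params.Lc
        fm = (ctx.kBT / params.p) * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
        go_up = fm < F
        lo = np.where(go_up, midx, lo)
        hi = np.where(go_up, hi, midx)
    out = 0.5 * (lo + hi)
    return out if out.ndim else float(out)


def bell_off_rate(F, profile: EnergyProfile, ctx: ThermalContext | None = None):
    """Bell off-rate ``k(F) = k0·exp(F·Δx‡/kBT)`` in s⁻¹."""
    ctx = ctx or ThermalContext()
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be nonnegative")
    # cap the exponent: rates beyond e^700 s⁻¹ are indistinguishable from
    # instantaneous rupture and would otherwise overflow to inf
    if profile.k0 == 0.0:
        out = np.zeros_like(F)
    else:
        log_rate = np.log(profile.k0) + F * profile.dx * ctx.beta
        out = np.exp(np.minimum(log_rate, 700.0))
    return out if out.ndim else float(out)


def bell_evans_modal_force(
    r, profile: EnergyProfile, ctx: ThermalContext | None = None
):
    """Most probable rupture force at constant loading rate ``r`` (pN/s).

    ``F* = (kBT/Δx‡)·ln(r·Δx‡/(k0·kBT))``; may be negative for very slow
    loading (the mode of the rupture-force density sits at F = 0 there) —
    the raw value is returned and left to the caller.
    """
    ctx = ctx or ThermalContext()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("loading rate must be positive")
    kBT = ctx.kBT
    out = (kBT / profile.dx) * np.log(r * profile.dx / (profile.k0 * kBT))
    return out if out.ndim else float(out)


def step_rupture_probability(rate, dt):
    """Per-step event probability ``P = 1 − exp(−rate·dt)`` for a constant hazard."""
    rate = np.asarray(rate, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(rate < 0) or np.any(dt < 0):
        raise ValueError("rate and dt must be nonnegative")
    out = -np.expm1(-rate * dt)
    return out if out.ndim else float(out)
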