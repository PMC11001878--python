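"""Rupture-force population statistics and Bell–Evans regression.

Rupture-force histograms at each pulling speed are decomposed into one or
two Gaussian populations (the low- and high-force unbinding pathways); the
high-force prevalence η is the area share of the high-force peak, with its
uncertainty propagated from the fitted area covariance. Per pathway, the
most probable rupture force versus the log of the loading rate is fit
linearly to extract the zero-force off-rate k0 and barrier distance Δx‡.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .elasticity import ThermalContext


@dataclass(frozen=True)
class GaussianComponent:
    """One fitted rupture-force population (mean/sd in pN, area in counts)."""

    mean: float
    sd: float
    area: float


@dataclass
class PopulationFit:
    """1- or 2-Gaussian decomposition of a rupture-force histogram.

    Components are ordered by mean; for two components the higher-mean one
    is the high-force pathway. ``area_cov`` is the covariance of the fitted
    areas (high first for 2 components).
    """

    components: list[GaussianComponent]
    area_cov: np.ndarray
    speed: float = np.nan
    mean_loading_rate: dict = field(default_factory=dict)
    bic_advice: str = ""

    @property
    def eta_high(self) -> float:
        return pathway_prevalence(self)[0]


def _gauss_counts(x, area, mean, sd, bin_width):
    return area * bin_width / (sd * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((x - mean) / sd) ** 2
    )


def fit_force_histogram(
    forces,
    n_components: int = 2,
    init=None,
    speed: float = np.nan,
    loading_rates=None,
) -> PopulationFit:
    """Least-squares Gaussian decomposition of the binned rupture forces.

    Binning follows the Freedman–Diaconis rule with a 2 pN floor on the
    bin width. The number of components is a caller decision (one per
    anchor geometry, as for the measured histograms); a degenerate
    two-component fit — one area below 2% or means closer than one pooled
    sd — collapses to one component with a warning. If per-record
    ``loading_rates`` are supplied, each component's mean loading rate is
    the average over records assigned to it by maximum responsibility.
    """
    forces = np.asarray(forces, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if forces.size < 50:
        warnings.warn(
            f"only {forces.size} rupture forces; population fit may be unstable",
            stacklevel=2,
        )

    iqr = np.subtract(*np.percentile(forces, [75, 25]))
    bw = max(2.0, 2.0 * iqr / forces.size ** (1 / 3))
    edges = np.arange(forces.min() - bw, forces.max() + 2 * bw, bw)
    counts, edges = np.histogram(forces, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    if init is None:
        if n_components == 1:
            init = [forces.size, np.mean(forces), max(np.std(forces), bw)]
        else:
            # mixture prefit finds the populations even when very unbalanced
            from sklearn.mixture import GaussianMixture

            gm = GaussianMixture(2, random_state=0, n_init=5).fit(
                forces.reshape(-1, 1)
            )
            means = gm.means_.ravel()
            sds = np.sqrt(gm.covariances_.ravel())
            wts = gm.weights_.ravel()
            init = []
            for j in range(2):
                init += [forces.size * wts[j], means[j], max(sds[j], bw / 2)]

    if n_components == 1:
        def model(x, a, m, s):
            return _gauss_counts(x, a, m, s, bw)
    else:
        def model(x, a1, m1, s1, a2, m2, s2):
            return (_gauss_counts(x, a1, m1, s1, bw)
                    + _gauss_counts(x, a2, m2, s2, bw))

    lo = [0.0, -np.inf, 1e-3] * n_components
    hi = [np.inf, np.inf, np.inf] * n_components
    try:
        popt, pcov = curve_fit(model, centers, counts, p0=init,
                               bounds=(lo, hi), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Gaussian histogram fit did not converge (init={init})"
        ) from err

    comps = [
        GaussianComponent(area=popt[3 * i], mean=popt[3 * i + 1], sd=popt[3 * i + 2])
        for i in range(n_components)
    ]
    order = np.argsort([c.mean for c in comps])[::-1]  # high-force first
    comps = [comps[i] for i in order]
    area_idx = [3 * i for i in order]
    area_cov = pcov[np.ix_(area_idx, area_idx)]

    if n_components == 2:
        total = comps[0].area + comps[1].area
        pooled_sd = np.sqrt(0.5 * (comps[0].sd ** 2 + comps[1].sd ** 2))
        if (min(c.area for c in comps) < 0.02 * total
                or abs(comps[0].mean - comps[1].mean) < pooled_sd):
            warnings.warn(
                "degenerate two-component fit; collapsing to one component",
                stacklevel=2,
            )
            return fit_force_histogram(forces, 1, None, speed, loading_rates)

    bic = _bic_advice(forces)
    fit = PopulationFit(components=comps, area_cov=np.atleast_2d(area_cov),
                        speed=speed, bic_advice=bic)

    if loading_rates is not None:
        loading_rates = np.asarray(loading_rates, dtype=float)
        if n_components == 1:
            fit.mean_loading_rate = {"high": float(np.mean(loading_rates))}
        else:
            resp_high = _responsibility(forces, comps)
            hi_mask = resp_high >= 0.5
            fit.mean_loading_rate = {
                "high": float(np.mean(loading_rates[hi_mask]))
                if hi_mask.any() else np.nan,
                "low": float(np.mean(loading_rates[~hi_mask]))
                if (~hi_mask).any() else np.nan,
            }
    return fit


def _responsibility(forces, comps) -> np.ndarray:
    """Posterior probability that each force belongs to the high-force component."""
    h, l = comps[0], comps[1]
    ph = h.area / h.sd * np.exp(-0.5 * ((forces - h.mean) / h.sd) ** 2)
    pl = l.area / l.sd * np.exp(-0.5 * ((forces - l.mean) / l.sd) ** 2)
    return ph / (ph + pl)


def _bic_advice(forces) -> str:
    """Advisory 1- vs 2-component comparison via a Gaussian mixture BIC."""
    from sklearn.mixture import GaussianMixture

    X = np.asarray(forces, dtype=float).reshape(-1, 1)
    bics = [
        GaussianMixture(k, random_state=0, n_init=3).fit(X).bic(X) for k in (1, 2)
    ]
    pref = 1 if bics[0] <= bics[1] else 2
    return f"BIC prefers {pref} component(s) (BIC1={bics[0]:.1f}, BIC2={bics[1]:.1f})"


def pathway_prevalence(fit: PopulationFit) -> tuple[float, float]:
    """High-force prevalence η = A_high/(A_high + A_low) with propagated sd.

    First-order propagation through the area covariance:
    σ_η² = (∂η/∂A_h)²σ²_h + (∂η/∂A_l)²σ²_l + 2(∂η/∂A_h)(∂η/∂A_l)cov.
    Single-component fits return (1, 0): a unimodal geometry is counted as
    always rupturing on its (only) pathway.
    """
    if len(fit.components) == 1:
        return 1.0, 0.0
    ah, al = fit.components[0].area, fit.components[1].area
    total = ah + al
    d_ah = al / total ** 2
    d_al = -ah / total ** 2
    cov = fit.area_cov
    var = (d_ah ** 2 * cov[0, 0] + d_al ** 2 * cov[1, 1]
           + 2 * d_ah * d_al * cov[0, 1])
    return float(ah / total), float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class BellEvansFit:
    """Linear fit F* = slope·ln r + intercept and the implied Bell parameters."""

    slope: float
    intercept: float
    k0: float
    dx: float
    slope_se: float
    intercept_se: float
    k0_se: float
    dx_se: float

    @property
    def log10_k0(self) -> float:
        return float(np.log10(self.k0))

    @property
    def log10_k0_se(self) -> float:
        return float(self.k0_se / (self.k0 * np.log(10.0)))


def bell_evans_regression(
    loading_rates,
    modal_forces,
    ctx: ThermalContext | None = None,
) -> BellEvansFit:
    """Extract (k0, Δx‡) from modal force vs loading rate.

    Fits F* = slope·ln r + intercept by least squares; then
    Δx‡ = kBT/slope and k0 = (1/slope)·exp(−intercept/slope) (r in pN/s,
    k0 in s⁻¹). Standard errors come from the fit covariance by the delta
    method.
    """
    ctx = ctx or ThermalContext()
    r = np.asarray(loading_rates, dtype=float)
    F = np.asarray(modal_forces, dtype=float)
    if r.size < 3 or np.unique(r).size < 3:
        raise ValueError("need at least 3 distinct loading rates")
    lnr = np.log(r)
    A = np.vstack([lnr, np.ones_like(lnr)]).T
    coef, res, *_ = np.linalg.lstsq(A, F, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if slope <= 0:
        raise ValueError("nonpositive slope: modal force must increase with ln r")

    dof = max(r.size - 2, 1)
    resid = F - A @ coef
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    slope_se, intercept_se = np.sqrt(np.diag(cov))

    kBT = ctx.kBT
    dx = kBT / slope
    k0 = (1.0 / slope) * np.exp(-intercept / slope)
    dx_se = kBT * slope_se / slope ** 2
    # delta method on k0(slope, intercept)
    dk_ds = k0 * (intercept / slope ** 2 - 1.0 / slope)
    dk_di = -k0 / slope
    k0_var = (dk_ds ** 2 * cov[0, 0] + dk_di ** 2 * cov[1, 1]
              + 2 * dk_ds * dk_di * cov[0, 1])
    return BellEvansFit(
        slope=slope, intercept=intercept, k0=float(k0), dx=float(dx),
        slope_se=float(slope_se), intercept_se=float(intercept_se),
        k0_se=float(np.sqrt(max(k0_var, 0.0))), dx_se=float(dx_se),
    )


def prevalence_trend_test(fits_or_obs) -> dict:
    """Weighted regression of η on ln(mean loading rate) across speeds.

    Accepts a sequence of ``(mean_loading_rate, eta, sd_eta)`` triples or
    of PopulationFit objects carrying mean loading rates. Weights are
    1/σ_η² (unweighted fallback with a warning when any σ_η = 0). Returns
    slope, its standard error and the two-sided p-value for slope = 0.
    """
    import statsmodels.api as sm

    rows = []
    for item in fits_or_obs:
        if isinstance(item, PopulationFit):
            eta, sd = pathway_prevalence(item)
            r = item.mean_loading_rate.get("high", np.nan)
            rows.append((r, eta, sd))
        else:
            rows.append(tuple(item))
    if len(rows) < 3:
        raise ValueError("need at least 3 speeds")
    r, eta, sd = map(np.asarray, zip(*rows))

    if np.any(sd == 0):
        warnings.warn("zero prevalence uncertainty; using unweighted fit",
                      stacklevel=2)
        w = np.ones_like(sd)
    else:
        w = 1.0 / sd ** 2
    X = sm.add_constant(np.log(r))
    fit = sm.WLS(eta, X, weights=w).fit()
    slope, se, p = float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
    if not np.isfinite(p):  # perfectly constant η: no evidence of a trend
        p = 1.0 if abs(slope) < 1e-12 else 0.0
    return {"slope": slope, "slope_se": se, "p_value": p}
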