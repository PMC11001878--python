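# Methods

## Kinetic models

Every dissociation (and the weak→strong transition of the catch model)
follows Bell kinetics, `k(F) = k0·exp(F·Δx‡/kBT)`, parameterized by the
zero-force rate `k0` (s⁻¹) and the distance to the transition state `Δx‡`
(nm). The thermal energy defaults to `kBT = 4.114 pN·nm` (T = 298 K,
configurable); all forces are in pN, lengths in nm, times in s.

Two bond topologies are supported:

- **Slip** — the complex is assigned one of several parallel,
  non-interchangeable pathways at binding (native geometry: strong with
  probability 0.64, weak 0.36) and ruptures along it. Pathway prevalence is
  therefore independent of loading rate, and clamp-force lifetimes decrease
  monotonically with force.
- **Catch** — the complex starts weak; per unit time it either ruptures
  (weak profile) or transitions irreversibly to the strong state
  (transition profile `k12`), from which it ruptures via the strong
  profile. Faster loading gives the transition more opportunity at forces
  where `k12` outcompetes weak rupture, so the strong-pathway prevalence η
  grows with pulling speed.

Landscape parameters for the five anchor geometries (native, NN-A…NN-D)
are tabulated in `kinetics.GEOMETRY_TABLE`; NN-C is the catch geometry with
transition profile `k0 = 0.019 s⁻¹`, `Δx‡ = 0.83 nm`.

## Constant-speed protocol

The pulling-force schedule is built on an evenly spaced molecular-extension
grid (default 10⁴ points from 1 nm to 0.995·Lc): the force follows the
interpolated WLC law `F = (kBT/p)[1/(4(1−x/Lc)²) − 1/4 + x/Lc]` (defaults
Lc = 124 nm — the two-ELP tether — and p = 0.4 nm), the cantilever bending
correction maps extension to head height `H = X + F/k` (default
k = 100 pN/nm, inside the 20–140 pN/nm range of the calibrated levers), and
time steps follow from the constant speed, `Δt = ΔH/V`.

Stepping uses the per-interval event probability `P = 1 − exp(−k(F)Δt)`.
Rather than drawing one uniform per step, each replicate draws an Exp(1)
variate and ruptures at the step where the cumulative hazard crosses it —
algebraically identical to the sequential uniform checks, but vectorized.
At the default grid the maximum per-step probability before rupture stays
well below 0.05 for all tabulated parameter sets, and halving the grid step
moves the mean rupture force by < 0.5%.

For the catch model the weak-state step carries two competing hazards.
The default `competing` rule fires an event with the total hazard and picks
its type proportionally to the rates; a `sequential` mode (rupture checked
before transition within the step) is provided for fidelity to
check-ordering conventions — the two coincide as Δt → 0 and agree within
Monte Carlo noise at the default grid.

The per-rupture loading rate is the least-squares slope of F(t) over the
trailing 5% of schedule samples before rupture (min 10 points), computed
with prefix sums. Replicates surviving the whole ramp are counted as
censored and excluded from force statistics (< 1% at defaults).

Force-clamp simulations need no time stepping: at constant force all rates
are constant, so the weak dwell is Exp(k_weak + k12), the branch to strong
has probability k12/(k_weak + k12), and the strong dwell adds Exp(k_strong).
This exact sampler doubles as an internal oracle for the stepped scheme.

## Master-equation twin

For the catch model the two-state occupancies obey

    dS1/dt = −(k_weak + k12)·S1,
    dS2/dt = k12·S1 − k_strong·S2,

integrated along the force schedule with piecewise-constant rates and exact
per-step updates (the degenerate case k_weak + k12 ≈ k_strong falls back to
the confluent closed form). The strong-pathway prevalence
η* = ∫k_strong·S2 dt / (total rupture probability) is deterministic and is
used both as an oracle for the Monte Carlo sampler (3σ binomial agreement
is asserted at n = 4000) and as the fast objective inside the transition
fit.

## Transition-profile inference

Given weak/strong profiles fixed by Bell–Evans fits, (log10 k12_0, Δx12)
minimize `Σ wᵢ(η*ᵢ − ηᵢ)²` with `wᵢ = 1/max(sd_ηᵢ, 0.01)²` via Nelder–Mead
from 5 deterministic starts on a log-spaced grid (objective tolerance
10⁻⁶, ≤ 500 iterations per start). Standard errors come from the numerical
curvature of the objective at the optimum. Constant η across speeds leaves
Δx12 unidentifiable; that case is flagged degenerate and returns the best
rate at Δx12 = 0. The ODE evaluator makes the objective noise-free; an
`mc` mode with common random numbers per candidate is retained. Noiseless
round trips recover both parameters to < 1%; with binomial noise at
n = 1000/speed the median errors stay within 20% (rate) and 0.1 nm
(distance) across the test suite's 6 + 4 parameter sets — a deliberately
desk-scale version of a larger sweep, chosen to keep the suite fast.

## Synthetic force curves

Specific curves emulate one retract cycle of the tethered-complex assay:
a WLC tether whose contour length starts at 124 nm (linkers) + 30 nm
(folded-domain offset, a stand-in — the true folded contribution is not
tabulated) and grows by 32 nm per fingerprint unfolding (two FLN domains by
default; an optional two-substep mode splits each into 16 + 16 nm). The
head-height ramp is evenly spaced (2000 points to 95% of the final contour
length); at each state change the extension/force pair is re-solved from
`x + F_wlc(x)/k = H` by bisection. Fingerprint unfolding competes with bond
rupture (and the catch transition) as Bell hazards along the ramp.

The FLN unfolding profile defaults to `log10 k0 = −4.4`, `Δx‡ = 1.0 nm`,
giving a narrow unfolding-force distribution around ~70 pN — below the
rupture forces of all tabulated geometries but high enough that the
unfolding force drop always clears the 15 pN detector threshold. (A broader
profile leaves a low-force tail of unfoldings whose drops are undetectable
in principle at that threshold.) True FLN kinetics are not tabulated; this
is a generator choice, not an estimate.

Measurement noise is white Gaussian on force (σ = 4 pN default); no 1/f
drift, adhesion peaks, approach segments or cantilever ringing are
modeled — detection statistics on this generator therefore bound, but do
not guarantee, performance on real curves. Non-specific contaminants are
short tethers (Lc uniform in 20–80 nm) with a single detachment and no
fingerprints. Ground truth (event indices, rupture force/pathway,
specific flag) is embedded in each curve's metadata.

## Curve pipeline

Each point with F ≥ 5 pN (the transform is ill-conditioned below) is mapped
to FRC contour length. The FRC inversion is piecewise in `Fb/kBT` against
`b/l` and `l/b`; the printed form of the low-force branch has inconsistent
dimensions, so the standard linear-response result `L = 3·kBT·x/(F·a)` is
used there (the default force floor means this branch is rarely exercised).
Boundary ties go to the higher-force branch.

Event detection: candidate force drops ≥ 15 pN (median-filtered, lag-4
difference; adjacent candidates merged at the steepest step) are confirmed
as unfoldings when the contour length steps by ≥ 10 nm and the post-drop
force does not return to baseline; the final baseline-returning drop is the
rupture. Segment contour lengths are medians over inter-event segments
restricted to the 40–120 pN force band — the band where the
WLC-generated/FRC-transformed contour length is flat to ~1%, so segment
values are mutually comparable; without the band the low-force points that
dominate an evenly-time-sampled ramp bias the medians several percent low.
The same band is applied to the pooled contour-length histogram (1 nm
bins), where the spacing between the first and last prominent peaks reports
the total fingerprint increment (≈ 64 nm for two FLN domains).

Curves are accepted when the final-segment contour length strictly exceeds
124 nm (both ELP linkers fully stretched), which removes the short
non-specific tethers; the loading rate is the trailing-window slope of
F(t) (window 0.5% of samples, min 10 — on an even-time grid the force
accelerates into the rupture, and a longer window underestimates the
rupture loading rate).

## Pathway statistics

Rupture-force histograms (Freedman–Diaconis binning, 2 pN floor) are fit by
nonlinear least squares with one or two Gaussians parameterized by area,
mean, sd; two-component fits are initialized from a Gaussian-mixture prefit
(percentile-based initialization fails when one population dominates, as it
does for the catch geometry at 3200 nm/s where η ≈ 0.85). The component
count is a caller decision per geometry, with an advisory BIC comparison
attached. Degenerate two-component solutions (area < 2% of total, or means
within one pooled sd) collapse to one component with a warning.

The high-force prevalence is η = A_h/(A_h + A_l) with first-order error
propagation through the full fitted area covariance (cross-covariance
included; the diagonal-only value differs negligibly in practice). A
single-component geometry reports (1, 0). Per-pathway loading rates are
means over records assigned by maximum responsibility.

Bell–Evans regression fits `F* = slope·ln r + intercept`, then
`Δx‡ = kBT/slope` and `k0 = (1/slope)·exp(−intercept/slope)`; standard
errors propagate from the fit covariance by the delta method. A
nonpositive slope is rejected as unphysical. The prevalence trend across
speeds is a 1/σ²-weighted linear regression of η on ln(mean loading rate)
with a two-sided p-value on the slope (unweighted fallback when a σ is 0).

## smFRET

The burst search marks a photon as in-burst when the 500 µs window centered
on it holds ≥ 4 photons; maximal runs of in-burst photons (split at gaps
longer than the window) with ≥ 40 photons total are bursts. The centered
window is a convention choice; trailing-window variants differ only at
burst edges. Per-burst counts I_DD/I_DA/I_AA subtract expected background
(rate × duration, floored at 0); the stoichiometry gate keeps
S ∈ [0.2, 0.8]. Efficiency corrections follow
`E = (I_DA − αI_DD − δI_AA)/(γI_DD + I_DA − αI_DD − δI_AA)`, reducing to
the proximity ratio at α = δ = 0, γ = 1; a nonpositive denominator flags
the burst invalid. Correction factors are inputs — global γ estimation from
1/S-vs-E fits, photobleaching/blinking filters and photon-distribution
distance fitting are out of scope (the filter hooks accept external
predicates). Histogram modality is declared bimodal only when a
2-component mixture improves BIC by > 10 *and* separates the means by > 2
pooled sd, guarding against shot-noise splitting.

The synthetic stream draws molecule transits as a Poisson process with
fixed transit duration and per-species brightness; channel assignment
implements S_true (excitation split) and E_true (FRET branch), with α/δ
photons injected and donor detection thinned by 1/γ so matched corrections
recover E_true (round-trip |ΔE| < 0.02 at ≥ 500 bursts). Diffusion-path
brightness variation within a transit is not modeled.

## Numerical choices and limitations

- Bell-rate exponents are capped at 700 (rates beyond e⁷⁰⁰ s⁻¹ are
  indistinguishable from instantaneous rupture) to avoid overflow.
- All simulations take one integer seed; draws are vectorized in a fixed
  order, so every result is bitwise reproducible for (inputs, seed).
- The WLC(p = 0.4 nm) tether and the FRC(b = 0.11 nm, γ = 41°) transform
  are different elasticity models; their residual mismatch is ~1% inside
  the 40–120 pN band and grows below 20 pN. The curve pipeline's banded
  medians are designed around this.
- The catch model's strong-pathway prevalence under force clamp is
  η(F) = k12(F)/(k12(F) + k_weak(F)) in closed form; with the default NN-C
  parameters it reaches 0.855 at 50 pN and crosses 0.99 only near 87 pN —
  the force-clamp pathway suppression saturates more slowly than the
  constant-speed prevalence suggests.
- Rebinding, reversible strong→weak transitions, >2 bound states and
  hydrodynamic cantilever effects are not modeled.
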