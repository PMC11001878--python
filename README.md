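# catchslip

Analysis and simulation toolkit for **anchor-geometry-dependent slip and
catch bond behavior** in single-molecule force spectroscopy (SMFS), built
around the dockerin:cohesin (Doc:Coh) adhesion complex but applicable to any
tethered receptor–ligand pair. It covers the full computational chain of an
AFM pulling experiment with smFRET support:

- **Polymer elasticity** — freely rotating chain (FRC) transform of
  force-extension curves into contour-length space, and the interpolated
  worm-like chain (WLC) force law used to build pulling-force schedules.
- **Curve pipeline** — fingerprint-domain (FLN) unfolding-event detection,
  rupture force / loading-rate extraction, and the two-ELP-linker
  specificity filter (total contour length at rupture > 124 nm).
- **Kinetic Monte Carlo** — stochastic rupture of slip bonds (parallel
  non-interchangeable pathways) and two-state catch bonds (weak state with
  an irreversible, force-activated weak→strong transition), under
  constant-speed and force-clamp protocols, plus a deterministic
  master-equation twin.
- **Pathway statistics** — one/two-Gaussian decomposition of rupture-force
  histograms, high-force prevalence η with propagated uncertainty, and
  Bell–Evans regression of modal force against log loading rate.
- **Transition-rate inference** — weighted nonlinear least squares fitting
  of the weak→strong Bell profile (k12) from η observed at several speeds.
- **smFRET bursts** — sliding-window burst search (500 µs / 4 photons / 40
  photons), ALEX stoichiometry gating (0.2–0.8), corrected FRET efficiency,
  and histogram modality assessment, with a synthetic photon-stream
  generator.

## The model

Bond rupture follows Bell kinetics along the pulling coordinate,

    k_off(F) = k0 · exp(β F Δx‡),      β⁻¹ = k_B T,

which under a constant loading rate r gives the most probable rupture force

    F* = (k_B T / Δx‡) · ln( r Δx‡ / (k0 k_B T) ).

A *slip* geometry assigns each binding event to one of the parallel
pathways (e.g. 64% strong / 36% weak for the native anchor geometry) whose
prevalence is independent of loading rate. The *catch* geometry (Coh residue
F13 / Doc N-terminus) starts every complex in the weak state; a
force-activated transition with its own Bell profile (k12: k0 = 0.019 s⁻¹,
Δx‡ = 0.83 nm) moves it irreversibly to the strong state, so the high-force
pathway prevalence grows with loading rate — the dynamic signature of a
catch bond — and the clamp-force lifetime is non-monotonic around 20–30 pN.

Force-extension curves are converted to contour length L with the FRC
inversion (segment length b = 0.11 nm, bond angle γ = 41°), whose mid-force
branch reads L = x / (1 − (4Fl/k_BT)^(−1/2)) with persistence length
l = b·cos(γ/2)/|ln cos γ|.

## Worked example

```python
from catchslip import *

# simulate the catch geometry at two speeds and compare pathway prevalence
model = bond_model_for_geometry("NN-C")
for V in (100.0, 3200.0):
    rec = simulate_constant_speed(model, PullProtocol(V=V), 1000, seed=1)
    eta, sd = pathway_fraction(rec)
    eta_ode = master_equation_eta(model, PullProtocol(V=V))
    print(f"V={V:6.0f} nm/s  eta_MC={eta:.3f}+-{sd:.3f}  eta_ODE={eta_ode:.3f}")

# fit the transition profile back from the deterministic prevalences
protocols = [PullProtocol(V=v) for v in EXPERIMENT_SPEEDS]
eta = predict_eta(model.transition, model.weak, model.strong, protocols)
obs = [EtaObservation(v, e, 0.02) for v, e in zip(EXPERIMENT_SPEEDS, eta)]
res = fit_transition_profile(obs, model.weak, model.strong, protocols)
print(f"k12_0 = {res.k12_0:.4f} s^-1, dx12 = {res.dx12:.3f} nm")
```

prints

```
V=   100 nm/s  eta_MC=0.418+-0.016  eta_ODE=0.434
V=  3200 nm/s  eta_MC=0.866+-0.011  eta_ODE=0.851
k12_0 = 0.0190 s^-1, dx12 = 0.830 nm
```

The strong-pathway prevalence η rises from ~0.43 at 100 nm/s to ~0.85 at
3200 nm/s — the loading-rate-dependent pathway switching that defines the
catch geometry — with the Monte Carlo estimate agreeing with the
deterministic master equation to within binomial noise. Refitting the
prevalence profile recovers the weak→strong transition parameters exactly.

A command-line interface mirrors the library
(`catchslip simulate-pull | simulate-clamp | generate-curves |
analyze-curves | fit-bell-evans | fit-k12 | fret-generate | fret-bursts |
reproduce`); every stochastic command takes `--seed` and is bitwise
reproducible.

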