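"""Synthetic AFM force-extension curves with the tethered-complex structure.

Each specific curve emulates one approach–retract cycle of the experiment:
two disordered ELP linkers (124 nm of combined contour length) plus folded
domains form a worm-like-chain tether; two filamin (FLN) fingerprint
domains unfold along the ramp, each releasing ~32 nm of contour length; the
final detachment is drawn from a slip or catch bond model. Non-specific
contaminant curves are short tethers (20–80 nm) with a single detachment
and no fingerprints.

Curves carry embedded ground-truth labels (event indices, rupture pathway,
specific/non-specific flag) so the downstream pipeline can be scored
against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .elasticity import (
    EnergyProfile,
    ThermalContext,
    WLCParameters,
    bell_off_rate,
)
from .kinetics import STRONG, WEAK, BondModel, bond_model_for_geometry


#: residues per ELP spacer and contour length per amino acid (nm)
ELP_RESIDUES = 170
CONTOUR_PER_RESIDUE_NM = 0.365


def elp_linker_contour_length(n_linkers: int = 2) -> float:
    """Total contour length (nm) of the fully stretched ELP spacers:
    n_linkers × 170 residues × 0.365 nm/residue."""
    return n_linkers * ELP_RESIDUES * CONTOUR_PER_RESIDUE_NM


@dataclass(frozen=True)
class CurveScenario:
    """Generative settings for one batch of synthetic pulls.

    Lengths in nm, forces in pN, speeds in nm/s, spring constant in pN/nm.
    ``fln_substeps`` splits each fingerprint's contour-length release into
    equal sub-events (the domains unfold through an intermediate; 1 merges
    them into a single step). ``folded_offset_Lc`` is the contour length
    contributed by the folded protein assembly before any unfolding.
    """

    linker_Lc_total: float = 124.0
    fln_count: int = 2
    fln_delta_Lc: float = 32.0
    fln_substeps: int = 1
    fln_unfold_profile: EnergyProfile = field(
        default_factory=lambda: EnergyProfile.from_log10_k0(-4.4, 1.0)
    )
    bond_model: BondModel = field(
        default_factory=lambda: bond_model_for_geometry("native")
    )
    spring_constant: float = 100.0
    pulling_speed: float = 800.0
    force_noise_sd: float = 4.0
    nonspecific_fraction: float = 0.0
    folded_offset_Lc: float = 30.0
    persistence_length: float = 0.4
    n_points: int = 2000
    max_relative_extension: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonspecific_fraction <= 1.0:
            raise ValueError("nonspecific_fraction must lie in [0, 1]")
        for name in ("linker_Lc_total", "fln_delta_Lc", "folded_offset_Lc",
                     "spring_constant", "pulling_speed", "persistence_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fln_count < 0 or self.fln_substeps < 1:
            raise ValueError("fln_count must be >= 0 and fln_substeps >= 1")

    @property
    def initial_Lc(self) -> float:
        return self.linker_Lc_total + self.folded_offset_Lc

    @property
    def final_Lc(self) -> float:
        return self.initial_Lc + self.fln_count * self.fln_delta_Lc


def scenario_from_geometry(code: str, **overrides) -> CurveScenario:
    """Scenario whose final rupture follows the named anchor geometry's bond model."""
    return CurveScenario(bond_model=bond_model_for_geometry(code), **overrides)


@dataclass
class ForceCurve:
    """One sampled force-extension trace with acquisition metadata.

    ``extension`` is the molecular extension (nm, nondecreasing while the
    tether is attached; equals head height after detachment), ``force`` the
    measured (noisy) force (pN). ``metadata`` carries speed, spring
    constant and — for synthetic curves — embedded truth labels.
    """

    extension: np.ndarray
    force: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.extension.shape != self.force.shape:
            raise ValueError("extension and force must have equal length")

    @property
    def time(self) -> np.ndarray:
        """Time axis reconstructed from head height and pulling speed."""
        k = self.metadata["spring_constant_pN_nm"]
        V = self.metadata["speed_nm_s"]
        H = self.extension + np.clip(self.force, 0.0, None) / k
        H = np.maximum.accumulate(H)
        return (H - H[0]) / V


def _extension_from_head_height(H, Lc, p, k, ctx) -> tuple[np.ndarray, np.ndarray]:
    """Solve x + F_wlc(x)/k = H for each head height (monotone bisection)."""
    wlc = WLCParameters(Lc=Lc, p=p)
    H = np.asarray(H, dtype=float)
    lo = np.zeros_like(H)
    hi = np.minimum(H, Lc * (1.0 - 1e-9))
    c = ctx.kBT / p
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        u = mid / Lc
        F = c * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
        go_up = mid + F / k < H
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    x = 0.5 * (lo + hi)
    u = x / Lc
    F = c * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
    return x, F


def _sample_event_step(cum_hazard: np.ndarray, rng) -> int:
    """Index of the step where the cumulative hazard crosses an Exp(1) draw.

    Returns len(cum_hazard) when the event never fires (censored).
    """
    return int(np.searchsorted(cum_hazard, rng.exponential()))


def generate_pull_curves(
    scenario: CurveScenario,
    n: int,
    seed,
    ctx: ThermalContext | None = None,
) -> list[ForceCurve]:
    """Generate ``n`` synthetic force-extension curves.

    Specific curves step a WLC tether along an evenly spaced head-height
    ramp; fingerprint unfolding and the final rupture compete as Bell
    hazards, with each unfolding incrementing the tether contour length.
    A ``nonspecific_fraction`` of curves are short featureless tethers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ctx = ctx or ThermalContext()
    rng = np.random.default_rng(seed)
    p, k, V = scenario.persistence_length, scenario.spring_constant, scenario.pulling_speed

    if scenario.final_Lc * scenario.max_relative_extension <= scenario.initial_Lc * 0.2:
        raise ValueError("inconsistent scenario: ramp never stretches the tether")

    curves: list[ForceCurve] = []
    nonspecific = rng.uniform(size=n) < scenario.nonspecific_fraction
    for i in range(n):
        if nonspecific[i]:
            curves.append(_generate_nonspecific(scenario, rng, ctx))
        else:
            curves.append(_generate_specific(scenario, rng, ctx))
    return curves


#: Generic Bell profile for the detachment of non-specific tip-surface tethers.
NONSPECIFIC_PROFILE = EnergyProfile.from_log10_k0(-2.0, 0.4)


def _generate_specific(scenario: CurveScenario, rng, ctx) -> ForceCurve:
    p, k, V = scenario.persistence_length, scenario.spring_constant, scenario.pulling_speed
    model = scenario.bond_model
    H = np.linspace(1.0, scenario.max_relative_extension * scenario.final_Lc,
                    scenario.n_points)
    dH = H[1] - H[0]
    dt = dH / V

    n_substeps_total = scenario.fln_count * scenario.fln_substeps
    delta_sub = scenario.fln_delta_Lc / scenario.fln_substeps

    # bond state
    if model.topology == "slip":
        probs = [pw.probability for pw in model.pathways]
        pw = model.pathways[rng.choice(len(probs), p=probs)]
        bond_profile, bond_label = pw.profile, pw.label
        transition_profile = None
    else:
        bond_profile, bond_label = model.weak, WEAK
        transition_profile = model.transition

    Lc = scenario.initial_Lc
    i0 = 0
    unfolded = 0
    force = np.zeros_like(H)
    extension = H.copy()
    event_indices: list[int] = []
    rupture_index: int | None = None
    rupture_force = np.nan

    while i0 < len(H):
        x_seg, F_seg = _extension_from_head_height(H[i0:], Lc, p, k, ctx)
        k_bond = bell_off_rate(F_seg, bond_profile, ctx)
        n_folded = n_substeps_total - unfolded
        k_unf = n_folded * bell_off_rate(F_seg, scenario.fln_unfold_profile, ctx)
        k_tr = (bell_off_rate(F_seg, transition_profile, ctx)
                if transition_profile is not None else np.zeros_like(F_seg))
        total = (k_bond + k_unf + k_tr) * dt
        j = _sample_event_step(np.cumsum(total), rng)
        stop = min(j + 1, len(x_seg))
        extension[i0:i0 + stop] = x_seg[:stop]
        force[i0:i0 + stop] = F_seg[:stop]
        if j >= len(x_seg):  # censored: survived the whole ramp
            break
        rates = np.array([k_bond[j], k_unf[j], k_tr[j]])
        kind = rng.choice(3, p=rates / rates.sum())
        at = i0 + j
        if kind == 0:  # final rupture
            rupture_index = at
            rupture_force = F_seg[j]
            extension[at + 1:] = H[at + 1:]
            force[at + 1:] = 0.0
            break
        if kind == 1:  # fingerprint unfolding
            unfolded += 1
            Lc += delta_sub
            event_indices.append(at)
        else:  # weak -> strong catch transition (silent in the trace)
            bond_profile, bond_label = model.strong, STRONG
        i0 = at + 1

    noisy = force + rng.normal(0.0, scenario.force_noise_sd, size=force.shape)
    meta = {
        "speed_nm_s": V,
        "spring_constant_pN_nm": k,
        "specific": True,
        "truth": {
            "event_indices": event_indices,
            "rupture_index": rupture_index,
            "rupture_force_pN": float(rupture_force),
            "pathway": bond_label,
            "n_unfolded_substeps": unfolded,
            "final_Lc_nm": Lc,
        },
    }
    return ForceCurve(extension=extension, force=noisy, metadata=meta)


def _generate_nonspecific(scenario: CurveScenario, rng, ctx) -> ForceCurve:
    p, k, V = scenario.persistence_length, scenario.spring_constant, scenario.pulling_speed
    Lc = rng.uniform(20.0, 80.0)
    H = np.linspace(1.0, scenario.max_relative_extension * scenario.final_Lc,
                    scenario.n_points)
    dt = (H[1] - H[0]) / V
    # tether detaches once it is taut; beyond Lc the tip is free
    attached_mask = H < Lc * scenario.max_relative_extension
    n_att = int(attached_mask.sum())
    x_seg, F_seg = _extension_from_head_height(H[:n_att], Lc, p, k, ctx)
    j = _sample_event_step(np.cumsum(bell_off_rate(F_seg, NONSPECIFIC_PROFILE, ctx) * dt),
                           rng)
    j = min(j, n_att - 1)
    extension = H.copy()
    force = np.zeros_like(H)
    extension[:j + 1] = x_seg[:j + 1]
    force[:j + 1] = F_seg[:j + 1]
    noisy = force + rng.normal(0.0, scenario.force_noise_sd, size=force.shape)
    meta = {
        "speed_nm_s": V,
        "spring_constant_pN_nm": k,
        "specific": False,
        "truth": {
            "event_indices": [],
            "rupture_index": int(j),
            "rupture_force_pN": float(F_seg[j]),
            "pathway": None,
            "n_unfolded_substeps": 0,
            "final_Lc_nm": float(Lc),
        },
    }
    return ForceCurve(extension=extension, force=noisy, metadata=meta)


# ---------------------------------------------------------------------------
# on-disk format: one TSV per curve + JSON sidecar, batch manifest CSV

def write_curve(curve: ForceCurve, path_prefix) -> None:
    """Write ``<prefix>.tsv`` (extension_nm, force_pN) and ``<prefix>.json``."""
    import pandas as pd

    pd.DataFrame(
        {"extension_nm": curve.extension, "force_pN": curve.force}
    ).to_csv(f"{path_prefix}.tsv", sep="\t", index=False)
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(curve.metadata, fh, indent=1)


def read_curve(path_prefix) -> ForceCurve:
    import pandas as pd

    df = pd.read_csv(f"{path_prefix}.tsv", sep="\t")
    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    return ForceCurve(
        extension=df["extension_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        metadata=meta,
    )


def write_batch(curves, directory, prefix="curve") -> "pd.DataFrame":  # noqa: F821
    """Write a batch of curves plus a manifest CSV; returns the manifest."""
    import os

    import pandas as pd

    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, c in enumerate(curves):
        stem = f"{prefix}_{i:05d}"
        write_curve(c, os.path.join(directory, stem))
        rows.append(
            {
                "curve_id": stem,
                "speed_nm_s": c.metadata["speed_nm_s"],
                "specific": c.metadata.get("specific", ""),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(directory, "manifest.csv"), index=False)
    return manifest
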