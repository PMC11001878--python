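"""Force-extension curve analysis: contour-length transform, event
detection, rupture extraction and specificity filtering.

The pipeline mirrors how tethered-complex AFM data are screened: every
point of a retraction curve is mapped to freely-rotating-chain contour
length; genuine single-complex tethers show the full stretch of both ELP
linkers (total contour length at rupture > 124 nm) plus fingerprint
unfolding steps, while short non-specific adhesions fail the contour
length filter and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .elasticity import FRCParameters, ThermalContext, frc_contour_length
from .synthetic import ForceCurve

#: Contour-length threshold (nm) above which a curve shows both fully
#: stretched 170-residue ELP linkers (2 × 170 × 0.365 nm).
ELP_FILTER_LC = 124.0


@dataclass
class ContourLengthProfile:
    """Per-point contour length (nm) with a validity mask."""

    Lc: np.ndarray
    valid: np.ndarray
    curve_id: str = ""

    def valid_values(self) -> np.ndarray:
        return self.Lc[self.valid]


@dataclass(frozen=True)
class UnfoldingEvent:
    """One detected contour-length step (domain unfolding)."""

    index: int
    force_at_event: float
    Lc_before: float
    Lc_after: float

    @property
    def delta_Lc(self) -> float:
        return self.Lc_after - self.Lc_before


@dataclass
class CurveSummary:
    rupture_force: float
    loading_rate: float
    total_Lc_at_rupture: float
    n_events: int
    accepted: bool
    speed: float
    reason: str = ""
    curve_id: str = ""


def transform_to_contour_space(
    curve: ForceCurve,
    frc: FRCParameters | None = None,
    ctx: ThermalContext | None = None,
    force_floor: float = 5.0,
) -> ContourLengthProfile:
    """Map every curve point to FRC contour length.

    Points below ``force_floor`` (pN) are masked invalid: the transform is
    ill-conditioned at low force and those points carry no length
    information.
    """
    if len(curve.force) == 0:
        raise ValueError("empty curve")
    frc = frc or FRCParameters()
    ctx = ctx or ThermalContext()
    F = curve.force
    x = curve.extension
    valid = F >= max(force_floor, 1e-9)
    Lc = np.full(F.shape, np.nan)
    if valid.any():
        Lc[valid] = frc_contour_length(x[valid], F[valid], frc, ctx)
    valid = valid & np.isfinite(Lc) & (Lc > 0)
    profile = ContourLengthProfile(Lc=Lc, valid=valid,
                                   curve_id=curve.metadata.get("curve_id", ""))
    if not valid.any():
        import warnings

        warnings.warn("no valid points above the force floor", stacklevel=2)
    return profile


#: Force band (pN) for segment contour-length medians: the transform is
#: ill-conditioned at low force and branch-limited at very high force, so
#: per-segment Lc values are compared in the band where it is flat.
LC_FORCE_BAND = (40.0, 120.0)


def _segment_median_Lc(
    profile: ContourLengthProfile, force: np.ndarray, lo: int, hi: int,
    force_band: tuple[float, float] = LC_FORCE_BAND,
) -> float:
    sel = profile.valid[lo:hi] & (force[lo:hi] >= force_band[0]) \
        & (force[lo:hi] <= force_band[1])
    vals = profile.Lc[lo:hi][sel]
    if vals.size == 0:  # segment entirely outside the band: fall back
        vals = profile.Lc[lo:hi][profile.valid[lo:hi]]
    return float(np.median(vals)) if vals.size else np.nan


def _candidate_drops(force: np.ndarray, min_force_drop: float, gap: int = 4):
    """Indices i where the (median-filtered) force drops by >= threshold
    between i and i+gap; adjacent candidates are merged to the steepest."""
    Fs = median_filter(force, size=5, mode="nearest")
    drop = Fs[:-gap] - Fs[gap:]
    cand = np.flatnonzero(drop >= min_force_drop)
    if cand.size == 0:
        return [], Fs
    groups = np.split(cand, np.flatnonzero(np.diff(cand) > gap) + 1)
    picks = []
    for g in groups:
        # steepest single-step fall inside the candidate group
        local = np.diff(Fs[g[0]: g[-1] + gap + 1])
        picks.append(int(g[0] + np.argmin(local)))
    return picks, Fs


def detect_unfolding_events(
    curve: ForceCurve,
    profile: ContourLengthProfile,
    min_force_drop: float = 15.0,
    min_delta_Lc: float = 10.0,
    window: int = 25,
) -> list[UnfoldingEvent]:
    """Detect domain-unfolding events on one curve.

    An event is a force drop of at least ``min_force_drop`` pN accompanied
    by a contour-length step of at least ``min_delta_Lc`` nm (median of
    ``window`` valid points on each side). The final detachment — where the
    force returns to baseline — is excluded: it is the rupture, not an
    unfolding.
    """
    picks, Fs = _candidate_drops(curve.force, min_force_drop)
    n = len(curve.force)
    unfolding_picks = []
    for i in picks:
        after_lo = min(i + 3, n - 1)
        after = Fs[after_lo: after_lo + window]
        if after.size == 0 or np.median(after) < max(10.0, min_force_drop / 2):
            continue  # force fell to baseline: detachment, not unfolding
        unfolding_picks.append(i)

    # contour lengths from the full inter-event segments: short windows right
    # after a drop sit at low force where the transform is still settling
    events: list[UnfoldingEvent] = []
    boundaries = [0] + [i + 3 for i in unfolding_picks] + [n]
    for j, i in enumerate(unfolding_picks):
        lc_before = _segment_median_Lc(profile, curve.force, boundaries[j], i + 1)
        lc_after = _segment_median_Lc(profile, curve.force,
                                      boundaries[j + 1], boundaries[j + 2])
        if np.isnan(lc_before) or np.isnan(lc_after):
            continue
        if lc_after - lc_before >= min_delta_Lc:
            events.append(
                UnfoldingEvent(
                    index=i,
                    force_at_event=float(np.median(curve.force[max(0, i - 2): i + 1])),
                    Lc_before=lc_before,
                    Lc_after=lc_after,
                )
            )
    return events


def summarize_curve(
    curve: ForceCurve,
    profile: ContourLengthProfile,
    events: list[UnfoldingEvent],
    tail_fraction: float = 0.005,
    min_force_drop: float = 15.0,
    min_total_Lc: float = ELP_FILTER_LC,
) -> CurveSummary:
    """Extract rupture force, loading rate and final-segment contour length.

    The rupture is the last force drop after which the force stays at
    baseline; the loading rate is the least-squares slope of F(t) over the
    trailing ``tail_fraction`` of samples (minimum 10) before rupture.
    """
    picks, Fs = _candidate_drops(curve.force, min_force_drop)
    n = len(curve.force)
    rupture_idx = None
    for i in reversed(picks):
        after = Fs[min(i + 3, n - 1):]
        if after.size == 0 or np.median(after) < max(10.0, min_force_drop / 2):
            rupture_idx = i
            break
    speed = curve.metadata.get("speed_nm_s", np.nan)
    if rupture_idx is None:
        return CurveSummary(
            rupture_force=np.nan, loading_rate=np.nan, total_Lc_at_rupture=np.nan,
            n_events=len(events), accepted=False, speed=speed, reason="no_rupture",
            curve_id=profile.curve_id,
        )

    rupture_force = float(np.median(curve.force[max(0, rupture_idx - 2): rupture_idx + 1]))
    t = curve.time
    w = max(10, int(np.ceil(tail_fraction * (rupture_idx + 1))))
    lo = max(0, rupture_idx + 1 - w)
    tt, ff = t[lo: rupture_idx + 1], curve.force[lo: rupture_idx + 1]
    if len(tt) >= 2 and np.ptp(tt) > 0:
        slope = float(np.polyfit(tt, ff, 1)[0])
    else:
        slope = np.nan

    seg_start = events[-1].index + 3 if events else 0
    seg_start = min(seg_start, rupture_idx)
    total_Lc = _segment_median_Lc(profile, curve.force, seg_start, rupture_idx + 1)

    accepted = bool(np.isfinite(total_Lc) and total_Lc > min_total_Lc)
    return CurveSummary(
        rupture_force=rupture_force,
        loading_rate=slope,
        total_Lc_at_rupture=total_Lc,
        n_events=len(events),
        accepted=accepted,
        speed=speed,
        reason="" if accepted else "short_tether",
        curve_id=profile.curve_id,
    )


def filter_curves(summaries, min_total_Lc: float = ELP_FILTER_LC):
    """Keep curves whose final-segment contour length strictly exceeds the
    two-linker threshold; returns (accepted list, rejection tally dict)."""
    accepted, tally = [], {}
    for s in summaries:
        ok = np.isfinite(s.total_Lc_at_rupture) and s.total_Lc_at_rupture > min_total_Lc
        if ok:
            accepted.append(s)
        else:
            reason = s.reason or "short_tether"
            tally[reason] = tally.get(reason, 0) + 1
    return accepted, tally


def analyze_curve(
    curve: ForceCurve,
    frc: FRCParameters | None = None,
    ctx: ThermalContext | None = None,
    force_floor: float = 5.0,
    min_force_drop: float = 15.0,
    min_delta_Lc: float = 10.0,
    min_total_Lc: float = ELP_FILTER_LC,
):
    """Convenience: transform, detect events and summarize one curve."""
    profile = transform_to_contour_space(curve, frc, ctx, force_floor)
    events = detect_unfolding_events(curve, profile, min_force_drop, min_delta_Lc)
    summary = summarize_curve(curve, profile, events,
                              min_force_drop=min_force_drop,
                              min_total_Lc=min_total_Lc)
    return profile, events, summary


def assemble_contour_histogram(profiles, bin_width: float = 1.0, forces=None,
                               force_band: tuple[float, float] = LC_FORCE_BAND):
    """Pool valid contour lengths across curves into one histogram.

    When per-curve ``forces`` are supplied, only points inside
    ``force_band`` contribute: the transform is flat there, so dwell states
    appear as sharp peaks instead of low-force smears. Returns
    (bin_edges, counts); the spacing between the first and last major peak
    reports the total fingerprint contour-length increment.
    """
    if not profiles:
        raise ValueError("no profiles")
    if forces is None:
        vals = np.concatenate([p.valid_values() for p in profiles])
    else:
        parts = []
        for p, f in zip(profiles, forces):
            sel = p.valid & (f >= force_band[0]) & (f <= force_band[1])
            parts.append(p.Lc[sel])
        vals = np.concatenate(parts)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no contour-length points in the histogram band")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return edges, counts


def histogram_peak_spacing(edges, counts, min_prominence_frac: float = 0.1) -> float:
    """Distance (nm) between the first and last prominent histogram peak."""
    from scipy.signal import find_peaks

    centers = 0.5 * (edges[:-1] + edges[1:])
    padded = np.concatenate([[0], counts, [0]])  # edge bins can hold peaks
    peaks, _ = find_peaks(padded, prominence=min_prominence_frac * counts.max())
    peaks -= 1
    if len(peaks) < 2:
        return 0.0
    return float(centers[peaks[-1]] - centers[peaks[0]])
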