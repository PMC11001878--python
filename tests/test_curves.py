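"""Curve pipeline: contour-length transform, event detection, rupture
extraction and the two-linker specificity filter."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from catchslip.curves import (
    analyze_curve,
    assemble_contour_histogram,
    detect_unfolding_events,
    filter_curves,
    histogram_peak_spacing,
    summarize_curve,
    transform_to_contour_space,
)
from catchslip.elasticity import (
    EnergyProfile,
    WLCParameters,
    wlc_extension,
    wlc_force,
)
from catchslip.kinetics import STRONG, BondModel, PullProtocol, simulate_constant_speed
from catchslip.synthetic import CurveScenario, ForceCurve, generate_pull_curves


def wlc_curve(Lc=218.0, p=0.5, F_range=(6.0, 140.0), n=800, ctx=None, speed=800.0):
    """Noiseless force-extension trace of a fixed-contour WLC tether."""
    F = np.linspace(*F_range, n)
    x = wlc_extension(F, WLCParameters(Lc=Lc, p=p), ctx)
    return ForceCurve(extension=x, force=F,
                      metadata={"speed_nm_s": speed, "spring_constant_pN_nm": 100.0})


class TestTransform:
    def test_profile_flat_for_matched_persistence(self, ctx):
        """A constant-Lc WLC segment maps to a flat contour-length profile
        (within 2% over 15-100 pN) when the tether's persistence length
        matches the FRC transform's effective one (~0.5 nm)."""
        curve = wlc_curve(Lc=218.0, p=0.5, F_range=(15.0, 100.0))
        prof = transform_to_contour_space(curve, ctx=ctx)
        vals = prof.valid_values()
        assert vals.min() / vals.max() > 0.98

    def test_force_floor_masks_everything(self, ctx):
        curve = wlc_curve()
        with pytest.warns(UserWarning):
            prof = transform_to_contour_space(curve, ctx=ctx, force_floor=np.inf)
        assert not prof.valid.any()

    def test_empty_curve_rejected(self, ctx):
        empty = ForceCurve(extension=np.array([]), force=np.array([]), metadata={})
        with pytest.raises(ValueError):
            transform_to_contour_space(empty, ctx=ctx)


class TestEventDetection:
    def test_noiseless_two_fingerprints(self, ctx):
        sc = CurveScenario(force_noise_sd=0.0)
        curves = generate_pull_curves(sc, 25, seed=11, ctx=ctx)
        for c in curves:
            if c.metadata["truth"]["n_unfolded_substeps"] != 2:
                continue
            prof = transform_to_contour_space(c, ctx=ctx)
            events = detect_unfolding_events(c, prof)
            assert len(events) == 2
            for e in events:
                assert e.delta_Lc == pytest.approx(32.0, abs=4.0)

    def test_flat_curve_no_events(self, ctx):
        curve = ForceCurve(
            extension=np.linspace(0, 100, 500), force=np.zeros(500),
            metadata={"speed_nm_s": 800.0, "spring_constant_pN_nm": 100.0},
        )
        prof = transform_to_contour_space(curve, ctx=ctx)
        assert detect_unfolding_events(curve, prof) == []

    def test_detection_and_false_positive_rates(self, ctx):
        """>=99% of embedded unfoldings recovered, <=1% spurious events, on
        noisy curves at the default thresholds."""
        sc = CurveScenario(force_noise_sd=4.0)
        curves = generate_pull_curves(sc, 500, seed=12, ctx=ctx)
        detected = spurious = total = 0
        for c in curves:
            truth_n = c.metadata["truth"]["n_unfolded_substeps"]
            prof = transform_to_contour_space(c, ctx=ctx)
            events = detect_unfolding_events(c, prof)
            total += truth_n
            detected += min(len(events), truth_n)
            spurious += max(0, len(events) - truth_n)
        assert detected / total >= 0.99
        assert spurious / total <= 0.01


class TestSummaries:
    def test_rupture_force_and_loading_rate_recovered(self, ctx):
        sc = CurveScenario(force_noise_sd=0.0)
        curves = generate_pull_curves(sc, 15, seed=13, ctx=ctx)
        for c in curves:
            truth = c.metadata["truth"]
            if truth["rupture_index"] is None:
                continue
            prof, events, summary = analyze_curve(c, ctx=ctx)
            assert summary.rupture_force == pytest.approx(
                truth["rupture_force_pN"], abs=1.0
            )
            # series-spring identity: r = k_eff * V at the rupture point
            x_r = c.extension[truth["rupture_index"]]
            wlc = WLCParameters(Lc=truth["final_Lc_nm"], p=sc.persistence_length)
            du = 1e-4
            k_wlc = (wlc_force(x_r + du, wlc, ctx)
                     - wlc_force(x_r - du, wlc, ctx)) / (2 * du)
            k_eff = 1.0 / (1.0 / sc.spring_constant + 1.0 / k_wlc)
            assert summary.loading_rate == pytest.approx(
                k_eff * sc.pulling_speed, rel=0.05
            )

    def test_unruptured_curve_flagged(self, ctx):
        curve = wlc_curve(F_range=(6.0, 120.0))
        prof = transform_to_contour_space(curve, ctx=ctx)
        summary = summarize_curve(curve, prof, [])
        assert not summary.accepted
        assert summary.reason == "no_rupture"


@pytest.fixture(scope="module")
def mixed_summaries(ctx):
    sc = CurveScenario(nonspecific_fraction=0.3)
    curves = generate_pull_curves(sc, 300, seed=14, ctx=ctx)
    out = []
    for c in curves:
        _, _, s = analyze_curve(c, ctx=ctx)
        out.append((s, c.metadata["specific"]))
    return out


@pytest.fixture(scope="module")
def histogram_inputs(ctx):
    curves = generate_pull_curves(CurveScenario(force_noise_sd=0.0), 40,
                                  seed=15, ctx=ctx)
    profiles = [transform_to_contour_space(c, ctx=ctx) for c in curves]
    forces = [c.force for c in curves]
    return profiles, forces


class TestFiltering:
    def test_accepted_fraction_matches_specific_fraction(self, mixed_summaries):
        summaries = [s for s, _ in mixed_summaries]
        accepted, tally = filter_curves(summaries)
        n = len(summaries)
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(len(accepted) - 0.7 * n) < 3 * sd
        assert sum(tally.values()) + len(accepted) == n

    def test_accepted_set_is_specific(self, mixed_summaries):
        accepted_flags = [spec for s, spec in mixed_summaries if s.accepted]
        assert np.mean(accepted_flags) >= 0.99

    def test_nonspecific_rejected(self, mixed_summaries):
        for s, specific in mixed_summaries:
            if not specific:
                assert not s.accepted

    def test_idempotent_and_order_independent(self, mixed_summaries):
        summaries = [s for s, _ in mixed_summaries]
        acc1, _ = filter_curves(summaries)
        acc2, _ = filter_curves(acc1)
        assert acc1 == acc2
        acc_rev, _ = filter_curves(summaries[::-1])
        assert {id(s) for s in acc_rev} == {id(s) for s in acc1}


class TestContourHistogram:
    def test_fingerprint_increment_between_extreme_peaks(self, histogram_inputs):
        profiles, forces = histogram_inputs
        edges, counts = assemble_contour_histogram(profiles, bin_width=1.0,
                                                   forces=forces)
        assert histogram_peak_spacing(edges, counts) == pytest.approx(64.0, abs=3.0)

    def test_single_state_single_peak(self, ctx):
        curve = wlc_curve(Lc=218.0, p=0.5, F_range=(20.0, 100.0))
        prof = transform_to_contour_space(curve, ctx=ctx)
        edges, counts = assemble_contour_histogram([prof], bin_width=1.0,
                                                   forces=[curve.force])
        assert histogram_peak_spacing(edges, counts) == 0.0

    def test_bin_doubling_preserves_peaks(self, histogram_inputs):
        profiles, forces = histogram_inputs
        s = [
            histogram_peak_spacing(*assemble_contour_histogram(
                profiles, bin_width=bw, forces=forces))
            for bw in (1.0, 2.0)
        ]
        assert abs(s[0] - s[1]) <= 2.0


class TestPipelineAgainstSimulator:
    def test_extracted_ruptures_match_direct_simulation(self, ctx):
        """Rupture forces read off noiseless curves reproduce the rupture
        simulator's distribution for the same bond model and tether."""
        profile = EnergyProfile.from_log10_k0(-4.2, 0.65)
        model = BondModel.slip([(STRONG, profile, 1.0)])
        sc = CurveScenario(fln_count=0, force_noise_sd=0.0, bond_model=model)
        curves = generate_pull_curves(sc, 600, seed=16, ctx=ctx)
        extracted = []
        for c in curves:
            _, _, s = analyze_curve(c, ctx=ctx, min_total_Lc=100.0)
            if np.isfinite(s.rupture_force):
                extracted.append(s.rupture_force)
        wlc = WLCParameters(Lc=sc.initial_Lc, p=sc.persistence_length)
        rec = simulate_constant_speed(
            model, PullProtocol(V=sc.pulling_speed, k=sc.spring_constant, wlc=wlc),
            600, seed=17, ctx=ctx,
        )
        assert ks_2samp(np.array(extracted), rec["force_pN"]).pvalue > 0.01
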