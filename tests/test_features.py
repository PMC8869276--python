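import numpy as np
import pytest

from thermofatigue.bands import BANDS_BY_LABEL, CANONICAL_BANDS, FrequencyBand
from thermofatigue.features import (
    AnalysisWindows,
    FEATURE_COLUMNS,
    PsdSettings,
    band_is_resolution_limited,
    band_power,
    compute_feature_table,
    delta_psd,
    delta_t_roi,
    estimate_psd,
)
from thermofatigue.synthetic import (
    BandOscillator,
    ROISignalModel,
    synthesize_trace,
)
from thermofatigue.timeline import make_default_timeline
from thermofatigue.trace import ROITrace

FS = 10.0


def tone(freq, amp=0.1, n=3000, fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestAnalysisWindows:
    def test_windows_anchor_to_timeline(self, default_timeline):
        win = AnalysisWindows.from_timeline(default_timeline)
        assert win.dt_baseline == (280.0, 290.0)
        assert win.dt_final == (1100.0, 1110.0)
        assert win.psd_pre == (0.0, 300.0)
        assert win.psd_post == (810.0, 1110.0)

    def test_short_recovery_violates_post_epoch(self):
        tl = make_default_timeline([60.0, 50.0, 40.0], recovery_s=200.0)
        win = AnalysisWindows.from_timeline(tl)
        assert "psd_post" in win.epoch_violations(tl)


class TestDeltaT:
    def test_constant_trace_gives_zero(self, default_timeline):
        tr = ROITrace("x", np.full(11100, 31.0), fs=FS)
        assert delta_t_roi(tr, default_timeline) == 0.0

    def test_plateau_construction_recovers_injected_change(self, default_timeline):
        model = ROISignalModel(
            baseline_temp=30.0, phase_slopes={"set": 1.5 / 150.0}, noise_sd=0.0
        )
        tr = synthesize_trace(model, default_timeline, fs=FS, seed=0)
        assert delta_t_roi(tr, default_timeline) == pytest.approx(1.5, abs=1e-12)

    def test_linear_ramp_closed_form(self, default_timeline):
        # window means sit at the window centres for a linear ramp:
        # 0.001 degC/s * (1105 - 285) s = 0.820 degC
        t = np.arange(11100) / FS
        tr = ROITrace("x", 30.0 + 0.001 * t, fs=FS)
        assert delta_t_roi(tr, default_timeline) == pytest.approx(0.820, abs=1e-9)

    def test_out_of_range_window_names_window(self):
        tl = make_default_timeline([60.0], baseline_s=15.0, recovery_s=300.0)
        n = int(round(tl.end_s * FS))
        tr = ROITrace("x", np.full(n, 31.0), fs=FS)
        with pytest.raises(ValueError, match="dt_baseline"):
            delta_t_roi(tr, tl)


class TestEstimatePsd:
    def test_zero_signal_gives_zero_density(self):
        psd = estimate_psd(np.zeros(3000), FS)
        assert np.all(psd.density == 0.0)

    def test_wrong_segment_length_rejected(self):
        with pytest.raises(ValueError, match="padding"):
            estimate_psd(np.zeros(2999), FS)

    def test_pure_tone_parseval(self):
        # integral of the PSD over [0, fs/2] recovers A^2/2 for a pure tone
        psd = estimate_psd(tone(0.1, amp=0.1), FS)
        assert psd.total_power() == pytest.approx(0.005, rel=0.05)

    def test_white_noise_total_power_matches_variance(self, rng):
        sigma = 0.03
        x = rng.normal(0, sigma, 3000)
        psd = estimate_psd(x, FS)
        assert psd.total_power() == pytest.approx(sigma**2, rel=0.10)

    def test_settings_are_recorded(self):
        st = PsdSettings(segment_s=100.0, overlap=0.25)
        psd = estimate_psd(np.zeros(3000), FS, st)
        assert psd.settings == st
        assert psd.df == pytest.approx(FS / 1000)


class TestBandPower:
    def test_zero_density_gives_zero_everywhere(self):
        psd = estimate_psd(np.zeros(3000), FS)
        assert all(band_power(psd, b) == 0.0 for b in CANONICAL_BANDS)

    def test_myogenic_tone_lands_in_myogenic_band(self):
        psd = estimate_psd(tone(0.1, amp=0.1), FS)
        total = psd.total_power()
        myo = band_power(psd, BANDS_BY_LABEL["myogenic"])
        assert myo == pytest.approx(0.005, rel=0.05)
        assert myo / total >= 0.90
        assert band_power(psd, BANDS_BY_LABEL["cardiac"]) <= 0.01 * total

    def test_white_noise_band_power_scales_with_bandwidth(self, rng):
        # flat spectrum: expected myogenic/neurogenic ratio = 0.11/0.02 = 5.5;
        # averaged over realizations to tame the narrow band's variance
        myo, neu = 0.0, 0.0
        for _ in range(20):
            psd = estimate_psd(rng.normal(0, 1.0, 3000), FS)
            myo += band_power(psd, BANDS_BY_LABEL["myogenic"])
            neu += band_power(psd, BANDS_BY_LABEL["neurogenic"])
        assert myo / neu == pytest.approx(5.5, rel=0.2)

    def test_band_above_nyquist_rejected(self):
        psd = estimate_psd(np.zeros(3000), FS)
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(psd, FrequencyBand("too_high", 4.0, 6.0))

    def test_band_power_additive_over_partition(self, rng):
        x = rng.normal(0, 1.0, 3000) + tone(0.1, 0.2)
        psd = estimate_psd(x, FS)
        whole = band_power(psd, FrequencyBand("myo", 0.04, 0.15))
        parts = [
            band_power(psd, FrequencyBand("a", 0.04, 0.071)),
            band_power(psd, FrequencyBand("b", 0.071, 0.1201)),
            band_power(psd, FrequencyBand("c", 0.1201, 0.15)),
        ]
        assert sum(parts) == pytest.approx(whole, rel=1e-12)

    def test_dc_offset_changes_no_band_power(self, rng):
        x = rng.normal(0, 0.1, 3000)
        p0 = estimate_psd(x, FS)
        p1 = estimate_psd(x + 5.0, FS)
        for b in CANONICAL_BANDS:
            assert band_power(p1, b) == pytest.approx(
                band_power(p0, b), rel=1e-9, abs=1e-15
            )

    def test_metabolic_band_is_resolution_limited_at_defaults(self):
        psd = estimate_psd(np.zeros(3000), FS)
        assert band_is_resolution_limited(psd, BANDS_BY_LABEL["metabolic"])
        assert not band_is_resolution_limited(psd, BANDS_BY_LABEL["myogenic"])

    def test_band_sum_tracks_injected_tone_power(self, rng):
        # independent oracle: the injected power of a noiseless multi-tone
        # signal is known exactly as sum(A_i^2 / 2)
        for _ in range(10):
            freqs = [
                rng.uniform(lo, hi)
                for lo, hi in [(0.025, 0.04), (0.05, 0.14), (0.2, 0.45), (0.55, 0.95)]
            ]
            amps = rng.uniform(0.02, 0.2, size=len(freqs))
            phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
            x = sum(tone(f, a, phase=ph) for f, a, ph in zip(freqs, amps, phases))
            psd = estimate_psd(x, FS)
            injected = float(np.sum(amps**2) / 2)
            band_sum = sum(band_power(psd, b) for b in CANONICAL_BANDS)
            assert band_sum == pytest.approx(injected, rel=0.05)


class TestDeltaPsd:
    def make_trace(self, default_timeline, pre=(), post=(), noise_sd=0.0, seed=0):
        model = ROISignalModel(
            baseline_temp=32.0, oscillators_pre=pre, oscillators_post=post,
            noise_sd=noise_sd,
        )
        return synthesize_trace(model, default_timeline, fs=FS, seed=seed)

    def test_identical_epochs_give_exact_zero(self, default_timeline):
        tr = self.make_trace(default_timeline)
        feats = delta_psd(tr, default_timeline)
        assert all(v == 0.0 for v in feats.delta_psd.values())
        for b in feats.band_power_pre:
            assert feats.delta_psd[b] == (
                feats.band_power_post[b] - feats.band_power_pre[b]
            )

    def test_injected_post_tone_appears_in_its_band(self, default_timeline):
        osc = (BandOscillator("myogenic", 0.1, frequency=0.1),)
        feats = delta_psd(self.make_trace(default_timeline, post=osc),
                          default_timeline)
        assert feats.delta_psd["myogenic"] == pytest.approx(0.005, rel=0.10)
        for other in ("neurogenic", "respiratory", "cardiac"):
            assert abs(feats.delta_psd[other]) < 0.0005

    def test_pre_tone_flips_the_sign(self, default_timeline):
        osc = (BandOscillator("myogenic", 0.1, frequency=0.1),)
        post_f = delta_psd(self.make_trace(default_timeline, post=osc),
                           default_timeline)
        pre_f = delta_psd(self.make_trace(default_timeline, pre=osc),
                          default_timeline)
        assert pre_f.delta_psd["myogenic"] == pytest.approx(
            -post_f.delta_psd["myogenic"], rel=1e-6
        )

    def test_infeasible_window_errors(self):
        tl = make_default_timeline([60.0], baseline_s=100.0)
        n = int(round(tl.end_s * FS))
        tr = ROITrace("x", np.full(n, 31.0), fs=FS)
        with pytest.raises(ValueError, match="psd_pre"):
            delta_psd(tr, tl)


class TestComputeFeatureTable:
    def test_shape_for_full_cohort(self, default_timeline):
        traces = {}
        for i in range(8):
            sid = f"S{i + 1:02d}"
            traces[sid] = {
                roi: synthesize_trace(
                    ROISignalModel(baseline_temp=31.0, noise_sd=0.01),
                    default_timeline, fs=FS, seed=i,
                    label=roi,
                )
                for roi in ("Exercised Leg", "Nonexercised Leg", "Nose Tip",
                            "Corrugator")
            }
        rpe = {sid: 7 for sid in traces}
        table = compute_feature_table(traces, default_timeline, rpe)
        assert len(table.data) == 32
        assert list(table.data.columns[2:8]) == list(FEATURE_COLUMNS)
        assert table.exclusions == ()
        assert (table.data["flags"] == "resolution_limited:metabolic").all()

    def test_recovered_delta_t_matches_injection(self, default_timeline):
        model = ROISignalModel(
            baseline_temp=30.0, phase_slopes={"set": 1.5 / 150.0}, noise_sd=0.03
        )
        traces = {
            "S01": {"Exercised Leg": synthesize_trace(
                model, default_timeline, fs=FS, seed=1, label="Exercised Leg")},
            "S02": {"Exercised Leg": synthesize_trace(
                model, default_timeline, fs=FS, seed=2, label="Exercised Leg")},
        }
        table = compute_feature_table(traces, default_timeline, {"S01": 7, "S02": 8})
        se = 0.03 * np.sqrt(2 / 100)  # two 100-sample window means
        assert table.data["delta_t"].mean() == pytest.approx(1.5, abs=4 * se)

    def test_subject_with_short_recovery_excluded_with_reason(self, default_timeline):
        short_tl = make_default_timeline([60.0, 50.0, 40.0], recovery_s=200.0)
        good = ROISignalModel(baseline_temp=31.0, noise_sd=0.0)
        traces = {
            "S01": {"Nose Tip": synthesize_trace(
                good, default_timeline, fs=FS, seed=1, label="Nose Tip")},
            "S02": {"Nose Tip": synthesize_trace(
                good, short_tl, fs=FS, seed=2, label="Nose Tip")},
        }
        timelines = {"S01": default_timeline, "S02": short_tl}
        table = compute_feature_table(traces, timelines, {"S01": 7, "S02": 8})
        assert [sid for sid, _ in table.exclusions] == ["S02"]
        assert "psd_post" in table.exclusions[0][1]
        assert set(table.data["subject_id"]) == {"S01"}
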