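"""Per-cell descriptors: polarity, transiency, speed, CPI, CFI, Gaussian fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.stats import spearmanr

from rgctypes import indices, metrics, stimuli as st, synthetic
from rgctypes.metrics import ChirpSpectrum, FlashPSTH, GratingResponseMap


def _psth(peaks, spont_mean, spont_sd):
    """FlashPSTH stub from (sign, peak) pairs."""
    transitions = [(2.0, -1), (4.0, 1), (6.0, 1), (8.0, -1)]
    tp = []
    for (t, sign), peak in zip(transitions, peaks):
        tp.append((t, sign, peak, t + 0.05))
    return FlashPSTH(time=np.arange(10_000) * 0.001, rate=np.zeros(10_000),
                     spont_mean=spont_mean, spont_sd=spont_sd,
                     transition_peaks=tp)


def _spectrum(freqs, ratio):
    return ChirpSpectrum(freqs=np.asarray(freqs, dtype=float),
                         ratio=np.asarray(ratio, dtype=float),
                         raw_ratio=np.asarray(ratio, dtype=float))


class TestPolarity:
    def test_on_cell(self):
        # positive peaks 30, negative 4; threshold = 5 + 2*2 = 9
        p = _psth([4.0, 30.0, 30.0, 4.0], 5.0, 2.0)
        assert indices.polarity(p) == "ON"

    def test_on_off_cell(self):
        p = _psth([25.0, 20.0, 20.0, 25.0], 5.0, 2.0)
        assert indices.polarity(p) == "ON-OFF"

    def test_none_below_threshold(self):
        p = _psth([8.0, 8.0, 8.0, 8.0], 5.0, 2.0)
        assert indices.polarity(p) == "none"

    def test_off_cell(self):
        p = _psth([30.0, 4.0, 4.0, 30.0], 5.0, 2.0)
        assert indices.polarity(p) == "OFF"


class TestTransiency:
    def _exponential_psth(self, tau, peak_sd=10.0, spont=5.0, sd=1.0):
        dt = 0.001
        time = np.arange(10_000) * dt
        rate = np.full(10_000, spont)
        t0 = 6.0
        mask = time >= t0
        rate[mask] = spont + peak_sd * sd * np.exp(-(time[mask] - t0) / tau)
        peaks = [(6.0, 1, float(rate.max()), t0)]
        return FlashPSTH(time=time, rate=rate, spont_mean=spont, spont_sd=sd,
                         transition_peaks=peaks)

    def test_closed_form_exponential_return(self):
        # peak 10 SD above spont, tau=100 ms: returns at tau*ln(10/2) ~ 161 ms
        p = self._exponential_psth(tau=0.1)
        expected = 0.1 * math.log(10.0 / 2.0) * 1000
        assert indices.transiency(p) == pytest.approx(expected, abs=2.0)

    def test_capped_at_step_duration(self):
        p = self._exponential_psth(tau=50.0)  # never returns within 2 s
        assert indices.transiency(p) == 2000.0

    def test_instant_drop_is_one_sample(self):
        time = np.arange(10_000) * 0.001
        rate = np.full(10_000, 5.0)
        rate[6000] = 50.0
        p = FlashPSTH(time=time, rate=rate, spont_mean=5.0, spont_sd=1.0,
                      transition_peaks=[(6.0, 1, 50.0, 6.0)])
        assert indices.transiency(p) == 1.0

    def test_no_responding_transition_raises(self):
        p = _psth([4.0, 4.0, 4.0, 4.0], 5.0, 2.0)
        with pytest.raises(ValueError):
            indices.transiency(p)

    def test_monotone_in_kinetic_tau(self):
        """Transiency ranks exactly follow the simulated decay constants."""
        # return times tau*ln((peak-spont)/2SD) must stay below the 2 s cap
        # or the top ranks tie at the cap
        taus = [0.04, 0.08, 0.15, 0.25, 0.4]
        measured = []
        base = synthetic.make_archetypes()[0]
        for tau in taus:
            cell = synthetic.SyntheticCellSpec(
                label="t", polarity="ON", kinetic_tau=tau,
                tf_center=base.tf_center, tf_sigma=base.tf_sigma,
                sf_center=base.sf_center, sf_sigma=base.sf_sigma,
                contrast_c50=0.3, baseline_rate=3.0, max_rate=70.0)
            rate = synthetic.simulate_rate(cell, st.FlashStimulus())
            psth = metrics.flash_psth_from_rate(rate)
            psth.spont_sd = 1.0  # model a 1 Hz noise floor for the 2-SD return
            measured.append(indices.transiency(psth))
        assert all(a < b for a, b in zip(measured, measured[1:]))
        rho, _ = spearmanr(taus, measured)
        assert rho == pytest.approx(1.0)


class TestMedianSpeed:
    def test_equal_peaks_hits_middle_speed(self):
        peaks = {s: 1.0 for s in (1.0, 2.0, 4.0, 8.0, 16.0)}
        assert indices.median_speed_preference(peaks) == 4.0

    def test_all_response_at_fastest(self):
        peaks = {1.0: 0.0, 2.0: 0.0, 4.0: 0.0, 8.0: 0.0, 16.0: 5.0}
        assert indices.median_speed_preference(peaks) == 16.0

    def test_cumulative_crossing(self):
        peaks = dict(zip((1.0, 2.0, 4.0, 8.0, 16.0), (10.0, 30.0, 5.0, 5.0, 0.0)))
        assert indices.median_speed_preference(peaks) == 2.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            indices.median_speed_preference({1.0: 0.0, 2.0: 0.0})


class TestCPI:
    def test_modulation_only_in_last_third(self):
        rate = np.full(8000, 10.0)
        rate[-2000:] = 40.0
        assert indices.contrast_preference_index(rate, 10.0) == pytest.approx(1.0)

    def test_symmetric_modulation_is_zero(self):
        rate = np.full(8000, 10.0)
        rate[:1000] = 30.0
        rate[-1000:] = 30.0
        assert indices.contrast_preference_index(rate, 10.0) == pytest.approx(0.0)

    def test_zero_modulation_rejected(self):
        with pytest.raises(ValueError):
            indices.contrast_preference_index(np.full(8000, 10.0), 10.0)

    def test_saturating_cell_has_lower_cpi(self, archetypes):
        from dataclasses import replace
        stim = st.ChirpStimulus(kind="contrast_ramp", pre_grey=2.0)
        def cpi_for(c50):
            cell = replace(archetypes["transient_on"], contrast_c50=c50)
            rate = synthetic.simulate_rate(cell, stim)
            return indices.contrast_preference_index(
                rate, cell.baseline_rate, ramp_start=2.0)
        assert cpi_for(0.1) < cpi_for(0.9)

    def test_antisymmetric_under_third_swap(self):
        rng = np.random.default_rng(0)
        rate = 10.0 + rng.uniform(0, 20, 8000)
        a = indices.contrast_preference_index(rate, 10.0)
        b = indices.contrast_preference_index(rate[::-1].copy(), 10.0)
        assert a == pytest.approx(-b)


class TestCFI:
    @staticmethod
    def _grid():
        return np.arange(0.5, 8.001, 0.125)

    def test_support_only_in_high_band(self):
        f = self._grid()
        ratio = np.where((f >= 6.0) & (f <= 7.2), 1.0, 0.0)
        assert indices.chirp_frequency_index(_spectrum(f, ratio)) == pytest.approx(1.0)

    def test_flat_ratio_is_zero(self):
        f = self._grid()
        assert indices.chirp_frequency_index(_spectrum(f, np.ones_like(f))) == \
            pytest.approx(0.0)

    def test_band_swap_negates_index(self):
        f = self._grid()
        hi = np.where((f >= 6.0) & (f <= 7.2), 1.0, 0.0)
        lo = np.where((f >= 0.7) & (f <= 3.0), 1.0, 0.0)
        a = indices.chirp_frequency_index(_spectrum(f, hi + 0.1))
        b = indices.chirp_frequency_index(_spectrum(f, lo + 0.1))
        assert a > 0 > b

    def test_simulated_low_vs_high_pass(self, archetypes):
        from rgctypes.metrics import BinnedResponse, chirp_spectrum
        stim = st.ChirpStimulus(kind="frequency_ramp")
        trace = stim.trace()
        def cfi_for(label):
            rate = synthetic.simulate_rate(archetypes[label], stim)
            trials = synthetic.generate_spikes(rate, 0.001, 10, seed=5)
            binned = np.zeros((10, trace.size))
            for i, tt in enumerate(trials):
                idx = np.minimum((tt / 0.001).astype(int), trace.size - 1)
                binned[i, idx] = 1.0
            spec = chirp_spectrum(BinnedResponse(trials=binned), trace)
            return indices.chirp_frequency_index(spec)
        assert cfi_for("lowtf_on") < 0
        assert cfi_for("transient_on") > 0

    def test_missing_band_rejected(self):
        f = np.arange(2.0, 5.0, 0.125)
        with pytest.raises(ValueError):
            indices.chirp_frequency_index(_spectrum(f, np.ones_like(f)))


def _map(strengths, valid=None):
    s = np.asarray(strengths, dtype=float)
    v = np.ones_like(s, dtype=bool) if valid is None else valid
    return GratingResponseMap(strengths=s, valid=v)


class TestGaussianFit:
    def test_point_mass(self):
        s = np.zeros((6, 4))
        s[2, 2] = 1.0  # (500 um, 4 Hz)
        fit = indices.fit_gaussian_heatmap(_map(s))
        assert (fit.csf, fit.ctf) == (500.0, 4.0)
        assert fit.a == fit.b == fit.c == 0.0
        assert fit.major_axes == (0.0, 0.0)

    def test_two_equal_entries_symmetric(self):
        s = np.zeros((6, 4))
        s[1, 1] = 1.0  # (200, 2)
        s[3, 1] = 1.0  # (1000, 2)
        fit = indices.fit_gaussian_heatmap(_map(s))
        assert fit.csf == pytest.approx(600.0)
        assert fit.ctf == pytest.approx(2.0)
        assert fit.b == pytest.approx(0.0)

    def test_scale_invariance_of_centroid(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0.1, 1.0, (6, 4))
        f1 = indices.fit_gaussian_heatmap(_map(s))
        f2 = indices.fit_gaussian_heatmap(_map(7.3 * s))
        assert f1.csf == pytest.approx(f2.csf)
        assert f1.ctf == pytest.approx(f2.ctf)

    def test_off_grid_gaussian_centroid_on_log_axes(self):
        # separable Gaussian centered between grid points; the log-axis fit
        # recovers the injected center within half a (one-octave) grid step
        periods = np.log2(np.asarray(st.GRATING_PERIODS_UM))
        freqs = np.log2(np.asarray(st.GRATING_FREQS_HZ))
        c_sf, c_tf = np.log2(700.0), np.log2(3.0)
        s = np.exp(-0.5 * (((periods[:, None] - c_sf) / 1.0) ** 2
                           + ((freqs[None, :] - c_tf) / 1.0) ** 2))
        fit = indices.fit_gaussian_heatmap(_map(s), log_axes=True)
        assert abs(np.log2(fit.csf) - c_sf) <= 0.5
        assert abs(np.log2(fit.ctf) - c_tf) <= 0.5

    def test_no_valid_entries_raises(self):
        s = np.ones((6, 4))
        with pytest.raises(ValueError):
            indices.fit_gaussian_heatmap(_map(s, valid=np.zeros((6, 4), bool)))

    @settings(max_examples=25, derandomize=True)
    @given(hst.integers(min_value=0, max_value=2 ** 24 - 1))
    def test_centroid_stays_inside_grid(self, bits):
        rng = np.random.default_rng(bits)
        s = rng.uniform(0, 1, (6, 4))
        v = rng.uniform(size=(6, 4)) < 0.7
        if not (v & (s > 0)).any():
            return
        fit = indices.fit_gaussian_heatmap(_map(s, valid=v))
        assert 100.0 <= fit.csf <= 4000.0
        assert 1.0 <= fit.ctf <= 8.0


class TestBuildProfile:
    def test_grating_only_profile(self):
        s = np.zeros((6, 4)); s[4, 2] = 1.0
        prof = indices.build_profile("u1", rmap=_map(s))
        assert prof.polarity is None
        assert prof.sf_preference_um == pytest.approx(2000.0)
        assert prof.tf_preference_hz == pytest.approx(4.0)

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            indices.build_profile("u1")

    def test_fully_probed_unit(self, mixed_population):
        _, labels, analyses = mixed_population
        full = [a for a, l in zip(analyses, labels)
                if l.archetype == "transient_on"]
        for a in full:
            p = a.profile
            assert p.polarity is not None
            assert p.sf_preference_um is not None
            assert p.cfi is not None and -1 <= p.cfi <= 1
            assert p.cpi is not None and -1 <= p.cpi <= 1
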