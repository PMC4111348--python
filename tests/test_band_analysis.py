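"""Band integration, the organic-phosphate ratio, replicate aggregation,
fluorescence rejection and C-H presence scoring."""

import math

import numpy as np
import pytest

import ramanbone as rb
from ramanbone import band_analysis as ba
from ramanbone.spectra_io import SpectrumRangeError


def _flat(value, lo=0.0, hi=3200.0, step=1.0):
    w = np.arange(lo, hi + step, step)
    return rb.RamanSpectrum("flat", 1, w, np.full(w.size, float(value)))


class TestIntegrateBand:
    def test_zero_spectrum_integrates_to_zero(self):
        spec = _flat(0.0)
        for mode in ("none", "local_linear"):
            assert rb.integrate_band(spec, ba.PO4_V1_WINDOW, mode) == 0.0

    def test_constant_cancels_under_chord_baseline(self):
        spec = _flat(7.5)
        assert rb.integrate_band(spec, ba.CH_WINDOW, "local_linear") == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_gaussian_band_matches_erf_oracle(self):
        # unit-height Gaussian, center 956 sigma 10, fine 0.1 cm^-1 grid
        w = np.arange(800.0, 1100.0, 0.1)
        y = np.exp(-0.5 * ((w - 956.0) / 10.0) ** 2)
        spec = rb.RamanSpectrum("g", 1, w, y)
        area = rb.integrate_band(spec, ba.PO4_V1_WINDOW, "none")
        exact = (
            10.0 * math.sqrt(math.pi / 2.0)
            * (math.erf((983 - 956) / (10 * math.sqrt(2)))
               - math.erf((930 - 956) / (10 * math.sqrt(2))))
        )
        assert area == pytest.approx(exact, rel=5e-4)
        assert area == pytest.approx(24.86, abs=0.01)

    def test_window_outside_range_rejected(self):
        spec = _flat(1.0, lo=500.0, hi=800.0)
        with pytest.raises(SpectrumRangeError):
            rb.integrate_band(spec, ba.CH_WINDOW, "none")


class TestBandAreas:
    def test_homogeneity_in_intensity_scale(self, clean_spectrum):
        k = 3.7
        scaled = clean_spectrum.with_values(
            clean_spectrum.wavenumbers, k * clean_spectrum.intensities
        )
        a = rb.band_areas(clean_spectrum)
        b = rb.band_areas(scaled)
        assert b.ch_area == pytest.approx(k * a.ch_area, rel=1e-12)
        assert b.po4_v1_area == pytest.approx(k * a.po4_v1_area, rel=1e-12)
        assert b.po4_v2_area == pytest.approx(k * a.po4_v2_area, rel=1e-12)

    def test_affine_baseline_invariance_is_exact(self, clean_spectrum):
        w = clean_spectrum.wavenumbers
        shifted = clean_spectrum.with_values(
            w, clean_spectrum.intensities + 123.0 - 0.45 * w
        )
        a = rb.band_areas(clean_spectrum, "local_linear")
        b = rb.band_areas(shifted, "local_linear")
        assert b.ch_area == pytest.approx(a.ch_area, rel=1e-9, abs=1e-9)
        assert b.po4_v1_area == pytest.approx(a.po4_v1_area, rel=1e-9)
        assert b.po4_v2_area == pytest.approx(a.po4_v2_area, rel=1e-9)

    def test_zero_organic_clips_ch_area_to_zero(self, noiseless_config):
        spec = rb.simulate_spectrum(noiseless_config, 0.0, seed=3)
        areas = rb.band_areas(spec)
        assert areas.ch_area == 0.0
        assert areas.po4_v1_area > 0.0

    def test_noiseless_synthetic_matches_generator_closed_form(
        self, noiseless_config
    ):
        spec = rb.simulate_spectrum(noiseless_config, 2.0, seed=0)
        areas = rb.band_areas(spec, baseline_mode="none")
        assert areas.ch_area / areas.po4_v1_area == pytest.approx(
            rb.closed_form_ratio(noiseless_config, 2.0), rel=1e-3
        )


class TestRatio:
    def _areas(self, ch, v1, v2=10.0):
        return ba.BandAreas(ch, v1, v2, "none")

    def test_zero_organic_gives_zero_ratio(self):
        assert rb.organic_phosphate_ratio(self._areas(0.0, 5.0)) == 0.0

    def test_equal_areas_give_unit_ratio(self):
        assert rb.organic_phosphate_ratio(self._areas(4.0, 4.0)) == 1.0

    def test_scale_invariance(self):
        r1 = rb.organic_phosphate_ratio(self._areas(2.0, 3.0, 4.0))
        r5 = rb.organic_phosphate_ratio(self._areas(10.0, 15.0, 20.0))
        assert r1 == pytest.approx(r5, rel=1e-15)

    def test_alternative_denominator_includes_nu2(self):
        areas = self._areas(6.0, 2.0, 4.0)
        assert rb.organic_phosphate_ratio(areas, "v1_plus_v2") == (
            pytest.approx(1.0)
        )

    def test_missing_mineral_band_raises(self):
        with pytest.raises(rb.UndefinedRatioError):
            rb.organic_phosphate_ratio(self._areas(1.0, 0.0))


class TestAggregateReplicates:
    @pytest.mark.parametrize(
        "ratios, mean, sd, flag",
        [
            ([0.3, 0.3, 0.3], 0.3, 0.0, False),
            # sd/mean = 0.333 exceeds the 0.25 heterogeneity threshold
            ([0.2, 0.3, 0.4], 0.3, 0.1, True),
            ([0.5], 0.5, 0.0, False),
        ],
    )
    def test_mean_sd_and_flag(self, ratios, mean, sd, flag):
        m, s, f = rb.aggregate_replicates(ratios)
        assert m == pytest.approx(mean)
        assert s == pytest.approx(sd)
        assert f is flag

    def test_empty_input_is_missing(self):
        m, s, f = rb.aggregate_replicates([])
        assert m is None and math.isnan(s) and f is False


class TestFluorescence:
    def test_huge_baseline_with_tiny_bands_flagged(self):
        cfg = rb.CohortConfig(
            mineral_amp=5.0, organic_gain=0.5, noise_sd=0.0,
            fluorescence_amp=50000.0, fluorescence_scale=3000.0,
        )
        spec = rb.simulate_spectrum(cfg, 0.5, seed=1)
        assert rb.detect_fluorescence(spec) is True

    def test_clean_bone_spectrum_not_flagged(self, clean_spectrum):
        assert rb.detect_fluorescence(clean_spectrum) is False

    def test_all_zero_spectrum_flagged(self):
        w = np.arange(0.0, 3201.0)
        spec = rb.RamanSpectrum("z", 1, w, np.zeros(w.size))
        assert rb.detect_fluorescence(spec) is True

    def test_saturation_flagged(self, clean_spectrum):
        assert rb.detect_fluorescence(clean_spectrum, saturation_level=10.0)


class TestChPresence:
    def test_zero_organic_is_absent(self, noiseless_config):
        spec = rb.simulate_spectrum(noiseless_config, 0.0, seed=2)
        assert rb.ch_presence(spec) == "absent"

    def test_strong_organic_is_prominent(self):
        cfg = rb.CohortConfig(noise_sd=2.0, replicate_jitter_sd=0.0)
        spec = rb.simulate_spectrum(cfg, 3.0, seed=6)
        assert rb.ch_presence(spec) == "prominent"

    def test_score_is_scale_invariant(self):
        cfg = rb.CohortConfig(noise_sd=2.0, replicate_jitter_sd=0.0)
        spec = rb.simulate_spectrum(cfg, 0.15, seed=7)
        scaled = spec.with_values(spec.wavenumbers, 10.0 * spec.intensities)
        assert rb.ch_presence(spec) == rb.ch_presence(scaled)

    def test_monotone_in_organic_gain(self):
        # same noise realisation throughout, so adding organic signal can
        # only raise the corrected C-H peak; the score must not decrease
        order = {"absent": 0, "weak": 1, "prominent": 2}
        scores = []
        for gain in (0.0, 2.0, 8.0, 30.0, 120.0):
            cfg = rb.CohortConfig(
                organic_gain=gain, noise_sd=2.0, replicate_jitter_sd=0.0
            )
            scores.append(order[rb.ch_presence(
                rb.simulate_spectrum(cfg, 1.0, seed=9)
            )])
        assert scores == sorted(scores)
        assert scores[-1] == 2


class TestAnalyseReplicates:
    def test_full_pipeline_aggregates_triplicates(self, noiseless_config):
        reps = [
            rb.simulate_spectrum(noiseless_config, 1.2, replicate_index=i,
                                 seed=20 + i, sample_id="B1")
            for i in (1, 2, 3)
        ]
        res = rb.analyse_replicates(reps)
        assert res.sample_id == "B1"
        assert res.n_replicates == 3
        assert not res.fluorescence_failed
        assert res.ratio_mean == pytest.approx(
            rb.organic_phosphate_ratio(rb.band_areas(reps[0])), rel=1e-9
        )

    def test_all_fluorescent_replicates_give_missing_ratio(self):
        cfg = rb.CohortConfig(
            mineral_amp=5.0, organic_gain=0.5, noise_sd=0.0,
            fluorescence_amp=50000.0, fluorescence_scale=3000.0,
        )
        reps = [rb.simulate_spectrum(cfg, 0.5, seed=s, sample_id="F1")
                for s in (1, 2, 3)]
        res = rb.analyse_replicates(reps)
        assert res.fluorescence_failed
        assert res.ratio_mean is None
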