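"""AR spectral periodicity: binarization, Yule-Walker fits against FFT and
closed-form oracles, band peak calls, region/window analyses, and the
random-segment null."""

import numpy as np
import pytest
from scipy.signal import periodogram

from bindmodes import (
    AT_DINUCLEOTIDES,
    GenomeSequence,
    Interval,
    IntervalSet,
    binarize_dinucleotides,
    detect_band_peak,
    fit_ar_spectrum,
    fixed_window_periodicity,
    genome_periodicity,
    make_genome,
    plant_periodic_dinucleotides,
    region_periodicity,
    resample_region_null,
)
from bindmodes.periodicity import SpectralDensity, default_max_order


class TestBinarize:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AATAG", [1, 0, 1, 0]),  # AA, AT, TA, AG
            ("TTTT", [1, 1, 1]),
            ("GCNGC", [0, 0, 0, 0]),  # N-containing and non-member dinucleotides
        ],
    )
    def test_direct_enumeration(self, seq, expected):
        sig = binarize_dinucleotides(seq, AT_DINUCLEOTIDES)
        assert sig.values.tolist() == expected

    def test_length_is_n_minus_one(self, small_genome):
        seq = small_genome["chr"]
        assert len(binarize_dinucleotides(seq)) == len(seq) - 1

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            binarize_dinucleotides("A")
        with pytest.raises(ValueError):
            binarize_dinucleotides("ACGT", set())


def _fft_argmax_in_band(x, fmin, fmax):
    f, p = periodogram(x - np.mean(x))
    m = (f >= fmin) & (f <= fmax)
    return f[m][np.argmax(p[m])]


class TestFitArSpectrum:
    def test_deterministic_comb_peaks_at_period_10(self):
        """A pure every-10th-position comb must peak at 0.100 cycles/bp,
        matching the raw FFT periodogram oracle."""
        x = np.zeros(10_000)
        x[::10] = 1
        spec = fit_ar_spectrum(x)
        j = np.argmax(spec.density)
        assert spec.frequencies[j] == pytest.approx(0.1, abs=0.5 / 2000)
        f_fft = _fft_argmax_in_band(x, 0.05, 0.15)
        assert abs(spec.frequencies[j] - f_fft) <= 2 * 0.5 / 2000

    def test_ar2_closed_form_peak_location(self, rng):
        """AR(2) with a1=1.0, a2=-0.9 peaks at cos(2 pi f*) = a1(1-a2)/(-4 a2)."""
        a1, a2 = 1.0, -0.9
        n = 20_000
        e = rng.standard_normal(n + 500)
        x = np.zeros(n + 500)
        for t in range(2, n + 500):
            x[t] = a1 * x[t - 1] + a2 * x[t - 2] + e[t]
        x = x[500:]
        f_star = np.arccos(a1 * (1 - a2) / (-4 * a2)) / (2 * np.pi)
        spec = fit_ar_spectrum(x)
        j = np.argmax(spec.density)
        assert spec.frequencies[j] == pytest.approx(f_star, abs=2 * 0.5 / 2000)

    def test_iid_bernoulli_has_no_band_peak(self, rng):
        """White noise shows no 10-bp band peak at the default threshold."""
        x = (rng.random(100_000) < 0.1).astype(float)
        spec = fit_ar_spectrum(x)
        peak = detect_band_peak(spec, (9.5, 10.5), prominence_threshold=1.5)
        assert not peak.detected

    def test_normalization_unit_grid_mean(self, rng):
        for _ in range(3):
            x = (rng.random(5_000) < 0.3).astype(float)
            spec = fit_ar_spectrum(x)
            assert spec.density.mean() == pytest.approx(1.0, abs=1e-9)
            assert np.all(spec.density > 0)
            assert np.all(np.diff(spec.frequencies) > 0)

    def test_matches_statsmodels_yule_walker(self, rng):
        """Independent cross-check of the AR coefficients at fixed order."""
        from statsmodels.regression.linear_model import yule_walker

        x = rng.standard_normal(5_000) + np.sin(np.arange(5_000) / 3.0)
        spec = fit_ar_spectrum(x, max_order=12)
        rho, sigma = yule_walker(x, order=spec.ar_order, method="adjusted", demean=True)
        # statsmodels 'adjusted' divides by (n-k); ours is the biased estimator,
        # so compare against the 'mle' (biased) variant
        rho_b, _ = yule_walker(x, order=spec.ar_order, method="mle", demean=True)
        assert np.allclose(spec.ar_coefficients, rho_b, atol=1e-6)

    def test_rejects_constant_signal(self):
        with pytest.raises(ValueError):
            fit_ar_spectrum(np.ones(100))
        with pytest.raises(ValueError):
            fit_ar_spectrum(np.arange(10.0), max_order=20)

    def test_oracle_equivalence_property(self, rng):
        """AR argmax agrees with the periodogram argmax within 2 grid steps
        whenever the periodogram peak is strong (>= 5x median)."""
        step = 0.5 / 2000
        for seed in range(10):
            r = np.random.default_rng(seed)
            P = int(r.integers(8, 14))
            x = np.zeros(10_000)
            x[::P] = 1
            x = np.clip(x + (r.random(10_000) < 0.05), 0, 1)
            # band around the fundamental: harmonics of a comb are equal
            # height in the periodogram, so the unrestricted argmax is
            # ambiguous; band restriction mirrors detect_band_peak
            fmin, fmax = 1 / (P + 1.5), 1 / (P - 1.5)
            f, p = periodogram(x - x.mean())
            band = (f >= fmin) & (f <= fmax)
            if p[band].max() < 5 * np.median(p[band]):
                continue
            f_fft = f[band][np.argmax(p[band])]
            spec = fit_ar_spectrum(x)
            m = (spec.frequencies >= fmin) & (spec.frequencies <= fmax)
            f_ar = spec.frequencies[m][np.argmax(spec.density[m])]
            assert abs(f_ar - f_fft) <= 2 * step


class TestDetectBandPeak:
    def _flat_spec(self, n=2000):
        f = np.arange(1, n + 1) * (0.5 / n)
        return SpectralDensity(f, np.ones(n), 0, np.array([]), 1.0, 1000)

    def test_flat_spectrum_not_detected(self):
        peak = detect_band_peak(self._flat_spec(), (9.5, 10.5), 1.5)
        assert peak.prominence == pytest.approx(1.0)
        assert not peak.detected

    def test_single_bump_detected_at_its_period(self):
        spec = self._flat_spec()
        j = np.argmin(np.abs(spec.frequencies - 0.1))
        spec.density[j] = 5.0
        peak = detect_band_peak(spec, (9.5, 10.5), 1.5)
        assert peak.detected
        assert peak.period == pytest.approx(10.0, abs=0.05)
        assert peak.prominence == pytest.approx(5.0)

    def test_band_validation(self):
        spec = self._flat_spec()
        with pytest.raises(ValueError):
            detect_band_peak(spec, (1.0, 1.5), 1.5)


class TestGenomePeriodicity:
    def test_planted_comb_recovered(self):
        g = make_genome(1_000_000, 0.6, seed=5)
        gp = plant_periodic_dinucleotides(g, 10, 0.3, seed=6)
        res = genome_periodicity(gp)
        assert res.peaks["10bp"].detected
        assert res.peaks["10bp"].period == pytest.approx(10.0, abs=0.2)

    def test_unplanted_control_undetected(self):
        g = make_genome(1_000_000, 0.6, seed=5)
        res = genome_periodicity(g)
        assert not res.peaks["10bp"].detected

    @pytest.mark.parametrize("period,band", [(10, "10bp"), (11, "11bp")])
    def test_period_recovery_across_strengths(self, period, band):
        """The band argmax period stays within 0.2 bp of the planted period
        over strengths 0.2-0.5, with detection from strength 0.3 up."""
        for strength in (0.2, 0.3, 0.5):
            for seed in range(3):
                g = make_genome(300_000, 0.6, seed=50 + seed)
                gp = plant_periodic_dinucleotides(g, period, strength, seed=60 + seed)
                pk = genome_periodicity(gp).peaks[band]
                assert abs(pk.period - period) <= 0.2
                if strength >= 0.3:
                    assert pk.detected

    def test_strand_symmetry(self):
        """{AA,TT,TA} is reverse-complement closed, so a sequence and its
        reverse complement give band peaks within one grid step."""
        g = make_genome(200_000, 0.55, seed=7)
        gp = plant_periodic_dinucleotides(g, 10, 0.4, seed=8)
        seq = gp["chr"]
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        r1 = genome_periodicity(gp)
        r2 = genome_periodicity(GenomeSequence({"chr": rc}))
        step_period = 10.5**2 * (0.5 / 2000)  # df -> dP at ~10 bp
        assert abs(r1.peaks["10bp"].period - r2.peaks["10bp"].period) <= 2 * step_period


class TestRegionPeriodicity:
    def test_whole_genome_intervals_equal_genome_analysis(self, small_genome):
        ivs = IntervalSet([Interval("chr", 0, len(small_genome["chr"]))])
        r_reg = region_periodicity(small_genome, ivs)
        r_gen = genome_periodicity(small_genome)
        assert np.allclose(r_reg.spectrum.density, r_gen.spectrum.density)

    def test_planted_regions_on_plain_background(self):
        """Loci carrying a 10-bp comb are detected even when the genome-wide
        signal is absent (bound-locus periodicity without a genome signal)."""
        g = make_genome(300_000, 0.6, seed=9)
        regions = IntervalSet([Interval("chr", s, s + 400) for s in range(0, 30_000, 3000)])
        planted = plant_periodic_dinucleotides(g, 10, 0.5, seed=10)
        hybrid = g["chr"][:]
        for iv in regions:
            hybrid = hybrid[: iv.start] + planted["chr"][iv.start : iv.end] + hybrid[iv.end :]
        hg = GenomeSequence({"chr": hybrid})
        assert not genome_periodicity(hg).peaks["10bp"].detected
        assert region_periodicity(hg, regions).peaks["10bp"].detected

    def test_too_short_rejected(self, small_genome):
        with pytest.raises(ValueError):
            region_periodicity(small_genome, IntervalSet([Interval("chr", 0, 50)]))


class TestFixedWindowPeriodicity:
    def test_planted_windows_recovered(self):
        g = make_genome(200_000, 0.6, seed=13)
        gp = plant_periodic_dinucleotides(g, 10, 0.5, seed=14)
        centers = [("chr", c) for c in range(5_000, 195_000, 10_000)]
        res = fixed_window_periodicity(gp, centers, window_length=150)
        assert res.peaks["10bp"].detected

    def test_single_window_is_legal(self, small_genome):
        res = fixed_window_periodicity(small_genome, [("chr", 1000)], 150)
        assert res.spectrum.n == 149
        assert res.spectrum.ar_order <= 148

    def test_clipped_windows_dropped_and_window1_rejected(self, small_genome):
        with pytest.raises(ValueError):
            fixed_window_periodicity(small_genome, [("chr", 5)], 1)
        with pytest.raises(ValueError):  # all windows clipped
            fixed_window_periodicity(small_genome, [("chr", 5)], 150)


class TestResampleNull:
    def test_self_comparison_height_matches(self, small_genome):
        """Analyzing the genome's own segments reproduces their height."""
        ivs = IntervalSet([Interval("chr", 1000, 1400), Interval("chr", 5000, 5400)])
        obs = region_periodicity(
            small_genome, ivs, bands={"null": (9.5, 10.5)}
        ).peaks["null"].height
        null = resample_region_null(
            small_genome, [400, 400], n_draws=5, band=(9.5, 10.5), seed=3,
            observed_height=obs,
        )
        assert len(null.heights) == 5
        assert null.n_exceeding == int(np.sum(null.heights > obs))
        assert 0 < null.empirical_p <= 1

    def test_planted_regions_beat_unplanted_background(self):
        """Construction guarantees separation: no random draw from the plain
        genome exceeds the planted loci's band peak height."""
        g = make_genome(300_000, 0.6, seed=15)
        regions = IntervalSet(
            [Interval("chr", s, s + 400) for s in range(0, 20_000, 2000)]
        )
        planted = plant_periodic_dinucleotides(g, 10, 0.6, seed=16)
        hybrid = g["chr"]
        for iv in regions:
            hybrid = hybrid[: iv.start] + planted["chr"][iv.start : iv.end] + hybrid[iv.end :]
        hg = GenomeSequence({"chr": hybrid})
        obs = region_periodicity(
            hg, regions, bands={"b": (9.5, 10.5)}
        ).peaks["b"].height
        null = resample_region_null(
            hg, [400] * len(regions), n_draws=30, band=(9.5, 10.5), seed=17,
            observed_height=obs,
        )
        assert null.n_exceeding == 0
        assert null.empirical_p == pytest.approx(1 / 31)

    def test_rejects_zero_draws(self, small_genome):
        with pytest.raises(ValueError):
            resample_region_null(small_genome, [100], 0, (9.5, 10.5), 1, 1.0)


def test_default_max_order_matches_classical_rule():
    assert default_max_order(1_000_000) == 60
    assert default_max_order(10) == 9  # min(n-1, 10)
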