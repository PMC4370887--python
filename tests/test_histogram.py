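"""BAS histograms: concentration recovery, dilution merging, CV fits."""
import numpy as np
import pytest

from bas import (AcquisitionParams, BasHistogram, FissionParams,
                 LiposomePopulation, LiposomeSpecies, brightness_of,
                 build_histogram, estimate_cv, evolve_fission,
                 fraction_of_total, log_edges, mean_intensity_ratio,
                 merge_dilution_series)
from bas.population import sample_diameters

from conftest import measure_histogram


def _uniform_hist(conc, intensities=None, n_events=None):
    n = len(conc)
    edges = log_edges(1.0, 10.0 ** n)[: n + 1]
    if intensities is None:
        intensities = np.sqrt(edges[:-1] * edges[1:])
    if n_events is None:
        n_events = np.full(n, 100)
    return BasHistogram(bin_edges=edges, concentration=np.asarray(conc),
                        mean_bin_intensity=np.asarray(intensities),
                        n_events=np.asarray(n_events))


class TestBuild:
    def test_concentration_recovered_at_100pM(self, mono_200):
        acq = AcquisitionParams(duration=120.0)
        h = measure_histogram(mono_200, acq, seed=1)
        n = h.n_events.sum()
        poisson_err = 4 * np.sqrt(n) / (acq.detection_rate_constant
                                        * acq.duration)
        assert abs(h.total_concentration - 100.0) < poisson_err + 2.0

    def test_empty_burst_list_gives_zero_histogram(self, fast_acq):
        with pytest.warns(UserWarning, match="no bursts"):
            h = build_histogram([], fast_acq)
        assert h.total_concentration == 0.0

    def test_modal_bins_16fold_apart_for_200_vs_50nm(self, fast_acq):
        acq = AcquisitionParams(duration=120.0)
        edges = log_edges(1.0, 1e8)
        modal = {}
        for d in (200.0, 50.0):
            pop = LiposomePopulation(
                species=(LiposomeSpecies(d, 0.35, 100.0),))
            h = measure_histogram(pop, acq, seed=2, edges=edges)
            modal[d] = h.mean_bin_intensity[np.argmax(h.concentration)]
        assert modal[200.0] / modal[50.0] == pytest.approx(16.0, rel=0.5)


class TestFractions:
    def test_single_occupied_bin(self):
        h = _uniform_hist([0.0, 5.0, 0.0])
        assert np.array_equal(fraction_of_total(h), [0.0, 1.0, 0.0])

    def test_uniform_bins(self):
        h = _uniform_hist([2.0] * 5)
        assert np.allclose(fraction_of_total(h), 0.2)

    def test_always_sums_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            h = _uniform_hist(rng.uniform(0, 10, size=8))
            assert fraction_of_total(h).sum() == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fraction_of_total(_uniform_hist([0.0, 0.0]))


class TestMeanIntensityRatio:
    def test_identity(self):
        h = _uniform_hist([1.0, 2.0, 3.0])
        fold, ratio = mean_intensity_ratio(h, h)
        assert fold == pytest.approx(1.0)
        assert ratio == pytest.approx(1.0)

    def test_empty_histogram_rejected(self):
        h = _uniform_hist([1.0])
        empty = _uniform_hist([0.0])
        with pytest.raises(ValueError):
            mean_intensity_ratio(h, empty)

    def test_implied_diameter_ratio_is_sqrt_fold(self, fast_acq):
        acq = AcquisitionParams(duration=120.0)
        pops = {d: LiposomePopulation(
            species=(LiposomeSpecies(d, 0.35, 100.0),))
            for d in (200.0, 100.0)}
        h1 = measure_histogram(pops[200.0], acq, seed=4)
        h2 = measure_histogram(pops[100.0], acq, seed=5)
        fold, diam = mean_intensity_ratio(h1, h2)
        assert fold == pytest.approx(4.0, rel=0.12)
        assert diam == pytest.approx(np.sqrt(fold))


class TestMerge:
    def test_identical_pair_is_idempotent(self):
        h = _uniform_hist([10.0, 20.0, 30.0])
        assert h.valid.all()
        merged = merge_dilution_series([h, _uniform_hist([10., 20., 30.])])
        assert np.allclose(merged.concentration, h.concentration)

    def test_dilution_scaling(self):
        # a 10x-diluted bin measured at 8 pM contributes 80 pM undiluted
        h1 = _uniform_hist([10.0, 20.0, 30.0])
        h10 = BasHistogram(bin_edges=h1.bin_edges,
                           concentration=[1.0, 2.0, 8.0],
                           mean_bin_intensity=h1.mean_bin_intensity,
                           n_events=[100, 100, 100], dilution_factor=10.0)
        assert np.allclose(h10.undiluted_concentration, [10.0, 20.0, 80.0])
        merged = merge_dilution_series([h1, h10])
        # anchor (1x) concentrations conserved in its valid window
        assert np.allclose(merged.concentration, h1.concentration)
        assert merged.dilution_factor == 1.0

    def test_disjoint_windows_rejected(self):
        edges = log_edges(1.0, 1e4)
        n = len(edges) - 1
        lo = np.zeros(n); lo[:3] = 10.0
        hi = np.zeros(n); hi[-3:] = 10.0
        centres = np.sqrt(edges[:-1] * edges[1:])
        h_lo = BasHistogram(edges, lo, centres, (lo > 0) * 100)
        h_hi = BasHistogram(edges, hi, centres, (hi > 0) * 100,
                            dilution_factor=10.0)
        with pytest.raises(ValueError, match="no overlap"):
            merge_dilution_series([h_lo, h_hi])

    def test_fission_mixture_recovered_within_15pct(self):
        """Partial fission measured at 1x and 10x: the merged histogram
        recovers both parent and product concentrations."""
        # high-flux calibration + long traces so the 10 pM surviving
        # parents clear the 5-events/bin validity rule across the
        # beam-factor-spread amplitude range
        acq = AcquisitionParams(duration=480.0,
                                detection_rate_constant=0.2)
        edges = log_edges(1.0, 1e8)
        parent = LiposomePopulation(
            species=(LiposomeSpecies(200.0, 0.35, 20.0),))
        fp = FissionParams(rate_constant=1.0, product_mean_diameter=20.0,
                           product_cv=0.30)
        t_half = np.log(2) / fp.rate_constant
        after = evolve_fission(parent, fp, t_half)  # half converted
        series = [measure_histogram(after, acq, seed=6, edges=edges,
                                    dilution=1.0),
                  measure_histogram(after, acq, seed=7, edges=edges,
                                    dilution=10.0)]
        merged = merge_dilution_series(series)
        # products dominate the particle count; parents carry half the
        # fluorescence — recovering both totals requires both ends of
        # the merged histogram to be right
        true_count = after.total_concentration
        mean_beam = 0.41662  # E[exp(-2 b^2 / w0^2)], b ~ U(0, 1.5 w0)
        amp_per_brightness = (acq.brightness_scale * mean_beam
                              * (acq.transit_time / 2)
                              * np.sqrt(2 * np.pi))
        true_ic = sum(s.concentration * s.mean_brightness
                      for s in after.species) * amp_per_brightness
        assert merged.concentration.sum() == \
            pytest.approx(true_count, rel=0.15)
        assert merged.total_intensity_concentration == \
            pytest.approx(true_ic, rel=0.20)
        # parent bursts (top decade of intensity) are present and scale
        # with the surviving parent concentration
        top = merged.mean_bin_intensity > brightness_of(200.0) \
            * amp_per_brightness / 4
        assert 2.0 < merged.concentration[top].sum() < 15.0


class TestEstimateCv:
    GRID = np.arange(0.10, 0.501, 0.05)

    def test_recovers_30pct_cv(self):
        proto = LiposomeSpecies(20.0, 0.30, 0.0)
        rng = np.random.default_rng(8)
        amps = brightness_of(sample_diameters(proto, 20_000, rng)) * 37.0
        est = estimate_cv(amps, self.GRID, n_template=20_000, seed=0)
        assert est.cv == pytest.approx(0.30)

    def test_degenerate_input_returns_lowest_grid_point(self):
        amps = np.full(5000, 123.0)
        with pytest.warns(UserWarning, match="boundary"):
            est = estimate_cv(amps, [0.05, 0.1, 0.2], n_template=5000,
                              seed=0)
        assert est.cv == 0.05

    def test_35_vs_50_distinguished_across_seeds(self):
        hits = 0
        for trial in range(10):
            rng = np.random.default_rng(100 + trial)
            d35 = sample_diameters(LiposomeSpecies(20.0, 0.35, 0.0),
                                   8000, rng)
            d50 = sample_diameters(LiposomeSpecies(20.0, 0.50, 0.0),
                                   8000, rng)
            e35 = estimate_cv(brightness_of(d35), [0.35, 0.50],
                              n_template=8000, seed=trial)
            e50 = estimate_cv(brightness_of(d50), [0.35, 0.50],
                              n_template=8000, seed=trial)
            hits += (e35.cv == 0.35) and (e50.cv == 0.50)
        assert hits == 10

    def test_calibrated_mean_diameter(self):
        proto = LiposomeSpecies(20.0, 0.30, 0.0)
        rng = np.random.default_rng(9)
        scale = 37.0
        amps = brightness_of(sample_diameters(proto, 20_000, rng)) * scale
        est = estimate_cv(amps, self.GRID, n_template=20_000, seed=1,
                          intensity_per_area=scale,
                          mean_diameter_grid=np.arange(10.0, 41.0, 2.0))
        assert est.mean_diameter == pytest.approx(20.0, abs=2.0)


class TestConcentrationLinearity:
    def test_linear_below_limit_sublinear_above(self):
        """Estimated concentration tracks truth up to ~500 pM and falls
        below it beyond the single-particle limit (coincidence loss)."""
        acq = AcquisitionParams(duration=120.0)
        truths = np.array([50.0, 150.0, 300.0, 450.0])
        est = []
        for i, c in enumerate(truths):
            pop = LiposomePopulation(
                species=(LiposomeSpecies(200.0, 0.35, c),))
            h = measure_histogram(pop, acq, seed=20 + i)
            est.append(h.total_concentration)
        est = np.array(est)
        slope = (est * truths).sum() / (truths ** 2).sum()
        assert slope == pytest.approx(1.0, abs=0.05)
        pop_hi = LiposomePopulation(
            species=(LiposomeSpecies(200.0, 0.35, 3000.0),))
        h_hi = measure_histogram(pop_hi, acq, seed=30)
        assert h_hi.total_concentration / 3000.0 < slope - 0.05
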