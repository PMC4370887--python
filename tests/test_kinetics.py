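"""Heat maps, signal conservation and plateau-time estimation."""
import numpy as np
import pytest

from bas import (AcquisitionParams, BasHistogram, FissionParams,
                 FissionTimeCourse, HeatMap, LiposomePopulation,
                 LiposomeSpecies, dose_response, evolve_fission,
                 fractional_intensity_row, log_edges, time_to_plateau,
                 total_signal_series)

from conftest import measure_histogram

EDGES = log_edges(1.0, 1e8)
CENTRES = np.sqrt(EDGES[:-1] * EDGES[1:])


def analytic_histogram(pop, scale=1.0):
    """Histogram placed directly from species concentrations (no trace
    rendering): each species contributes at its mean brightness."""
    conc = np.zeros(len(CENTRES))
    intensity = CENTRES.copy()
    for s in pop.species:
        i = np.searchsorted(EDGES, s.mean_brightness * scale) - 1
        conc[i] += s.concentration
        intensity[i] = s.mean_brightness * scale
    return BasHistogram(EDGES, conc, intensity,
                        (conc > 0) * 1000)


def analytic_course(k_per_min, times_min, parent_conc=50.0):
    parent = LiposomePopulation(
        species=(LiposomeSpecies(200.0, 0.35, parent_conc),))
    fp = FissionParams(k_per_min / 60.0, 20.0, 0.30)
    hists = [analytic_histogram(evolve_fission(parent, fp, t * 60.0))
             for t in times_min]
    return FissionTimeCourse(times=np.asarray(times_min), histograms=hists)


class TestFractionalIntensity:
    def test_single_occupied_bin(self):
        h = BasHistogram(EDGES[:3], [0.0, 7.0], [1.5, 20.0], [0, 10])
        row = fractional_intensity_row(h)
        assert np.array_equal(row, [0.0, 1.0])

    def test_hand_computed_balance(self):
        # (I=1, C=100) and (I=100, C=1) carry equal fluorescence
        h = BasHistogram(EDGES[:3], [100.0, 1.0], [1.0, 100.0], [100, 1])
        assert np.allclose(fractional_intensity_row(h), [0.5, 0.5])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            conc = rng.uniform(0, 5, len(CENTRES))
            h = BasHistogram(EDGES, conc, CENTRES,
                             (conc > 0).astype(int))
            assert fractional_intensity_row(h).sum() == pytest.approx(1.0)

    def test_zero_fluorescence_rejected(self):
        h = BasHistogram(EDGES[:3], [0.0, 0.0], [1.0, 10.0], [0, 0])
        with pytest.raises(ValueError):
            fractional_intensity_row(h)


class TestHeatMap:
    def test_rows_sum_to_one_and_nonnegative(self):
        tc = analytic_course(0.05, np.linspace(1.0, 100.0, 6))
        hm = HeatMap.from_timecourse(tc)
        assert np.allclose(hm.values.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(hm.values >= 0)
        assert len(hm.row_labels) == 6

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            HeatMap(values=np.array([[0.5, 0.4]]), row_labels=["x"],
                    bin_edges=EDGES[:3])


class TestTotalSignal:
    def test_lossless_course_conserves_signal(self):
        tc = analytic_course(0.05, np.linspace(1.0, 100.0, 8))
        totals = total_signal_series(tc)
        assert totals.max() == 1.0
        assert totals.min() > 0.995  # quantization only

    def test_end_to_end_within_20pct(self):
        """Through trace rendering and detection the total I*C stays in
        the observed 10-20% conservation band."""
        # early points are parent-dominated: the 5 pM of diluted
        # parents needs a few hundred bursts for a stable I*C total
        acq = AcquisitionParams(duration=240.0,
                                detection_rate_constant=0.2)
        parent = LiposomePopulation(
            species=(LiposomeSpecies(200.0, 0.35, 50.0),))
        fp = FissionParams(0.05 / 60.0, 20.0, 0.30)
        times = np.array([1.0, 30.0, 60.0, 100.0])
        hists = [measure_histogram(evolve_fission(parent, fp, t * 60.0),
                                   acq, seed=40 + i, edges=EDGES,
                                   dilution=10.0)
                 for i, t in enumerate(times)]
        totals = total_signal_series(
            FissionTimeCourse(times=times, histograms=hists))
        assert totals.min() >= 0.8


class TestTimeToPlateau:
    def test_matches_first_order_closed_form(self):
        """C(t) = C_inf (1 - e^{-kt}), frac=0.95 -> t = ln(20)/k."""
        k = 0.04
        t = np.linspace(0.01, 250.0, 2000)
        conc = 1.0 - np.exp(-k * t)
        hists = [BasHistogram(EDGES[:3], [c, 0.0], [1.5, 20.0], [100, 0])
                 for c in conc]
        tc = FissionTimeCourse(times=t, histograms=hists)
        window = np.array([True, False])
        t95 = time_to_plateau(tc, window=window, frac=0.95)
        # the plateau reference is the last sample, not C_inf
        target = 0.95 * conc[-1]
        expected = -np.log(1 - target) / k
        assert t95 == pytest.approx(expected, rel=0.01)
        assert expected == pytest.approx(np.log(20) / k, rel=0.01)

    def test_monotone_in_frac(self):
        tc = analytic_course(0.05, np.linspace(1.0, 100.0, 40))
        t50 = time_to_plateau(tc, frac=0.50)
        t95 = time_to_plateau(tc, frac=0.95)
        assert t95 >= t50

    def test_unreached_plateau_rejected(self):
        tc = analytic_course(0.01, np.linspace(1.0, 60.0, 5))
        with pytest.raises(ValueError, match="plateau not reached"):
            time_to_plateau(tc)


class TestDoseResponse:
    def _hist_at_k(self, k_per_min, t_min=20.0):
        parent = LiposomePopulation(
            species=(LiposomeSpecies(200.0, 0.35, 50.0),))
        if k_per_min == 0:
            return analytic_histogram(parent)
        fp = FissionParams(k_per_min / 60.0, 20.0, 0.30)
        return analytic_histogram(evolve_fission(parent, fp, t_min * 60.0))

    def test_zero_activity_fraction_near_one(self):
        ref = self._hist_at_k(0.0)
        table = dose_response([(0.0, self._hist_at_k(0.0))], ref)
        assert table.remaining_fraction.iloc[0] == pytest.approx(1.0)

    def test_strictly_decreasing_with_dose(self):
        ref = self._hist_at_k(0.0)
        doses = [0.5, 1.0, 5.0, 10.0]
        ks = [0.01, 0.03, 0.1, 0.3]  # activity grows with dose
        table = dose_response(
            [(c, self._hist_at_k(k)) for c, k in zip(doses, ks)], ref)
        fractions = table.remaining_fraction.to_numpy()
        assert np.all(np.diff(fractions) < 0)

    def test_complete_conversion_below_5pct(self):
        ref = self._hist_at_k(0.0)
        table = dose_response([(10.0, self._hist_at_k(1.0, t_min=1e5))],
                              ref)
        assert table.remaining_fraction.iloc[0] < 0.05

    def test_mismatched_binning_rejected(self):
        ref = self._hist_at_k(0.0)
        other = BasHistogram(EDGES[:5], [1.0] * 4, CENTRES[:4], [10] * 4)
        with pytest.raises(ValueError, match="binning"):
            dose_response([(1.0, other)], ref)
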