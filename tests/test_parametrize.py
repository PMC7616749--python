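"""Tests for the multi-peak fit / weight / reduction parametrization pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyamine_builder import (
    BondedParam,
    DistributionSample,
    FitError,
    GaussianPeak,
    evaluate_potential,
    fit_peaks,
    make_peaks,
    peak_weights,
    reduce_peaks,
    sample_synthetic_distribution,
)
from polyamine_builder.parametrize import KB


def _peak(kind="bond", amplitude=1.0, mean=0.35, sigma=0.02, K=5000.0, area=None):
    p = GaussianPeak(kind=kind, amplitude=amplitude, mean=mean, sigma=sigma,
                     force_constant=K)
    if area is not None:
        p.area = area
    return p


class TestDistributionSample:
    def test_rejects_nonpositive_bonds(self):
        with pytest.raises(ValueError):
            DistributionSample(kind="bond", values=[0.3, -0.1])

    def test_rejects_out_of_range_angles(self):
        with pytest.raises(ValueError):
            DistributionSample(kind="angle", values=[90.0, 181.0])

    def test_angle_fit_values_are_cosines(self):
        s = DistributionSample(kind="angle", values=[60.0, 90.0, 180.0])
        assert s.fit_values == pytest.approx([0.5, 0.0, -1.0], abs=1e-12)


class TestSyntheticSampling:
    def test_single_peak_mean_within_clt_bound(self):
        peaks = make_peaks("bond", [(0.35, 5000.0, 1.0)])
        n = 50_000
        s = sample_synthetic_distribution(peaks, n, seed=1)
        sigma = np.sqrt(KB * 298.15 / 5000.0)
        assert abs(s.values.mean() - 0.35) < 3 * sigma / np.sqrt(n)

    def test_deterministic_given_seed(self):
        peaks = make_peaks("angle", [(120.0, 50.0, 1.0)])
        a = sample_synthetic_distribution(peaks, 1000, seed=9)
        b = sample_synthetic_distribution(peaks, 1000, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_degenerate_weights_draw_single_component(self):
        peaks = make_peaks("bond", [(0.30, 5000.0, 1.0), (0.50, 5000.0, 0.0),
                                    (0.70, 5000.0, 0.0)])
        s = sample_synthetic_distribution(peaks, 5000, seed=2)
        assert np.all(np.abs(s.values - 0.30) < 0.1)

    def test_angles_stay_physical(self):
        # broad component near 180 deg: rejection must keep angles in range
        peaks = make_peaks("angle", [(170.0, 10.0, 1.0)])
        s = sample_synthetic_distribution(peaks, 20_000, seed=3)
        assert np.all((s.values > 0) & (s.values <= 180.0))


class TestFitPeaks:
    def test_single_bond_peak_recovery(self):
        peaks = make_peaks("bond", [(0.35, 5000.0, 1.0)])
        s = sample_synthetic_distribution(peaks, 100_000, seed=7)
        fit = fit_peaks(s)
        assert len(fit) == 1
        assert fit[0].equilibrium == pytest.approx(0.35, rel=0.01)
        assert fit[0].force_constant == pytest.approx(5000.0, rel=0.10)

    def test_two_separated_equal_peaks(self):
        peaks = make_peaks("bond", [(0.30, 8000.0, 0.5), (0.40, 8000.0, 0.5)])
        s = sample_synthetic_distribution(peaks, 100_000, seed=42)
        fit = fit_peaks(s)
        assert len(fit) == 2
        assert sorted(p.weight for p in fit) == pytest.approx([0.5, 0.5], abs=0.05)
        assert [p.equilibrium for p in fit] == pytest.approx([0.30, 0.40], rel=0.02)

    def test_constant_series_is_unfittable(self):
        s = DistributionSample(kind="bond", values=np.full(1000, 0.35))
        with pytest.raises((FitError, ValueError)):
            fit_peaks(s)

    def test_too_few_values_rejected(self):
        s = DistributionSample(kind="bond", values=np.random.default_rng(0).normal(0.35, 0.01, 100))
        with pytest.raises(ValueError):
            fit_peaks(s)

    @pytest.mark.parametrize("K", [500.0, 5000.0, 20000.0])
    def test_round_trip_bond_force_constants(self, K):
        peaks = make_peaks("bond", [(0.35, K, 1.0)])
        s = sample_synthetic_distribution(peaks, 100_000, seed=int(K))
        param = reduce_peaks(fit_peaks(s))
        assert param.equilibrium == pytest.approx(0.35, rel=0.01)
        assert param.force_constant == pytest.approx(K, rel=0.10)

    @pytest.mark.parametrize("K", [10.0, 100.0, 500.0])
    def test_round_trip_angle_force_constants(self, K):
        peaks = make_peaks("angle", [(120.0, K, 1.0)])
        s = sample_synthetic_distribution(peaks, 100_000, seed=int(K) + 1)
        param = reduce_peaks(fit_peaks(s))
        assert param.kind == "angle"
        assert param.equilibrium == pytest.approx(120.0, rel=0.01)
        assert param.force_constant == pytest.approx(K, rel=0.10)


class TestPeakWeights:
    def test_equal_areas_split_evenly(self):
        peaks = [_peak(area=2.0) for _ in range(3)]
        assert peak_weights(peaks) == pytest.approx([1 / 3] * 3)

    def test_proportional_to_area(self):
        peaks = [_peak(area=9.0), _peak(area=1.0)]
        assert peak_weights(peaks) == pytest.approx([0.9, 0.1])

    def test_single_peak_weight_is_one(self):
        assert peak_weights([_peak()]) == pytest.approx([1.0])

    def test_area_is_analytic_gaussian_area(self):
        p = _peak(amplitude=2.0, sigma=0.01)
        assert p.area == pytest.approx(2.0 * 0.01 * np.sqrt(2 * np.pi))

    def test_all_zero_areas_rejected(self):
        with pytest.raises(ValueError):
            peak_weights([_peak(area=0.0), _peak(area=0.0)])


class TestReducePeaks:
    def test_single_peak_identity(self):
        p = _peak(mean=0.35, K=5000.0)
        out = reduce_peaks([p])
        assert out.equilibrium == pytest.approx(0.35)
        assert out.force_constant == pytest.approx(5000.0)

    def test_weighted_harmonic_mean_arithmetic(self):
        # w = (0.5, 0.5), K = (10, 40): 1/K = 0.05 + 0.0125 -> K = 16
        peaks = [_peak(kind="angle", mean=np.cos(np.radians(100)), K=10.0, area=1.0),
                 _peak(kind="angle", mean=np.cos(np.radians(140)), K=40.0, area=1.0)]
        out = reduce_peaks(peaks)
        assert out.force_constant == pytest.approx(16.0)
        assert out.equilibrium == pytest.approx(120.0)  # weighted mean in degrees

    def test_low_weight_peak_excluded(self):
        keep = _peak(mean=0.35, K=5000.0, area=0.9995)
        drop = _peak(mean=0.50, K=100.0, area=0.0005)
        out = reduce_peaks([keep, drop])
        assert out.equilibrium == pytest.approx(0.35)
        assert out.force_constant == pytest.approx(5000.0)
        assert len(out.peaks) == 1

    def test_low_k_peak_excluded(self):
        keep = _peak(mean=0.35, K=5000.0, area=0.5)
        drop = _peak(mean=0.50, K=0.5, area=0.5)  # K < 1 in native units
        out = reduce_peaks([keep, drop])
        assert out.force_constant == pytest.approx(5000.0)

    def test_all_filtered_raises(self):
        with pytest.raises(FitError):
            reduce_peaks([_peak(K=0.01)])

    def test_invariant_to_peak_ordering(self):
        peaks = [_peak(mean=0.30, K=4000.0, area=0.3),
                 _peak(mean=0.35, K=6000.0, area=0.5),
                 _peak(mean=0.40, K=9000.0, area=0.2)]
        a = reduce_peaks(peaks)
        b = reduce_peaks(peaks[::-1])
        assert a.equilibrium == pytest.approx(b.equilibrium)
        assert a.force_constant == pytest.approx(b.force_constant)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        ks=st.lists(st.floats(10.0, 20000.0), min_size=1, max_size=3),
        areas=st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3),
    )
    def test_force_constant_bounded_by_retained_extremes(self, ks, areas):
        peaks = [
            _peak(mean=0.3 + 0.05 * i, K=k, area=a)
            for i, (k, a) in enumerate(zip(ks, areas))
        ]
        out = reduce_peaks(peaks)
        retained_k = [p.force_constant for p in out.peaks]
        assert min(retained_k) - 1e-9 <= out.force_constant <= max(retained_k) + 1e-9

    def test_lowering_w_min_shifts_result_at_most_by_excluded_share(self):
        peaks = [_peak(mean=0.35, K=5000.0, area=0.999),
                 _peak(mean=0.40, K=3000.0, area=0.0008)]
        strict = reduce_peaks(peaks, w_min=0.001)
        loose = reduce_peaks(peaks, w_min=0.0)
        excluded_share = 0.0008 / (0.999 + 0.0008)
        assert abs(strict.equilibrium - loose.equilibrium) <= excluded_share * 0.05 + 1e-9


class TestEvaluatePotential:
    def test_zero_at_equilibrium(self):
        bond = BondedParam(type=None, kind="bond", equilibrium=0.35,
                           force_constant=5000.0)
        angle = BondedParam(type=None, kind="angle", equilibrium=120.0,
                            force_constant=50.0)
        assert evaluate_potential(bond, 0.35) == 0.0
        assert evaluate_potential(angle, 120.0) == 0.0

    def test_harmonic_bond_arithmetic(self):
        bond = BondedParam(type=None, kind="bond", equilibrium=0.35,
                           force_constant=5000.0)
        assert evaluate_potential(bond, 0.36) == pytest.approx(0.25)

    def test_nonnegative_and_zero_only_at_equilibrium(self):
        angle = BondedParam(type=None, kind="angle", equilibrium=120.0,
                            force_constant=50.0)
        thetas = np.linspace(10.0, 175.0, 60)
        v = evaluate_potential(angle, thetas)
        assert np.all(v >= 0)
        assert np.sum(np.isclose(v, 0.0, atol=1e-12)) <= 1
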