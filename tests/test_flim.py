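"""FRET quantification: lifetime MLE, autofluorescence filtering, efficiency
formula, per-patient aggregation, and the scale-invariance property."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flimlca.flim import (EmptyAfterFilterError, FretResult, LifetimeImagePair,
                          UnidentifiableDecayError, estimate_lifetime,
                          filter_lifetimes, fret_efficiency,
                          patient_fret_covariates)
from flimlca.synthetic import (FlimSceneSpec, simulate_decay_histogram,
                               simulate_flim_pair)


def _pair(tau_d, tau_da, intensity=1.0, labels=None):
    tau_d = np.asarray(tau_d, dtype=float)
    shape = tau_d.shape
    labels = np.ones(shape, dtype=int) if labels is None else labels
    return LifetimeImagePair(
        tau_d_map=tau_d, tau_da_map=np.asarray(tau_da, dtype=float),
        donor_intensity_map=np.full(shape, float(intensity)),
        mask=np.ones(shape, dtype=bool), region_labels=labels)


class TestEstimateLifetime:
    def test_noiseless_discretized_decay_recovered_exactly(self):
        tau, bw, nb = 2.0, 0.05, 200
        edges = np.arange(nb + 1) * bw
        p = np.diff(1.0 - np.exp(-edges / tau))
        counts = 1e7 * p / p.sum()
        assert estimate_lifetime(counts, bw) == pytest.approx(2.0, abs=1e-6)

    def test_simulated_histogram_recovered_within_one_percent(self):
        h = simulate_decay_histogram(3.0, 10**6, 256, 0.05, seed=2)
        assert estimate_lifetime(h, 0.05) == pytest.approx(3.0, rel=0.01)

    def test_uniform_counts_flagged_nonconvergent(self):
        with pytest.warns(RuntimeWarning, match="did not converge"):
            tau = estimate_lifetime(np.full(32, 100.0), 0.1)
        assert math.isinf(tau)

    def test_single_occupied_bin_unidentifiable(self):
        counts = np.zeros(16)
        counts[3] = 500
        with pytest.raises(UnidentifiableDecayError):
            estimate_lifetime(counts, 0.1)


class TestFilter:
    def test_contaminant_removed_signal_retained(self):
        spec = FlimSceneSpec(shape=(64, 64), e_true=(0.02,), af_fraction=0.2,
                             af_lifetime=0.8, noise_sd=0.02, seed=5)
        pair, truth = simulate_flim_pair(spec)
        filtered, report = filter_lifetimes(pair, (1.5, 4.0))
        assert report.n_removed == truth.contaminated.sum()
        assert filtered.mask[~truth.contaminated].all()
        assert not filtered.mask[truth.contaminated].any()

    def test_wide_window_is_identity_on_mask(self):
        pair = _pair(np.full((5, 5), 2.5), np.full((5, 5), 2.4))
        filtered, report = filter_lifetimes(pair, (1e-9, 1e9))
        np.testing.assert_array_equal(filtered.mask, pair.mask)
        assert report.n_removed == 0

    def test_disjoint_window_errors(self):
        pair = _pair(np.full((5, 5), 2.5), np.full((5, 5), 2.4))
        with pytest.raises(EmptyAfterFilterError):
            filter_lifetimes(pair, (10.0, 20.0))


class TestFretEfficiency:
    @pytest.mark.parametrize("tau_da,expected", [(2.0, 0.0), (1.0, 0.5)])
    def test_point_examples(self, tau_da, expected):
        pair = _pair(np.full((4, 4), 2.0), np.full((4, 4), tau_da))
        res = fret_efficiency(pair, min_pixels=1)
        assert res[0].fret_efficiency == pytest.approx(expected, abs=1e-12)

    def test_efficiency_equals_one_minus_lifetime_ratio_exactly(self):
        rng = np.random.default_rng(0)
        pair = _pair(rng.uniform(2, 3, (10, 10)), rng.uniform(1.5, 2.5, (10, 10)))
        res = fret_efficiency(pair, min_pixels=1)[0]
        assert res.fret_efficiency == pytest.approx(
            1 - res.mean_tau_da / res.mean_tau_d, abs=1e-14)

    def test_negative_efficiency_kept_and_flagged(self):
        pair = _pair(np.full((4, 4), 2.0), np.full((4, 4), 2.2))
        res = fret_efficiency(pair, min_pixels=1)[0]
        assert res.fret_efficiency < 0
        assert "NEGATIVE_E" in res.qc_flags

    def test_low_pixel_count_gives_missing_efficiency(self):
        pair = _pair(np.full((2, 2), 2.0), np.full((2, 2), 1.9))
        res = fret_efficiency(pair, min_pixels=10)[0]
        assert "LOW_PIXEL_COUNT" in res.qc_flags
        assert math.isnan(res.fret_efficiency)

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        """E depends only on the lifetime ratio, so a common rescaling of
        both maps leaves it unchanged."""
        rng = np.random.default_rng(11)
        d = rng.uniform(2, 3, (6, 6))
        da = rng.uniform(1.5, 2.5, (6, 6))
        e0 = fret_efficiency(_pair(d, da), min_pixels=1)[0].fret_efficiency
        e1 = fret_efficiency(_pair(c * d, c * da), min_pixels=1)[0].fret_efficiency
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_monotone_in_lifetime_gap(self):
        base = np.full((4, 4), 2.0)
        es = [fret_efficiency(_pair(base, np.full((4, 4), da)), min_pixels=1)[0]
              .fret_efficiency for da in (1.8, 1.4, 1.0, 0.6)]
        assert np.all(np.diff(es) > 0)

    def test_end_to_end_recovery_of_planted_efficiency(self):
        spec = FlimSceneSpec(shape=(100, 100), e_true=(0.016,), noise_sd=0.05,
                             af_fraction=0.1, af_lifetime=0.8, seed=3)
        pair, _ = simulate_flim_pair(spec)
        filtered, _ = filter_lifetimes(pair, (1.5, 4.0))
        res = fret_efficiency(filtered)[0]
        assert res.fret_efficiency == pytest.approx(0.016, abs=0.005)


class TestPatientCovariates:
    def _result(self, rid, e, fxh, n):
        return FretResult(rid, 2.0, 2.0 * (1 - e), e, fxh, n, 0, [])

    def test_single_region_passthrough(self):
        out = patient_fret_covariates({"P1": [self._result(1, 0.02, 5.0, 100)]})
        assert out.loc[0, "fret"] == pytest.approx(0.02)
        assert out.loc[0, "fret_x_her3"] == pytest.approx(5.0)

    def test_equal_weight_average(self):
        out = patient_fret_covariates({"P1": [self._result(1, 0.01, 1.0, 50),
                                              self._result(2, 0.03, 3.0, 50)]})
        assert out.loc[0, "fret"] == pytest.approx(0.02)

    def test_pixel_weighted_average(self):
        out = patient_fret_covariates({"P1": [self._result(1, 0.01, 1.0, 30),
                                              self._result(2, 0.04, 4.0, 10)]})
        assert out.loc[0, "fret"] == pytest.approx(0.0175)

    def test_all_invalid_regions_marked_missing_not_dropped(self):
        bad = FretResult(1, math.nan, math.nan, math.nan, math.nan, 2, 98,
                         ["LOW_PIXEL_COUNT"])
        out = patient_fret_covariates({"P1": [bad]})
        assert len(out) == 1
        assert math.isnan(out.loc[0, "fret"])
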