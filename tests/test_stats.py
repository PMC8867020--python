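"""Exponent estimators, bimodality detection, scaling and classification."""

import numpy as np
import pytest

from avalanchekit.avalanche import AvalancheRecord
from avalanchekit.fixtures import mixture_samples, sample_power_law
from avalanchekit.stats import (
    classify_regime,
    detect_bimodality,
    duration_size_scaling,
    fit_power_law,
    log_binned_histogram,
)


class TestLogBinnedHistogram:
    def test_slope_matches_sampling_density(self):
        samples = sample_power_law(1.5, 1.0, 100_000, seed=0)
        samples = samples[samples < 1e4]
        centers, densities, _, counts = log_binned_histogram(samples, 10)
        m = (counts >= 50) & (centers < 1e3)
        slope = np.polyfit(np.log10(centers[m]), np.log10(densities[m]), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.05)

    def test_total_mass_normalized_and_binning_invariant(self):
        samples = sample_power_law(2.0, 1.0, 20_000, seed=1)
        masses = []
        for bpd in (5, 10):
            _, densities, edges, _ = log_binned_histogram(samples, bpd)
            masses.append(float(np.sum(densities * np.diff(edges))))
        assert masses[0] == pytest.approx(1.0, abs=0.02)
        assert masses[0] == pytest.approx(masses[1], rel=0.01)

    def test_all_equal_samples_single_bin(self):
        centers, densities, _, counts = log_binned_histogram(np.full(20, 3.0))
        assert counts.sum() == 20
        assert (densities > 0).sum() == 1

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(ValueError):
            log_binned_histogram(np.array([1.0, -2.0] * 10))


class TestFitPowerLaw:
    @pytest.mark.parametrize("true_exponent", [1.5, 2.0, 3.0])
    def test_mle_recovers_known_exponents_within_2_se(self, true_exponent):
        samples = sample_power_law(true_exponent, 1.0, 100_000, seed=7)
        fit = fit_power_law(samples, method="mle", fit_range=(1.0, np.inf))
        assert abs(fit.exponent - true_exponent) < 2 * fit.exponent_se

    def test_mle_auto_cutoff_near_true_cutoff(self):
        rng = np.random.default_rng(3)
        body = rng.uniform(0.5, 5.0, 30_000)  # non-power-law contamination below 5
        tail = sample_power_law(2.0, 5.0, 30_000, seed=4)
        fit = fit_power_law(np.concatenate([body, tail]), method="mle")
        assert 3.0 < fit.fit_range[0] < 10.0
        assert fit.exponent == pytest.approx(2.0, abs=0.1)

    def test_scale_invariance(self):
        samples = sample_power_law(1.5, 1.0, 50_000, seed=5)
        a = fit_power_law(samples, fit_range=(1.0, np.inf)).exponent
        b = fit_power_law(10 * samples, fit_range=(10.0, np.inf)).exponent
        assert a == pytest.approx(b, rel=1e-9)

    def test_exponential_samples_flagged_as_poor_fit(self):
        rng = np.random.default_rng(6)
        samples = 1.0 + rng.exponential(2.0, 50_000)
        fit = fit_power_law(samples, method="mle")
        assert fit.ks_ok is False or fit.fit_range[0] > np.quantile(samples, 0.9)

    def test_logbin_ls_straight_window_recovery(self):
        samples = sample_power_law(2.0, 1.0, 100_000, seed=8)
        fit = fit_power_law(samples, method="logbin_ls", min_scale=1.0)
        assert fit.exponent == pytest.approx(2.0, abs=0.15)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.full(200, 2.0))


class TestDurationSizeScaling:
    def test_noiseless_half_power_recovery(self):
        rng = np.random.default_rng(9)
        sizes = 10 ** rng.uniform(0, 4, 2000)
        records = [
            AvalancheRecord(0.0, float(np.sqrt(s)), float(s), 1) for s in sizes
        ]
        fit = duration_size_scaling(records)
        assert not fit.gap_detected
        assert len(fit.regimes) == 1
        assert fit.regimes[0]["exponent"] == pytest.approx(0.5, abs=0.01)

    def test_gap_splits_two_regimes(self):
        rng = np.random.default_rng(10)
        small = 10 ** rng.uniform(0, 1.5, 1000)
        large = 10 ** rng.uniform(3.5, 5, 1000)
        records = [
            AvalancheRecord(0.0, float(s**0.5), float(s), 1) for s in small
        ] + [AvalancheRecord(0.0, float(s**1.0 / 100), float(s), 1) for s in large]
        fit = duration_size_scaling(records)
        assert fit.gap_detected
        assert len(fit.regimes) == 2
        assert fit.regimes[0]["exponent"] == pytest.approx(0.5, abs=0.05)
        assert fit.regimes[1]["exponent"] == pytest.approx(1.0, abs=0.05)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            duration_size_scaling([AvalancheRecord(0, 1, 1, 1)] * 50)


class TestBimodality:
    def test_mixture_with_system_size_hump_flagged(self):
        samples = mixture_samples(1.5, 1.0, 50_000, 2000.0, 200.0, 4000, seed=11)
        fit = fit_power_law(samples, method="mle")
        flag, hump, mass = detect_bimodality(fit)
        assert flag
        assert 800 < hump < 5000
        assert 0.02 < mass < 0.2

    def test_pure_power_law_not_flagged(self):
        """False-positive control over independent replicates (< 5%)."""
        hits = 0
        for rep in range(40):
            samples = sample_power_law(1.5, 1.0, 10_000, seed=100 + rep)
            fit = fit_power_law(samples, method="mle")
            hits += detect_bimodality(fit)[0]
        assert hits <= 2

    def test_monotone_decreasing_density_not_flagged(self):
        samples = sample_power_law(2.5, 1.0, 20_000, seed=12)
        fit = fit_power_law(samples, method="mle")
        assert detect_bimodality(fit)[0] is False


class TestClassifyRegime:
    def _fit(self, samples):
        return fit_power_law(np.asarray(samples), method="mle")

    def test_bimodal_sample_is_supercritical(self):
        samples = mixture_samples(1.5, 1.0, 20_000, 2000.0, 200.0, 2000, seed=13)
        fit = self._fit(samples)
        flag, _, _ = detect_bimodality(fit)
        assert classify_regime(fit, fit, flag, system_size=2000.0) == "supercritical"

    def test_clean_power_law_is_critical(self):
        samples = sample_power_law(1.5, 1.0, 20_000, seed=14)
        samples = samples[samples < 1e6]
        fit = self._fit(samples)
        assert classify_regime(fit, fit, False, system_size=2000.0) == "critical"

    def test_sharply_truncated_sample_is_subcritical(self):
        rng = np.random.default_rng(15)
        body = sample_power_law(1.2, 1.0, 60_000, seed=16)
        keep = rng.random(len(body)) < np.exp(-body / 100.0)  # cutoff scale 100
        samples = body[keep]
        fit = self._fit(samples)
        assert classify_regime(fit, fit, False, system_size=2000.0) == "subcritical"

    def test_insufficient_records_undetermined(self):
        samples = sample_power_law(1.5, 1.0, 300, seed=17)
        fit = fit_power_law(samples, method="mle", fit_range=(1.0, np.inf))
        assert classify_regime(fit, fit, False) == "undetermined"
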