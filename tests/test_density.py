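"""Posterior weights, weighted KDE marginals, summaries, peak widths."""

import numpy as np
import pytest

from neurocalib import density as de
from neurocalib.exceptions import ConfigurationError, DegenerateSampleError


class TestPosteriorWeights:
    def test_equal_losses_give_uniform_weights(self):
        w = de.posterior_weights(np.full(8, 3.7))
        np.testing.assert_allclose(w, 1 / 8)

    def test_infinite_loss_gets_zero_weight(self):
        w = de.posterior_weights(np.array([0.0, np.inf]))
        np.testing.assert_allclose(w, [1.0, 0.0])

    def test_hand_evaluated_shifted_softmax(self):
        w = de.posterior_weights(np.array([0.0, np.log(2)]))
        np.testing.assert_allclose(w, [2 / 3, 1 / 3])

    def test_shift_invariance(self, rng):
        J = rng.uniform(0, 5, 30)
        np.testing.assert_allclose(de.posterior_weights(J),
                                   de.posterior_weights(J + 123.4))

    def test_all_nonfinite_rejected(self):
        with pytest.raises(DegenerateSampleError):
            de.posterior_weights(np.array([np.nan, np.inf]))

    def test_prior_box_excludes_out_of_box_samples(self):
        samples = {"a": np.array([0.5, 1.5, 0.7]),
                   "b": np.array([2.0, 2.0, 9.0])}
        w = de.box_restricted_weights(samples, np.zeros(3),
                                      {"a": (0, 1), "b": (0, 5)})
        # sample 1 violates a's box, sample 2 violates b's box
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0])

    def test_prior_box_all_excluded_raises(self):
        with pytest.raises(DegenerateSampleError):
            de.box_restricted_weights({"a": np.array([2.0])}, np.zeros(1),
                                      {"a": (0, 1)})


class TestMarginal:
    def test_normalization(self, rng):
        vals = rng.normal(2.0, 0.5, 400)
        md = de.marginal(vals, losses=rng.uniform(0, 1, 400))
        assert md.normalization == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_symmetric_input(self, rng):
        vals = np.concatenate([np.zeros(200), np.ones(200)])
        vals = vals + rng.normal(0, 0.01, 400)
        md = de.marginal(vals, losses=np.zeros(400), bandwidth=0.05)
        peaks = de.peak_widths(md)
        assert peaks.n_peaks == 2
        np.testing.assert_allclose(np.sort(peaks.peak_locations), [0, 1], atol=0.03)

    def test_gaussian_sample_recovers_gaussian(self, rng):
        s, h = 0.8, 0.2
        vals = rng.normal(5.0, s, 4000)
        md = de.marginal(vals, losses=np.zeros(4000), bandwidth=h)
        summary = de.summarize(md)
        assert summary["expectation"] == pytest.approx(5.0, abs=0.1)
        # KDE convolution widens the SD to sqrt(s^2 + h^2)
        assert summary["sd"] == pytest.approx(np.hypot(s, h), rel=0.05)
        fwhm = de.peak_widths(md).widths[0]
        assert fwhm == pytest.approx(2.3548 * np.hypot(s, h), rel=0.1)

    def test_requires_two_distinct_values(self):
        with pytest.raises(ConfigurationError):
            de.marginal(np.ones(10), losses=np.zeros(10))

    def test_zero_bandwidth_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            de.marginal(rng.normal(size=20), losses=np.zeros(20), bandwidth=0.0)

    def test_brute_force_binned_oracle_equivalence(self, rng):
        """Weighted KDE equals direct binned exp(-J) summation smoothed
        with the same Gaussian kernel (within 2% of the peak height)."""
        n = 800
        vals = np.concatenate([rng.normal(1, 0.3, n // 2), rng.normal(3, 0.5, n // 2)])
        J = rng.uniform(0, 3, n)
        h = 0.25
        md = de.marginal(vals, losses=J, bandwidth=h, grid_size=400)
        # oracle: fine histogram of exp(-J) mass, then exact Gaussian smear
        edges = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, 4001)
        centers = (edges[:-1] + edges[1:]) / 2
        mass, _ = np.histogram(vals, bins=edges, weights=np.exp(-J))
        mass /= mass.sum()
        oracle = (
            mass[None, :]
            * np.exp(-0.5 * ((md.grid[:, None] - centers[None, :]) / h) ** 2)
        ).sum(axis=1) / (np.sqrt(2 * np.pi) * h)
        oracle /= np.trapezoid(oracle, md.grid)
        assert np.max(np.abs(md.density - oracle)) < 0.02 * md.density.max()


class TestSummaries:
    def test_delta_like_density(self, rng):
        vals = rng.normal(2.5, 1e-4, 200)
        md = de.marginal(vals, losses=np.zeros(200), bandwidth=0.01)
        s = de.summarize(md)
        assert s["mle"] == pytest.approx(2.5, abs=0.01)
        assert s["expectation"] == pytest.approx(2.5, abs=0.01)
        assert s["sd"] < 0.05

    def test_symmetric_unimodal_mle_equals_expectation(self, rng):
        vals = rng.normal(0.0, 1.0, 5000)
        md = de.marginal(vals, losses=np.zeros(5000), bandwidth=0.3)
        s = de.summarize(md)
        assert s["mle"] == pytest.approx(s["expectation"], abs=0.1)

    def test_flat_density_ambiguous_mle(self):
        md = de.MarginalDensity("x", np.linspace(0, 1, 11), np.ones(11), 0.1)
        with pytest.raises(de.AmbiguousMLEError) as err:
            de.summarize(md)
        assert len(err.value.locations) == 11


class TestPeakWidths:
    def test_single_peak_width_sd_is_exactly_zero(self, rng):
        vals = rng.normal(1.0, 0.4, 1000)
        md = de.marginal(vals, losses=np.zeros(1000))
        peaks = de.peak_widths(md)
        assert peaks.n_peaks == 1
        assert peaks.width_sd == 0.0

    def test_two_identical_gaussians_equal_widths(self, rng):
        vals = np.concatenate([rng.normal(0, 0.2, 2000), rng.normal(3, 0.2, 2000)])
        md = de.marginal(vals, losses=np.zeros(4000), bandwidth=0.1)
        peaks = de.peak_widths(md)
        assert peaks.n_peaks == 2
        assert peaks.width_sd / peaks.mean_width < 0.1

    def test_prominence_filters_minor_bumps(self, rng):
        vals = np.concatenate([rng.normal(0, 0.2, 2000), rng.normal(3, 0.2, 10)])
        md = de.marginal(vals, losses=np.zeros(2010), bandwidth=0.1)
        peaks = de.peak_widths(md)  # default prominence: 5% of max
        assert peaks.n_peaks == 1

    def test_no_peak_error(self):
        md = de.MarginalDensity("x", np.linspace(0, 1, 50),
                                np.linspace(0, 2, 50), 0.1)
        # monotone ramp: argmax at the edge is rescued, so force a real failure
        with pytest.raises(de.NoPeakError):
            de.peak_widths(md, prominence=np.inf)
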