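"""Statistical and spectral fidelity of the synthetic jujube generator."""

import numpy as np
import pytest

from hyperssc import (
    STAGE_PRIORS,
    STAGES,
    SpectralModel,
    StagePrior,
    calibrate_reflectance,
    generate_cube,
    generate_dataset,
    generate_spectrum,
    sample_ssc,
)


class TestSampleSSC:
    @pytest.mark.parametrize("stage", STAGES)
    def test_stage_statistics_recovered(self, stage):
        prior = STAGE_PRIORS[stage]
        x = sample_ssc(prior, 10_000, seed=42)
        assert abs(x.mean() - prior.mean_pct) < 0.15
        assert x.min() >= prior.min_pct and x.max() <= prior.max_pct

    def test_deterministic_by_seed(self):
        a = sample_ssc(STAGE_PRIORS["immature"], 100, seed=7)
        b = sample_ssc(STAGE_PRIORS["immature"], 100, seed=7)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, sample_ssc(STAGE_PRIORS["immature"], 100, seed=8))

    def test_matches_rejection_sampler(self):
        """Truncated-normal draws agree with a brute-force rejection sampler."""
        prior = STAGE_PRIORS["immature"]
        x = sample_ssc(prior, 20_000, seed=1)
        rng = np.random.default_rng(2)
        accepted = []
        while len(accepted) < 20_000:
            draw = rng.normal(prior.mean_pct, prior.sd_pct, 10_000)
            accepted.extend(draw[(draw >= prior.min_pct) & (draw <= prior.max_pct)])
        ref = np.array(accepted[:20_000])
        se = prior.sd_pct / np.sqrt(20_000)
        assert abs(x.mean() - ref.mean()) < 6 * se
        assert abs(x.std() - ref.std()) < 6 * se

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            sample_ssc(StagePrior("x", 10.0, 1.0, 10.0, 10.0), 5)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            sample_ssc(STAGE_PRIORS["immature"], 0)


class TestGenerateSpectrum:
    def test_higher_ssc_lower_reflectance_in_window(self, noiseless_model):
        m = noiseless_model
        s1 = generate_spectrum(15.0, m, seed=0)
        s2 = generate_spectrum(35.0, m, seed=0)
        lo, hi = m.sensitive_window
        win = (m.wavelengths >= lo) & (m.wavelengths <= hi)
        assert np.all(s2[win] < s1[win])

    def test_absorption_minima_at_feature_centers(self):
        m = SpectralModel(noise_sd=0.0)  # full 256-band grid for resolution
        s = generate_spectrum(20.0, m, seed=0)
        spacing = m.wavelengths[1] - m.wavelengths[0]
        for center, _, _ in m.absorption_features:
            i = int(np.abs(m.wavelengths - center).argmin())
            j = i - 5 + int(np.argmin(s[i - 5 : i + 6]))  # minimum in the neighborhood
            assert abs(m.wavelengths[j] - center) <= spacing + 1e-9
            assert s[j] < s[i - 5] and s[j] < s[i + 5]

    def test_window_slope_equals_configured_sensitivity(self, noiseless_model):
        """OLS slope of deep-window mean reflectance on SSC recovers the coefficient."""
        m = noiseless_model
        lo, hi = m.sensitive_window
        deep = (m.wavelengths >= lo + m.window_ramp_nm) & (m.wavelengths <= hi - m.window_ramp_nm)
        ssc = np.linspace(5, 45, 200)
        means = np.array([generate_spectrum(s, m, seed=0)[deep].mean() for s in ssc])
        slope = np.polyfit(ssc, means, 1)[0]
        assert slope == pytest.approx(m.ssc_sensitivity, abs=1e-12)

    def test_edge_noise_amplified(self, small_model):
        m = small_model
        reps = np.array([generate_spectrum(20.0, m, seed=s) for s in range(200)])
        sd = reps.std(axis=0)
        edge = m.wavelengths < m.keep_window[0]
        inside = (m.wavelengths >= m.keep_window[0]) & (m.wavelengths <= m.keep_window[1])
        assert sd[edge].mean() > 3 * sd[inside].mean()

    def test_reflectance_within_physical_range(self, small_model):
        for s in (0.0, 30.0, 60.0):
            x = generate_spectrum(s, small_model, seed=3)
            assert np.all(x > 0) and np.all(x < 1.2)

    def test_out_of_range_ssc_rejected(self, small_model):
        with pytest.raises(ValueError):
            generate_spectrum(65.0, small_model)


class TestGenerateCube:
    def test_uniform_field_shares_one_spectrum(self, noiseless_model):
        cube, refs, truth = generate_cube(20.0, (32, 32), noiseless_model, heterogeneity_sd=0.0, seed=0)
        refl = calibrate_reflectance(cube, refs)
        pix = refl.data[truth.mask]
        assert np.allclose(pix, pix[0], atol=1e-6)
        # consistent with the single-spectrum generator
        expected = generate_spectrum(20.0, noiseless_model, seed=0)
        assert np.allclose(pix[0], expected, atol=1e-6)

    def test_calibration_inverts_dn_encoding(self, noiseless_model):
        cube, refs, truth = generate_cube(25.0, (32, 32), noiseless_model, heterogeneity_sd=0.0, seed=1)
        refl = calibrate_reflectance(cube, refs)
        expected = generate_spectrum(25.0, noiseless_model, seed=0)
        r, c = np.argwhere(truth.mask)[0]
        np.testing.assert_allclose(refl.data[r, c], expected, atol=1e-6)

    def test_truth_field_mean_matches_sample_ssc(self, small_model):
        _, _, truth = generate_cube(27.3, (48, 48), small_model, heterogeneity_sd=2.0, seed=2)
        assert abs(np.nanmean(truth.pixel_field[truth.mask]) - 27.3) < 0.1

    def test_field_is_heterogeneous_and_asymmetric(self, small_model):
        _, _, truth = generate_cube(27.3, (48, 48), small_model, heterogeneity_sd=2.0, seed=3)
        vals = truth.pixel_field[truth.mask]
        assert vals.std() == pytest.approx(2.0, rel=0.01)
        left = truth.pixel_field[:, :24][truth.mask[:, :24]]
        right = truth.pixel_field[:, 24:][truth.mask[:, 24:]]
        assert abs(left.mean() - right.mean()) > 0.1  # gradient term forces asymmetry

    def test_too_small_shape_rejected(self, small_model):
        with pytest.raises(ValueError):
            generate_cube(20.0, (8, 32), small_model)


class TestGenerateDataset:
    def test_default_design_counts(self):
        ds = generate_dataset(seed=0, model=SpectralModel(n_bands=32))
        assert len(ds) == 600
        labels, counts = np.unique(ds.stage, return_counts=True)
        assert set(labels) == set(STAGES) and np.all(counts == 150)

    def test_stage_means_ordered(self, small_dataset):
        means = [small_dataset.y[small_dataset.stage == s].mean() for s in STAGES]
        assert np.all(np.diff(means) > 0)

    def test_truncation_respected(self, small_dataset):
        for s in STAGES:
            prior = STAGE_PRIORS[s]
            y = small_dataset.y[small_dataset.stage == s]
            assert y.min() >= prior.min_pct and y.max() <= prior.max_pct

    def test_seeding_contract(self, small_model):
        a = generate_dataset(20, small_model, seed=1)
        b = generate_dataset(20, small_model, seed=1)
        c = generate_dataset(20, small_model, seed=2)
        np.testing.assert_array_equal(a.y, b.y)
        assert a.X.shape == c.X.shape and not np.array_equal(a.y, c.y)

    def test_monotone_stage_contrast_in_window(self, noiseless_model):
        """Mean in-window reflectance strictly decreases across stage means (noise 0)."""
        m = noiseless_model
        ds = generate_dataset(20, m, seed=5)
        lo, hi = m.sensitive_window
        win = (ds.wavelengths >= lo) & (ds.wavelengths <= hi)
        means = [ds.X[ds.stage == s][:, win].mean() for s in STAGES]
        assert np.all(np.diff(means) < 0)
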