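"""Synthetic-data generators: closed forms, determinism, statistical laws."""

import numpy as np
import pytest
from scipy import stats

from slbphase import (
    FrapGenParams,
    SceneParams,
    TitrationParams,
    gen_actin_timecourse,
    gen_bilayer_image,
    gen_calibration,
    gen_frap_trace,
    gen_titration,
    sample_cluster_areas,
    titration_area_fraction,
)


class TestBilayerImage:
    def test_noiseless_flat_scene_is_constant(self):
        params = SceneParams(
            width=32, height=32, morphology="none", noise_sd=0.0,
            vignette_strength=0.0, mean_intensity=500.0, camera_offset=80.0,
        )
        img, mask = gen_bilayer_image(params)
        assert np.all(img.values == 580.0)
        assert not mask.any()

    def test_enrichment_is_exact_without_noise(self):
        params = SceneParams(
            width=256, height=256, morphology="nucleated", enrichment=4.0,
            noise_sd=0.0, camera_offset=0.0, seed=2,
        )
        img, mask = gen_bilayer_image(params)
        ratio = img.values[mask].mean() / img.values[~mask].mean()
        assert ratio == pytest.approx(4.0, abs=1e-12)

    def test_seed_determinism(self):
        params = SceneParams(width=64, height=64, morphology="nucleated", seed=5)
        a, ma = gen_bilayer_image(params)
        b, mb = gen_bilayer_image(params)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(ma, mb)

    def test_poisson_cluster_counts(self):
        """Component counts across images match direct Poisson sampling.

        Low area fraction keeps cluster merging rare, so the number of
        ground-truth components tracks the Poisson number of seeded
        puncta.
        """
        from skimage.measure import label

        n_images = 93
        params = [
            SceneParams(
                width=128, height=128, morphology="nucleated",
                cluster_density=0.02, mean_cluster_area=0.5, noise_sd=0.0,
                seed=100 + i,
            )
            for i in range(n_images)
        ]
        counts = np.array(
            [label(gen_bilayer_image(p)[1], connectivity=2).max() for p in params]
        )
        lam = 0.02 * 128 * 128 * 0.16**2
        oracle = np.random.default_rng(0).poisson(lam, n_images)
        t, p = stats.ttest_ind(counts, oracle)
        assert p > 0.01
        assert counts.mean() == pytest.approx(lam, rel=0.1)

    def test_nucleated_mean_area_converges(self):
        """Realized component areas average to the exponential-law mean."""
        from skimage.measure import label, regionprops

        areas = []
        i = 0
        while len(areas) < 5000:
            p = SceneParams(
                width=256, height=256, morphology="nucleated",
                cluster_density=0.02, mean_cluster_area=1.0, noise_sd=0.0,
                seed=9000 + i,
            )
            _, mask = gen_bilayer_image(p)
            lab = label(mask, connectivity=2)
            areas.extend(r.area * 0.16**2 for r in regionprops(lab))
            i += 1
        assert np.mean(areas) == pytest.approx(1.0, rel=0.05)

    def test_spinodal_area_fraction(self):
        params = SceneParams(
            width=512, height=512, morphology="spinodal",
            clustered_fraction=0.3, noise_sd=0.0, seed=1,
        )
        _, mask = gen_bilayer_image(params)
        assert mask.mean() == pytest.approx(0.3, abs=0.02 * 0.3 + 0.002)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(width=0)
        with pytest.raises(ValueError):
            SceneParams(enrichment=0.5)
        with pytest.raises(ValueError):
            SceneParams(morphology="spinodal", clustered_fraction=1.0)


class TestTitration:
    def test_below_onset_images_are_homogeneous(self):
        tp = TitrationParams(
            concentrations=(10.0, 50.0, 100.0, 150.0),
            critical_concentration=200.0,
            scene=SceneParams(width=32, height=32, noise_sd=0.0, camera_offset=0.0),
        )
        for _, img in gen_titration(tp):
            assert np.all(img.values == img.values.flat[0])

    def test_onset_law_closed_form(self):
        tp = TitrationParams(
            concentrations=(25.0, 100.0, 300.0, 1000.0),
            critical_concentration=200.0,
            rise_width=150.0,
            max_clustered_fraction=0.25,
        )
        assert titration_area_fraction(150.0, tp) == 0.0
        assert titration_area_fraction(350.0, tp) == pytest.approx(
            0.25 * (1 - np.exp(-1))
        )

    def test_ground_truth_breakpoint_is_200(self):
        conc = tuple(np.geomspace(25, 1000, 12))
        tp = TitrationParams(concentrations=conc, critical_concentration=200.0)
        phis = [titration_area_fraction(c, tp) for c in conc]
        first_rise = next(c for c, phi in zip(conc, phis) if phi > 0)
        last_flat = max(c for c in conc if c <= 200.0)
        assert last_flat < 200.0 < first_rise

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError, match="empty|concentration"):
            TitrationParams(concentrations=())


class TestFrapTrace:
    def test_no_bleach_identity(self):
        p = FrapGenParams(tau_values=(10.0,), bleach_depth=0.0, noise_sd=0.0)
        trace, _ = gen_frap_trace(p)
        assert np.allclose(trace.values, 1.0)

    def test_single_tau_closed_form(self):
        tau = 12.0
        p = FrapGenParams(
            tau_values=(tau,), bleach_depth=0.6, mobile_fraction=1.0,
            frame_interval=1.0, duration=100.0, noise_sd=0.0,
        )
        trace, _ = gen_frap_trace(p)
        t, y = trace.postbleach()
        k = int(tau / 1.0)
        assert t[k] == tau
        assert y[k] - y[0] == pytest.approx(0.6 * (1 - np.exp(-1)))

    def test_biexp_matches_direct_formula(self):
        p = FrapGenParams(
            tau_values=(86.0, 526.0), fractions=(0.76, 0.24),
            bleach_depth=0.8, frame_interval=2.0, duration=2000.0, noise_sd=0.0,
        )
        trace, _ = gen_frap_trace(p)
        t, y = trace.postbleach()
        expected = 0.2 + 0.8 * (
            0.76 * (1 - np.exp(-t / 86.0)) + 0.24 * (1 - np.exp(-t / 526.0))
        )
        assert np.allclose(y, expected)
        assert y[-1] == pytest.approx(0.2 + 0.8 * 1.0, abs=0.02)  # near-full recovery

    def test_acquisition_bleaching_reference(self):
        p = FrapGenParams(
            tau_values=(5.0,), acq_bleach_tau=200.0, noise_sd=0.0,
            frame_interval=1.0, duration=50.0,
        )
        trace, ref = gen_frap_trace(p)
        elapsed = trace.times - trace.times[0]
        assert np.allclose(ref, np.exp(-elapsed / 200.0))
        assert np.allclose(trace.values[: trace.n_prebleach], ref[: trace.n_prebleach])

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FrapGenParams(tau_values=(1.0, 2.0), fractions=(0.5, 0.4))


class TestCalibrationGen:
    def test_noiseless_points_on_line(self):
        ds = gen_calibration(2.0, 4.0, 3.0, noise_sd=0.0)
        for table, slope in [(ds.dye_solution, 2.0), (ds.protein_solution, 4.0)]:
            assert np.allclose(table[:, 1], slope * table[:, 0])
        assert ds.true_F == pytest.approx(2.0)

    def test_equal_slopes_give_unit_F(self):
        assert gen_calibration(3.0, 3.0, 1.0).true_F == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gen_calibration(1.0, 1.0, 1.0, n_points=1)


class TestActinTimecourse:
    def test_lags_within_range_and_3min_frames(self):
        traces = gen_actin_timecourse(n_clusters=40, lag_range_min=(6.0, 15.0), seed=3)
        for tr in traces:
            assert np.allclose(np.diff(tr.times), 3.0)
            baseline = tr.values[0]
            rise_start = tr.times[np.argmax(tr.values > baseline + 1e-9)]
            assert 6.0 - 3.0 <= rise_start <= 15.0 + 3.0

    def test_zero_lag_halftime_closed_form(self):
        from slbphase import actin_halftime

        traces = gen_actin_timecourse(
            n_clusters=1, lag_range_min=(0.0, 0.0), rise_tau=4.0,
            frame_interval_min=0.1, baseline=0.0, seed=0,
        )
        # saturating rise 1 - exp(-t/tau) reaches half its (sampled) max at
        # t_half = -tau * ln(1 - max/2); with long sampling max ~ 1
        tr = traces[0]
        observed_max = tr.values.max()
        expected = -4.0 * np.log(1 - observed_max / 2)
        assert actin_halftime(tr, window=60.0) == pytest.approx(expected, rel=0.05)


class TestSampleClusterAreas:
    def test_exponential_mean(self):
        areas = sample_cluster_areas(20000, "exponential", mean_area=2.0, seed=1)
        assert areas.mean() == pytest.approx(2.0, rel=0.05)

    def test_power_law_tail_exponent(self):
        areas = sample_cluster_areas(20000, "power_law", exponent=2.5, min_area=0.1, seed=1)
        # MLE of the Pareto tail index: alpha = 1 + n / sum(ln(s/s_min))
        alpha = 1 + areas.size / np.log(areas / 0.1).sum()
        assert alpha == pytest.approx(2.5, rel=0.05)
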