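"""Partially-synthetic generator: components, targets, augmentation."""

import dataclasses

import numpy as np
import pytest

from guancest import fitting
from guancest.bmc import PerturbationRanges, generate_tissue_mimicking_set
from guancest.fitting import lorentzian
from guancest.partial_synth import (
    MeasuredComponents,
    TrainingSample,
    augment_invivo_pairs,
    build_dataset,
    extract_measured_components,
    generate_fully_synthetic,
    generate_partially_synthetic,
    peak_amplitude_width,
    samples_from_simulation,
)
from guancest.physics import RexSpectrum, ZSpectrum, cos2_theta, rex_lorentzian


@pytest.fixture(scope="module")
def components(scheme, default_ranges):
    z, _ = generate_tissue_mimicking_set(default_ranges, 1, seed=3, scheme=scheme)[0]
    zc = fitting.estimate_and_correct_b0(z)
    return extract_measured_components(zc, source_label="sim0")


class TestExtractComponents:
    def test_components_on_full_grid_and_finite(self, components, scheme):
        assert components.rex_mt.values.shape == scheme.offsets_ppm.shape
        assert components.rex_amines.values.shape == scheme.offsets_ppm.shape
        assert np.all(np.isfinite(components.rex_mt.values))

    def test_mt_lineshape_tracks_analytic_truth(self, components, scheme, default_ranges):
        """Fitted MT R_ex vs the true MT pool's analytic line shape over
        1.5-5 ppm: near-perfect shape agreement even when amplitudes err."""
        rng = np.random.default_rng(3)
        tissue = default_ranges.sample_tissue(rng)
        truth = rex_lorentzian(tissue.pool("mt"), scheme.offsets_ppm, scheme)
        m = (scheme.offsets_ppm >= 1.5) & (scheme.offsets_ppm <= 5.0)
        r = np.corrcoef(components.rex_mt.values[m], truth.values[m])[0, 1]
        assert r >= 0.99

    def test_mt_free_input_gives_negligible_mt_component(self, scheme):
        # synthetic 1-Z with no broad MT baseline
        z = 1.0 - lorentzian(scheme.offsets_ppm, 0.8, 0.0, 1.8) - lorentzian(scheme.offsets_ppm, 0.06, 2.5, 3.0)
        zs = ZSpectrum(scheme.offsets_ppm, z, r1obs=0.6, fm=0.0)
        comp = extract_measured_components(zs)
        assert np.max(comp.rex_mt.values) < 0.01

    def test_metadata_required(self, scheme):
        z = ZSpectrum(scheme.offsets_ppm, np.full(scheme.n_offsets, 0.8))
        with pytest.raises(ValueError):
            extract_measured_components(z)


class TestPeakAmplitudeWidth:
    def test_exact_lorentzian_measured(self):
        grid = np.arange(0.5, 3.5, 0.01)
        spec = RexSpectrum(grid, lorentzian(grid, 0.1, 2.0, 0.8))
        a, w = peak_amplitude_width(spec)
        assert a == pytest.approx(0.1, rel=1e-3)
        assert w == pytest.approx(0.8, rel=0.01)

    def test_vanishing_amplitude_uses_fallback_width(self):
        grid = np.arange(0.5, 3.5, 0.01)
        a, w = peak_amplitude_width(RexSpectrum(grid, np.zeros(grid.size)), fallback_width_ppm=0.7)
        assert a == 0.0 and w == 0.7


class TestGeneratePartiallySynthetic:
    def test_seed_determinism(self, components, default_ranges, scheme):
        a = generate_partially_synthetic(components, default_ranges, scheme, n=5, seed=2)
        b = generate_partially_synthetic(components, default_ranges, scheme, n=5, seed=2)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.z, sb.z)
            assert sa.target_a == sb.target_a and sa.target_w == sb.target_w

    def test_degenerate_zero_guanidine_range_gives_zero_targets(self, components, default_ranges, scheme):
        pools = {k: dict(v) for k, v in default_ranges.pools.items()}
        pools["guan"] = dict(pools["guan"], fs=(0.0, 0.0))
        ranges = dataclasses.replace(default_ranges, pools=pools)
        samples = generate_partially_synthetic(components, ranges, scheme, n=4, seed=1)
        assert all(s.target_a == 0.0 for s in samples)

    def test_noiseless_target_matches_bookkeeping(self, components, default_ranges, scheme):
        """Algebraic round trip: target A equals the drawn guanidine pool's
        R_ex peak scaled by (1+fm)/((1+r_MT·fm)·cos²θ(2 ppm))."""
        from guancest.physics import PoolParams

        samples = generate_partially_synthetic(
            components, default_ranges, scheme, n=3, seed=7, noise_sigma=0.0, finite_duration=False
        )
        c2 = cos2_theta(np.array([2.0]), scheme)[0]
        for s in samples:
            p = s.provenance
            pool = PoolParams("guan", 2.0, fs=p["guan_fs"], ksw=p["guan_ksw"], r2s=p["guan_r2s"])
            rex_peak = rex_lorentzian(pool, np.array([2.0]), scheme).values[0]
            expected = rex_peak * (1.0 + s.fm) / ((1.0 + p["r_mt"] * s.fm) * c2)
            assert s.target_a == pytest.approx(expected, abs=1e-8)

    def test_empty_component_list_rejected(self, default_ranges, scheme):
        with pytest.raises(ValueError):
            generate_partially_synthetic([], default_ranges, scheme, n=2, seed=0)

    def test_two_sources_split_equally(self, components, default_ranges, scheme):
        other = MeasuredComponents(
            components.rex_mt, components.rex_amines, components.r1obs, components.fm, "other"
        )
        samples = generate_partially_synthetic([components, other], default_ranges, scheme, n=10, seed=3)
        labels = [s.provenance["source"] for s in samples]
        assert labels.count("sim0") == labels.count("other") == 5

    def test_r_amines_zero_removes_amine_contribution(self, components, scheme):
        from guancest.partial_synth import _synth_sample
        from guancest.physics import PoolParams, WaterMTParams

        pools = {"guan": PoolParams("guan", 2.0, fs=0.001, ksw=200.0, r2s=40.0)}
        water = WaterMTParams(0.55, 20.0, fm=components.fm, r_mt=1.0)
        z0 = _synth_sample(scheme, components, pools, water, r_amines=0.0, b0=0.0, b1=1.0)
        z1 = _synth_sample(scheme, components, pools, water, r_amines=1.0, b0=0.0, b1=1.0)
        assert np.all(z0.z >= z1.z - 1e-12)
        downfield = (scheme.offsets_ppm > 1.0) & (scheme.offsets_ppm < 5.0)
        assert np.any(z0.z[downfield] > z1.z[downfield] + 1e-4)

    def test_lorentzian_shape_adequacy(self, components, default_ranges, scheme):
        """Reconstructing the target from (A, W) as a Lorentzian reproduces
        the exact label/reference target to <5% relative L2 over 1.5-2.5 ppm."""
        from guancest.physics import PoolParams

        samples = generate_partially_synthetic(
            components, default_ranges, scheme, n=5, seed=8, noise_sigma=0.0, finite_duration=False
        )
        dense = np.arange(1.5, 2.5 + 1e-9, 0.005)
        c2 = cos2_theta(dense, scheme)
        for s in samples:
            p = s.provenance
            pool = PoolParams("guan", 2.0, fs=p["guan_fs"], ksw=p["guan_ksw"], r2s=p["guan_r2s"])
            exact = (
                rex_lorentzian(pool, dense, scheme).values
                * (1.0 + s.fm) / ((1.0 + p["r_mt"] * s.fm) * c2)
            )
            recon = lorentzian(dense, s.target_a, 2.0, s.target_w)
            rel_l2 = np.linalg.norm(recon - exact) / np.linalg.norm(exact)
            assert rel_l2 < 0.05


class TestFullySyntheticAndSimSamples:
    def test_seed_determinism_and_peak_location(self, scheme):
        ranges = PerturbationRanges.default_fully_synthetic()
        a = generate_fully_synthetic(ranges, scheme, n=3, seed=4)
        b = generate_fully_synthetic(ranges, scheme, n=3, seed=4)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.z, sb.z)
        assert all(s.target_a >= 0 and s.target_w > 0 for s in a)

    def test_build_dataset_normalizes_by_r1obs(self, scheme, default_ranges):
        pairs = generate_tissue_mimicking_set(default_ranges, 2, seed=5, scheme=scheme)
        samples = samples_from_simulation(pairs)
        ds = build_dataset(samples)
        assert np.allclose(ds.X[0], samples[0].z / samples[0].r1obs)
        assert ds.y[0, 0] == pytest.approx(100.0 * samples[0].target_a)

    def test_dataset_subset_selects_columns(self, scheme, default_ranges):
        pairs = generate_tissue_mimicking_set(default_ranges, 2, seed=5, scheme=scheme)
        ds = build_dataset(samples_from_simulation(pairs))
        sub = ds.subset([0, 5, 10])
        assert sub.X.shape == (2, 3)
        assert np.allclose(sub.offsets_ppm, ds.offsets_ppm[[0, 5, 10]])


class TestAugmentInvivo:
    def _voxels(self, scheme, n):
        rng = np.random.default_rng(0)
        return [
            ZSpectrum(scheme.offsets_ppm, 0.7 + 0.01 * rng.normal(size=scheme.n_offsets),
                      r1obs=0.6, fm=0.1)
            for _ in range(n)
        ]

    def test_four_spectra_give_six_pair_means(self, scheme):
        out = augment_invivo_pairs(self._voxels(scheme, 4))
        assert len(out) == 6

    def test_pair_mean_of_identical_spectra_is_the_spectrum(self, scheme):
        v = self._voxels(scheme, 1) * 2
        out = augment_invivo_pairs(v)
        assert np.allclose(out[0].z, v[0].z)

    def test_b0_variants_double_the_output(self, scheme):
        out = augment_invivo_pairs(self._voxels(scheme, 4), b0_range=(-0.1, 0.1), seed=1)
        assert len(out) == 12

    def test_fewer_than_two_voxels_rejected(self, scheme):
        with pytest.raises(ValueError):
            augment_invivo_pairs(self._voxels(scheme, 1))

    def test_expansion_factor_is_n_minus_1_over_2(self):
        # C(n,2)/n = (n-1)/2: 1894 voxels -> ~946-fold expansion
        n = 1894
        assert (n * (n - 1) // 2) / n == pytest.approx(946.5)


class TestTrainingSampleInvariants:
    def test_nonpositive_width_rejected(self, scheme):
        with pytest.raises(ValueError):
            TrainingSample(scheme.offsets_ppm, np.ones(scheme.n_offsets), 0.6, 0.1, 0.1, 0.0)

    def test_negative_amplitude_rejected(self, scheme):
        with pytest.raises(ValueError):
            TrainingSample(scheme.offsets_ppm, np.ones(scheme.n_offsets), 0.6, 0.1, -0.1, 0.5)
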