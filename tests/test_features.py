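"""Spherical-harmonic feature blocks and the SHORE representation."""

import numpy as np
import pytest

from freewater import sh
from freewater.features import (
    MAX_SH_DEGREE,
    N_SH_COEFFS,
    SHORE_N_COEFFS,
    ShellFeatureSet,
    ann_input_vectors,
    build_feature_set,
    sh_fit,
    sh_reconstruct,
    shore_fit,
    shore_reconstruct,
    shore_zeta,
)
from freewater.gradients import ShellCode, shell_code_for
from freewater.harmonize import normalize_signal
from freewater.phantom import dispersed_directions, make_scheme


@pytest.fixture(scope="module")
def dirs90():
    return dispersed_directions(90, seed=2)


class TestSHFit:
    def test_constant_signal_is_pure_degree_zero(self, dirs90):
        c = sh_fit(np.full(90, 0.73), dirs90)
        rec = sh_reconstruct(c, dirs90)
        assert np.allclose(rec, 0.73, atol=1e-10)
        assert np.abs(c[1:]).max() < 1e-10

    def test_degree4_coefficients_recovered_exactly(self, dirs90):
        rng = np.random.default_rng(3)
        c_true = np.zeros(N_SH_COEFFS)
        c_true[: sh.n_coeffs(4)] = rng.normal(size=sh.n_coeffs(4))
        vals = sh_reconstruct(c_true, dirs90)
        c_fit = sh_fit(vals, dirs90)
        assert np.abs(c_fit - c_true).max() < 1e-8

    def test_batched_fit_matches_per_voxel(self, dirs90):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.2, 1.0, size=(5, 90))
        batch = sh_fit(vals, dirs90)
        single = np.stack([sh_fit(v, dirs90) for v in vals])
        assert np.allclose(batch, single, atol=1e-12)

    def test_reconstruction_error_small_at_sample_points(self, dirs90):
        # band-limited input reconstructs at samples to near machine precision
        rng = np.random.default_rng(5)
        c = rng.normal(size=N_SH_COEFFS)
        vals = sh_reconstruct(c, dirs90)
        assert np.abs(sh_reconstruct(sh_fit(vals, dirs90), dirs90) - vals).max() < 1e-8

    def test_rotated_signal_fits_to_wigner_rotated_coefficients(self, dirs90):
        rng = np.random.default_rng(6)
        c = rng.normal(size=N_SH_COEFFS)
        R = sh.random_rotation(rng)
        D = sh.sh_rotation_matrix(R, MAX_SH_DEGREE)
        vals_rot = sh_reconstruct(c, dirs90 @ R)
        c_rot = sh_fit(vals_rot, dirs90)
        assert np.abs(c_rot - D @ c).max() < 1e-6

    def test_degenerate_direction_set_raises(self):
        dirs = np.tile(np.array([[0.0, 0.0, 1.0]]), (50, 1))
        with pytest.raises(ValueError, match="degenerate"):
            sh_fit(np.ones(50), dirs, reg=0.0)


@pytest.fixture(scope="module")
def norm_volume(noiseless_phantom):
    ph = noiseless_phantom
    norm, _, _ = normalize_signal(ph.signal, ph.scheme)
    return ph, norm


class TestFeatureSet:

    def test_full_code_gives_k_blocks_of_45(self, norm_volume):
        ph, norm = norm_volume
        fs = build_feature_set(norm, ph.scheme, ShellCode([1, 1, 1]))
        assert fs.coeffs.shape == ph.truth_f.shape + (3, N_SH_COEFFS)

    def test_absent_blocks_are_zero(self, norm_volume):
        ph, norm = norm_volume
        fs = build_feature_set(norm, ph.scheme, ShellCode([1, 0, 0]))
        assert np.all(fs.coeffs[..., 1, :] == 0.0)
        assert np.all(fs.coeffs[..., 2, :] == 0.0)

    def test_dropout_consistency_with_genuine_single_shell(self, norm_volume):
        """Zeroing shells of full data equals features of genuinely
        single-shell data of the same voxels."""
        ph, norm = norm_volume
        full = build_feature_set(norm, ph.scheme, ShellCode([1, 0, 0]))
        keep = np.sort(np.concatenate([ph.scheme.b0_indices, ph.scheme.shells[1000.0]]))
        sub_scheme = ph.scheme.subset(keep)
        sub_norm, _, _ = normalize_signal(ph.signal[..., keep], sub_scheme)
        single = build_feature_set(sub_norm, sub_scheme, shell_code_for(sub_scheme))
        assert list(single.code) == [1, 0, 0]
        assert np.abs(full.coeffs - single.coeffs).max() < 1e-8

    def test_zero_filling_never_alters_present_blocks(self, norm_volume):
        ph, norm = norm_volume
        full = build_feature_set(norm, ph.scheme, ShellCode([1, 1, 1]))
        partial = build_feature_set(norm, ph.scheme, ShellCode([1, 0, 1]))
        assert np.array_equal(full.coeffs[..., 0, :], partial.coeffs[..., 0, :])
        assert np.array_equal(full.coeffs[..., 2, :], partial.coeffs[..., 2, :])

    def test_nonzero_absent_block_rejected(self):
        bad = np.ones((2, 3, N_SH_COEFFS))
        with pytest.raises(ValueError, match="zero-filled"):
            ShellFeatureSet(coeffs=bad, code=ShellCode([1, 0, 1]))

    def test_ann_vector_length_96_for_90_directions(self, norm_volume):
        ph, norm = norm_volume
        vec = ann_input_vectors(norm, ph.scheme, 1000.0)
        assert vec.shape[-1] == 96


@pytest.fixture(scope="module")
def shore_scheme():
    return make_scheme(shells=(1000.0, 2000.0, 3000.0), dirs_per_shell=30,
                       n_b0=3, seed=7)


class TestShore:

    def test_coefficient_count_is_50_at_order_6(self, shore_scheme):
        feats = shore_fit(np.ones(len(shore_scheme)), shore_scheme, md=0.7e-3)
        assert feats.coeffs.shape == (SHORE_N_COEFFS,)
        assert SHORE_N_COEFFS == 50

    def test_zeta_formula_and_tau_homogeneity(self):
        md, tau = 0.8e-3, 0.025
        z = shore_zeta(md, tau)
        assert abs(z - 1.0 / (8 * np.pi**2 * tau * md)) < 1e-9
        assert abs(shore_zeta(md, 2 * tau) - z / 2) < 1e-9

    def test_nonpositive_md_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="nonpositive MD"):
            z = shore_zeta(0.0)
        assert z == pytest.approx(1.0 / (8 * np.pi**2 * 0.025 * 0.7e-3))

    def test_mono_exponential_reconstruction_within_one_percent(self, shore_scheme):
        adc = 0.9e-3
        sig = np.exp(-shore_scheme.bvals * adc)
        feats = shore_fit(sig, shore_scheme, md=adc)
        rec = shore_reconstruct(feats, shore_scheme)
        assert np.abs(rec - sig).max() < 0.01
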