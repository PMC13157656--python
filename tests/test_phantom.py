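"""Bi-tensor forward model, Rician noise and phantom generator."""

import numpy as np
import pytest

from freewater.gradients import build_scheme
from freewater.phantom import (
    BiTensorParams,
    add_rician_noise,
    bitensor_signal,
    bitensor_signal_field,
    dispersed_directions,
    generate_phantom,
    make_scheme,
)


@pytest.fixture(scope="module")
def scheme():
    return make_scheme(shells=(1000.0, 2000.0), dirs_per_shell=30, n_b0=3, seed=5)


class TestBiTensorSignal:
    def test_b0_returns_s0(self, scheme):
        p = BiTensorParams(f=0.37, D_tissue=np.diag([1.5e-3, 3e-4, 3e-4]), S0=420.0)
        s = bitensor_signal(p, scheme)
        assert np.allclose(s[scheme.b0_indices], 420.0, rtol=0, atol=1e-12)

    def test_matches_scalar_evaluation_for_isotropic_mixture(self, scheme):
        # f=0.5, isotropic tissue 0.7e-3, free water 3e-3 at b=1000
        p = BiTensorParams(f=0.5, D_tissue=np.eye(3) * 0.7e-3)
        s = bitensor_signal(p, scheme)
        expected = 0.5 * np.exp(-0.7) + 0.5 * np.exp(-3.0)
        idx = scheme.shells[1000.0]
        assert np.allclose(s[idx], expected, atol=1e-12)

    def test_pure_free_water_is_direction_independent(self, scheme):
        p = BiTensorParams(f=1.0, D_tissue=np.diag([1.7e-3, 2e-4, 2e-4]))
        s = bitensor_signal(p, scheme)
        for b, idx in scheme.shells.items():
            assert np.allclose(s[idx], np.exp(-b * p.D_iso), atol=1e-12)

    def test_non_psd_tensor_rejected(self):
        with pytest.raises(ValueError):
            BiTensorParams(f=0.1, D_tissue=np.diag([1e-3, -1e-3, 1e-3]))

    def test_directional_mean_monotone_in_f(self, scheme):
        """d(mean signal)/df has the sign of (water attenuation - tissue mean
        attenuation) at every shell."""
        D = np.diag([1.4e-3, 3e-4, 3e-4])
        fs = np.linspace(0.0, 1.0, 11)
        sig = bitensor_signal_field(fs, np.repeat(D[None], 11, axis=0), scheme)
        for b, idx in scheme.shells.items():
            means = sig[:, idx].mean(axis=1)
            tissue_att = np.exp(
                -b * np.einsum("ni,ij,nj->n", scheme.bvecs[idx], D, scheme.bvecs[idx])
            ).mean()
            water_att = np.exp(-b * 3.0e-3)
            diffs = np.diff(means)
            if water_att > tissue_att:
                assert np.all(diffs > 0)
            else:
                assert np.all(diffs < 0)


class TestRicianNoise:
    def test_infinite_snr_is_identity(self):
        s = np.linspace(0, 1, 50)
        assert np.array_equal(add_rician_noise(s, np.inf, seed=0), s)

    def test_fixed_seed_reproducible(self):
        s = np.random.default_rng(2).uniform(size=100)
        a = add_rician_noise(s, 20.0, seed=9)
        b = add_rician_noise(s, 20.0, seed=9)
        assert np.array_equal(a, b)

    def test_zero_signal_gives_rayleigh_mean(self):
        # E[sqrt(n1²+n2²)] = sigma * sqrt(pi/2)
        n = 100_000
        snr = 25.0
        out = add_rician_noise(np.zeros(n), snr, seed=4)
        expected = (1.0 / snr) * np.sqrt(np.pi / 2.0)
        assert abs(out.mean() - expected) / expected < 0.01


class TestDirections:
    def test_min_pairwise_angle_exceeds_5_degrees_at_90(self):
        d = dispersed_directions(90, seed=3)
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        assert np.degrees(np.arccos(dots.max())) > 5.0

    def test_unit_norm(self):
        d = dispersed_directions(48, seed=1)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)


class TestGeneratePhantom:
    def test_measurement_count_for_training_scheme(self):
        s = make_scheme(shells=(1000.0, 2000.0, 3000.0), dirs_per_shell=90, n_b0=18, seed=0)
        assert len(s) == 3 * 90 + 18

    def test_same_seed_bit_identical(self):
        a = generate_phantom(shape=(4, 4, 4), dirs_per_shell=30, snr=25.0, seed=8)
        b = generate_phantom(shape=(4, 4, 4), dirs_per_shell=30, snr=25.0, seed=8)
        assert np.array_equal(a.signal, b.signal)
        assert np.array_equal(a.truth_f, b.truth_f)

    def test_noiseless_signal_matches_forward_model_of_stored_truth(self, noiseless_phantom):
        ph = noiseless_phantom
        i, j, k = 3, 2, 5
        p = BiTensorParams(
            f=float(ph.truth_f[i, j, k]), D_tissue=ph.truth_tensors[i, j, k],
            D_iso=ph.D_iso, S0=ph.S0,
        )
        assert np.allclose(ph.signal[i, j, k], bitensor_signal(p, ph.scheme), atol=1e-14)

    def test_noiseless_b0_equals_s0(self, noiseless_phantom):
        ph = noiseless_phantom
        assert np.allclose(ph.signal[..., ph.scheme.b0_indices], ph.S0, atol=1e-14)

    def test_explicit_f_field_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            generate_phantom(shape=(2, 2, 2), dirs_per_shell=12,
                             f_field=np.full((2, 2, 2), 1.5), seed=0)

    def test_save_round_trip(self, tmp_path):
        ph = generate_phantom(shape=(3, 3, 3), dirs_per_shell=12, n_b0=2, snr=30.0, seed=5)
        ph.save(tmp_path / "ph")
        import nibabel as nib

        img = nib.load(tmp_path / "ph_dwi.nii.gz")
        assert img.shape == ph.signal.shape
        from freewater.gradients import read_gradients

        s2 = read_gradients(tmp_path / "ph.bval", tmp_path / "ph.bvec")
        assert s2.shell_bvalues == ph.scheme.shell_bvalues
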