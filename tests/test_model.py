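"""Model architecture contracts: shapes, ranges, equivariance, checkpoints."""

import numpy as np
import pytest

from freewater import sh
from freewater.features import N_SH_COEFFS
from freewater.gradients import ShellCode
from freewater.model import (
    ANN,
    SCNN,
    ANNConfig,
    SCNNConfig,
    ShoreFCN,
    build_model,
    load_checkpoint,
)


@pytest.fixture(scope="module")
def scnn():
    m = SCNN(seed=0)
    m.set_training(False)
    return m


@pytest.fixture(scope="module")
def coeffs():
    rng = np.random.default_rng(1)
    return (rng.normal(size=(32, 3, N_SH_COEFFS)) * 0.3).astype(np.float32)


class TestSCNN:
    def test_output_in_unit_interval(self, scnn, coeffs):
        out = scnn.forward(coeffs, ShellCode([1, 1, 1])).data
        assert out.shape == (32,)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_exact_rotation_invariance_of_untrained_net(self, scnn, coeffs):
        """The architecture is invariant by construction: a Wigner rotation
        of the input coefficients leaves predictions unchanged to float32
        precision, trained or not."""
        rng = np.random.default_rng(2)
        R = sh.random_rotation(rng)
        D = sh.sh_rotation_matrix(R, 8).astype(np.float32)
        rotated = np.einsum("ij,bkj->bki", D, coeffs)
        a = scnn.forward(coeffs, ShellCode([1, 1, 1])).data
        b = scnn.forward(rotated, ShellCode([1, 1, 1])).data
        assert np.abs(a - b).max() < 1e-5

    def test_dynamic_kernels_deterministic_per_code(self, scnn):
        k1 = scnn.first_layer_kernels(ShellCode([1, 0, 1]))
        k2 = scnn.first_layer_kernels(ShellCode([1, 0, 1]))
        for a, b in zip(k1, k2):
            assert np.array_equal(a, b)

    def test_all_zero_code_rejected(self):
        with pytest.raises(ValueError):
            ShellCode([0, 0, 0])

    def test_non_finite_features_rejected_with_voxel_index(self, scnn, coeffs):
        bad = coeffs.copy()
        bad[7, 0, 0] = np.nan
        with pytest.raises(ValueError, match="voxel 7"):
            scnn.forward(bad, ShellCode([1, 1, 1]))

    def test_repeated_evaluation_bit_identical(self, scnn, coeffs):
        code = ShellCode([1, 1, 0])
        a = scnn.forward(coeffs, code).data
        b = scnn.forward(coeffs, code).data
        assert np.array_equal(a, b)

    def test_l1_penalty_matches_external_recomputation(self, scnn):
        expected = 0.0
        for name, p in scnn.named_parameters().items():
            if name.startswith("conv.") and ".bn" not in name and "gain" not in name:
                expected += np.abs(p.data).sum()
        expected *= scnn.config.l1_strength
        assert np.isclose(float(scnn.l1_penalty().data), expected, rtol=1e-6)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SCNNConfig(bandlimits=(10, 20, 10, 6, 3, 1))
        with pytest.raises(ValueError):
            SCNNConfig(degree_caps=(8, 8, 10, 6, 2, 2))


class TestBaselines:
    def test_ann_hidden_sizes_follow_input(self):
        cfg = ANNConfig(N_b=96)
        assert cfg.hidden == (48, 24)
        m = ANN(cfg, seed=0)
        assert m.fc[0].W.shape == (96, 48)
        assert m.fc[1].W.shape == (48, 24)
        assert m.fc[2].W.shape == (24, 1)

    def test_ann_output_range_and_length_check(self):
        m = ANN(ANNConfig(N_b=96), seed=0)
        m.set_training(False)
        x = np.random.default_rng(0).uniform(0, 1, size=(10, 96)).astype(np.float32)
        out = m.forward(x).data
        assert out.min() >= 0 and out.max() <= 1
        with pytest.raises(ValueError, match="N_b"):
            m.forward(x[:, :90])

    def test_ann_not_permutation_invariant(self):
        """The raw-signal baseline has no rotation/permutation symmetry."""
        m = ANN(ANNConfig(N_b=96), seed=0)
        m.set_training(False)
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 1.0, size=(5, 96)).astype(np.float32)
        xp = x[:, rng.permutation(96)]
        assert np.abs(m.forward(x).data - m.forward(xp).data).max() > 1e-6

    def test_shore_fcn_architecture_sizes(self):
        m = ShoreFCN(seed=0)
        assert m.fc[0].W.shape == (50, 100)
        assert m.fc[1].W.shape == (100, 50)
        assert m.fc[2].W.shape == (50, 1)


class TestCheckpoints:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path, coeffs):
        m = SCNN(seed=4)
        m.set_training(False)
        code = ShellCode([1, 1, 1])
        before = m.forward(coeffs, code).data
        ckpt = m.checkpoint(training_meta={"note": "unit"})
        ckpt.save(tmp_path / "m.npz")
        loaded = load_checkpoint(tmp_path / "m.npz")
        from freewater.model import _restore

        m2 = _restore(loaded)
        after = m2.forward(coeffs, code).data
        assert np.array_equal(before, after)

    def test_contract_mismatch_refused(self, tmp_path):
        m = ANN(seed=0)
        ckpt = m.checkpoint()
        ckpt.feature_contract = dict(ckpt.feature_contract, max_degree=6)
        ckpt.save(tmp_path / "bad.npz")
        from freewater.model import forward_ann

        with pytest.raises(ValueError, match="contract"):
            forward_ann(np.zeros((1, 96), dtype=np.float32), load_checkpoint(tmp_path / "bad.npz"))

    def test_build_model_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            build_model("transformer")
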