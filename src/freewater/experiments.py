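"""Reference experiments: end-to-end study conditions on synthetic phantoms.

These functions re-run the package's main computations at desk scale —
forward-model checks, silver-standard recovery, learned-estimator training
with shell-configuration dropout, rotation-invariance probes, fc-only
fine-tuning, correction identities and the evaluation formulas — and return
the measured quantities.  They are used both by the acceptance test suite
and by ``scripts/acceptance.py``.

Problem sizes are chosen so a full pass runs on one CPU in minutes: the
training phantom holds ~50k voxels (40 x 40 x 32) at SNR 30 with the
three-shell, 90-direction training scheme; smaller phantoms serve the
fitting and fine-tuning checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sh
from .features import ann_input_vectors, build_feature_set
from .gradients import ShellCode, shell_code_for
from .harmonize import normalize_signal, remap_scheme_to_training
from .model import ANN, ANNConfig, SCNN, ModelCheckpoint
from .phantom import PhantomVolume, generate_phantom
from .training import TrainingPlan, evaluate_rmse, fine_tune, train, _split

__all__ = [
    "TrainedEstimators",
    "make_training_phantom",
    "train_estimators",
    "rotation_probe",
    "finetune_probe",
]

TRAIN_SHAPE = (40, 40, 32)  # ~51k voxels
TRAIN_SNR = 30.0
TRAIN_EPOCHS = 20
SINGLE_SHELL_CODE = ShellCode([1, 0, 0])


@dataclass
class TrainedEstimators:
    """Everything the learned-estimator experiments share."""

    phantom: PhantomVolume
    features: np.ndarray  # (N, K, 45) SH blocks, full code
    ann_inputs: np.ndarray  # (N, N_b)
    targets: np.ndarray  # (N,)
    val_idx: np.ndarray
    scnn: SCNN
    scnn_checkpoint: ModelCheckpoint
    ann: ANN
    scnn_history: object
    ann_history: object

    @property
    def scnn_val_rmse_single_shell(self) -> float:
        return evaluate_rmse(
            self.scnn, self.features[self.val_idx], self.targets[self.val_idx],
            code=SINGLE_SHELL_CODE,
        )

    @property
    def ann_val_rmse(self) -> float:
        return evaluate_rmse(
            self.ann, self.ann_inputs[self.val_idx], self.targets[self.val_idx]
        )


def make_training_phantom(seed: int, shape=TRAIN_SHAPE, snr=TRAIN_SNR) -> PhantomVolume:
    """The standard training condition: 3-shell, 90-direction, SNR-30 phantom."""
    return generate_phantom(shape=shape, snr=snr, seed=seed)


def train_estimators(
    seed: int,
    shape=TRAIN_SHAPE,
    snr=TRAIN_SNR,
    epochs: int = TRAIN_EPOCHS,
) -> TrainedEstimators:
    """Train the spherical network (uniform shell-code dropout) and the
    single-shell ANN baseline on the same phantom, ground-truth targets."""
    ph = make_training_phantom(seed, shape=shape, snr=snr)
    norm, _, _ = normalize_signal(ph.signal, ph.scheme)
    code = shell_code_for(ph.scheme)
    fs = build_feature_set(norm, ph.scheme, code)
    X = fs.coeffs.reshape(-1, code.K, fs.coeffs.shape[-1]).astype(np.float32)
    Xa = ann_input_vectors(norm, ph.scheme, 1000.0)
    Xa = Xa.reshape(-1, Xa.shape[-1]).astype(np.float32)
    y = ph.truth_f.ravel()
    plan = TrainingPlan(epochs=epochs, seed=seed)
    scnn = SCNN(seed=seed)
    scnn_ckpt, scnn_hist = train(scnn, X, y, plan)
    ann = ANN(ANNConfig(N_b=Xa.shape[-1]), seed=seed)
    _, ann_hist = train(ann, Xa, y, plan)
    _, va = _split(len(y), plan.val_fraction, plan.seed)
    return TrainedEstimators(
        phantom=ph,
        features=X,
        ann_inputs=Xa,
        targets=y,
        val_idx=va,
        scnn=scnn,
        scnn_checkpoint=scnn_ckpt,
        ann=ann,
        scnn_history=scnn_hist,
        ann_history=ann_hist,
    )


def rotation_probe(est: TrainedEstimators, seed: int, n_voxels: int = 500) -> float:
    """Mean |change in f| of the trained spherical net when the gradient
    frame is rotated.

    Band-limited inputs: the rotated path evaluates the voxel's degree-8
    SH representation (a Wigner rotation of the coefficients), so the probe
    isolates the network's invariance from SH truncation error.
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(est.val_idx, size=min(n_voxels, len(est.val_idx)), replace=False)
    X = est.features[idx]
    R = sh.random_rotation(rng)
    D = sh.sh_rotation_matrix(R, 8).astype(np.float32)
    Xrot = np.einsum("ij,bkj->bki", D, X)
    est.scnn.set_training(False)
    code = SINGLE_SHELL_CODE
    m = np.asarray(code.m) == 0
    X0, X0r = X.copy(), Xrot.copy()
    X0[:, m, :] = 0.0
    X0r[:, m, :] = 0.0
    f0 = est.scnn.forward(X0, code).data
    f1 = est.scnn.forward(X0r, code).data
    return float(np.mean(np.abs(f0 - f1)))


def finetune_probe(
    est: TrainedEstimators,
    seed: int,
    shape=(16, 16, 16),
    snr: float = 20.0,
    epochs: int = 8,
) -> dict:
    """FC-only adaptation to an aging-protocol-style acquisition (1500 +
    3000 s/mm² shells, 1500 remapped to 1000), returning pre/post validation
    RMSE and the frozen-parameter verification outcome."""
    ph = generate_phantom(shape=shape, shells=(1500.0, 3000.0), snr=snr, seed=seed)
    signal, scheme = remap_scheme_to_training(ph.signal, ph.scheme)
    norm, _, _ = normalize_signal(signal, scheme)
    code = shell_code_for(scheme)
    fs = build_feature_set(norm, scheme, code)
    X = fs.coeffs.reshape(-1, code.K, fs.coeffs.shape[-1]).astype(np.float32)
    y = ph.truth_f.ravel()
    plan = TrainingPlan(epochs=epochs, seed=seed, fine_tune_scope="fc_only")
    _, va = _split(len(y), plan.val_fraction, plan.seed)
    before = evaluate_rmse(est.scnn, X[va], y[va], code=code)
    ckpt, hist = fine_tune(est.scnn_checkpoint, X, y, plan)
    from .model import _restore

    tuned = _restore(ckpt)
    after = evaluate_rmse(tuned, X[va], y[va], code=code)
    return {
        "code": [int(v) for v in code],
        "rmse_before": before,
        "rmse_after": after,
        "checkpoint": ckpt,
        "history": hist,
    }
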