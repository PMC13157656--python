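"""Training and fine-tuning of the fraction estimators.

The training trick that makes one spherical network serve every acquisition
subset is *shell-configuration dropout*: each batch draws a shell code from a
distribution over the 2^K - 1 valid configurations and zeroes the feature
blocks of absent shells before the forward pass, so the network learns to
transfer between the full multi-shell signal and its dropped-out versions.
The criterion is RMSE; the checkpoint returned is the best-validation epoch.

Fine-tuning to a new dataset updates only the fully connected head — every
convolutional parameter, the dynamic head and the normalization gains stay
bit-identical, which is verified by hash comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .gradients import ShellCode
from .model import ANN, SCNN, ModelCheckpoint, ShoreFCN, _restore
from .nn import Adam, Tensor, rmse_loss

__all__ = ["TrainingPlan", "TrainingHistory", "train", "fine_tune", "evaluate_rmse"]


@dataclass
class TrainingPlan:
    """Hyperparameters of one training run (all logged into the checkpoint)."""

    epochs: int = 20
    batch_size: int = 256
    lr: float = 1e-3
    #: cosine-decay the learning rate from ``lr`` to ~0 across the run; the
    #: standard schedule that damps late-training gradient noise.
    lr_schedule: str = "cosine"  # "cosine" | "constant"
    #: stochastic weight averaging: average the last ``swa_window`` epochs'
    #: weights, recalibrate normalization statistics, and adopt the average
    #: only if it validates better than the best single epoch.  Damps the
    #: epoch-to-epoch oscillation that configuration dropout induces.
    #: 0 disables.
    swa_window: int = 5
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 10
    loss: str = "rmse"
    #: probabilities over ShellCode.all_valid(K); None = uniform.  Only the
    #: spherical network consumes shell codes.
    config_sampler: np.ndarray | None = None
    fine_tune_scope: str = "all"  # "all" | "fc_only"

    def __post_init__(self) -> None:
        if self.loss != "rmse":
            raise ValueError("RMSE is the training criterion")
        if self.fine_tune_scope not in ("all", "fc_only"):
            raise ValueError("fine_tune_scope must be 'all' or 'fc_only'")
        if self.config_sampler is not None:
            p = np.asarray(self.config_sampler, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("config_sampler must be a probability vector")
            self.config_sampler = p


@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.epochs).to_csv(path, index=False)

    @property
    def best(self) -> dict:
        return min(self.epochs, key=lambda e: e["val_rmse"])


def _split(n: int, val_fraction: float, seed: int, group_size: int = 64):
    """Disjoint train/validation split over voxel groups (contiguous blocks
    of voxels stay together so spatially correlated neighbours do not leak)."""
    rng = np.random.default_rng(seed)
    n_groups = max(int(np.ceil(n / group_size)), 2)
    groups = rng.permutation(n_groups)
    n_val = max(int(round(val_fraction * n_groups)), 1)
    if n_val >= n_groups:
        raise ValueError("empty training split")
    val_groups = set(groups[:n_val].tolist())
    idx = np.arange(n)
    in_val = np.isin(idx // group_size, list(val_groups))
    return idx[~in_val], idx[in_val]


def _apply_code(x: np.ndarray, code: ShellCode) -> np.ndarray:
    """Zero the feature blocks of absent shells (SCNN inputs only)."""
    out = x.copy()
    out[:, np.asarray(code.m) == 0, :] = 0.0
    return out


def evaluate_rmse(model, inputs: np.ndarray, targets: np.ndarray,
                  code: ShellCode | None = None, batch: int = 8192) -> float:
    """Deterministic eval-mode RMSE of a model on (inputs, targets)."""
    model.set_training(False)
    preds = []
    for i in range(0, len(inputs), batch):
        xb = inputs[i : i + batch]
        if isinstance(model, SCNN):
            xb = _apply_code(xb, code) if code is not None else xb
            preds.append(model.forward(xb, code or ShellCode(np.ones(model.config.K, int))).data)
        else:
            preds.append(model.forward(xb).data)
    p = np.concatenate(preds)
    return float(np.sqrt(np.mean((p - np.asarray(targets, dtype=np.float64).ravel()) ** 2)))


def _val_rmse(model, x_val, y_val, codes) -> float:
    """Validation RMSE; for the spherical net, averaged over the code support."""
    if isinstance(model, SCNN):
        return float(np.mean([evaluate_rmse(model, x_val, y_val, code=c) for c in codes]))
    return evaluate_rmse(model, x_val, y_val)


def train(
    model,
    inputs: np.ndarray,
    targets: np.ndarray,
    plan: TrainingPlan,
    trainable: set[str] | None = None,
    initial_best: bool = False,
) -> tuple[ModelCheckpoint, TrainingHistory]:
    """Fit ``model`` to (inputs, targets) under ``plan``.

    ``inputs`` is (N, K, 45) SH blocks for the spherical network, (N, N_b)
    signal vectors for the ANN, (N, 50) coefficients for the SHORE net;
    ``targets`` are fractions in [0, 1].  Returns the best-validation-epoch
    checkpoint and the per-epoch history.

    ``trainable`` restricts optimization to the named parameter subset (used
    by :func:`fine_tune`); ``initial_best`` seeds the best checkpoint with
    the untrained model's validation score, so the result can only improve.
    """
    targets = np.asarray(targets, dtype=np.float32).ravel()
    if targets.min() < 0 or targets.max() > 1:
        raise ValueError("targets must lie in [0, 1]")
    n = len(targets)
    tr_idx, va_idx = _split(n, plan.val_fraction, plan.seed)
    if len(va_idx) == 0:
        raise ValueError("empty validation split")
    rng = np.random.default_rng(plan.seed + 1)

    is_scnn = isinstance(model, SCNN)
    codes = ShellCode.all_valid(model.config.K) if is_scnn else []
    probs = plan.config_sampler
    if is_scnn and probs is None:
        probs = np.full(len(codes), 1.0 / len(codes))
    if is_scnn and len(probs) != len(codes):
        raise ValueError(f"config_sampler must have length {len(codes)}")

    named = model.named_parameters()
    if trainable is None:
        params = list(named.values())
    else:
        unknown = trainable - set(named)
        if unknown:
            raise ValueError(f"unknown trainable parameters {unknown}")
        params = [p for name, p in named.items() if name in trainable]
    opt = Adam(params, lr=plan.lr)

    history = TrainingHistory()
    recent_states: list[dict] = []
    x_val, y_val = inputs[va_idx], targets[va_idx]
    best_rmse, best_state, best_epoch = np.inf, None, -1
    if initial_best:
        best_rmse = _val_rmse(model, x_val, y_val, codes)
        best_state = model.state_dict()
        best_epoch = 0
    stale = 0
    for epoch in range(plan.epochs):
        # fc-only runs keep normalization/dropout in eval mode so frozen
        # running statistics stay bit-identical
        model.set_training(trainable is None)
        if plan.lr_schedule == "cosine":
            opt.lr = plan.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(plan.epochs, 1)))
        order = rng.permutation(tr_idx)
        epoch_losses = []
        code_hist = np.zeros(max(len(codes), 1), dtype=int)
        for start in range(0, len(order), plan.batch_size):
            sel = order[start : start + plan.batch_size]
            xb, yb = inputs[sel], targets[sel]
            if is_scnn:
                ci = rng.choice(len(codes), p=probs)
                code_hist[ci] += 1
                code = codes[ci]
                out = model.forward(_apply_code(xb, code), code)
            else:
                out = model.forward(xb)
            loss = rmse_loss(out, yb) + model.l1_penalty()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // plan.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val = _val_rmse(model, x_val, y_val, codes)
        history.epochs.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_rmse": val,
                "code_histogram": code_hist.tolist(),
            }
        )
        if plan.swa_window > 1:
            recent_states.append(model.state_dict())
            if len(recent_states) > plan.swa_window:
                recent_states.pop(0)
        if val < best_rmse:
            best_rmse, best_state, best_epoch = val, model.state_dict(), epoch
            stale = 0
        else:
            stale += 1
            if stale > plan.patience:
                break

    # stochastic weight averaging over the trailing epochs: average the
    # trainable parameters, recompute normalization statistics exactly on a
    # reference batch, and keep the average only if it validates better
    best_is_swa = False
    if plan.swa_window > 1 and len(recent_states) >= 2 and best_state is not None:
        avg = {}
        for key in recent_states[-1]:
            vals = [st[key] for st in recent_states]
            if key.startswith("__buf__") or (trainable is not None and key not in trainable):
                avg[key] = recent_states[-1][key]
            else:
                avg[key] = np.mean(vals, axis=0).astype(vals[-1].dtype)
        model.load_state_dict(avg)
        if trainable is None:  # fc-only runs must keep frozen statistics
            calib = inputs[tr_idx[: min(8192, len(tr_idx))]]
            if is_scnn:
                model.recalibrate_norms(calib, codes)
            elif hasattr(model, "recalibrate_norms"):
                model.recalibrate_norms(calib)
        val_swa = _val_rmse(model, x_val, y_val, codes)
        if val_swa < best_rmse:
            best_rmse, best_state, best_is_swa = val_swa, model.state_dict(), True
            best_epoch = len(history.epochs) - 1
    if best_state is not None:
        model.load_state_dict(best_state)
    model.set_training(False)
    meta = {
        "best_epoch": best_epoch,
        "swa": best_is_swa,
        "best_val_rmse": float(best_rmse),
        "seed": plan.seed,
        "epochs_run": len(history.epochs),
        "plan": {
            "epochs": plan.epochs,
            "batch_size": plan.batch_size,
            "lr": plan.lr,
            "val_fraction": plan.val_fraction,
            "fine_tune_scope": plan.fine_tune_scope,
        },
    }
    return model.checkpoint(training_meta=meta), history


def _hash_params(model, names: set[str]) -> dict[str, str]:
    return {
        n: hashlib.sha256(p.data.tobytes()).hexdigest()
        for n, p in model.named_parameters().items()
        if n in names
    }


def fine_tune(
    checkpoint: ModelCheckpoint,
    inputs: np.ndarray,
    targets: np.ndarray,
    plan: TrainingPlan,
) -> tuple[ModelCheckpoint, TrainingHistory]:
    """Adapt a trained model to a new dataset, updating the FC head only.

    Every non-FC parameter (convolutions, dynamic head, normalization gains)
    is verified bit-identical before vs after by SHA-256 comparison; a
    mismatch is a hard failure.  The returned checkpoint is the best of the
    initial model and every fine-tuning epoch, so validation RMSE on the
    adaptation set never increases.
    """
    if plan.fine_tune_scope != "fc_only":
        raise ValueError("fine_tune requires plan.fine_tune_scope == 'fc_only'")
    model = _restore(checkpoint)
    fc_names = model.fc_parameter_names()
    frozen = set(model.named_parameters()) - fc_names
    before = _hash_params(model, frozen)
    ckpt, history = train(
        model, inputs, targets, plan, trainable=fc_names, initial_best=True
    )
    after = _hash_params(model, frozen)
    if before != after:
        changed = [n for n in before if before[n] != after[n]]
        raise RuntimeError(f"fine-tuning scope violation: {changed} changed")
    ckpt.training_meta["fine_tuned_from"] = checkpoint.training_meta.get("seed")
    ckpt.training_meta["frozen_hashes"] = sorted(after.values())
    return ckpt, history
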