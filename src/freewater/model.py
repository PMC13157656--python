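"""Free-water-fraction regressors.

Three estimators map a voxel's diffusion signal to the free-water volume
fraction f in [0, 1]:

* :class:`SCNN` — the proposed estimator: a rotation-invariant spherical
  network whose first convolution is *generated by a dynamic head* from the
  K-bit shell-availability code, so one model serves every subset of the
  training shells.  Per-shell SH blocks enter as K channels of one spherical
  signal.  The S² layer (dynamic), the SO(3) layer and the restricted
  generalized convolutions are per-degree channel-mixing linear maps — the
  coefficient-space form of group convolution, exactly equivariant.  The
  three channel-wise tensor-product activations square the signal pointwise
  on an exact quadrature grid and re-project, which realizes the tensor
  product of the representation with itself (also exactly equivariant).
  Fragments are batch-normalized by their average norm only, never
  translated.  Resolution decreases down the bandlimit schedule
  (20, 10, 10, 6, 3, 1) while channels grow (20, 22, 24, 26, 28); with a
  degree-8 even input the effective even-degree caps are 8, 8, 10, 6, 2, 0.
  The final convolution keeps only degree 0 — a rotation-invariant feature
  vector — which a small fully connected head turns into f.

* :class:`ANN` — 4-layer fully connected baseline on the raw normalized
  measurement vector (input N_b, hidden N_b/2 and N_b/4, one output), with
  dropout and batch normalization.  No rotation invariance by construction.

* :class:`ShoreFCN` — 4-layer fully connected baseline on the 50 order-6
  SHORE coefficients (50 -> 100 -> 50 -> 1).

All three are pure functions of (input, checkpoint) at evaluation time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import sh
from .features import MAX_SH_DEGREE, N_SH_COEFFS, ShellFeatureSet, ShoreFeatures, SHORE_N_COEFFS
from .gradients import ShellCode
from .nn import BatchNorm1d, Dropout, Linear, Module, Parameter, Tensor, make_node

__all__ = [
    "SCNNConfig",
    "ANNConfig",
    "ShoreFCNConfig",
    "ModelCheckpoint",
    "SCNN",
    "ANN",
    "ShoreFCN",
    "build_model",
    "load_checkpoint",
    "forward_scnn",
    "forward_ann",
    "forward_shore_fcn",
    "dynamic_first_layer",
    "FEATURE_CONTRACT",
]

#: Basis/normalization contract a checkpoint must match to be loaded.
FEATURE_CONTRACT = {
    "basis": "real-even-sh",
    "max_degree": MAX_SH_DEGREE,
    "n_coeffs": N_SH_COEFFS,
    "normalization": "mean-b0, clip [1e-6, 1.5]",
}

CHECKPOINT_VERSION = 1


@dataclass
class SCNNConfig:
    """Architecture constants of the spherical network."""

    bandlimits: tuple[int, ...] = (20, 10, 10, 6, 3, 1)
    channels: tuple[int, ...] = (1, 20, 22, 24, 26, 28)
    l1_strength: float = 1e-5
    K: int = 3
    fc_sizes: tuple[int, ...] = (64, 32, 1)
    # effective even-degree caps of each stage given the degree-8 input
    degree_caps: tuple[int, ...] = (8, 8, 10, 6, 2, 0)

    def __post_init__(self) -> None:
        if list(self.bandlimits) != sorted(self.bandlimits, reverse=True):
            raise ValueError("bandlimits must be non-increasing")
        if list(self.channels[1:]) != sorted(self.channels[1:]):
            raise ValueError("channels must be non-decreasing")
        if self.degree_caps[-1] != 0:
            raise ValueError("final representation must be degree-0 (invariant)")


@dataclass
class ANNConfig:
    N_b: int = 96

    @property
    def hidden(self) -> tuple[int, int]:
        return (self.N_b // 2, self.N_b // 4)


@dataclass
class ShoreFCNConfig:
    n_in: int = SHORE_N_COEFFS
    hidden: tuple[int, int] = (100, 50)


@dataclass
class ModelCheckpoint:
    """Weights + config + contracts, serialized as one .npz archive."""

    kind: str
    weights: dict[str, np.ndarray]
    config: dict
    feature_contract: dict = field(default_factory=lambda: dict(FEATURE_CONTRACT))
    training_meta: dict = field(default_factory=dict)
    version: int = CHECKPOINT_VERSION

    def save(self, path: str | Path) -> None:
        meta = {
            "kind": self.kind,
            "config": self.config,
            "feature_contract": self.feature_contract,
            "training_meta": self.training_meta,
            "version": self.version,
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **self.weights)


def load_checkpoint(path: str | Path) -> ModelCheckpoint:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        weights = {k: z[k] for k in z.files if k != "__meta__"}
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
    return ModelCheckpoint(
        kind=meta["kind"],
        weights=weights,
        config=meta["config"],
        feature_contract=meta["feature_contract"],
        training_meta=meta.get("training_meta", {}),
        version=meta["version"],
    )


def _check_contract(contract: dict) -> None:
    if contract != FEATURE_CONTRACT:
        raise ValueError(
            f"feature contract mismatch: checkpoint {contract} vs package {FEATURE_CONTRACT}"
        )


# --------------------------------------------------------------------------
# Equivariant building blocks
# --------------------------------------------------------------------------


def code_index(code: ShellCode) -> int:
    """Stable index of a shell code among the 2^K − 1 valid configurations."""
    bits = sum(int(m) << k for k, m in enumerate(code.m))
    return bits - 1


def _equivariant_mix(x: Tensor, W: Tensor, counts: np.ndarray, offsets: np.ndarray) -> Tensor:
    """out[b, o, i] = sum_c W[deg(i), o, c] * x[b, c, i] for kept coefficients.

    ``W`` is (n_degrees, c_out, c_in), one mixing matrix per even degree
    shared across orders m (Schur's lemma form of group convolution);
    ``counts``/``offsets`` give the 2l+1 block layout.  The input may carry
    more degrees than are kept; trailing blocks are dropped.
    """
    n = int(counts.sum())
    Wexp = np.repeat(W.data, counts, axis=0)  # (n, c_out, c_in)
    xd = x.data[:, :, :n]
    out = np.einsum("ioc,bci->boi", Wexp, xd)

    def backward(g):
        gx = gW = None
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, :, :n] = np.einsum("ioc,boi->bci", Wexp, g)
        if W.requires_grad:
            t = np.einsum("boi,bci->ioc", g, xd)
            gW = np.add.reduceat(t, offsets, axis=0)
        return (gx, gW)

    return make_node(out, (x, W), backward)


class EquivariantLinear(Module):
    """Per-degree channel mixing: the coefficient-space group convolution.

    For each even degree l <= cap, out[b, o, lm] = sum_c W_l[o, c] x[b, c, lm]
    (one weight matrix per degree, shared across orders m), plus a bias on
    the degree-0 block.  Commutes with rotations by Schur's lemma.
    """

    def __init__(self, c_in: int, c_out: int, deg_in: int, deg_out: int,
                 rng: np.random.Generator):
        super().__init__()
        self.deg_in, self.deg_out = deg_in, deg_out
        self.degrees = sh.even_degrees(min(deg_in, deg_out))
        self.counts = np.array([2 * l + 1 for l in self.degrees])
        self.offsets = np.concatenate([[0], np.cumsum(self.counts)[:-1]])
        self.W = Parameter(
            rng.standard_normal((len(self.degrees), c_out, c_in)) / np.sqrt(c_in)
        )
        self.bias = Parameter(np.zeros(c_out))
        e0 = np.zeros(int(self.counts.sum()), dtype=np.float32)
        e0[0] = 1.0
        self._e0 = Tensor(e0.reshape(1, 1, -1))

    def __call__(self, x: Tensor, scale: Tensor | None = None) -> Tensor:
        W = self.W if scale is None else self.W * scale
        out = _equivariant_mix(x, W, self.counts, self.offsets)
        return out + self.bias.reshape(1, -1, 1) * self._e0

    def named(self, prefix: str) -> dict[str, Parameter]:
        return {f"{prefix}.W": self.W, f"{prefix}.bias": self.bias}


class TensorProductActivation(Module):
    """Channel-wise tensor-product nonlinearity g -> g + g² on the sphere.

    The feature is synthesized on a Gauss-Legendre x uniform grid whose
    quadrature is exact to degree 2*deg_in + deg_out, squared pointwise
    (the channel-wise tensor product of the representation with itself,
    projected to degrees <= deg_out) with the linear term kept so sign
    information survives.  Exactness of the quadrature makes the layer
    exactly rotation-equivariant.
    """

    def __init__(self, deg_in: int, deg_out: int):
        super().__init__()
        self.deg_in, self.deg_out = deg_in, deg_out
        pts, wts = sh.quadrature_grid(2 * deg_in + deg_out)
        E_in = sh.sh_basis(pts, deg_in)  # (M, n_in)
        E_out = sh.sh_basis(pts, deg_out)
        self.synth = Tensor(E_in.T)  # (n_in, M)
        self.project = Tensor(wts[:, None] * E_out)  # (M, n_out)

    def __call__(self, x: Tensor) -> Tensor:
        b, c, n = x.shape
        g = x.reshape(b * c, n) @ self.synth
        out = g.poly_quadratic() @ self.project
        return out.reshape(b, c, out.shape[-1])


class RestrictedBatchNorm(Module):
    """Fragment normalization that scales and never translates.

    Each (channel, degree) fragment is divided by the running batch average
    of its norm and multiplied by a learned positive gain — a pure scaling,
    so equivariance is preserved.  Running statistics are kept *per shell
    code*: zeroed input channels shrink fragment norms by a code-dependent
    factor, and conditioning the normalization on the code removes that
    systematic scale shift between configurations.
    """

    def __init__(self, channels: int, max_degree: int, n_codes: int = 7,
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.degrees = sh.even_degrees(max_degree)
        self.counts = np.array([2 * l + 1 for l in self.degrees])
        self.offsets = np.concatenate([[0], np.cumsum(self.counts)[:-1]])
        self.gain = Parameter(np.ones((channels, len(self.degrees))))
        self.running = np.ones((n_codes, channels, len(self.degrees)), dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, code_idx: int = 0) -> Tensor:
        if self.training:
            sq = np.add.reduceat(x.data**2, self.offsets, axis=2)  # (B, C, ndeg)
            norm = np.sqrt(sq).mean(axis=0)
            self.running[code_idx] = (
                (1 - self.momentum) * self.running[code_idx] + self.momentum * norm
            )
        gain, eps = self.gain, self.eps
        counts, offsets = self.counts, self.offsets
        denom = (self.running[code_idx] + eps).astype(np.float32)
        sexp = np.repeat(gain.data / denom, counts, axis=1)[None]  # (1, C, ncoef)
        out = x.data * sexp

        def backward(g):
            gx = g * sexp if x.requires_grad else None
            gg = None
            if gain.requires_grad:
                t = (g * x.data).sum(axis=0)  # (C, ncoef)
                gg = np.add.reduceat(t, offsets, axis=1) / denom
            return (gx, gg)

        return make_node(out, (x, gain), backward)

    def named(self, prefix: str) -> dict[str, Parameter]:
        return {f"{prefix}.gain": self.gain}


class DynamicHead(Module):
    """Two-layer perceptron from the K-bit shell code to a multiplicative
    scaling of the base S² kernel (the feature-scaling-matrix reading of the
    dynamic head).  Zero-initialized output => scaling exactly 1 at init;
    identical codes always yield identical kernels."""

    def __init__(self, K: int, c_out: int, c_in: int, rng: np.random.Generator,
                 hidden: int = 16):
        super().__init__()
        self.c_out, self.c_in = c_out, c_in
        self.W1 = Parameter(rng.standard_normal((K, hidden)) / np.sqrt(K))
        self.b1 = Parameter(np.zeros(hidden))
        self.W2 = Parameter(np.zeros((hidden, c_out * c_in)))
        self.b2 = Parameter(np.zeros(c_out * c_in))

    def __call__(self, code: np.ndarray) -> Tensor:
        h = (Tensor(code.reshape(1, -1)) @ self.W1 + self.b1).relu()
        s = (h @ self.W2 + self.b2).sigmoid() * 2.0
        return s.reshape(self.c_out, self.c_in)

    def named(self, prefix: str) -> dict[str, Parameter]:
        return {f"{prefix}.{n}": getattr(self, n) for n in ("W1", "b1", "W2", "b2")}


# --------------------------------------------------------------------------
# The three estimators
# --------------------------------------------------------------------------


class _BaseModel(Module):
    kind = "base"

    def named_parameters(self) -> dict[str, Parameter]:  # pragma: no cover - abstract
        raise NotImplementedError

    def fc_parameter_names(self) -> set[str]:
        return {n for n in self.named_parameters() if n.startswith("fc")}

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {n: p.data.copy() for n, p in self.named_parameters().items()}
        for n, buf in self.buffers().items():
            out[f"__buf__{n}"] = buf.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        bufs = self.buffers()
        for n, v in state.items():
            if n.startswith("__buf__"):
                bufs[n[len("__buf__"):]][...] = v
            else:
                params[n].data = np.asarray(v, dtype=np.float32)

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def checkpoint(self, training_meta: dict | None = None) -> ModelCheckpoint:
        return ModelCheckpoint(
            kind=self.kind,
            weights=self.state_dict(),
            config=asdict(self.config),
            training_meta=training_meta or {},
        )


class SCNN(_BaseModel):
    """Dynamic-head rotation-invariant spherical network (the proposed model)."""

    kind = "scnn"

    def __init__(self, config: SCNNConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or SCNNConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        K = cfg.K
        c = cfg.channels
        d = cfg.degree_caps
        # dynamic first (S²) layer: base kernel + code-conditioned scaling
        self.s2 = EquivariantLinear(K, c[1], MAX_SH_DEGREE, d[0], rng)
        self.head = DynamicHead(K, c[1], K, rng)
        self.so3 = EquivariantLinear(c[1], c[2], d[0], d[1], rng)
        self.bn0 = RestrictedBatchNorm(c[2], min(d[0], d[1]))
        self.act1 = TensorProductActivation(min(d[0], d[1]), d[2])
        self.rgc1 = EquivariantLinear(c[2], c[3], d[2], d[3], rng)
        self.bn1 = RestrictedBatchNorm(c[3], min(d[2], d[3]))
        self.act2 = TensorProductActivation(min(d[2], d[3]), d[3])
        self.rgc2 = EquivariantLinear(c[3], c[4], d[3], d[4], rng)
        self.bn2 = RestrictedBatchNorm(c[4], min(d[3], d[4]))
        self.act3 = TensorProductActivation(min(d[3], d[4]), d[4])
        self.rgc_final = EquivariantLinear(c[4], c[5], d[4], 0, rng)
        fc_rng = np.random.default_rng(seed + 1)
        # the FC head consumes the concatenated rotation-invariant (degree-0)
        # fragments of every stage — including the K per-shell input means,
        # the most fraction-informative invariant — not just the final
        # convolution's output
        n_invariant = K + c[2] + c[3] + c[4] + c[5]
        sizes = (n_invariant,) + tuple(cfg.fc_sizes)
        self.fc = [Linear(sizes[i], sizes[i + 1], fc_rng) for i in range(len(sizes) - 1)]

    # -- forward ------------------------------------------------------------
    def first_layer_kernels(self, code: ShellCode) -> list[np.ndarray]:
        """Materialized per-degree kernels of the dynamically generated first
        layer for a given shell code (deterministic in the code)."""
        scale = self.head(np.asarray(code.m, dtype=np.float32)).data
        return [w * scale for w in self.s2.W.data]

    def forward(self, coeffs: np.ndarray | Tensor, code: ShellCode) -> Tensor:
        """(B, K, 45) SH blocks + shell code -> (B,) fraction estimates."""
        x = coeffs if isinstance(coeffs, Tensor) else Tensor(coeffs)
        if not np.isfinite(x.data).all():
            bad = int(np.where(~np.isfinite(x.data).reshape(x.shape[0], -1).all(axis=1))[0][0])
            raise ValueError(f"non-finite features at voxel {bad}")
        scale = self.head(np.asarray(code.m, dtype=np.float32))
        ci = code_index(code)
        h = self.s2(x, scale=scale)
        h0 = self.bn0(self.so3(h), code_idx=ci)
        h1 = self.bn1(self.rgc1(self.act1(h0)), code_idx=ci)
        h2 = self.bn2(self.rgc2(self.act2(h1)), code_idx=ci)
        h3 = self.rgc_final(self.act3(h2))  # (B, C, 1) degree-0 only
        # concatenate every stage's invariant (degree-0) fragments
        inv = Tensor.concat([t[:, :, 0] for t in (x, h0, h1, h2, h3)], axis=1)
        for layer in self.fc[:-1]:
            inv = layer(inv).relu()
        return self.fc[-1](inv).sigmoid().reshape(-1)

    def predict(self, features: ShellFeatureSet, batch: int = 4096) -> np.ndarray:
        """Evaluate on a feature field of any leading shape."""
        _check = features.coeffs.reshape(-1, features.code.K, N_SH_COEFFS)
        self.set_training(False)
        out = np.empty(_check.shape[0], dtype=np.float32)
        for i in range(0, _check.shape[0], batch):
            out[i : i + batch] = self.forward(_check[i : i + batch], features.code).data
        return out.reshape(features.coeffs.shape[:-2])

    # -- bookkeeping ---------------------------------------------------------
    def named_parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        out.update(self.s2.named("conv.s2"))
        out.update(self.head.named("conv.head"))
        out.update(self.so3.named("conv.so3"))
        out.update(self.rgc1.named("conv.rgc1"))
        out.update(self.rgc2.named("conv.rgc2"))
        out.update(self.rgc_final.named("conv.rgc_final"))
        out.update(self.bn0.named("conv.bn0"))
        out.update(self.bn1.named("conv.bn1"))
        out.update(self.bn2.named("conv.bn2"))
        for i, layer in enumerate(self.fc):
            out[f"fc.{i}.W"] = layer.W
            out[f"fc.{i}.b"] = layer.b
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"bn{i}.running": bn.running for i, bn in enumerate((self.bn0, self.bn1, self.bn2))}

    def recalibrate_norms(self, coeffs: np.ndarray, codes: list[ShellCode]) -> None:
        """Recompute the per-code fragment-norm statistics exactly on a
        reference batch (used after weight averaging, whose activations
        differ in scale from any single epoch's)."""
        bns = (self.bn0, self.bn1, self.bn2)
        saved = [(bn.momentum, bn.training) for bn in bns]
        for bn in bns:
            bn.momentum, bn.training = 1.0, True
        try:
            for code in codes:
                xb = coeffs.copy()
                xb[:, np.asarray(code.m) == 0, :] = 0.0
                self.forward(xb, code)
        finally:
            for bn, (mom, tr) in zip(bns, saved):
                bn.momentum, bn.training = mom, tr

    def l1_penalty(self) -> Tensor:
        """l1_strength * sum |w| over convolution weights only (not the FC head
        and not the normalization gains)."""
        total = Tensor(np.zeros(()))
        for name, p in self.named_parameters().items():
            if name.startswith("conv.") and ".bn" not in name and "gain" not in name:
                total = total + p.abs().sum()
        return total * self.config.l1_strength


class ANN(_BaseModel):
    """4-layer fully connected baseline on the raw measurement vector."""

    kind = "ann"

    def __init__(self, config: ANNConfig | None = None, seed: int = 0,
                 dropout: float = 0.1):
        super().__init__()
        self.config = config or ANNConfig()
        rng = np.random.default_rng(seed)
        h1, h2 = self.config.hidden
        self.fc = [
            Linear(self.config.N_b, h1, rng),
            Linear(h1, h2, rng),
            Linear(h2, 1, rng),
        ]
        self.bns = [BatchNorm1d(h1), BatchNorm1d(h2)]
        self.drops = [Dropout(dropout, rng), Dropout(dropout, rng)]

    def forward(self, x: np.ndarray | Tensor, code: ShellCode | None = None) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] != self.config.N_b:
            raise ValueError(f"input length {x.shape[-1]} != N_b {self.config.N_b}")
        h = x
        for lin, bn, drop in zip(self.fc[:-1], self.bns, self.drops):
            h = drop(bn(lin(h)).relu())
        return self.fc[-1](h).sigmoid().reshape(-1)

    def predict(self, signals: np.ndarray, batch: int = 8192) -> np.ndarray:
        self.set_training(False)
        flat = signals.reshape(-1, signals.shape[-1])
        out = np.empty(flat.shape[0], dtype=np.float32)
        for i in range(0, flat.shape[0], batch):
            out[i : i + batch] = self.forward(flat[i : i + batch]).data
        return out.reshape(signals.shape[:-1])

    def recalibrate_norms(self, inputs: np.ndarray, codes=None) -> None:
        """Recompute batch-norm statistics exactly on a reference batch."""
        saved = [(bn.momentum, bn.training) for bn in self.bns]
        for bn in self.bns:
            bn.momentum, bn.training = 1.0, True
        drop_states = [d.training for d in self.drops]
        for d in self.drops:
            d.training = False
        try:
            self.forward(inputs)
        finally:
            for bn, (mom, tr) in zip(self.bns, saved):
                bn.momentum, bn.training = mom, tr
            for d, st in zip(self.drops, drop_states):
                d.training = st

    def named_parameters(self) -> dict[str, Parameter]:
        out = {}
        for i, layer in enumerate(self.fc):
            out[f"fc.{i}.W"] = layer.W
            out[f"fc.{i}.b"] = layer.b
        for i, bn in enumerate(self.bns):
            out[f"fc.bn{i}.gamma"] = bn.gamma
            out[f"fc.bn{i}.beta"] = bn.beta
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for i, bn in enumerate(self.bns):
            out[f"bn{i}.mean"] = bn.running_mean
            out[f"bn{i}.var"] = bn.running_var
        return out

    def l1_penalty(self) -> Tensor:
        return Tensor(np.zeros(()))


class ShoreFCN(_BaseModel):
    """4-layer fully connected baseline on order-6 SHORE coefficients."""

    kind = "shore_fcn"

    def __init__(self, config: ShoreFCNConfig | None = None, seed: int = 0,
                 dropout: float = 0.1):
        super().__init__()
        self.config = config or ShoreFCNConfig()
        rng = np.random.default_rng(seed)
        h1, h2 = self.config.hidden
        self.fc = [
            Linear(self.config.n_in, h1, rng),
            Linear(h1, h2, rng),
            Linear(h2, 1, rng),
        ]
        self.bns = [BatchNorm1d(h1), BatchNorm1d(h2)]
        self.drops = [Dropout(dropout, rng), Dropout(dropout, rng)]

    def forward(self, x: np.ndarray | Tensor, code: ShellCode | None = None) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] != self.config.n_in:
            raise ValueError(f"input length {x.shape[-1]} != {self.config.n_in}")
        h = x
        for lin, bn, drop in zip(self.fc[:-1], self.bns, self.drops):
            h = drop(bn(lin(h)).relu())
        return self.fc[-1](h).sigmoid().reshape(-1)

    def predict(self, coeffs: np.ndarray, batch: int = 8192) -> np.ndarray:
        self.set_training(False)
        flat = coeffs.reshape(-1, coeffs.shape[-1])
        out = np.empty(flat.shape[0], dtype=np.float32)
        for i in range(0, flat.shape[0], batch):
            out[i : i + batch] = self.forward(flat[i : i + batch]).data
        return out.reshape(coeffs.shape[:-1])

    named_parameters = ANN.named_parameters
    buffers = ANN.buffers
    l1_penalty = ANN.l1_penalty
    recalibrate_norms = ANN.recalibrate_norms


_MODEL_CLASSES = {"scnn": SCNN, "ann": ANN, "shore_fcn": ShoreFCN}
_CONFIG_CLASSES = {"scnn": SCNNConfig, "ann": ANNConfig, "shore_fcn": ShoreFCNConfig}


def build_model(kind: str, config=None, seed: int = 0):
    if kind not in _MODEL_CLASSES:
        raise ValueError(f"unknown model kind {kind!r}")
    return _MODEL_CLASSES[kind](config, seed=seed)


def _restore(checkpoint: ModelCheckpoint):
    _check_contract(checkpoint.feature_contract)
    cfg_cls = _CONFIG_CLASSES[checkpoint.kind]
    cfg = checkpoint.config.copy()
    for key, val in cfg.items():
        if isinstance(val, list):
            cfg[key] = tuple(val)
    model = _MODEL_CLASSES[checkpoint.kind](cfg_cls(**cfg))
    model.load_state_dict(checkpoint.weights)
    model.set_training(False)
    return model


def dynamic_first_layer(code: ShellCode, checkpoint: ModelCheckpoint) -> list[np.ndarray]:
    """Per-degree kernels the dynamic head generates for ``code``."""
    model = _restore(checkpoint)
    if not isinstance(model, SCNN):
        raise ValueError("dynamic first layer is defined for the spherical network")
    return model.first_layer_kernels(code)


def forward_scnn(features: ShellFeatureSet, checkpoint: ModelCheckpoint) -> np.ndarray:
    """Fraction estimates from SH feature blocks via a trained spherical net."""
    model = _restore(checkpoint)
    return model.predict(features)


def forward_ann(signal_vectors: np.ndarray, checkpoint: ModelCheckpoint) -> np.ndarray:
    model = _restore(checkpoint)
    return model.predict(np.asarray(signal_vectors, dtype=np.float32))


def forward_shore_fcn(features: ShoreFeatures, checkpoint: ModelCheckpoint) -> np.ndarray:
    model = _restore(checkpoint)
    return model.predict(np.asarray(features.coeffs, dtype=np.float32))
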