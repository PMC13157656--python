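"""Diffusion tensor and two-compartment (free-water DTI) model fitting.

Two fits live here:

* :func:`fit_dti` — classical single-tensor fit by two-pass weighted least
  squares on the log signal, yielding the tensor, its eigenvalues and the
  FA/MD scalar metrics.
* :func:`fit_fwdti` — per-voxel nonlinear least squares of the bi-tensor
  model over (f, D_tissue) with the free-water diffusivity fixed, used on
  multi-shell data to produce the *silver standard* fraction maps that the
  learned estimators are trained against.  The tissue tensor is parameterized
  through its Cholesky factor so positive semi-definiteness is preserved, and
  f is box-constrained to [0, 1].

A mean-diffusivity regularization is applied after fitting: voxels whose
plain-DTI MD exceeds 2.7e-3 mm²/s (approximately the free-water diffusivity)
are treated as pure free water — f is set to 1 and the tissue tensor to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .gradients import GradientScheme
from .phantom import FREE_WATER_DIFFUSIVITY

__all__ = [
    "DTIMetrics",
    "FreeWaterMap",
    "MD_THRESHOLD",
    "FLAG_SKIPPED",
    "FLAG_CONVERGED",
    "FLAG_THRESHOLDED",
    "FLAG_FAILED",
    "IllPosedError",
    "fit_dti",
    "fit_dti_volume",
    "fit_fwdti",
    "apply_md_threshold",
    "fa_md_from_eigenvalues",
]

#: MD regularization threshold, mm²/s: above it a voxel is deemed pure free water.
MD_THRESHOLD = 2.7e-3
#: Tissue reference MD used to initialize f from the plain-DTI MD, mm²/s.
TISSUE_REFERENCE_MD = 0.6e-3

FLAG_SKIPPED = 0
FLAG_CONVERGED = 1
FLAG_THRESHOLDED = 2
FLAG_FAILED = 3

_SIGNAL_FLOOR_FRACTION = 1e-6  # of S0, before taking logs


class IllPosedError(ValueError):
    """Raised when the multi-shell bi-tensor fit is requested on single-shell
    data; the learned estimator is the tool for that regime."""


@dataclass
class DTIMetrics:
    """Single-tensor fit result with spectral scalar metrics."""

    tensor: np.ndarray  # (3, 3), mm²/s
    eigenvalues: np.ndarray  # sorted descending, clamped at 0
    FA: float
    MD: float
    S0: float


@dataclass
class FreeWaterMap:
    """Free-water fraction field with tissue tensors and per-voxel status."""

    f: np.ndarray  # (x, y, z) in [0, 1]
    tissue_tensors: np.ndarray  # (x, y, z, 3, 3)
    exit_flags: np.ndarray  # (x, y, z) int, FLAG_* codes


def fa_md_from_eigenvalues(eigvals: np.ndarray) -> tuple[float, float]:
    """FA and MD from tensor eigenvalues (clamped at zero first)."""
    lam = np.maximum(np.asarray(eigvals, dtype=float), 0.0)
    md = lam.mean()
    denom = np.sqrt((lam**2).sum())
    if denom == 0.0:
        return 0.0, 0.0
    fa = np.sqrt(1.5 * ((lam - md) ** 2).sum()) / denom
    return float(min(fa, 1.0)), float(md)


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Rows [-b gx², -b gy², -b gz², -2b gxgy, -2b gxgz, -2b gygz, 1]."""
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones_like(b),
        ]
    )


def _tensor_from_coeffs(c: np.ndarray) -> np.ndarray:
    return np.array(
        [[c[0], c[3], c[4]], [c[3], c[1], c[5]], [c[4], c[5], c[2]]]
    )


def fit_dti(signal: np.ndarray, scheme: GradientScheme) -> DTIMetrics:
    """Single-tensor weighted least squares on the log signal.

    An ordinary pass provides predicted signals whose squares weight the
    second pass (the standard two-step WLS).  Requires at least six non-b0
    directions spanning 3-space and one b0; nonpositive signals are floored
    at 1e-6 of the b0 level before the log.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    n_dw = len(signal) - len(scheme.b0_indices)
    if n_dw < 6 or len(scheme.b0_indices) < 1:
        raise ValueError("need >= 6 diffusion-weighted measurements and >= 1 b0")
    s0_ref = max(float(signal[scheme.b0_indices].mean()), 1e-12)
    s = np.maximum(signal, _SIGNAL_FLOOR_FRACTION * s0_ref)
    y = np.log(s)
    X = _design_matrix(scheme)
    cond = np.linalg.cond(X[:, :6])
    if not np.isfinite(cond) or cond > 1e8:
        raise ValueError("rank-deficient gradient design (coplanar directions?)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.exp(X @ coef)  # predicted signal; weights = w**2
    Xw = X * w[:, None]
    coef, *_ = np.linalg.lstsq(Xw, y * w, rcond=None)
    D = _tensor_from_coeffs(coef)
    lam = np.sort(np.linalg.eigvalsh(D))[::-1]
    fa, md = fa_md_from_eigenvalues(lam)
    return DTIMetrics(
        tensor=D, eigenvalues=np.maximum(lam, 0.0), FA=fa, MD=md, S0=float(np.exp(coef[6]))
    )


def fit_dti_volume(
    signal: np.ndarray, scheme: GradientScheme, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-wise DTI over a 4-D volume -> (FA, MD, tensors) arrays."""
    shape = signal.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    fa = np.zeros(shape)
    md = np.zeros(shape)
    tensors = np.zeros(shape + (3, 3))
    flat = signal.reshape(-1, signal.shape[-1])
    mflat = mask.ravel()
    fa_f, md_f = fa.ravel(), md.ravel()
    t_f = tensors.reshape(-1, 3, 3)
    for i in np.where(mflat)[0]:
        m = fit_dti(flat[i], scheme)
        fa_f[i], md_f[i], t_f[i] = m.FA, m.MD, m.tensor
    return fa, md, tensors


def _cholesky_params(D: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky entries of a PSD tensor (jittered if needed)."""
    for jitter in (0.0, 1e-12, 1e-9, 1e-7):
        try:
            L = np.linalg.cholesky(D + jitter * np.eye(3))
            return np.array([L[0, 0], L[1, 0], L[1, 1], L[2, 0], L[2, 1], L[2, 2]])
        except np.linalg.LinAlgError:
            continue
    return np.array([np.sqrt(0.7e-3), 0.0, np.sqrt(0.7e-3), 0.0, 0.0, np.sqrt(0.7e-3)])


def _tensor_from_cholesky(p: np.ndarray) -> np.ndarray:
    L = np.array([[p[0], 0, 0], [p[1], p[2], 0], [p[3], p[4], p[5]]])
    return L @ L.T


def _fwdti_residual(
    params: np.ndarray, s: np.ndarray, b: np.ndarray, g: np.ndarray, d_iso: float
) -> np.ndarray:
    f = params[0]
    D = _tensor_from_cholesky(params[1:])
    q = np.einsum("ni,ij,nj->n", g, D, g)
    model = (1.0 - f) * np.exp(-b * q) + f * np.exp(-b * d_iso)
    return model - s


def _fit_fwdti_voxel(
    signal: np.ndarray,
    scheme: GradientScheme,
    d_iso: float,
    dti: DTIMetrics,
) -> tuple[float, np.ndarray, int]:
    """NLS of the bi-tensor model on one voxel of normalized signal."""
    b, g = scheme.bvals, scheme.bvecs
    s0 = max(float(signal[scheme.b0_indices].mean()), 1e-12)
    s = np.clip(signal / s0, _SIGNAL_FLOOR_FRACTION, 2.0)
    # f initialized by placing the DTI MD between tissue and free-water MD
    f0 = np.clip(
        (dti.MD - TISSUE_REFERENCE_MD) / (d_iso - TISSUE_REFERENCE_MD), 0.05, 0.95
    )
    # tissue tensor init: the DTI tensor with eigenvalues pulled into tissue range
    lam = np.clip(dti.eigenvalues, 0.1e-3, 2.4e-3)
    w, V = np.linalg.eigh(dti.tensor)
    D0 = V @ np.diag(np.clip(w, 0.1e-3, 2.4e-3)) @ V.T
    del lam
    lower = np.array([0.0] + [-np.inf] * 6)
    upper = np.array([1.0] + [np.inf] * 6)
    best = None
    for f_init in (f0, 0.1, 0.5, 0.9):
        x0 = np.concatenate([[f_init], _cholesky_params(D0)])
        try:
            res = least_squares(
                _fwdti_residual,
                x0,
                args=(s, b, g, d_iso),
                bounds=(lower, upper),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=400,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-12:
            break
    if best is None:
        return float(f0), _tensor_from_cholesky(_cholesky_params(D0)), FLAG_FAILED
    flag = FLAG_CONVERGED if best.status > 0 else FLAG_FAILED
    return float(best.x[0]), _tensor_from_cholesky(best.x[1:]), flag


def fit_fwdti(
    signal: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    d_iso: float = FREE_WATER_DIFFUSIVITY,
    md_threshold: float = MD_THRESHOLD,
) -> FreeWaterMap:
    """Multi-shell bi-tensor fit over a volume -> silver-standard fractions.

    Requires at least two distinct nonzero shells; the two compartments are
    only well disentangled across diffusion weightings, and single-shell
    input raises :class:`IllPosedError` directing the caller to the learned
    estimator.  The MD threshold is applied to the result.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 2:
        signal = signal[:, None, None, :]
    if len(scheme.shells) < 2:
        raise IllPosedError(
            "bi-tensor fitting needs >= 2 nonzero shells; use the learned "
            "estimator (predict) for single-shell data"
        )
    shape = signal.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    f = np.zeros(shape)
    tensors = np.zeros(shape + (3, 3))
    flags = np.full(shape, FLAG_SKIPPED, dtype=int)
    flat = signal.reshape(-1, signal.shape[-1])
    f_f, t_f, fl_f = f.ravel(), tensors.reshape(-1, 3, 3), flags.ravel()
    md_flat = np.zeros(flat.shape[0])
    for i in np.where(mask.ravel())[0]:
        dti = fit_dti(flat[i], scheme)
        md_flat[i] = dti.MD
        f_f[i], t_f[i], fl_f[i] = _fit_fwdti_voxel(flat[i], scheme, d_iso, dti)
    fw = FreeWaterMap(f=f, tissue_tensors=tensors, exit_flags=flags)
    return apply_md_threshold(fw, md_flat.reshape(shape), threshold=md_threshold)


def apply_md_threshold(
    fwmap: FreeWaterMap, md: np.ndarray, threshold: float = MD_THRESHOLD
) -> FreeWaterMap:
    """Voxels with plain-DTI MD above ``threshold`` become pure free water.

    There the signal is assumed to originate entirely from free water: f is
    set to 1, the tissue tensor to exactly zero, and the voxel flagged.
    Voxels below the threshold are untouched; ``threshold = inf`` is a no-op.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    md = np.asarray(md, dtype=float)
    over = (md > threshold) & (fwmap.exit_flags != FLAG_SKIPPED)
    f = fwmap.f.copy()
    tensors = fwmap.tissue_tensors.copy()
    flags = fwmap.exit_flags.copy()
    f[over] = 1.0
    tensors[over] = 0.0
    flags[over] = FLAG_THRESHOLDED
    return FreeWaterMap(f=f, tissue_tensors=tensors, exit_flags=flags)
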