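"""Per-voxel signal representations fed to the estimators.

The spherical network consumes, per voxel, one block of real spherical-
harmonic coefficients (even degrees up to 8, i.e. 45 coefficients) per
training shell; blocks of absent shells are zero-filled and the K-bit shell
code records which are real.  The Deep-SHORE baseline instead consumes 50
coefficients of the order-6 SHORE basis, whose radial scale is set from the
voxel's mean diffusivity as zeta = 1 / (8 pi^2 tau MD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import genlaguerre, gamma

from .gradients import GradientScheme, ShellCode, TRAINING_SHELLS
from . import sh

__all__ = [
    "MAX_SH_DEGREE",
    "N_SH_COEFFS",
    "ShellFeatureSet",
    "ShoreFeatures",
    "sh_fit",
    "sh_reconstruct",
    "build_feature_set",
    "ann_input_vectors",
    "shore_fit",
    "shore_zeta",
    "SHORE_RADIAL_ORDER",
    "SHORE_N_COEFFS",
]

#: Maximum SH degree of the shell expansion (even degrees only -> 45 coeffs).
MAX_SH_DEGREE = 8
N_SH_COEFFS = sh.n_coeffs(MAX_SH_DEGREE)  # 45

#: Laplace-Beltrami regularization weight used when a shell has fewer
#: directions than coefficients; conditioning aid, zero for rich shells.
DEFAULT_LB_REG = 6e-3

SHORE_RADIAL_ORDER = 6
SHORE_DEFAULT_TAU = 0.025  # s, effective diffusion time when unknown
SHORE_DEFAULT_LAMBDA = 1e-8


@dataclass
class ShellFeatureSet:
    """K zero-filled-or-fit SH blocks per voxel plus the shell code.

    ``coeffs`` has shape (..., K, 45); block k is all zeros whenever
    ``code.m[k] == 0``.
    """

    coeffs: np.ndarray
    code: ShellCode

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape[-2] != self.code.K or self.coeffs.shape[-1] != N_SH_COEFFS:
            raise ValueError(
                f"coeffs trailing shape {self.coeffs.shape[-2:]} != "
                f"(K={self.code.K}, {N_SH_COEFFS})"
            )
        absent = np.asarray(self.code.m) == 0
        if np.any(np.abs(self.coeffs[..., absent, :]) > 0):
            raise ValueError("absent-shell blocks must be zero-filled")


@dataclass
class ShoreFeatures:
    """Order-6 SHORE coefficients with their radial scale bookkeeping."""

    coeffs: np.ndarray  # (..., 50)
    zeta: np.ndarray | float  # mm^-2
    tau: float
    lambda_reg: float


def _lb_penalty(max_degree: int) -> np.ndarray:
    """Diagonal Laplace-Beltrami penalty l²(l+1)² per coefficient."""
    vals = []
    for l in sh.even_degrees(max_degree):
        vals.extend([float(l**2 * (l + 1) ** 2)] * (2 * l + 1))
    return np.diag(vals)


def sh_fit(
    values: np.ndarray,
    directions: np.ndarray,
    max_degree: int = MAX_SH_DEGREE,
    reg: float | None = None,
) -> np.ndarray:
    """Least-squares real-SH coefficients of per-direction values.

    ``values`` may be (..., N) for N directions; a Laplace-Beltrami penalty
    (weight ``reg``, default on only when N < number of coefficients) keeps
    under-determined fits conditioned.  Deterministic.
    """
    directions = np.asarray(directions, dtype=float)
    values = np.asarray(values, dtype=float)
    B = sh.sh_basis(directions, max_degree)
    n, p = B.shape
    if reg is None:
        reg = 0.0 if n >= p else DEFAULT_LB_REG
    if reg > 0:
        A = B.T @ B + reg * _lb_penalty(max_degree)
    else:
        A = B.T @ B
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e10:
            raise ValueError(
                f"degenerate direction set (normal-matrix condition {cond:.3g}); "
                "pass a Laplace-Beltrami reg weight"
            )
    rhs = values @ B  # (..., p)
    return np.linalg.solve(A, rhs[..., :, None])[..., 0]


def sh_reconstruct(coeffs: np.ndarray, directions: np.ndarray, max_degree: int = MAX_SH_DEGREE) -> np.ndarray:
    """Evaluate an SH expansion at unit ``directions``."""
    B = sh.sh_basis(np.asarray(directions, dtype=float), max_degree)
    return np.asarray(coeffs, dtype=float) @ B.T


def build_feature_set(
    volume: np.ndarray,
    scheme: GradientScheme,
    code: ShellCode,
    training_shells: tuple[float, ...] = TRAINING_SHELLS,
    shell_tolerance: float = 100.0,
) -> ShellFeatureSet:
    """Per-voxel SH blocks for every present training shell, zeros elsewhere.

    ``volume`` is normalized signal with trailing measurement axis (any
    leading shape: a flat voxel list or a 3-D grid).  Blocks are ordered by
    nominal training b-value.  Present shells flagged in ``code`` must exist
    in ``scheme``.
    """
    volume = np.asarray(volume, dtype=float)
    lead = volume.shape[:-1]
    out = np.zeros(lead + (code.K, N_SH_COEFFS))
    for k, b in enumerate(training_shells[: code.K]):
        if code.m[k] == 0:
            continue
        match = [s for s in scheme.shells if abs(s - b) <= shell_tolerance]
        if not match:
            raise ValueError(
                f"shell code marks b={b:g} present but scheme has {scheme.shell_bvalues}"
            )
        idx = scheme.shells[match[0]]
        out[..., k, :] = sh_fit(volume[..., idx], scheme.bvecs[idx])
    return ShellFeatureSet(coeffs=out, code=code)


def ann_input_vectors(
    volume: np.ndarray,
    scheme: GradientScheme,
    shell_b: float,
    n_b0: int = 6,
    shell_tolerance: float = 100.0,
) -> np.ndarray:
    """Raw-signal input vectors for the fully connected baseline.

    The vector is the first ``n_b0`` normalized b0 measurements followed by
    the shell's directional measurements — N_b = n_b0 + n_directions, which
    is 96 for a 90-direction shell with the default 6 b0 entries.
    """
    volume = np.asarray(volume, dtype=float)
    match = [s for s in scheme.shells if abs(s - shell_b) <= shell_tolerance]
    if not match:
        raise ValueError(f"no shell near b={shell_b:g} in {scheme.shell_bvalues}")
    if len(scheme.b0_indices) < n_b0:
        raise ValueError(f"need {n_b0} b0 volumes, scheme has {len(scheme.b0_indices)}")
    idx = np.concatenate([scheme.b0_indices[:n_b0], scheme.shells[match[0]]])
    return volume[..., idx]


def shore_zeta(md: np.ndarray | float, tau: float = SHORE_DEFAULT_TAU) -> np.ndarray | float:
    """Radial scale zeta = 1 / (8 pi^2 tau MD), mm^-2.

    Nonpositive MD falls back to 0.7e-3 mm²/s with a warning (degenerate fit
    upstream).
    """
    md = np.asarray(md, dtype=float)
    if np.any(md <= 0):
        import warnings

        warnings.warn("nonpositive MD in zeta; falling back to 0.7e-3 mm²/s", stacklevel=2)
        md = np.where(md > 0, md, 0.7e-3)
    out = 1.0 / (8.0 * np.pi**2 * tau * md)
    return float(out) if out.ndim == 0 else out


def _shore_index_set(radial_order: int) -> list[tuple[int, int, int]]:
    """(n, l, m) triples of the basis; 50 of them at radial order 6."""
    idx = []
    for l in range(0, radial_order + 1, 2):
        for n in range(l, (radial_order + l) // 2 + 1):
            for m in range(-l, l + 1):
                idx.append((n, l, m))
    return idx


SHORE_N_COEFFS = len(_shore_index_set(SHORE_RADIAL_ORDER))  # 50


def _shore_matrix(
    scheme: GradientScheme, zeta: float, tau: float, radial_order: int = SHORE_RADIAL_ORDER
) -> np.ndarray:
    """Design matrix of the 3-D SHORE signal basis at the scheme's q-points.

    q = sqrt(b / (4 pi^2 tau)); radial part is a generalized Laguerre series
    in x = q²/zeta with a Gaussian envelope, angular part the real SH basis.
    """
    q2 = scheme.bvals / (4.0 * np.pi**2 * tau)  # |q|², mm^-2
    x = q2 / zeta
    theta, phi = sh.cart_to_sphere(scheme.bvecs)
    idx = _shore_index_set(radial_order)
    M = np.empty((len(scheme), len(idx)))
    from scipy.special import sph_harm_y

    for j, (n, l, m) in enumerate(idx):
        kappa = np.sqrt(
            2.0 * gamma(n - l + 1) / gamma(n + l / 2.0 + 1.5)
        )
        radial = (
            kappa
            * x ** (l / 2.0)
            * np.exp(-x / 2.0)
            * genlaguerre(n - l, l + 0.5)(x)
        )
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            ang = np.sqrt(2.0) * y.imag
        elif m == 0:
            ang = y.real
        else:
            ang = np.sqrt(2.0) * y.real
        M[:, j] = radial * ang
    return M


def shore_fit(
    values: np.ndarray,
    scheme: GradientScheme,
    md: float,
    tau: float = SHORE_DEFAULT_TAU,
    lambda_reg: float = SHORE_DEFAULT_LAMBDA,
) -> ShoreFeatures:
    """Regularized least-squares SHORE coefficients (order 6, 50 of them).

    ``values`` is normalized signal (..., N) over all measurements of
    ``scheme``; ``md`` scales the basis through zeta.  Tikhonov-regularized
    with ``lambda_reg`` (the small default just stabilizes the solve).
    """
    z = shore_zeta(md, tau)
    M = _shore_matrix(scheme, float(z), tau)
    A = M.T @ M + lambda_reg * np.eye(M.shape[1])
    coef = np.linalg.solve(A, np.asarray(values, dtype=float) @ M)
    return ShoreFeatures(coeffs=coef, zeta=z, tau=tau, lambda_reg=lambda_reg)


def build_shore_features(
    volume: np.ndarray,
    scheme: GradientScheme,
    md: float | None = None,
    tau: float = SHORE_DEFAULT_TAU,
    lambda_reg: float = SHORE_DEFAULT_LAMBDA,
    mask: np.ndarray | None = None,
) -> ShoreFeatures:
    """Order-6 SHORE coefficients for a whole volume with one shared scale.

    The radial scale zeta is computed once per dataset — from ``md`` when
    given, else from the median plain-DTI MD over the (masked) volume — so
    coefficients are comparable across voxels, which is what the downstream
    regressor needs.  ``volume`` is normalized signal with trailing
    measurement axis; returns coefficients of shape ``volume.shape[:-1] + (50,)``.
    """
    from .tensorfit import fit_dti

    volume = np.asarray(volume, dtype=float)
    flat = volume.reshape(-1, volume.shape[-1])
    if md is None:
        sel = np.ones(flat.shape[0], bool) if mask is None else np.asarray(mask, bool).ravel()
        mds = np.array([fit_dti(v, scheme).MD for v in flat[sel]])
        mds = mds[mds > 0]
        md = float(np.median(mds)) if mds.size else 0.7e-3
    z = float(np.asarray(shore_zeta(md, tau)))
    M = _shore_matrix(scheme, z, tau)
    A = M.T @ M + lambda_reg * np.eye(M.shape[1])
    coeffs = np.linalg.solve(A, (flat @ M).T).T.reshape(volume.shape[:-1] + (M.shape[1],))
    return ShoreFeatures(coeffs=coeffs, zeta=z, tau=tau, lambda_reg=lambda_reg)


def shore_reconstruct(features: ShoreFeatures, scheme: GradientScheme) -> np.ndarray:
    """Evaluate a SHORE expansion back at the scheme's measurements."""
    M = _shore_matrix(scheme, float(np.asarray(features.zeta)), features.tau)
    return np.asarray(features.coeffs, dtype=float) @ M.T
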