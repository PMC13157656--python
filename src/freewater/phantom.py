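"""Synthetic free-water-contaminated DWI phantoms with known ground truth.

The generative model is the two-compartment (bi-tensor) signal model: each
voxel mixes an anisotropic tissue tensor compartment with an isotropic
free-water compartment of diffusivity ``D_iso``,

    S_i = S0 * [ (1 - f) * exp(-b_i g_i^T D_tissue g_i) + f * exp(-b_i D_iso) ].

Phantoms emulate multi-shell HARDI acquisitions (by default b = 1000, 2000,
3000 s/mm² with 90 electrostatically spread directions per shell plus
interleaved b0s) with magnitude (Rician) noise, so that fitting, training
and evaluation are all exercised against a known truth field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .gradients import GradientScheme, build_scheme, write_gradients

__all__ = [
    "BiTensorParams",
    "PhantomVolume",
    "FREE_WATER_DIFFUSIVITY",
    "bitensor_signal",
    "bitensor_signal_field",
    "add_rician_noise",
    "dispersed_directions",
    "make_scheme",
    "random_tissue_tensors",
    "generate_phantom",
    "tensor_from_eigs",
]

#: Free-water diffusivity at body temperature, mm²/s.  The MD regularization
#: threshold of 2.7e-3 mm²/s used downstream approximates this value.
FREE_WATER_DIFFUSIVITY = 3.0e-3

#: Tissue-tensor eigenvalue bounds used by the generator (mm²/s).
_TISSUE_MD_RANGE = (0.5e-3, 0.9e-3)
_TISSUE_FA_RANGE = (0.2, 0.9)


@dataclass
class BiTensorParams:
    """Per-voxel generative parameters of the two-compartment model."""

    f: float
    D_tissue: np.ndarray
    D_iso: float = FREE_WATER_DIFFUSIVITY
    S0: float = 1.0

    def __post_init__(self) -> None:
        self.D_tissue = np.asarray(self.D_tissue, dtype=float).reshape(3, 3)
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f = {self.f} outside [0, 1]")
        if self.D_iso <= 0 or self.S0 <= 0:
            raise ValueError("D_iso and S0 must be positive")
        if not np.allclose(self.D_tissue, self.D_tissue.T, atol=1e-15):
            raise ValueError("D_tissue must be symmetric")
        if np.linalg.eigvalsh(self.D_tissue).min() < -1e-12:
            raise ValueError("D_tissue must be positive semi-definite")


@dataclass
class PhantomVolume:
    """A simulated 4-D acquisition plus its generative ground truth."""

    signal: np.ndarray  # (x, y, z, n_meas)
    truth_f: np.ndarray  # (x, y, z)
    truth_tensors: np.ndarray  # (x, y, z, 3, 3)
    scheme: GradientScheme
    mask: np.ndarray  # (x, y, z) bool
    seed: int
    S0: float = 1.0
    D_iso: float = FREE_WATER_DIFFUSIVITY

    def __post_init__(self) -> None:
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError("signal measurement axis inconsistent with scheme")
        if self.truth_f.shape != self.signal.shape[:3]:
            raise ValueError("truth_f spatial shape mismatch")

    def save(self, prefix: str | Path) -> None:
        """Write NIfTI volumes (+ .bval/.bvec) under ``prefix``."""
        import nibabel as nib

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        aff = np.eye(4)
        nib.save(nib.Nifti1Image(self.signal.astype(np.float32), aff), f"{prefix}_dwi.nii.gz")
        nib.save(nib.Nifti1Image(self.truth_f.astype(np.float32), aff), f"{prefix}_truthf.nii.gz")
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), aff), f"{prefix}_mask.nii.gz")
        write_gradients(self.scheme, f"{prefix}.bval", f"{prefix}.bvec")


def bitensor_signal(params: BiTensorParams, scheme: GradientScheme) -> np.ndarray:
    """Noiseless two-compartment signal for every measurement of ``scheme``."""
    return bitensor_signal_field(
        np.array([params.f]),
        params.D_tissue[None],
        scheme,
        D_iso=params.D_iso,
        S0=params.S0,
    )[0]


def bitensor_signal_field(
    f: np.ndarray,
    tensors: np.ndarray,
    scheme: GradientScheme,
    D_iso: float = FREE_WATER_DIFFUSIVITY,
    S0: float = 1.0,
) -> np.ndarray:
    """Vectorized forward model: (V,) fractions + (V,3,3) tensors -> (V, N)."""
    f = np.asarray(f, dtype=float)
    tensors = np.asarray(tensors, dtype=float)
    b = scheme.bvals[None, :]
    g = scheme.bvecs  # (N, 3)
    # quadratic form g^T D g per voxel per measurement
    q = np.einsum("ni,vij,nj->vn", g, tensors, g)
    tissue = np.exp(-b * q)
    water = np.exp(-scheme.bvals * D_iso)[None, :]
    return S0 * ((1.0 - f)[:, None] * tissue + f[:, None] * water)


def add_rician_noise(
    signal: np.ndarray, snr: float, seed: int, S0: float = 1.0
) -> np.ndarray:
    """Magnitude-MR noise: sqrt((S + n1)² + n2²), n ~ N(0, (S0/snr)²).

    ``snr`` is defined against the b0 level ``S0``.  Reproducible given
    ``seed``; ``snr = inf`` returns the input unchanged.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return np.asarray(signal, dtype=float).copy()
    rng = np.random.default_rng(seed)
    sigma = S0 / snr
    s = np.asarray(signal, dtype=float)
    n1 = rng.normal(0.0, sigma, size=s.shape)
    n2 = rng.normal(0.0, sigma, size=s.shape)
    return np.sqrt((s + n1) ** 2 + n2**2)


def dispersed_directions(n: int, seed: int, iterations: int = 200) -> np.ndarray:
    """``n`` quasi-uniform unit vectors via antipodal electrostatic repulsion.

    Charges interact with both a point and its antipode (diffusion directions
    are sign-invariant), starting from a seeded spherical Fibonacci layout.
    """
    if n < 6:
        raise ValueError("need at least 6 directions")
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / (2.0 * n)  # hemisphere-ish spread
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i + rng.uniform(0, 2 * np.pi)
    r = np.sqrt(1.0 - z**2)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    pts += 0.01 * rng.standard_normal(pts.shape)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    step = 0.005
    for _ in range(iterations):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            d = pts[:, None, :] - sign * pts[None, :, :]
            dist2 = np.sum(d * d, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            dist2[dist2 < 1e-12] = np.inf
            force += np.sum(d / dist2[..., None] ** 1.5, axis=1)
        # project onto tangent plane and step
        force -= np.sum(force * pts, axis=1, keepdims=True) * pts
        nf = np.linalg.norm(force, axis=1, keepdims=True)
        nf[nf == 0] = 1.0
        pts = pts + step * force / nf
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def make_scheme(
    shells: tuple[float, ...] = (1000.0, 2000.0, 3000.0),
    dirs_per_shell: int = 90,
    n_b0: int = 18,
    seed: int = 0,
) -> GradientScheme:
    """HARDI-style scheme: interleaved b0s then per-shell direction sets."""
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for k, b in enumerate(sorted(shells)):
        dirs = dispersed_directions(dirs_per_shell, seed=seed * 1009 + k + 1)
        bvals.extend([float(b)] * dirs_per_shell)
        bvecs.extend(list(dirs))
    return build_scheme(np.asarray(bvals), np.asarray(bvecs))


def tensor_from_eigs(eigvals: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Tensor with given eigenvalues and principal frame."""
    return rotation @ np.diag(eigvals) @ rotation.T


def _eigs_for_fa_md(fa: np.ndarray, md: np.ndarray) -> np.ndarray:
    """Axially symmetric eigenvalues (l1 >= l2 = l3) with given FA and MD.

    For l2 = l3 the FA formula inverts in closed form: with ratio
    r = l1/l2, FA = (r - 1) / sqrt(r² + 2) ... solved numerically per voxel
    via the quadratic it induces.
    """
    fa = np.asarray(fa, dtype=float)
    md = np.asarray(md, dtype=float)
    # FA² (r² + 2) = (r-1)² with x = r => (1-FA²) r² - 2 r + (1 - 2 FA²) = 0
    a = 1.0 - fa**2
    disc = np.sqrt(np.maximum(4.0 - 4.0 * a * (1.0 - 2.0 * fa**2), 0.0))
    r = (2.0 + disc) / (2.0 * a)
    l2 = 3.0 * md / (r + 2.0)
    l1 = r * l2
    return np.stack([l1, l2, l2], axis=-1)


def random_tissue_tensors(
    n: int, rng: np.random.Generator, fa_range: tuple[float, float] = _TISSUE_FA_RANGE
) -> np.ndarray:
    """(n, 3, 3) prolate tensors, FA uniform in ``fa_range``, random frames."""
    fa = rng.uniform(*fa_range, size=n)
    md = rng.uniform(*_TISSUE_MD_RANGE, size=n)
    eigs = _eigs_for_fa_md(fa, md)
    out = np.empty((n, 3, 3))
    for i in range(n):
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        out[i] = tensor_from_eigs(eigs[i], q)
    return out


def _default_f_field(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """Smooth truth-f field: CSF band ramping 0 -> 1 plus low tissue background.

    A free-water "ventricle" interface runs across the last axis so partial
    volume voxels (every intermediate f) exist, over a background of mild
    contamination f in [0, 0.2].
    """
    nx, ny, nz = shape
    background = rng.uniform(0.0, 0.2, size=shape)
    z = np.linspace(-1.0, 1.0, nz)[None, None, :]
    ramp_center = rng.uniform(-0.2, 0.2)
    ramp = 1.0 / (1.0 + np.exp(-(z - ramp_center) / 0.15))
    f = np.clip(background + ramp * (1.0 - background), 0.0, 1.0)
    f = gaussian_filter(f, sigma=1.0)
    return np.clip(f, 0.0, 1.0)


def generate_phantom(
    shape: tuple[int, int, int] = (32, 32, 32),
    shells: tuple[float, ...] = (1000.0, 2000.0, 3000.0),
    dirs_per_shell: int = 90,
    n_b0: int = 18,
    f_field: np.ndarray | str = "interface",
    snr: float = np.inf,
    seed: int = 0,
    S0: float = 1.0,
    D_iso: float = FREE_WATER_DIFFUSIVITY,
) -> PhantomVolume:
    """Simulate a multi-shell acquisition with known f and tensor fields.

    Parameters
    ----------
    f_field : "interface" for the default CSF-band + background field,
        "uniform" for f ~ U[0, 0.9] i.i.d. per voxel, or an explicit array.
    snr : b0-referenced SNR of the Rician noise; ``inf`` keeps the phantom
        noiseless.
    """
    if min(shape) < 1 or dirs_per_shell < 6:
        raise ValueError("invalid phantom shape or direction count")
    rng = np.random.default_rng(seed)
    scheme = make_scheme(shells, dirs_per_shell, n_b0, seed=seed)
    if isinstance(f_field, str):
        if f_field == "interface":
            f = _default_f_field(shape, rng)
        elif f_field == "uniform":
            f = rng.uniform(0.0, 0.9, size=shape)
        else:
            raise ValueError(f"unknown f_field spec {f_field!r}")
    else:
        f = np.asarray(f_field, dtype=float)
        if f.shape != tuple(shape) or f.min() < 0 or f.max() > 1:
            raise ValueError("explicit f_field must match shape with values in [0,1]")
    nvox = int(np.prod(shape))
    tensors = random_tissue_tensors(nvox, rng).reshape(*shape, 3, 3)
    signal = bitensor_signal_field(
        f.ravel(), tensors.reshape(-1, 3, 3), scheme, D_iso=D_iso, S0=S0
    ).reshape(*shape, len(scheme))
    if np.isfinite(snr):
        signal = add_rician_noise(signal, snr, seed=seed + 1, S0=S0)
    mask = np.ones(shape, dtype=bool)
    return PhantomVolume(
        signal=signal,
        truth_f=f,
        truth_tensors=tensors,
        scheme=scheme,
        mask=mask,
        seed=seed,
        S0=S0,
        D_iso=D_iso,
    )
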