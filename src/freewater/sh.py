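"""Real symmetric spherical-harmonic basis and exact quadrature on S².

Diffusion signals are antipodally symmetric, so only even degrees carry
signal; the basis here is the real, even-degree basis in the ordering used
throughout the dMRI literature: for each even degree l = 0, 2, ..., L and
order m = -l..l, with

    m < 0 :  sqrt(2) * Im( Y_l^{|m|} )
    m = 0 :  Y_l^0
    m > 0 :  sqrt(2) * Re( Y_l^m )

where Y_l^m are the complex orthonormal spherical harmonics.  This basis is
orthonormal on the sphere; the ordering is part of the model/checkpoint
contract.  Quadrature grids (Gauss-Legendre in cos(theta) x uniform in phi)
are exact for band-limited integrands, which keeps the network's grid-based
activations exactly rotation-equivariant.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "n_coeffs",
    "even_degrees",
    "degree_slices",
    "sh_basis",
    "cart_to_sphere",
    "quadrature_grid",
    "sh_rotation_matrix",
    "random_rotation",
]


def even_degrees(max_degree: int) -> list[int]:
    return list(range(0, max_degree + 1, 2))


def n_coeffs(max_degree: int) -> int:
    """Number of real coefficients for even degrees up to ``max_degree``."""
    return sum(2 * l + 1 for l in even_degrees(max_degree))


def degree_slices(max_degree: int) -> dict[int, slice]:
    """Coefficient-vector slice of each even degree block."""
    out, start = {}, 0
    for l in even_degrees(max_degree):
        out[l] = slice(start, start + 2 * l + 1)
        start += 2 * l + 1
    return out


def cart_to_sphere(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors -> (polar theta, azimuth phi)."""
    xyz = np.asarray(xyz, dtype=float)
    r = np.linalg.norm(xyz, axis=-1)
    theta = np.arccos(np.clip(xyz[..., 2] / np.where(r > 0, r, 1.0), -1.0, 1.0))
    phi = np.arctan2(xyz[..., 1], xyz[..., 0])
    return theta, phi


def sh_basis(directions: np.ndarray, max_degree: int) -> np.ndarray:
    """Design matrix B with ``B[i, j] = Y_j(direction_i)``.

    ``directions`` is (N, 3) of unit vectors; columns follow the even-degree
    real basis ordering documented in the module docstring.
    """
    theta, phi = cart_to_sphere(directions)
    cols = []
    for l in even_degrees(max_degree):
        # sph_harm_y(l, m, theta, phi): complex orthonormal Y_l^m
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * y.imag)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * y.real)
    return np.stack(cols, axis=-1)


def quadrature_grid(exact_degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Spherical quadrature exact for integrands of degree ``exact_degree``.

    Gauss-Legendre nodes in cos(theta) crossed with a uniform phi grid.
    Returns (points (M, 3), weights (M,)) with weights summing to 4*pi.
    """
    n_theta = int(np.ceil((exact_degree + 1) / 2))
    n_phi = exact_degree + 1
    x, w = np.polynomial.legendre.leggauss(n_theta)  # x = cos(theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    ct = np.repeat(x, n_phi)
    st = np.sqrt(1.0 - ct**2)
    ph = np.tile(phi, n_theta)
    pts = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=1)
    wts = np.repeat(w, n_phi) * (2.0 * np.pi / n_phi)
    return pts, wts


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def sh_rotation_matrix(rotation: np.ndarray, max_degree: int) -> np.ndarray:
    """Block-diagonal Wigner matrix for the real even-degree basis.

    Built numerically: for each degree the (2l+1)x(2l+1) block is solved from
    basis evaluations on a quadrature grid, using that rotating a function is
    evaluating it at inversely rotated points.  Exact to solver precision.
    """
    pts, wts = quadrature_grid(2 * max_degree)
    B = sh_basis(pts, max_degree)
    Brot = sh_basis(pts @ rotation, max_degree)  # rows: Y(R^T x)
    # projection <Y_i(R^T .), Y_j> gives the transpose blocks; do lstsq per degree
    n = B.shape[1]
    D = np.zeros((n, n))
    for l, sl in degree_slices(max_degree).items():
        # coefficients c' of rotated function: f(R^T x) = sum c'_j Y_j(x)
        # with f = Y_i: c'_ji = integral Y_i(R^T x) Y_j(x)
        D[sl, sl] = (B[:, sl] * wts[:, None]).T @ Brot[:, sl]
    return D
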