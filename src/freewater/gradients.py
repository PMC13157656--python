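"""Acquisition geometry: b-values, gradient directions and shell structure.

Diffusion acquisitions are described by FSL-style sidecar files: a ``.bval``
file with one whitespace-separated row of diffusion weightings (s/mm²) and a
``.bvec`` file with three rows holding the x, y and z components of the unit
gradient directions.  Measurements are grouped into *shells* — sets of
directions sharing one nominal b-value — plus the non-diffusion-weighted
(b0) reference volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "ShellCode",
    "GradientFormatError",
    "ShellAmbiguityError",
    "UnusableAcquisitionError",
    "read_gradients",
    "write_gradients",
    "build_scheme",
    "shell_code_for",
]

#: b-values at or below this (s/mm²) count as b0 reference volumes.
DEFAULT_B0_THRESHOLD = 50.0
#: Measured b-values within this distance (s/mm²) of a nominal shell center
#: are assigned to that shell; real schemes jitter around the nominal value.
DEFAULT_SHELL_TOLERANCE = 100.0
#: The shell scheme the learned estimators are trained on (s/mm²).
TRAINING_SHELLS = (1000.0, 2000.0, 3000.0)


class GradientFormatError(ValueError):
    """Malformed .bval/.bvec content (length mismatch, zero direction, ...)."""


class ShellAmbiguityError(ValueError):
    """A measured b-value is within tolerance of two nominal shell centers."""


class UnusableAcquisitionError(ValueError):
    """The acquisition shares no shell with the training scheme."""


@dataclass
class GradientScheme:
    """Directions, b-values and shell structure of one acquisition.

    Attributes
    ----------
    bvals : (N,) float array of diffusion weightings in s/mm².
    bvecs : (N, 3) float array of unit direction vectors (zero rows for b0s).
    b0_indices : indices with ``bval <= b0_threshold``.
    shells : mapping nominal shell b-value -> sorted measurement indices,
        with strictly increasing nominal keys.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_indices: np.ndarray
    shells: dict[float, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise GradientFormatError(
                f"{self.bvals.shape[0]} b-values vs {self.bvecs.shape[0]} directions"
            )
        self.b0_indices = np.asarray(self.b0_indices, dtype=int)
        self.shells = {float(k): np.asarray(v, dtype=int) for k, v in self.shells.items()}

    def __len__(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def shell_bvalues(self) -> tuple[float, ...]:
        return tuple(sorted(self.shells))

    def validate(self) -> None:
        """Check the partition and unit-norm invariants; raise on violation."""
        seen = np.zeros(len(self), dtype=int)
        seen[self.b0_indices] += 1
        for idx in self.shells.values():
            seen[idx] += 1
        if not np.all(seen == 1):
            raise GradientFormatError("indices not partitioned into b0s + shells")
        nonb0 = np.setdiff1d(np.arange(len(self)), self.b0_indices)
        norms = np.linalg.norm(self.bvecs[nonb0], axis=1)
        if nonb0.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise GradientFormatError("non-b0 directions are not unit vectors")
        keys = list(self.shells)
        if keys != sorted(keys):
            raise GradientFormatError("shell keys not increasing")

    def subset(self, indices: np.ndarray) -> "GradientScheme":
        """Scheme restricted to ``indices`` (e.g. one shell plus b0s)."""
        indices = np.asarray(indices, dtype=int)
        return build_scheme(self.bvals[indices], self.bvecs[indices])


@dataclass
class ShellCode:
    """Binary presence/absence vector over the K training shells.

    ``m[k] = 1`` iff shell ``k`` of the training scheme is available in the
    input.  K = 3 for the {1000, 2000, 3000} s/mm² training scheme, giving
    2^K − 1 = 7 valid configurations.
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=int).ravel()
        if not np.isin(self.m, (0, 1)).all():
            raise ValueError("shell code entries must be 0 or 1")
        if self.m.sum() < 1:
            raise ValueError("a valid shell code has at least one shell present")

    @property
    def K(self) -> int:
        return int(self.m.shape[0])

    def __iter__(self):
        return iter(self.m.tolist())

    @staticmethod
    def all_valid(K: int) -> list["ShellCode"]:
        """Enumerate all 2^K − 1 valid configurations."""
        codes = []
        for bits in range(1, 2**K):
            codes.append(ShellCode(np.array([(bits >> k) & 1 for k in range(K)])))
        return codes


def _cluster_shells(
    bvals: np.ndarray, b0_threshold: float, shell_tolerance: float
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Greedy 1-D clustering of non-b0 b-values into nominal shells."""
    b0_idx = np.where(bvals <= b0_threshold)[0]
    dw_idx = np.where(bvals > b0_threshold)[0]
    centers: list[float] = []
    members: list[list[int]] = []
    for i in dw_idx[np.argsort(bvals[dw_idx], kind="stable")]:
        b = bvals[i]
        hits = [k for k, c in enumerate(centers) if abs(b - c) <= shell_tolerance]
        if len(hits) > 1:
            raise ShellAmbiguityError(
                f"b={b:g} is within {shell_tolerance:g} of shells "
                f"{[centers[h] for h in hits]}"
            )
        if hits:
            members[hits[0]].append(int(i))
            # running mean keeps the center at the cluster centroid
            centers[hits[0]] = float(np.mean(bvals[members[hits[0]]]))
        else:
            centers.append(float(b))
            members.append([int(i)])
    # nominal value = rounded cluster centroid
    shells = {}
    for c, idx in sorted(zip(centers, members)):
        nominal = float(np.round(c))
        if nominal in shells:
            raise ShellAmbiguityError(f"two clusters share nominal b={nominal:g}")
        shells[nominal] = np.sort(np.asarray(idx, dtype=int))
    return b0_idx, shells


def build_scheme(
    bvals: np.ndarray,
    bvecs: np.ndarray,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> GradientScheme:
    """Build a validated :class:`GradientScheme` from arrays.

    Directions are renormalized to unit length; a zero direction at a
    diffusion-weighted b-value is a format error.
    """
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.ndim != 2:
        raise GradientFormatError("bvecs must be a 2-D array")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    if bvecs.shape[1] != 3:
        raise GradientFormatError(f"bvecs shape {bvecs.shape} has no 3-axis")
    if bvals.shape[0] != bvecs.shape[0]:
        raise GradientFormatError(
            f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dw = bvals > b0_threshold
    if np.any(dw & (norms < 1e-12)):
        bad = int(np.where(dw & (norms < 1e-12))[0][0])
        raise GradientFormatError(f"zero direction at diffusion-weighted index {bad}")
    out = bvecs.copy()
    nz = norms > 1e-12
    out[nz] = out[nz] / norms[nz, None]
    out[~nz] = 0.0
    b0_idx, shells = _cluster_shells(bvals, b0_threshold, shell_tolerance)
    scheme = GradientScheme(bvals=bvals, bvecs=out, b0_indices=b0_idx, shells=shells)
    scheme.validate()
    return scheme


def read_gradients(
    bval_path: str | Path,
    bvec_path: str | Path,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> GradientScheme:
    """Read FSL-style ``.bval``/``.bvec`` text files into a scheme.

    The ``.bvec`` layout (3×N or N×3) is auto-detected; directions are
    renormalized and b-values clustered into shells within
    ``shell_tolerance`` of their nominal centers.
    """
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    for p in (bval_path, bvec_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    return build_scheme(bvals, bvecs, b0_threshold, shell_tolerance)


def write_gradients(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write a scheme back to FSL text files (bvec as 3 rows × N columns)."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.9f")


def shell_code_for(
    scheme: GradientScheme,
    training_shells: tuple[float, ...] = TRAINING_SHELLS,
    shell_tolerance: float = DEFAULT_SHELL_TOLERANCE,
) -> ShellCode:
    """Presence code of ``scheme`` against the K training shells.

    Raises :class:`UnusableAcquisitionError` when no shell of the scheme
    matches any training shell (the estimator has nothing to condition on).
    """
    if len(training_shells) == 0 or list(training_shells) != sorted(training_shells):
        raise ValueError("training_shells must be nonempty and sorted")
    m = np.zeros(len(training_shells), dtype=int)
    for k, b in enumerate(training_shells):
        for s in scheme.shells:
            if abs(s - b) <= shell_tolerance:
                m[k] = 1
    if m.sum() == 0:
        raise UnusableAcquisitionError(
            f"shells {scheme.shell_bvalues} share nothing with training scheme "
            f"{tuple(training_shells)}; consider b-value remapping"
        )
    return ShellCode(m)
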