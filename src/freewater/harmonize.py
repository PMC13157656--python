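"""Mapping acquisitions onto the training shell scheme.

Two steps: (1) *b-value remapping* — in the low-b regime the log-signal
decays approximately linearly in b, so a shell acquired at ``b_original``
can be recalibrated to a nominal ``b_new`` by

    S_bnew = S0 * exp( (b_new / b_original) * log(S_b / S0) ),

exact for mono-exponential decay; and (2) *normalization* — dividing every
diffusion-weighted volume by the voxelwise mean b0 signal, which is the
input convention of all the learned estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientScheme, build_scheme

__all__ = [
    "RemapSpec",
    "RemapRangeError",
    "remap_bvalue",
    "remap_shell",
    "remap_scheme_to_training",
    "normalize_signal",
]

#: Signal clip range after normalization: Rician noise can push values above
#: the b0 level; anything past 1.5 is implausible and clipped.
_NORM_CLIP = (1e-6, 1.5)


class RemapRangeError(ValueError):
    """Both endpoints of a requested remap lie outside the linear-decay range."""


@dataclass
class RemapSpec:
    """One shell remapping ``b_original -> b_new`` (s/mm²).

    The linear-decay approximation holds for 500 < b < 1500 s/mm²; a remap
    is accepted when either endpoint lies within (500, 1500] (so the 700 ->
    1000 recalibration used for low-b clinical shells is allowed, with a
    warning for the upward extrapolation).
    """

    b_original: float
    b_new: float
    valid_range: tuple[float, float] = field(default=(500.0, 1500.0))

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        in_range = lambda b: lo < b <= hi  # noqa: E731
        if not (in_range(self.b_original) or in_range(self.b_new)):
            raise RemapRangeError(
                f"remap {self.b_original:g}->{self.b_new:g} outside the "
                f"linear-decay range ({lo:g}, {hi:g}]"
            )
        if self.b_original <= 0 or self.b_new <= 0:
            raise ValueError("b-values must be positive")
        if self.b_new > self.b_original and not in_range(self.b_original):
            warnings.warn(
                f"extrapolating upward from b={self.b_original:g} outside the "
                "linear-decay range",
                stacklevel=2,
            )


def remap_bvalue(signal: np.ndarray, s0: np.ndarray | float, spec: RemapSpec) -> np.ndarray:
    """Recalibrate shell signals from ``spec.b_original`` to ``spec.b_new``.

    Vectorized over any shape broadcastable with ``s0``; signals are floored
    at a tiny positive fraction of S0 before the log.
    """
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 <= 0):
        raise ValueError("s0 must be positive")
    s = np.maximum(np.asarray(signal, dtype=float), 1e-12 * s0)
    ratio = spec.b_new / spec.b_original
    return s0 * np.exp(ratio * np.log(s / s0))


def remap_shell(
    signal: np.ndarray,
    scheme: GradientScheme,
    b_original: float,
    b_new: float,
) -> tuple[np.ndarray, GradientScheme]:
    """Remap one shell of a 4-D volume; returns new volume + relabeled scheme.

    Remapped measurements keep their original directions; the returned scheme
    carries ``b_new`` at those indices.
    """
    if b_original not in scheme.shells:
        raise ValueError(f"scheme has no shell at b={b_original:g}")
    spec = RemapSpec(b_original=b_original, b_new=b_new)
    idx = scheme.shells[b_original]
    s0 = np.asarray(signal, dtype=float)[..., scheme.b0_indices].mean(axis=-1)
    out = np.asarray(signal, dtype=float).copy()
    out[..., idx] = remap_bvalue(out[..., idx], s0[..., None], spec)
    bvals = scheme.bvals.copy()
    bvals[idx] = b_new
    return out, build_scheme(bvals, scheme.bvecs)


def remap_scheme_to_training(
    signal: np.ndarray,
    scheme: GradientScheme,
    target: float = 1000.0,
    upper: float = 1500.0,
) -> tuple[np.ndarray, GradientScheme]:
    """Recalibrate the lowest sub-1500 shell to the training b=1000 s/mm².

    For schemes with several shells at or below ``upper`` only the lowest is
    remapped; the others are dropped with a warning (their calibration would
    collide with the remapped shell).  Shells above ``upper`` pass through.
    """
    low = [b for b in scheme.shell_bvalues if b <= upper]
    if not low:
        return np.asarray(signal, dtype=float), scheme
    keep_low = low[0]
    if abs(keep_low - target) < 1e-9:
        remapped, new_scheme = np.asarray(signal, dtype=float), scheme
    else:
        remapped, new_scheme = remap_shell(signal, scheme, keep_low, target)
    drop = [b for b in low[1:]]
    if drop:
        warnings.warn(
            f"dropping sub-{upper:g} shells {drop} after remapping b={keep_low:g}",
            stacklevel=2,
        )
        keep_idx = np.concatenate(
            [new_scheme.b0_indices]
            + [new_scheme.shells[b] for b in new_scheme.shell_bvalues if b not in drop]
        )
        keep_idx = np.sort(keep_idx)
        remapped = remapped[..., keep_idx]
        new_scheme = new_scheme.subset(keep_idx)
    return remapped, new_scheme


def normalize_signal(
    signal: np.ndarray, scheme: GradientScheme, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Divide a 4-D volume voxelwise by the mean b0 signal.

    Returns ``(normalized, s0_map, valid)`` where ``valid`` marks voxels with
    a positive S0 (others are excluded and zero-filled).  Normalized values
    are clipped to [1e-6, 1.5].
    """
    signal = np.asarray(signal, dtype=float)
    if len(scheme.b0_indices) < 1:
        raise ValueError("need at least one b0 volume to normalize")
    s0 = signal[..., scheme.b0_indices].mean(axis=-1)
    valid = s0 > 0
    if mask is not None:
        valid &= mask.astype(bool)
    safe = np.where(valid, s0, 1.0)
    out = np.clip(signal / safe[..., None], *_NORM_CLIP)
    out[~valid] = 0.0
    return out, s0, valid
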