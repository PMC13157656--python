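"""Free-water elimination of the DWI signal.

Given an estimated fraction map, the free-water compartment's contribution
is subtracted measurement-wise:

    S_hat_i = S_i - S0 * f * exp(-b_i * D_iso),

leaving (for an exact bi-tensor voxel) the pure tissue signal
S0 * (1 - f) * exp(-b_i g_i^T D g_i).  At b = 0 this convention gives
S_hat_0 = S0 * (1 - f); downstream tensor fits on corrected data use that
corrected b0, which keeps the normalization self-consistent.  Negative
values (possible under magnitude noise) are floored at zero and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gradients import GradientScheme, write_gradients
from .phantom import FREE_WATER_DIFFUSIVITY

__all__ = ["CorrectedDWI", "eliminate_free_water"]


@dataclass
class CorrectedDWI:
    """Free-water-eliminated 4-D signal plus bookkeeping."""

    signal_hat: np.ndarray
    scheme: GradientScheme
    f_used: np.ndarray
    floor_count: int

    def save(self, prefix: str | Path) -> None:
        import nibabel as nib

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        aff = np.eye(4)
        nib.save(nib.Nifti1Image(self.signal_hat.astype(np.float32), aff), f"{prefix}_corrected.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(self.f_used, dtype=np.float32), aff), f"{prefix}_fw.nii.gz")
        write_gradients(self.scheme, f"{prefix}.bval", f"{prefix}.bvec")


def eliminate_free_water(
    signal: np.ndarray,
    s0: np.ndarray | float,
    f: np.ndarray,
    scheme: GradientScheme,
    d_iso: float = FREE_WATER_DIFFUSIVITY,
) -> CorrectedDWI:
    """Subtract the isotropic free-water signal from every measurement.

    ``signal`` has trailing measurement axis matching ``scheme``; ``s0`` and
    ``f`` broadcast over the leading (spatial) axes.  f must lie in [0, 1].
    """
    signal = np.asarray(signal, dtype=float)
    f = np.asarray(f, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if signal.shape[-1] != len(scheme):
        raise ValueError(
            f"signal measurement axis {signal.shape[-1]} != scheme length {len(scheme)}"
        )
    if f.shape != signal.shape[:-1]:
        raise ValueError(f"fraction map shape {f.shape} vs signal {signal.shape[:-1]}")
    if f.min() < 0 or f.max() > 1:
        raise ValueError("fractions must lie in [0, 1]")
    water = np.exp(-scheme.bvals * d_iso)  # (N,)
    hat = signal - s0[..., None] * f[..., None] * water
    negatives = int((hat < 0).sum())
    np.maximum(hat, 0.0, out=hat)
    return CorrectedDWI(signal_hat=hat, scheme=scheme, f_used=f, floor_count=negatives)
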