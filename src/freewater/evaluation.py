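"""Estimator and correction quality metrics.

Covers the four evaluation views used throughout: fraction RMSE against a
reference map, FA/MD statistics in a centered cubic region of interest
(before vs after correction), whole-volume FA/MD histograms, and scan-rescan
reproducibility expressed as per-region percentage differences

    100 * |mean_scan - mean_rescan| / ((mean_scan + mean_rescan) / 2),

absolute by convention and with the symmetric session-mean denominator
(configurable to the first-session value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalReport",
    "rmse_fraction",
    "roi_patch_stats",
    "metric_histogram",
    "retest_percent_diff",
]

FA_HIST_RANGE = (0.0, 1.0)
MD_HIST_RANGE = (0.0, 3.5e-3)
N_HIST_BINS = 100


@dataclass
class EvalReport:
    """Bundle of evaluation outputs, JSON-serializable."""

    rmse_f: float | None = None
    roi_stats: dict = field(default_factory=dict)
    histograms: dict = field(default_factory=dict)
    retest: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "rmse_f": self.rmse_f,
                    "roi_stats": self.roi_stats,
                    "histograms": self.histograms,
                    "retest": self.retest,
                },
                fh,
                indent=2,
            )


def rmse_fraction(
    estimate: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Root-mean-square error between fraction maps over masked voxels."""
    estimate = np.asarray(estimate, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if estimate.shape != reference.shape:
        raise ValueError("shape mismatch between estimate and reference")
    if mask is None:
        mask = np.ones(estimate.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    diff = estimate[mask] - reference[mask]
    return float(np.sqrt(np.mean(diff**2)))


def _center_patch_slices(shape, edge: int):
    out = []
    for s in shape:
        if edge > s:
            warnings.warn(f"patch edge {edge} clipped to volume extent {s}", stacklevel=3)
        e = min(edge, s)
        start = (s - e) // 2
        out.append(slice(start, start + e))
    return tuple(out)


def roi_patch_stats(
    fa_map: np.ndarray,
    md_map: np.ndarray,
    patch_edge: int = 50,
    mask: np.ndarray | None = None,
) -> dict:
    """Mean ± sd of FA and MD in a centered cubic patch.

    The patch is clipped (with a warning) if it exceeds the volume; an ROI
    entirely outside the mask is an error.  Returns
    ``{"FA": {"mean": ., "sd": .}, "MD": {...}, "n_voxels": .}``.
    """
    fa_map = np.asarray(fa_map, dtype=float)
    md_map = np.asarray(md_map, dtype=float)
    sl = _center_patch_slices(fa_map.shape, patch_edge)
    sel = np.zeros(fa_map.shape, dtype=bool)
    sel[sl] = True
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if not sel.any():
        raise ValueError("ROI patch lies entirely outside the mask")
    out = {"n_voxels": int(sel.sum())}
    for name, vol in (("FA", fa_map), ("MD", md_map)):
        vals = vol[sel]
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std())}
    return out


def metric_histogram(values: np.ndarray, mask: np.ndarray, metric: str = "FA") -> dict:
    """Binned counts of a scalar metric over masked voxels (100 bins)."""
    rng = FA_HIST_RANGE if metric.upper() == "FA" else MD_HIST_RANGE
    vals = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
    counts, edges = np.histogram(np.clip(vals, *rng), bins=N_HIST_BINS, range=rng)
    return {"counts": counts.tolist(), "edges": edges.tolist()}


def retest_percent_diff(
    metric_scan: np.ndarray,
    metric_rescan: np.ndarray,
    region_masks: dict[str, np.ndarray],
    denominator: str = "session_mean",
) -> dict[str, float]:
    """Scan-rescan percentage difference of a metric per region.

    Regions are intersected across sessions implicitly (masks are assumed
    aligned; empty regions are skipped with a warning).  The percentage is
    absolute; ``denominator`` chooses the symmetric session mean (default)
    or the first-session mean.
    """
    out: dict[str, float] = {}
    for name, m in region_masks.items():
        m = np.asarray(m, dtype=bool)
        if not m.any():
            warnings.warn(f"region {name!r} empty; skipped", stacklevel=2)
            continue
        a = float(np.asarray(metric_scan, dtype=float)[m].mean())
        b = float(np.asarray(metric_rescan, dtype=float)[m].mean())
        denom = (a + b) / 2.0 if denominator == "session_mean" else a
        if denom == 0:
            warnings.warn(f"region {name!r} has zero denominator; skipped", stacklevel=2)
            continue
        out[name] = 100.0 * abs(a - b) / abs(denom)
    return out
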