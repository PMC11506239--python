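"""Cross-modal activation overlap: Dice percent overlap and peak distance.

The percent overlap of activation between two thresholded maps k and m is

    omega = 2 * V_km / (V_k + V_m)

with V_k, V_m the activated voxel counts and V_km the count activated in
both — the Dice similarity coefficient, 0 (no overlap) to 1 (perfect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OverlapReport", "dice", "peak_distance"]


@dataclass
class OverlapReport:
    v_k: int
    v_m: int
    v_km: int
    omega: float
    both_empty: bool = False


def dice(mask_k: np.ndarray, mask_m: np.ndarray) -> OverlapReport:
    """Exact set counts and the percent-overlap coefficient omega.

    When both masks are empty omega is defined as 0 and flagged.
    """
    a = np.asarray(mask_k, dtype=bool)
    b = np.asarray(mask_m, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    v_k = int(a.sum())
    v_m = int(b.sum())
    v_km = int((a & b).sum())
    if v_k + v_m == 0:
        return OverlapReport(0, 0, 0, 0.0, both_empty=True)
    return OverlapReport(v_k, v_m, v_km, 2.0 * v_km / (v_k + v_m))


def peak_distance(
    t_map_a: np.ndarray,
    t_map_b: np.ndarray,
    roi_mask: np.ndarray,
    voxel_size=(1.0, 1.0, 1.0),
) -> tuple[float, np.ndarray, np.ndarray]:
    """Euclidean mm distance between within-ROI peak-t voxel centres.

    Ties break at the lowest linear voxel index; returns
    (distance_mm, peak_a_mm, peak_b_mm).
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    vs = np.asarray(voxel_size, dtype=float)
    peaks = []
    for t_map in (t_map_a, t_map_b):
        vals = np.where(roi, np.asarray(t_map, dtype=float), -np.inf)
        if not np.any(np.isfinite(vals[roi])):
            raise ValueError("ROI contains no finite values")
        idx = np.unravel_index(int(np.nanargmax(vals)), vals.shape)
        peaks.append(np.asarray(idx, dtype=float) * vs)
    dist = float(np.sqrt(np.sum((peaks[0] - peaks[1]) ** 2)))
    return dist, peaks[0], peaks[1]
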