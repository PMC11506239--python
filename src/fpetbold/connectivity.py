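"""Seed-based functional (BOLD) and molecular (fPET) connectivity.

Connectivity is the Pearson correlation between the seed region's mean
time course and every voxel's course, computed separately on stimulation
("ogs") and rest ("baseline") frame windows after per-voxel linear
detrending of the selected frames, and Fisher z-transformed.  The group
contrast is a paired one-sample t on per-subject z-map differences with
permutation cluster correction.

For fPET the correlation is computed on residuals of the uptake model
(the baseline-course fit removed); the task ramp is linear in cumulative
stimulation time, so the within-condition detrend removes it and the
contrast isolates genuinely shared fluctuations rather than the common
deterministic uptake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import ClusterTable, cluster_inference
from .protocol import StimulationProtocol, FrameTiming, boxcar
from .series import FrameSeries

__all__ = [
    "ConnectivityMap",
    "condition_windows",
    "remove_global_course",
    "seed_connectivity",
    "connectivity_contrast",
]

_R_CAP = 1.0 - 1e-7  # keeps Fisher z finite for (near-)perfect correlation


@dataclass
class ConnectivityMap:
    r_map: np.ndarray   # 3D correlation volume
    z_map: np.ndarray   # Fisher-transformed
    condition: str
    seed_course: np.ndarray


def condition_windows(
    protocol: StimulationProtocol, timing: FrameTiming, equalize: bool = True
) -> dict[str, np.ndarray]:
    """Frame indices per condition: stimulation blocks vs inter-block rests.

    With ``equalize`` the larger set is truncated (from the end) to the
    smaller set's count so both correlations use equally many frames.
    """
    stim = boxcar(protocol, timing) > 0
    t = timing.frame_centers
    rest = np.zeros(timing.n_frames, dtype=bool)
    for b in range(1, protocol.n_blocks):
        r0 = protocol.block_start(b) + protocol.block_duration
        rest |= (t >= r0) & (t < r0 + protocol.rest_duration)
    ogs_idx = np.flatnonzero(stim)
    rest_idx = np.flatnonzero(rest)
    if equalize:
        n = min(ogs_idx.size, rest_idx.size)
        ogs_idx, rest_idx = ogs_idx[:n], rest_idx[:n]
    return {"ogs": ogs_idx, "baseline": rest_idx}


def remove_global_course(
    series: FrameSeries, courses: np.ndarray | None = None
) -> FrameSeries:
    """Residualize every voxel on nuisance course(s) plus an intercept.

    By default the nuisance is the in-mask global mean course.  For fPET
    this removes the shared uptake curve (and scanner-wide fluctuations)
    that would otherwise correlate every voxel with every seed; the
    stimulation-locked shared fluctuations of interest survive because
    they are regional, not global.
    """
    y = series.in_mask()
    if courses is None:
        courses = y.mean(axis=0)
    courses = np.atleast_2d(np.asarray(courses, dtype=float))
    X = np.column_stack([courses.T, np.ones(series.n_frames)])
    beta = np.linalg.lstsq(X, y.T, rcond=None)[0]
    out = np.zeros_like(series.data)
    out[series.brain_mask] = y - (X @ beta).T
    return series.with_data(out)


def _detrend(y: np.ndarray) -> np.ndarray:
    n = y.shape[-1]
    X = np.column_stack([np.arange(n, dtype=float), np.ones(n)])
    beta = np.linalg.lstsq(X, y.T, rcond=None)[0]
    return y - (X @ beta).T


def seed_connectivity(
    series: FrameSeries,
    seed_mask: np.ndarray,
    window: np.ndarray,
    condition: str = "ogs",
) -> ConnectivityMap:
    """Seed-to-voxel correlation over one condition's frames (Fisher z)."""
    window = np.asarray(window)
    if window.size < 8:
        raise ValueError("need at least 8 frames per condition window")
    seed = np.asarray(seed_mask, dtype=bool) & series.brain_mask
    if not seed.any():
        raise ValueError("seed region is empty")
    y = _detrend(series.data[series.brain_mask][:, window])
    raw_seed = series.data[seed][:, window].mean(axis=0)
    seed_course = _detrend(raw_seed[None, :])[0]
    s_sd = seed_course.std()
    if s_sd <= 1e-12 * (np.abs(raw_seed).max() + 1.0):
        raise ValueError("constant seed course in this window")
    s = (seed_course - seed_course.mean()) / s_sd
    y_sd = y.std(axis=1)
    yc = y - y.mean(axis=1, keepdims=True)
    r = np.zeros(y.shape[0])
    np.divide(yc @ s / window.size, y_sd, out=r, where=y_sd > 0)
    r = np.clip(r, -_R_CAP, _R_CAP)
    r_vol = np.zeros(series.shape)
    r_vol[series.brain_mask] = r
    return ConnectivityMap(r_vol, np.arctanh(r_vol), condition, seed_course)


def connectivity_contrast(
    maps_per_subject: list[dict[str, ConnectivityMap]],
    mask: np.ndarray,
    contrast: tuple[str, str] = ("ogs", "baseline"),
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ClusterTable:
    """Paired condition contrast on Fisher z maps with cluster correction.

    Each subject contributes z(first) − z(second); the stack goes through
    a sign-flip one-sample permutation test.  Swapping the contrast order
    mirrors the t map (antisymmetry of the paired difference).
    """
    if len(maps_per_subject) < 3:
        raise ValueError("need at least 3 subjects for the paired contrast")
    diffs = []
    for m in maps_per_subject:
        if contrast[0] not in m or contrast[1] not in m:
            raise ValueError("unpaired condition maps for at least one subject")
        diffs.append(m[contrast[0]].z_map - m[contrast[1]].z_map)
    return cluster_inference(
        np.stack(diffs), mask, kind="one_sample",
        voxel_p=voxel_p, alpha=alpha, n_perm=n_perm, seed=seed,
        voxel_size=voxel_size,
    )
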