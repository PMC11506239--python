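"""Voxelwise general linear model and permutation group inference.

The first-level model is ordinary least squares per voxel:

    y_v = X b_v + e_v,    t = c'b / sqrt(s^2 c'(X'X)^{-1} c)

For fPET the design holds a ramp regressor (cumulative stimulation frames,
modelling task-attributable tracer uptake) and a baseline regressor (the
gray-matter mean time course, excluding voxels declared activated, which
captures the shared uptake curve).  For BOLD it holds the HRF-convolved
block regressor plus an intercept; the inter-block baseline is the implicit
reference of the OGS > baseline contrast.

Group inference is permutation based: voxel threshold P < 0.001 on the
group t map, clusters formed with 26-connectivity, and family-wise error
control from the permutation distribution of the maximum cluster size
(sign flips for one-sample designs, group-label shuffles for two-sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats

from .phantom import RegionAtlas
from .series import FrameSeries
from .protocol import StimulationProtocol, FrameTiming, ramp_regressor, boxcar, hrf_convolve

__all__ = [
    "DesignMatrix",
    "VoxelGLM",
    "VoxelGLMResults",
    "ClusterTable",
    "fpet_baseline_regressor",
    "fpet_design",
    "bold_design",
    "fit_glm",
    "group_ttest",
    "cluster_inference",
    "region_summary",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)  # 26-neighbour connectivity


@dataclass(frozen=True)
class DesignMatrix:
    """Frames-by-regressors design with column names."""

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "names", tuple(self.names))
        if m.ndim != 2 or m.shape[1] != len(self.names):
            raise ValueError("matrix columns must match names")
        if not np.all(np.isfinite(m)):
            raise ValueError("design contains non-finite entries")
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def contrast(self, name: str) -> np.ndarray:
        c = np.zeros(len(self.names))
        c[self.names.index(name)] = 1.0
        return c


def fpet_baseline_regressor(
    series: FrameSeries,
    gm_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gray-matter mean time course, excluding activated voxels.

    The exclusion mask (typically the thresholded activation map of the
    companion modality, or an a-priori mask) guards against the task effect
    contaminating the baseline regressor.
    """
    keep = np.asarray(gm_mask, dtype=bool) & series.brain_mask
    if exclusion_mask is not None:
        keep &= ~np.asarray(exclusion_mask, dtype=bool)
    if not keep.any():
        raise ValueError("no gray-matter voxels left after exclusion")
    return series.data[keep].mean(axis=0)


def fpet_design(
    protocol: StimulationProtocol, timing: FrameTiming, baseline: np.ndarray
) -> DesignMatrix:
    """Design with the task ramp, the empirical baseline course and an
    intercept (the two-regressor uptake model plus offset)."""
    ramp = ramp_regressor(protocol, timing)
    return DesignMatrix(
        np.column_stack([ramp, np.asarray(baseline, float), np.ones(timing.n_frames)]),
        ("ramp", "baseline", "intercept"),
    )


def bold_design(protocol: StimulationProtocol, timing: FrameTiming,
                granularity: str = "block") -> DesignMatrix:
    """HRF-convolved task regressor plus intercept for the BOLD model."""
    task = hrf_convolve(boxcar(protocol, timing, granularity=granularity), timing)
    return DesignMatrix(
        np.column_stack([task, np.ones(timing.n_frames)]), ("task", "intercept")
    )


class VoxelGLM:
    """Massively univariate OLS model for a masked 4D series.

    Parameters
    ----------
    series : FrameSeries or (n_voxels, n_frames) array
    design : DesignMatrix

    ``fit()`` returns a :class:`VoxelGLMResults`.
    """

    def __init__(self, series: FrameSeries | np.ndarray, design: DesignMatrix):
        if isinstance(series, FrameSeries):
            self._series = series
            self.endog = series.in_mask()
        else:
            self._series = None
            self.endog = np.asarray(series, dtype=float)
        if self.endog.shape[1] != design.n_frames:
            raise ValueError("design rows must equal number of frames")
        self.design = design

    def fit(self) -> "VoxelGLMResults":
        X = self.design.matrix
        Y = self.endog.T  # frames x voxels
        xtx_inv = np.linalg.inv(X.T @ X)
        betas = xtx_inv @ X.T @ Y  # regressors x voxels
        resid = Y - X @ betas
        dof = X.shape[0] - X.shape[1]
        sigma2 = np.sum(resid**2, axis=0) / dof
        return VoxelGLMResults(self, betas.T, sigma2, dof, xtx_inv)


@dataclass
class VoxelGLMResults:
    """Per-voxel OLS estimates with contrast t maps and a summary table."""

    model: VoxelGLM
    betas: np.ndarray  # voxels x regressors
    residual_variance: np.ndarray
    dof: int
    _xtx_inv: np.ndarray

    def t_values(self, contrast) -> np.ndarray:
        """t statistic of contrast c'b per voxel (0 where variance is 0)."""
        if isinstance(contrast, str):
            contrast = self.model.design.contrast(contrast)
        c = np.asarray(contrast, dtype=float)
        eff = self.betas @ c
        var = self.residual_variance * float(c @ self._xtx_inv @ c)
        t = np.zeros_like(eff)
        np.divide(eff, np.sqrt(var), out=t, where=var > 0)
        return t

    def beta_map(self, name: str) -> np.ndarray:
        """3D volume of the named regressor's coefficients (needs a series)."""
        return self._to_volume(self.betas[:, self.model.design.names.index(name)])

    def t_map(self, contrast) -> np.ndarray:
        return self._to_volume(self.t_values(contrast))

    def _to_volume(self, values: np.ndarray) -> np.ndarray:
        series = self.model._series
        if series is None:
            return values
        vol = np.zeros(series.shape)
        vol[series.brain_mask] = values
        return vol

    def plot_fit(self, voxel: int, ax=None):
        """Observed vs fitted time course for one (in-mask) voxel index."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model.endog[voxel]
        yhat = self.model.design.matrix @ self.betas[voxel]
        ax.plot(y, ".", label="observed", alpha=0.6)
        ax.plot(yhat, "-", label="fitted")
        ax.set_xlabel("frame")
        ax.set_ylabel("signal")
        ax.legend()
        return ax

    def summary(self) -> pd.DataFrame:
        """Median coefficient / t per regressor across voxels."""
        rows = []
        for j, name in enumerate(self.model.design.names):
            c = np.zeros(len(self.model.design.names))
            c[j] = 1.0
            t = self.t_values(c)
            rows.append({
                "regressor": name,
                "beta_median": float(np.median(self.betas[:, j])),
                "t_median": float(np.median(t)),
                "dof": self.dof,
            })
        return pd.DataFrame(rows)


def fit_glm(series: FrameSeries | np.ndarray, design: DesignMatrix
            ) -> VoxelGLMResults:
    """Convenience wrapper: ``VoxelGLM(series, design).fit()``."""
    return VoxelGLM(series, design).fit()


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    np.divide(mean * np.sqrt(n), sd, out=t, where=sd > 0)
    return t


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1 / na + 1 / nb))
    t = np.zeros_like(denom)
    np.divide(a.mean(axis=0) - b.mean(axis=0), denom, out=t, where=denom > 0)
    return t


def group_ttest(
    beta_maps: np.ndarray,
    kind: str = "one_sample",
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Voxelwise group t map from stacked subject maps (subjects first axis).

    ``kind='one_sample'`` tests the mean against 0; ``'two_sample'`` is a
    pooled-variance two-group comparison with labels in ``groups``.
    """
    maps = np.asarray(beta_maps, dtype=float)
    if kind == "one_sample":
        if maps.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        return _one_sample_t(maps)
    if kind == "two_sample":
        groups = np.asarray(groups)
        labels = np.unique(groups)
        if labels.size != 2:
            raise ValueError("two_sample requires exactly two group labels")
        a, b = maps[groups == labels[0]], maps[groups == labels[1]]
        if min(a.shape[0], b.shape[0]) < 2:
            raise ValueError("need at least 2 subjects per group")
        return _two_sample_t(a, b)
    raise ValueError(f"unknown kind {kind!r}")


@dataclass
class ClusterTable:
    """Supra-threshold clusters with permutation-corrected p values."""

    clusters: pd.DataFrame
    voxel_threshold_p: float
    cluster_alpha: float
    t_threshold: float
    label_volume: np.ndarray = field(repr=False, default=None)
    t_map: np.ndarray = field(repr=False, default=None)

    def significant_mask(self) -> np.ndarray:
        mask = np.zeros(self.label_volume.shape, dtype=bool)
        for _, row in self.clusters.iterrows():
            if row["p_corrected"] <= self.cluster_alpha:
                mask |= self.label_volume == row["label"]
        return mask

    @property
    def n_significant(self) -> int:
        return int((self.clusters["p_corrected"] <= self.cluster_alpha).sum())


def _cluster_sizes(sup: np.ndarray) -> tuple[np.ndarray, int]:
    labels, n = ndimage.label(sup, structure=_STRUCT26)
    return labels, n


def _max_cluster_size(sup: np.ndarray) -> int:
    labels, n = _cluster_sizes(sup)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(np.ones_like(labels), labels,
                                         index=np.arange(1, n + 1))))


def cluster_inference(
    subject_maps: np.ndarray,
    mask: np.ndarray,
    kind: str = "one_sample",
    groups: np.ndarray | None = None,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    two_sided: bool = False,
) -> ClusterTable:
    """Cluster-level FWE inference by max-cluster-size permutation.

    ``subject_maps`` is (subjects, x, y, z); the group t map is thresholded
    at the one-sided ``voxel_p`` quantile of the t distribution, clusters
    are formed with 26-connectivity, and each observed cluster's corrected
    p is (1 + #{null max size >= observed}) / (1 + n_perm), with the null
    built from sign flips (one-sample) or label shuffles (two-sample).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 for FWE calibration")
    maps4d = np.asarray(subject_maps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n_sub = maps4d.shape[0]
    flat = maps4d[:, mask]  # subjects x voxels

    if kind == "one_sample":
        dof = n_sub - 1
        t_obs = _one_sample_t(flat)
    elif kind == "two_sample":
        groups = np.asarray(groups)
        labels = np.unique(groups)
        dof = n_sub - 2
        t_obs = _two_sample_t(flat[groups == labels[0]], flat[groups == labels[1]])
    else:
        raise ValueError(f"unknown kind {kind!r}")

    t_crit = stats.t.ppf(1 - (voxel_p / 2 if two_sided else voxel_p), dof)

    def suprathreshold(tvals: np.ndarray) -> np.ndarray:
        vol = np.zeros(mask.shape, dtype=bool)
        vol[mask] = (np.abs(tvals) if two_sided else tvals) > t_crit
        return vol

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    for p in range(n_perm):
        if kind == "one_sample":
            signs = rng.choice([-1.0, 1.0], size=(n_sub, 1))
            t_null = _one_sample_t(flat * signs)
        else:
            perm = rng.permutation(n_sub)
            g = groups[perm]
            t_null = _two_sample_t(flat[g == labels[0]], flat[g == labels[1]])
        null_max[p] = _max_cluster_size(suprathreshold(t_null))

    sup_obs = suprathreshold(t_obs)
    label_vol, n_clusters = _cluster_sizes(sup_obs)
    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t_obs
    rows = []
    vs = np.asarray(voxel_size, dtype=float)
    for lab in range(1, n_clusters + 1):
        members = label_vol == lab
        size = int(members.sum())
        tv = np.where(members, np.abs(t_vol) if two_sided else t_vol, -np.inf)
        peak_flat = int(np.argmax(tv))  # argmax takes the lowest linear index on ties
        peak_idx = np.unravel_index(peak_flat, mask.shape)
        p_corr = (1 + int(np.sum(null_max >= size))) / (1 + n_perm)
        rows.append({
            "label": lab,
            "size_voxels": size,
            "peak_t": float(t_vol[peak_idx]),
            "peak_x_mm": peak_idx[0] * vs[0],
            "peak_y_mm": peak_idx[1] * vs[1],
            "peak_z_mm": peak_idx[2] * vs[2],
            "p_corrected": p_corr,
        })
    table = pd.DataFrame(
        rows, columns=["label", "size_voxels", "peak_t", "peak_x_mm",
                       "peak_y_mm", "peak_z_mm", "p_corrected"]
    )
    if len(table):
        table = table.sort_values("size_voxels", ascending=False).reset_index(drop=True)
    return ClusterTable(table, voxel_p, alpha, float(t_crit), label_vol, t_vol)


def region_summary(
    t_map: np.ndarray, significant_mask: np.ndarray, atlas: RegionAtlas
) -> pd.DataFrame:
    """Per-region percentage of significant voxels and their mean t.

    Mirrors the activation-table layout: one row per atlas region with the
    fraction (in %) of its voxels inside the significant mask and the mean
    t over that intersection (0 when the intersection is empty).
    """
    sig = np.asarray(significant_mask, dtype=bool)
    rows = []
    for rid, (name, hemi) in atlas.region_table.items():
        region = atlas.label_volume == rid
        inter = region & sig
        n_region = int(region.sum())
        n_sig = int(inter.sum())
        rows.append({
            "region": name,
            "hemisphere": hemi,
            "n_voxels": n_region,
            "pct_significant": 100.0 * n_sig / n_region,
            "mean_t": float(t_map[inter].mean()) if n_sig else 0.0,
        })
    return pd.DataFrame(rows)
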