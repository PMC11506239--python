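"""Group spatial ICA of relative-uptake fPET data with kurtosis sorting.

Pipeline: whole-brain-normalized subject series are each reduced by PCA
retaining at least 99% of their variance, temporally concatenated, reduced
again to the target component count, whitened, and unmixed with FastICA.
Component spatial maps are z-scored, and four descriptive measures are
computed per component:

* kurtosis — excess (Fisher) kurtosis of in-mask map values; spatially
  sparse (task-like) components score high, which is what makes automatic
  kurtosis sorting pick out the stimulation component first;
* skewness — third standardized moment;
* variability — RMS distance of supra-threshold (|z| > 2) voxels from
  their own centroid divided by the RMS distance of all in-mask voxels
  from the mask centroid (small = focal, near 1 = widespread);
* frequency — spectral centre of mass of the mixing time course's
  periodogram, in cycles per frame (task components are slow).

Subject-level maps are recovered by dual regression (regressing each
subject's data on the group spatial maps) and passed to the permutation
cluster inference of :mod:`fpetbold.glm`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.decomposition import PCA, FastICA

from .glm import ClusterTable, cluster_inference
from .series import FrameSeries

__all__ = [
    "ICADecomposition",
    "ComponentMetrics",
    "reduce_and_whiten",
    "run_fastica",
    "group_ica",
    "component_metrics",
    "metrics_table",
    "rank_components",
    "back_reconstruct",
    "component_group_map",
]


@dataclass
class ICADecomposition:
    """Group ICA result: z-scored spatial maps and a group mixing course."""

    spatial_maps: np.ndarray      # components x in-mask voxels, z-scored
    mixing: np.ndarray            # frames x components (mean over subjects)
    n_components: int
    variance_retained: float
    mask: np.ndarray              # 3D boolean grid
    frame_duration: float
    converged: bool = True

    def map_volume(self, component: int) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.spatial_maps[component]
        return vol


@dataclass
class ComponentMetrics:
    kurtosis: float
    skewness: float
    variability: float
    frequency: float
    variability_defined: bool = True


def reduce_and_whiten(
    series_list: list[FrameSeries], variance: float = 0.99
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject PCA (>= ``variance`` retained) + temporal concatenation.

    Returns ``(concatenated, retained)`` where ``concatenated`` stacks each
    subject's whitened principal spatial rows (components x voxels) along
    the first axis and ``retained`` holds per-subject variance fractions.
    """
    if not series_list:
        raise ValueError("need at least one subject series")
    blocks, retained = [], []
    for s in series_list:
        y = s.in_mask().T  # frames x voxels
        y = y - y.mean(axis=0, keepdims=True)
        if np.allclose(y, 0):
            raise ValueError("degenerate (constant) subject data")
        pca = PCA(n_components=variance, svd_solver="full", whiten=False)
        pca.fit(y.T)  # samples = voxels, features = frames
        # whitened spatial rows: principal voxel-space directions
        scores = pca.transform(y.T).T  # components x voxels
        scores /= scores.std(axis=1, keepdims=True)
        blocks.append(scores)
        retained.append(float(pca.explained_variance_ratio_.sum()))
    return np.vstack(blocks), np.asarray(retained)


def run_fastica(
    reduced: np.ndarray,
    n_components: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """FastICA (logcosh contrast) on reduced (rows x voxels) data.

    Returns ``(sources, unmixing_applied, converged)`` where ``sources`` is
    components x voxels.  Non-convergence is flagged, not raised: the
    partial result is still usable for ranking.
    """
    reduced = np.asarray(reduced, dtype=float)
    rank = np.linalg.matrix_rank(reduced)
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds data rank {rank}"
        )
    import warnings

    ica = FastICA(
        n_components=n_components, fun="logcosh", max_iter=max_iter,
        tol=tol, random_state=seed, whiten="unit-variance",
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(reduced.T).T  # components x voxels
        for w in caught:
            if "did not converge" in str(w.message):
                converged = False
    return sources, ica.mixing_, converged


def group_ica(
    series_list: list[FrameSeries],
    n_components: int = 20,
    seed: int = 0,
    variance: float = 0.99,
) -> ICADecomposition:
    """Temporal-concatenation group spatial ICA with z-scored maps."""
    concatenated, retained = reduce_and_whiten(series_list, variance=variance)
    n_components = min(n_components, np.linalg.matrix_rank(concatenated))
    sources, _, converged = run_fastica(concatenated, n_components, seed=seed)
    # z-score maps in-mask; canonical sign: positive skewness, so a sparse
    # task component loads positively (ICA sign is otherwise arbitrary)
    maps = (sources - sources.mean(axis=1, keepdims=True))
    maps /= maps.std(axis=1, keepdims=True)
    flip = np.where(stats.skew(maps, axis=1) < 0, -1.0, 1.0)
    maps *= flip[:, None]
    mask = series_list[0].brain_mask
    # group mixing: mean over subjects of dual-regression time courses
    mixing = np.mean(
        [_dual_regression_timecourses(s, maps) for s in series_list], axis=0
    )
    return ICADecomposition(
        spatial_maps=maps,
        mixing=mixing,
        n_components=n_components,
        variance_retained=float(retained.min()),
        mask=mask,
        frame_duration=series_list[0].timing.frame_duration,
        converged=converged,
    )


def _dual_regression_timecourses(series: FrameSeries, maps: np.ndarray
                                 ) -> np.ndarray:
    """Frames x components course: LS regression of data on spatial maps."""
    y = series.in_mask().T  # frames x voxels
    y = y - y.mean(axis=0, keepdims=True)
    return y @ np.linalg.pinv(maps)


def component_metrics(
    decomposition: ICADecomposition, component: int, z_threshold: float = 2.0
) -> ComponentMetrics:
    """The four descriptive measures of one component (see module docs)."""
    z = decomposition.spatial_maps[component]
    kurt = float(stats.kurtosis(z, fisher=True, bias=True))
    skew = float(stats.skew(z, bias=True))

    coords = np.argwhere(decomposition.mask).astype(float)
    centroid_all = coords.mean(axis=0)
    rms_all = float(np.sqrt(np.mean(np.sum((coords - centroid_all) ** 2, axis=1))))
    supra = np.abs(z) > z_threshold
    if supra.any():
        c_sup = coords[supra]
        centroid_sup = c_sup.mean(axis=0)
        rms_sup = float(np.sqrt(np.mean(np.sum((c_sup - centroid_sup) ** 2, axis=1))))
        variability = rms_sup / rms_all
        defined = True
    else:
        variability = np.nan
        defined = False

    course = decomposition.mixing[:, component]
    freqs, power = signal.periodogram(course, fs=1.0)  # cycles per frame
    freqs, power = freqs[1:], power[1:]  # drop DC
    total = power.sum()
    frequency = float((freqs * power).sum() / total) if total > 0 else 0.0
    return ComponentMetrics(kurt, skew, variability, frequency, defined)


def metrics_table(decomposition: ICADecomposition) -> pd.DataFrame:
    """Table of the four measures for every component."""
    rows = []
    for k in range(decomposition.n_components):
        m = component_metrics(decomposition, k)
        rows.append({
            "component": k,
            "kurtosis": m.kurtosis,
            "skewness": m.skewness,
            "variability": m.variability,
            "frequency": m.frequency,
        })
    return pd.DataFrame(rows)


def rank_components(
    decomposition: ICADecomposition, by: str = "kurtosis"
) -> np.ndarray:
    """Component ordering: descending kurtosis or ascending frequency.

    Ties (and the all-Gaussian degenerate case) break by component index.
    Kurtosis is an even moment, so the ordering is invariant to map sign.
    """
    table = metrics_table(decomposition)
    if by == "kurtosis":
        key = -table["kurtosis"].to_numpy()
    elif by == "frequency":
        key = table["frequency"].to_numpy()
    else:
        raise ValueError(f"unknown ranking key {by!r}")
    return np.lexsort((table["component"].to_numpy(), key))


def back_reconstruct(
    decomposition: ICADecomposition,
    series_list: list[FrameSeries],
    component: int,
) -> np.ndarray:
    """Subject-specific spatial maps of one component by dual regression.

    Stage 1 regresses each subject's data on the group maps to get subject
    time courses; stage 2 regresses the data on those courses to get
    subject maps.  Returns (subjects, x, y, z).
    """
    out = []
    for s in series_list:
        y = s.in_mask().T
        y = y - y.mean(axis=0, keepdims=True)
        courses = _dual_regression_timecourses(s, decomposition.spatial_maps)
        maps = np.linalg.pinv(courses) @ y  # components x voxels
        vol = np.zeros(s.brain_mask.shape)
        vol[s.brain_mask] = maps[component]
        out.append(vol)
    return np.stack(out)


def component_group_map(
    decomposition: ICADecomposition,
    series_list: list[FrameSeries],
    component: int,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    t_cap: float = 1e6,
) -> ClusterTable:
    """One-sample group inference on a component's subject maps.

    The component's sign is aligned so its group-mean map loads positively
    (ICA sign is arbitrary); degenerate zero-variance voxels would give
    infinite t and are capped at ``t_cap``.
    """
    if len(series_list) < 2:
        raise ValueError("need at least 2 subjects")
    subject_maps = back_reconstruct(decomposition, series_list, component)
    mean_map = subject_maps.mean(axis=0)
    group_z = decomposition.map_volume(component)
    if np.sum(mean_map * group_z) < 0:
        subject_maps = -subject_maps
    table = cluster_inference(
        subject_maps, series_list[0].brain_mask,
        kind="one_sample", voxel_p=voxel_p, alpha=alpha,
        n_perm=n_perm, seed=seed,
        voxel_size=series_list[0].voxel_size,
    )
    np.clip(table.t_map, -t_cap, t_cap, out=table.t_map)
    return table
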