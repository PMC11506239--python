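"""Multivariate pattern analysis: stimulation vs baseline decoding.

Samples are per-block pattern summaries: for each stimulation block, one
"ogs" sample over the block's frames and one "baseline" sample over the
rest window immediately preceding it, after removal of each voxel's
baseline trend (for fPET, the global uptake slope would otherwise separate
late from early windows even in control animals).  Classification is a
regularized linear model under leave-one-subject-out cross-validation;
significance comes from permutation of condition labels within subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from .glm import DesignMatrix, fit_glm, _max_cluster_size, _cluster_sizes
from .protocol import StimulationProtocol, block_frame_indices
from .series import FrameSeries

__all__ = ["SampleSet", "MVPAResult", "build_samples", "roi_mvpa", "searchlight"]


@dataclass
class SampleSet:
    """Per-block feature maps with condition labels and subject ids."""

    feature_maps: np.ndarray   # samples x voxels
    labels: np.ndarray         # "ogs" | "baseline"
    subject_ids: np.ndarray
    mask: np.ndarray           # 3D boolean grid the voxel axis indexes
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        for sid in np.unique(self.subject_ids):
            sel = self.subject_ids == sid
            classes, counts = np.unique(self.labels[sel], return_counts=True)
            if classes.size != 2 or counts[0] != counts[1]:
                raise ValueError(f"labels not balanced within subject {sid!r}")
            if counts.min() < 2:
                raise ValueError(f"subject {sid!r} has fewer than 2 samples per class")

    def restrict(self, roi_mask: np.ndarray) -> np.ndarray:
        """Feature matrix restricted to an ROI (3D mask on the grid)."""
        roi = np.asarray(roi_mask, dtype=bool) & self.mask
        if not roi.any():
            raise ValueError("ROI is empty inside the sample mask")
        keep = roi[self.mask]
        return self.feature_maps[:, keep]


@dataclass
class MVPAResult:
    fold_accuracies: np.ndarray  # percent, one per held-out subject
    mean_accuracy: float         # percent
    null_distribution: np.ndarray | None
    p_value: float | None

    def summary(self) -> str:
        p = "n/a" if self.p_value is None else f"{self.p_value:.4g}"
        return (
            f"LOSO accuracy {self.mean_accuracy:.2f}% over "
            f"{self.fold_accuracies.size} folds (P = {p})"
        )


def _detrended_block_features(
    series: FrameSeries, protocol: StimulationProtocol, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block (ogs, baseline) feature maps for one subject.

    ``method='beta'`` fits per-voxel OLS with one indicator per block
    window plus a linear trend and intercept, taking the window betas as
    features; ``'mean'`` removes the voxelwise linear trend and averages
    the window frames.
    """
    timing = series.timing
    n = timing.n_frames
    windows = []  # (label, frame slice)
    rest_frames = max(int(round(protocol.rest_duration / timing.frame_duration)), 2)
    for b in range(1, protocol.n_blocks + 1):
        first, last = block_frame_indices(protocol, timing, b)
        if last - first + 1 < 2:
            raise ValueError(f"block {b} not covered by at least 2 frames")
        lo = first - 1 - rest_frames
        if lo < 0:
            raise ValueError(f"missing rest frames before block {b}")
        windows.append(("baseline", slice(lo, first - 1)))
        windows.append(("ogs", slice(first - 1, last)))

    y = series.in_mask()  # voxels x frames
    trend = np.column_stack([np.arange(n, dtype=float), np.ones(n)])
    if method == "mean":
        beta = np.linalg.lstsq(trend, y.T, rcond=None)[0]
        resid = y - (trend @ beta).T
        feats = np.stack([resid[:, w].mean(axis=1) for _, w in windows])
    elif method == "beta":
        indicators = np.zeros((n, len(windows)))
        for j, (_, w) in enumerate(windows):
            indicators[w, j] = 1.0
        X = np.column_stack([indicators, trend])
        names = tuple(f"w{j}" for j in range(len(windows))) + ("trend", "intercept")
        res = fit_glm(y, DesignMatrix(X, names))
        feats = res.betas[:, : len(windows)].T
    else:
        raise ValueError(f"unknown feature method {method!r}")
    # residual drift removal: the global detrend leaves a slow sawtooth
    # (the uptake ramp is piecewise, not linear), which varies across runs
    # far more than the condition difference within a run.  Model it as a
    # per-voxel line over the baseline-window features and subtract the
    # fitted line from every window; fitting on baseline windows only
    # avoids pairing ogs samples with their rest windows.
    labels = np.array([lab for lab, _ in windows])
    run_idx = np.repeat(np.arange(len(windows) // 2, dtype=float), 2)
    base_rows = labels == "baseline"
    Xb = np.column_stack([run_idx[base_rows], np.ones(base_rows.sum())])
    coef = np.linalg.lstsq(Xb, feats[base_rows], rcond=None)[0]
    feats = feats - np.column_stack([run_idx, np.ones(len(windows))]) @ coef
    return feats, labels


def build_samples(
    subjects: list[tuple[str, FrameSeries]],
    protocol: StimulationProtocol,
    method: str = "beta",
) -> SampleSet:
    """One ogs + one baseline sample per block per subject (see module docs)."""
    feats, labels, sids = [], [], []
    mask = subjects[0][1].brain_mask
    for sid, series in subjects:
        f, lab = _detrended_block_features(series, protocol, method)
        feats.append(f)
        labels.append(lab)
        sids.extend([sid] * len(lab))
    return SampleSet(
        np.vstack(feats), np.concatenate(labels), np.asarray(sids), mask,
        subjects[0][1].voxel_size,
    )


def _loso_accuracy(
    X: np.ndarray, y: np.ndarray, subject_ids: np.ndarray, C: float = 1.0
) -> np.ndarray:
    """Percent accuracy per held-out subject (L2 logistic regression).

    Features are standardized with training-fold statistics only.
    """
    sids = np.unique(subject_ids)
    if sids.size < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    accs = np.empty(sids.size)
    for i, sid in enumerate(sids):
        test = subject_ids == sid
        train = ~test
        if np.unique(y[train]).size < 2:
            raise ValueError("single-class training fold")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(C=C, max_iter=1000)
        clf.fit((X[train] - mu) / sd, y[train])
        accs[i] = 100.0 * clf.score((X[test] - mu) / sd, y[test])
    return accs


def _permute_within_subject(
    y: np.ndarray, subject_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = y.copy()
    for sid in np.unique(subject_ids):
        sel = np.flatnonzero(subject_ids == sid)
        out[sel] = y[sel[rng.permutation(sel.size)]]
    return out


def roi_mvpa(
    samples: SampleSet,
    roi_mask: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> MVPAResult:
    """LOSO decoding within an ROI with a within-subject permutation null.

    p = (1 + #{null mean accuracy >= observed}) / (1 + n_perm); with 1000
    permutations the smallest attainable p is 1/1001.
    """
    X = samples.restrict(roi_mask)
    y = samples.labels
    accs = _loso_accuracy(X, y, samples.subject_ids, C=C)
    observed = float(accs.mean())
    null = None
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for k in range(n_perm):
            y_perm = _permute_within_subject(y, samples.subject_ids, rng)
            null[k] = _loso_accuracy(X, y_perm, samples.subject_ids, C=C).mean()
        p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return MVPAResult(accs, observed, null, p)


def sphere_offsets(radius_mm: float, voxel_size) -> np.ndarray:
    """Voxel offsets within a sphere of the given radius (mm)."""
    vs = np.asarray(voxel_size, dtype=float)
    r_vox = np.maximum(np.floor(radius_mm / vs).astype(int), 0)
    grids = np.meshgrid(*(np.arange(-r, r + 1) for r in r_vox), indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    dist = np.sqrt(np.sum((offs * vs) ** 2, axis=1))
    return offs[dist <= radius_mm + 1e-9]


def _searchlight_map(
    samples: SampleSet, y: np.ndarray, neighbors: list[np.ndarray], C: float
) -> np.ndarray:
    accs = np.empty(len(neighbors))
    for v, cols in enumerate(neighbors):
        accs[v] = _loso_accuracy(
            samples.feature_maps[:, cols], y, samples.subject_ids, C=C
        ).mean()
    return accs


def searchlight(
    samples: SampleSet,
    radius_mm: float,
    n_perm: int = 100,
    seed: int = 0,
    accuracy_threshold: float = 65.0,
    alpha: float = 0.05,
    C: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Whole-brain searchlight LOSO decoding with cluster-level correction.

    Every in-mask voxel's spherical neighborhood is classified; voxels with
    accuracy above ``accuracy_threshold`` (%) form clusters whose size is
    compared against the permutation null of the maximum cluster size
    (labels shuffled within subject, full map recomputed per permutation).

    Returns (accuracy volume, significant-voxel volume, info dict).
    """
    mask = samples.mask
    coords = np.argwhere(mask)
    index_vol = -np.ones(mask.shape, dtype=int)
    index_vol[mask] = np.arange(coords.shape[0])
    offs = sphere_offsets(radius_mm, samples.voxel_size)
    if offs.shape[0] < 1:
        raise ValueError("searchlight radius smaller than one voxel")
    neighbors = []
    for c in coords:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < mask.shape), axis=1)
        idx = index_vol[tuple(pts[ok].T)]
        idx = idx[idx >= 0]
        if idx.size < 1:
            idx = np.array([index_vol[tuple(c)]])
        neighbors.append(idx)

    acc = _searchlight_map(samples, samples.labels, neighbors, C)
    acc_vol = np.zeros(mask.shape)
    acc_vol[mask] = acc

    sup = np.zeros(mask.shape, dtype=bool)
    sup[mask] = acc > accuracy_threshold
    labels_vol, n_clusters = _cluster_sizes(sup)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        y_perm = _permute_within_subject(samples.labels, samples.subject_ids, rng)
        a = _searchlight_map(samples, y_perm, neighbors, C)
        vol = np.zeros(mask.shape, dtype=bool)
        vol[mask] = a > accuracy_threshold
        null_max[k] = _max_cluster_size(vol)

    sig = np.zeros(mask.shape, dtype=bool)
    cluster_p = {}
    for lab in range(1, n_clusters + 1):
        size = int(np.sum(labels_vol == lab))
        p = (1 + int(np.sum(null_max >= size))) / (1 + n_perm)
        cluster_p[lab] = p
        if p <= alpha:
            sig |= labels_vol == lab
    info = {"cluster_p": cluster_p, "null_max": null_max,
            "threshold": accuracy_threshold}
    return acc_vol, sig, info
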