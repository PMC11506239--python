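"""Synthetic fPET/BOLD phantom cohorts with known ground truth.

The generator emulates the statistical structure the analyses assume:

* fPET — near-linear whole-brain FDG accumulation under bolus + constant
  infusion, with an extra uptake slope (a ramp) in stimulation-responsive
  regions of responsive ("ChR2") subjects only;
* BOLD — block responses built from an on-phase boxcar convolved with the
  canonical HRF, a post-stimulation overshoot transient at each block's
  termination, negative responses in contralateral regions via negative
  amplitudes, slow scanner drift (half-cosine) and i.i.d. Gaussian noise;
* an optional stimulation-locked latent signal shared between regions, to
  exercise the seed-based connectivity contrast.

Everything is seeded and deterministic: per-subject generators are spawned
from the cohort seed, so identical specs reproduce identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .protocol import FrameTiming, StimulationProtocol, boxcar, hrf_kernel
from .series import FrameSeries

__all__ = [
    "RegionAtlas",
    "PhantomSpec",
    "Cohort",
    "Subject",
    "make_atlas",
    "simulate_fpet",
    "simulate_bold",
    "simulate_cohort",
]

# fractional bounding boxes (x0, x1, y0, y1, z0, z1) on the unit grid;
# boxes are pairwise disjoint and all lie inside the brain envelope
_REGION_BOXES: dict[str, tuple[float, float, float, float, float, float]] = {
    "right_striatum": (0.56, 0.75, 0.31, 0.50, 0.38, 0.69),
    "left_striatum": (0.25, 0.44, 0.31, 0.50, 0.38, 0.69),
    "right_sn": (0.56, 0.75, 0.53, 0.72, 0.13, 0.44),
    "right_thalamus": (0.56, 0.75, 0.53, 0.72, 0.50, 0.88),
    "left_thalamus": (0.25, 0.44, 0.53, 0.72, 0.50, 0.88),
    "right_cortex": (0.56, 0.81, 0.15, 0.38, 0.75, 0.95),
    "left_cortex": (0.19, 0.44, 0.15, 0.38, 0.75, 0.95),
    "cerebellum": (0.38, 0.62, 0.78, 0.94, 0.31, 0.63),
    "gray_matter_other": (0.25, 0.75, 0.03, 0.13, 0.38, 0.75),
}

_HEMISPHERE = {
    "right_striatum": "R", "left_striatum": "L", "right_sn": "R",
    "right_thalamus": "R", "left_thalamus": "L", "right_cortex": "R",
    "left_cortex": "L", "cerebellum": "M", "gray_matter_other": "M",
}

#: regions counted as gray matter for the fPET baseline regressor
GRAY_MATTER_REGIONS = (
    "right_striatum", "left_striatum", "right_sn", "right_thalamus",
    "left_thalamus", "right_cortex", "left_cortex", "gray_matter_other",
)


@dataclass
class RegionAtlas:
    """Integer label volume plus a region lookup table.

    Label 0 is background; ``region_table`` maps id -> (name, hemisphere).
    """

    label_volume: np.ndarray
    voxel_size: tuple[float, float, float]
    region_table: dict[int, tuple[str, str]]

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.min() < 0:
            raise ValueError("labels must be non-negative")
        names = [n for n, _ in self.region_table.values()]
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")
        for rid, (name, _) in self.region_table.items():
            if not np.any(self.label_volume == rid):
                raise ValueError(f"region {name!r} (id {rid}) is empty")

    def id_of(self, name: str) -> int:
        for rid, (n, _) in self.region_table.items():
            if n == name:
                return rid
        raise KeyError(name)

    def mask(self, name: str) -> np.ndarray:
        return self.label_volume == self.id_of(name)

    def gray_matter_mask(self) -> np.ndarray:
        out = np.zeros(self.label_volume.shape, dtype=bool)
        for name in GRAY_MATTER_REGIONS:
            out |= self.mask(name)
        return out

    def brain_mask(self) -> np.ndarray:
        """Ellipsoidal brain envelope union of all labelled regions."""
        nx, ny, nz = self.label_volume.shape
        x, y, z = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
        r = (
            ((x - cx) / (0.48 * nx)) ** 2
            + ((y - cy) / (0.5 * ny)) ** 2
            + ((z - cz) / (0.5 * nz)) ** 2
        )
        return (r <= 1.0) | (self.label_volume > 0)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.region_table.values()]

    def to_nifti(self, path: str | Path) -> None:
        aff = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.label_volume.astype(np.int16), aff), str(path))

    def table_frame(self) -> pd.DataFrame:
        rows = [
            {"id": rid, "name": n, "hemisphere": h,
             "n_voxels": int(np.sum(self.label_volume == rid))}
            for rid, (n, h) in self.region_table.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class PhantomSpec:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    fPET intensities are in arbitrary kBq-like units with a whole-brain
    uptake slope of 1 per frame (matching the unit-slope ramp regressor);
    task slope increments are fractions of that slope in responsive
    regions.  BOLD amplitudes are fractional signal changes of a baseline
    of 100 (so 0.02 = a 2% response).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    protocol: StimulationProtocol = field(default_factory=StimulationProtocol)
    fdg_baseline_slope: float = 1.0
    fdg_task_slope_increment: dict[str, float] = field(
        default_factory=lambda: {
            "right_striatum": 0.10, "right_sn": 0.15, "right_thalamus": 0.08,
        }
    )
    bold_baseline: float = 100.0
    bold_on_amplitude: dict[str, float] = field(
        default_factory=lambda: {
            "right_striatum": 0.02, "right_thalamus": 0.01,
            "left_striatum": -0.01, "left_cortex": -0.01,
        }
    )
    bold_overshoot_amplitude: dict[str, float] = field(
        default_factory=lambda: {"right_striatum": 0.02, "right_thalamus": 0.01}
    )
    drift_amplitude: float = 0.01
    noise_sd_pet: float = 0.5
    noise_sd_bold: float = 1.0
    pet_coupling: dict[str, float] = field(default_factory=dict)
    ar1: float = 0.0
    pet_n_frames: int = 95
    pet_frame_duration: float = 60.0
    bold_frame_duration: float = 2.0
    n_chr2: int = 10
    n_gfp: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chr2 < 1 or self.n_gfp < 1:
            raise ValueError("need at least one subject per group")
        for d in (self.fdg_task_slope_increment, self.bold_on_amplitude,
                  self.bold_overshoot_amplitude, self.pet_coupling):
            if not all(np.isfinite(v) for v in d.values()):
                raise ValueError("non-finite effect amplitude")
        if not np.isfinite([self.noise_sd_pet, self.noise_sd_bold,
                            self.drift_amplitude]).all():
            raise ValueError("non-finite noise/drift value")

    def pet_timing(self) -> FrameTiming:
        return FrameTiming.uniform(self.pet_n_frames, self.pet_frame_duration)

    def bold_timing(self) -> FrameTiming:
        n = int(round(self.protocol.acquisition_duration / self.bold_frame_duration))
        return FrameTiming.uniform(n, self.bold_frame_duration)


def make_atlas(spec: PhantomSpec) -> RegionAtlas:
    """Deterministic box-parcel atlas scaled to the requested grid."""
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    table: dict[int, tuple[str, str]] = {}
    for rid, (name, box) in enumerate(_REGION_BOXES.items(), start=1):
        x0, x1, y0, y1, z0, z1 = box
        sl = (
            slice(int(round(x0 * nx)), int(round(x1 * nx))),
            slice(int(round(y0 * ny)), int(round(y1 * ny))),
            slice(int(round(z0 * nz)), int(round(z1 * nz))),
        )
        region = np.zeros_like(labels, dtype=bool)
        region[sl] = True
        if region.sum() < 27:
            raise ValueError(
                f"grid {spec.grid_shape} too small: region {name!r} has "
                f"{int(region.sum())} voxels (< 27)"
            )
        if np.any(labels[region] != 0):
            raise RuntimeError("atlas boxes overlap")  # layout is fixed; guard
        labels[region] = rid
        table[rid] = (name, _HEMISPHERE[name])
    return RegionAtlas(labels, spec.voxel_size, table)


def _region_field(atlas: RegionAtlas, amplitudes: dict[str, float]) -> np.ndarray:
    out = np.zeros(atlas.label_volume.shape)
    for name, amp in amplitudes.items():
        out[atlas.mask(name)] = amp
    return out


def _noise(rng: np.random.Generator, shape, sd: float, ar1: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=shape)
    if ar1 > 0:
        for t in range(1, shape[-1]):
            eps[..., t] = ar1 * eps[..., t - 1] + np.sqrt(1 - ar1**2) * eps[..., t]
    return eps


def _coupling_latent(spec: PhantomSpec, timing: FrameTiming,
                     rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-sd latent course, active only during stimulation blocks."""
    stim = boxcar(spec.protocol, timing) > 0
    latent = np.zeros(timing.n_frames)
    raw = rng.normal(size=int(stim.sum()))
    raw -= raw.mean()
    sd = raw.std()
    latent[stim] = raw / sd if sd > 0 else raw
    return latent


def simulate_fpet(
    spec: PhantomSpec, atlas: RegionAtlas, subject_seed: int,
    responsive: bool = True,
) -> FrameSeries:
    """One subject's dynamic fPET series.

    Voxel TAC = baseline_slope * frame_number + increment(region) * ramp +
    optional coupling latent + Gaussian noise.  Control (``responsive=False``)
    subjects and the cerebellum carry zero task increment.
    """
    from .protocol import ramp_regressor

    timing = spec.pet_timing()
    rng = np.random.default_rng(subject_seed)
    mask = atlas.brain_mask()
    frames = np.arange(1, timing.n_frames + 1, dtype=float)
    ramp = ramp_regressor(spec.protocol, timing)

    base = spec.fdg_baseline_slope * frames  # shared uptake course
    data = np.zeros(spec.grid_shape + (timing.n_frames,))
    data[mask] = base
    if responsive and spec.fdg_task_slope_increment:
        inc = _region_field(atlas, spec.fdg_task_slope_increment)
        data += inc[..., None] * ramp
    if responsive and spec.pet_coupling:
        latent = _coupling_latent(spec, timing, rng)
        strength = _region_field(atlas, spec.pet_coupling)
        data += strength[..., None] * latent
    if spec.noise_sd_pet > 0:
        data[mask] += _noise(rng, (int(mask.sum()), timing.n_frames),
                             spec.noise_sd_pet, spec.ar1)
    data[~mask] = 0.0
    return FrameSeries(data, timing, spec.voxel_size, mask)


def bold_task_waveforms(
    spec: PhantomSpec, timing: FrameTiming
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-normalized (on-response, overshoot) waveforms on the BOLD grid.

    The on-response is the cycle-level on-phase boxcar convolved with the
    canonical HRF.  The overshoot is an impulse at the termination of each
    stimulation block convolved with the same kernel, producing the
    characteristic transient that peaks a few seconds after each block
    ends and exceeds the suppressed on-plateau.
    """
    p = spec.protocol
    dt = timing.frame_duration
    t = timing.frame_centers
    on = boxcar(p, timing, granularity="cycle")
    impulses = np.zeros(timing.n_frames)
    for b in range(1, p.n_blocks + 1):
        block_end = p.block_start(b) + p.block_duration
        idx = np.searchsorted(t, block_end)
        if idx < timing.n_frames:
            impulses[idx] = 1.0
    kernel = hrf_kernel(dt)
    resp_on = np.convolve(on, kernel)[: timing.n_frames]
    resp_over = np.convolve(impulses, kernel)[: timing.n_frames]
    for r in (resp_on, resp_over):
        peak = np.max(np.abs(r))
        if peak > 0:
            r /= peak
    return resp_on, resp_over


def simulate_bold(
    spec: PhantomSpec, atlas: RegionAtlas, subject_seed: int,
    responsive: bool = True,
) -> FrameSeries:
    """One subject's BOLD series: block responses, overshoot, drift, noise."""
    timing = spec.bold_timing()
    rng = np.random.default_rng(subject_seed)
    mask = atlas.brain_mask()
    resp_on, resp_over = bold_task_waveforms(spec, timing)
    t = timing.frame_centers

    course = np.ones(timing.n_frames)
    data = np.zeros(spec.grid_shape + (timing.n_frames,))
    data[mask] = spec.bold_baseline
    if responsive:
        amp_on = _region_field(atlas, spec.bold_on_amplitude)
        amp_over = _region_field(atlas, spec.bold_overshoot_amplitude)
        data += spec.bold_baseline * (
            amp_on[..., None] * resp_on + amp_over[..., None] * resp_over
        )
        data[~mask] = 0.0
    drift = spec.drift_amplitude * spec.bold_baseline * np.cos(
        np.pi * t / spec.protocol.acquisition_duration
    )
    data[mask] += drift
    if spec.noise_sd_bold > 0:
        data[mask] += _noise(rng, (int(mask.sum()), timing.n_frames),
                             spec.noise_sd_bold, spec.ar1)
    return FrameSeries(data, timing, spec.voxel_size, mask)


@dataclass
class Subject:
    subject_id: str
    group: str  # "chr2" | "gfp"
    fpet: FrameSeries
    bold: FrameSeries | None = None


@dataclass
class Cohort:
    spec: PhantomSpec
    atlas: RegionAtlas
    subjects: list[Subject]
    truth: pd.DataFrame

    def group(self, name: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == name]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.atlas.to_nifti(out / "atlas.nii.gz")
        self.atlas.table_frame().to_csv(out / "regions.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        with open(out / "spec.yaml", "w") as fh:
            yaml.safe_dump(_spec_to_dict(self.spec), fh, sort_keys=False)
        for s in self.subjects:
            d = out / s.subject_id
            d.mkdir(exist_ok=True)
            s.fpet.save(d / "fpet.nii.gz", mask_path=d / "brain_mask.nii.gz")
            if s.bold is not None:
                s.bold.to_nifti(d / "bold.nii.gz")


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = {}
    for k, v in vars(spec).items():
        if isinstance(v, StimulationProtocol):
            d[k] = dict(vars(v))
        elif isinstance(v, tuple):
            d[k] = list(v)
        else:
            d[k] = v
    return d


def subject_seeds(spec: PhantomSpec) -> list[int]:
    """Deterministic per-subject seeds spawned from the cohort seed."""
    ss = np.random.SeedSequence(spec.seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in
            ss.spawn(spec.n_chr2 + spec.n_gfp)]


def simulate_cohort(spec: PhantomSpec, include_bold: bool = True) -> Cohort:
    """Simulate the full two-group cohort with its ground-truth table."""
    atlas = make_atlas(spec)
    seeds = subject_seeds(spec)
    subjects: list[Subject] = []
    rows = []
    groups = ["chr2"] * spec.n_chr2 + ["gfp"] * spec.n_gfp
    for i, (group, seed) in enumerate(zip(groups, seeds)):
        responsive = group == "chr2"
        sid = f"sub-{i + 1:02d}"
        fpet = simulate_fpet(spec, atlas, seed, responsive=responsive)
        bold = (
            simulate_bold(spec, atlas, seed + 1, responsive=responsive)
            if include_bold else None
        )
        subjects.append(Subject(sid, group, fpet, bold))
        for name in atlas.names:
            rows.append({
                "subject_id": sid,
                "group": group,
                "region": name,
                "fdg_slope_increment": (
                    spec.fdg_task_slope_increment.get(name, 0.0) if responsive else 0.0
                ),
                "bold_on_amplitude": (
                    spec.bold_on_amplitude.get(name, 0.0) if responsive else 0.0
                ),
                "bold_overshoot_amplitude": (
                    spec.bold_overshoot_amplitude.get(name, 0.0) if responsive else 0.0
                ),
                "pet_coupling": (
                    spec.pet_coupling.get(name, 0.0) if responsive else 0.0
                ),
            })
    return Cohort(spec, atlas, subjects, pd.DataFrame(rows))
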