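"""Stimulation protocol representation and task regressors.

The experimental design is a block design: after a pre-stimulation baseline,
``n_blocks`` stimulation blocks of ``block_duration`` seconds alternate with
rest periods of ``rest_duration`` seconds.  Within each block, light is
cycled through on/off phases (``on_period`` / ``off_period``); within an on
phase the laser is pulsed at ``pulse_frequency`` with a given duty cycle.

All timing quantities the downstream analyses need — pulse duration, cycles
per block, frame windows per block, boxcar/ramp regressors and the
HRF-convolved task regressor — are derived from this single description.
Frame/scan indices are 0-based internally and 1-based in reports; intervals
are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "StimulationProtocol",
    "FrameTiming",
    "InvalidProtocolError",
    "pulse_duration",
    "cycles_per_block",
    "block_frame_indices",
    "boxcar",
    "ramp_regressor",
    "canonical_hrf",
    "hrf_convolve",
]


class InvalidProtocolError(ValueError):
    """Raised when protocol parameters violate the design invariants."""


@dataclass(frozen=True)
class StimulationProtocol:
    """Timing of an optogenetic block-design stimulation experiment.

    Defaults reproduce the study design: 95-min acquisition, stimulation
    starting at 20 min, six 10-min blocks separated by 3-min rests, 60-s
    on / 15-s off cycling, 20-Hz pulses at 50% duty cycle.
    """

    acquisition_duration: float = 5700.0
    stim_onset: float = 1200.0
    n_blocks: int = 6
    block_duration: float = 600.0
    rest_duration: float = 180.0
    on_period: float = 60.0
    off_period: float = 15.0
    pulse_frequency: float = 20.0
    duty_cycle: float = 0.5

    def __post_init__(self) -> None:
        if self.pulse_frequency <= 0:
            raise InvalidProtocolError("pulse_frequency must be positive")
        if not (0 < self.duty_cycle <= 1):
            raise InvalidProtocolError("duty_cycle must lie in (0, 1]")
        cycle = self.on_period + self.off_period
        if cycle <= 0:
            raise InvalidProtocolError("on_period + off_period must be positive")
        ratio = self.block_duration / cycle
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidProtocolError(
                "block_duration must be an integer multiple of on+off period"
            )
        span = (
            self.stim_onset
            + self.n_blocks * self.block_duration
            + (self.n_blocks - 1) * self.rest_duration
        )
        if span > self.acquisition_duration + 1e-9:
            raise InvalidProtocolError(
                f"protocol spans {span} s but acquisition is "
                f"{self.acquisition_duration} s"
            )

    def block_start(self, block: int) -> float:
        """Start time (s) of 1-based stimulation block ``block``."""
        if not 1 <= block <= self.n_blocks:
            raise InvalidProtocolError(
                f"block {block} out of range 1..{self.n_blocks}"
            )
        return self.stim_onset + (block - 1) * (self.block_duration + self.rest_duration)


@dataclass(frozen=True)
class FrameTiming:
    """Uniform frame grid: start times (s) and a common frame duration (s)."""

    frame_starts: np.ndarray
    frame_duration: float

    def __post_init__(self) -> None:
        starts = np.asarray(self.frame_starts, dtype=float)
        object.__setattr__(self, "frame_starts", starts)
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        if starts.ndim != 1 or starts.size == 0:
            raise ValueError("frame_starts must be a non-empty 1-D array")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame_starts must be strictly increasing")

    @classmethod
    def uniform(cls, n_frames: int, frame_duration: float, start: float = 0.0
                ) -> "FrameTiming":
        return cls(start + np.arange(n_frames) * frame_duration, frame_duration)

    @property
    def n_frames(self) -> int:
        return int(self.frame_starts.size)

    @property
    def frame_centers(self) -> np.ndarray:
        return self.frame_starts + self.frame_duration / 2.0


def pulse_duration(protocol: StimulationProtocol) -> float:
    """Single light-pulse duration in seconds (duty cycle / pulse frequency)."""
    return protocol.duty_cycle / protocol.pulse_frequency


def cycles_per_block(protocol: StimulationProtocol) -> int:
    """Number of on/off cycles inside one stimulation block."""
    return int(round(protocol.block_duration / (protocol.on_period + protocol.off_period)))


def block_frame_indices(
    protocol: StimulationProtocol, timing: FrameTiming, block: int
) -> tuple[int, int]:
    """1-based (first, last) frame indices covered by a stimulation block.

    A frame belongs to the block when its interval lies inside
    ``[block_start, block_start + block_duration)``.  With the default
    design and 95 one-minute frames, block 6 maps to frames (86, 95).
    """
    start = protocol.block_start(block)
    end = start + protocol.block_duration
    s = timing.frame_starts
    inside = (s >= start - 1e-9) & (s + timing.frame_duration <= end + 1e-9)
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        raise InvalidProtocolError(f"no frames cover block {block}")
    return int(idx[0]) + 1, int(idx[-1]) + 1


def boxcar(
    protocol: StimulationProtocol,
    timing: FrameTiming,
    granularity: str = "block",
) -> np.ndarray:
    """Task boxcar on the frame grid: 1 during stimulation, 0 otherwise.

    ``granularity='block'`` treats whole 10-min blocks as on (the main
    model); ``'cycle'`` only flags the on phases of each on/off cycle.
    Frames are classified by their centre time.
    """
    if granularity not in ("block", "cycle"):
        raise ValueError(f"unknown granularity {granularity!r}")
    t = timing.frame_centers
    out = np.zeros(timing.n_frames)
    for b in range(1, protocol.n_blocks + 1):
        b0 = protocol.block_start(b)
        in_block = (t >= b0) & (t < b0 + protocol.block_duration)
        if granularity == "block":
            out[in_block] = 1.0
        else:
            phase = (t - b0) % (protocol.on_period + protocol.off_period)
            out[in_block & (phase < protocol.on_period)] = 1.0
    return out


def ramp_regressor(protocol: StimulationProtocol, timing: FrameTiming) -> np.ndarray:
    """Ramp regressor: unit slope per frame while stimulation is active.

    Cumulative count of stimulation frames elapsed up to and including each
    frame — the discrete integral of the block-level boxcar — flat during
    rests.  This models cumulative tracer uptake attributable to the task
    under irreversible FDG kinetics.
    """
    return np.cumsum(boxcar(protocol, timing, granularity="block"))


def canonical_hrf(
    t: np.ndarray | float,
    peak_delay: float = 5.0,
    undershoot_delay: float = 15.0,
    ratio: float = 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    Difference of two gamma densities with modes at ``peak_delay`` and
    ``undershoot_delay`` and peak:undershoot amplitude ratio ``ratio``;
    the early positive peak sits near 5 s with a later negative undershoot.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    # gamma pdf with unit rate peaks at shape-1, so shape = delay/disp + 1
    a1 = peak_delay / dispersion + 1.0
    a2 = undershoot_delay / dispersion + 1.0
    h = (
        _gamma_dist.pdf(t, a1, scale=dispersion)
        - _gamma_dist.pdf(t, a2, scale=dispersion) / ratio
    )
    h[t < 0] = 0.0
    grid = np.linspace(0, undershoot_delay + 30.0, 2048)
    peak = np.max(
        _gamma_dist.pdf(grid, a1, scale=dispersion)
        - _gamma_dist.pdf(grid, a2, scale=dispersion) / ratio
    )
    return h / peak


def hrf_kernel(frame_duration: float, support: float = 32.0) -> np.ndarray:
    """Canonical HRF averaged over frame-length bins.

    Bin averaging (rather than point sampling) keeps the kernel faithful
    at coarse frame spacings, where point samples can miss the early
    positive lobe entirely.
    """
    fine = 0.05
    t = np.arange(0, support, fine)
    h = canonical_hrf(t)
    n_bins = int(np.ceil(support / frame_duration))
    bins = np.minimum((t / frame_duration).astype(int), n_bins - 1)
    return np.bincount(bins, weights=h, minlength=n_bins) / np.bincount(
        bins, minlength=n_bins
    )


def hrf_convolve(regressor: np.ndarray, timing: FrameTiming) -> np.ndarray:
    """Convolve a frame-grid regressor with the canonical HRF.

    Discrete convolution with the frame-integrated HRF kernel, truncated
    to the acquisition length and peak-normalized, so a sustained block
    plateaus near the HRF integral ratio of its peak.
    """
    regressor = np.asarray(regressor, dtype=float)
    if regressor.shape[0] != timing.n_frames:
        raise ValueError("regressor length does not match frame grid")
    kernel = hrf_kernel(timing.frame_duration)
    out = np.convolve(regressor, kernel)[: timing.n_frames]
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out
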