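"""From raw skeleton recordings to the fixed-size posture array.

The preprocessing chain is: cubic-spline resampling to a uniform 30 Hz grid,
reduction to the nine frontal-plane landmarks (18 coordinates per frame),
sway-cycle segmentation on the mean shoulder medio-lateral signal, selection
of ten cycles (the first detected cycle is always discarded; trials with
fewer than ten remaining cycles are dropped from analysis), per-trial sway
amplitude and dominant sway frequency, and time normalization of each cycle
to 30 phase points, yielding 300 frames x 18 coordinates per retained trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, periodogram

from .errors import MalformedInputError, NoCyclesError
from .synthetic import AXES, FRONTAL_LANDMARKS, RawTrial, SEGMENT_NAMES

#: Frames per time-normalized sway cycle.
FRAMES_PER_CYCLE = 30
#: Sway cycles retained per trial.
CYCLES_PER_TRIAL = 10
#: Frames per retained trial (10 cycles x 30 frames).
FRAMES_PER_TRIAL = FRAMES_PER_CYCLE * CYCLES_PER_TRIAL
#: Coordinates per posture vector (9 landmarks x 2 frontal axes).
POSTURE_DIM = 2 * len(FRONTAL_LANDMARKS)


@dataclass
class UniformTrial:
    """A uniformly sampled trial: (n_frames, n_segments, n_axes)."""

    trial_id: str
    subject_id: str
    condition_id: int
    group: str
    rate: float
    positions: np.ndarray
    segment_names: tuple[str, ...]
    axes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape[1:] != (len(self.segment_names), len(self.axes)):
            raise ValueError("positions shape inconsistent with labels")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.rate

    def segment(self, name: str) -> np.ndarray:
        try:
            return self.positions[:, self.segment_names.index(name), :]
        except ValueError as exc:
            raise MalformedInputError(f"segment {name!r} missing") from exc

    def frontal_matrix(self) -> np.ndarray:
        """(n_frames, 18) posture matrix: nine x-coordinates then nine
        y-coordinates, in canonical landmark order."""
        if self.axes != ("x", "y") or self.segment_names != FRONTAL_LANDMARKS:
            raise MalformedInputError(
                "frontal_matrix requires the 9-landmark frontal reduction")
        return np.concatenate(
            [self.positions[:, :, 0], self.positions[:, :, 1]], axis=1)


@dataclass
class CycleSegmentation:
    """Sway-cycle boundaries (frame indices of outermost-left positions)."""

    boundaries: np.ndarray  # strictly increasing frame indices
    rate: float

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if np.any(np.diff(self.boundaries) < 2):
            raise ValueError("each cycle must span at least 2 frames")

    @property
    def n_cycles(self) -> int:
        return max(len(self.boundaries) - 1, 0)

    @property
    def durations(self) -> np.ndarray:
        """Per-cycle duration, seconds."""
        return np.diff(self.boundaries) / self.rate

    def cycle_slices(self) -> list[slice]:
        """Half-open frame intervals [b_i, b_{i+1}) of successive cycles."""
        return [slice(int(a), int(b))
                for a, b in zip(self.boundaries[:-1], self.boundaries[1:])]


def resample_uniform(trial: RawTrial, rate: float = 30.0) -> UniformTrial:
    """Resample every coordinate onto a uniform grid with cubic splines.

    The grid spans [t_first, t_last]; no extrapolation is performed.
    """
    t = np.asarray(trial.timestamps, dtype=float)
    if len(t) < 4:
        raise MalformedInputError("need at least 4 frames to resample")
    if np.any(np.diff(t) <= 0):
        raise MalformedInputError("timestamps must be strictly increasing")
    n_out = int(np.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n_out) / rate
    flat = trial.positions.reshape(len(t), -1)
    spline = CubicSpline(t, flat, axis=0)
    resampled = spline(grid).reshape(n_out, *trial.positions.shape[1:])
    return UniformTrial(
        trial_id=trial.trial_id, subject_id=trial.subject_id,
        condition_id=trial.condition_id, group=trial.group, rate=rate,
        positions=resampled, segment_names=tuple(trial.segment_names),
        axes=AXES)


def reduce_to_frontal(trial: UniformTrial) -> UniformTrial:
    """Drop hands, elbows and feet, and the sagittal (z) axis.

    Selection is label-driven, so any segment/axis ordering with the
    canonical names is accepted.  The result holds the nine frontal
    landmarks with (x, y) coordinates: 18 values per frame.
    """
    try:
        seg_idx = [trial.segment_names.index(name) for name in FRONTAL_LANDMARKS]
        ax_idx = [trial.axes.index(a) for a in ("x", "y")]
    except ValueError as exc:
        raise MalformedInputError(str(exc)) from exc
    reduced = trial.positions[:, seg_idx][:, :, ax_idx]
    return replace(trial, positions=reduced,
                   segment_names=FRONTAL_LANDMARKS, axes=("x", "y"))


def detect_cycles(trial: UniformTrial,
                  prominence_fraction: float = 0.25) -> CycleSegmentation:
    """Segment sway cycles at outermost-left shoulder positions.

    A sway cycle is a full left-right-left sway: boundaries are local
    minima of the mean shoulder medio-lateral coordinate (left is negative
    x) whose prominence exceeds ``prominence_fraction`` of the signal's
    interquartile range.
    """
    if trial.duration < 2.0:
        raise ValueError("need at least 2 s of data to detect cycles")
    shoulders = 0.5 * (trial.segment("left_shoulder")[:, 0]
                       + trial.segment("right_shoulder")[:, 0])
    q75, q25 = np.percentile(shoulders, [75, 25])
    prominence = prominence_fraction * (q75 - q25)
    if prominence <= 0:
        raise NoCyclesError("flat shoulder signal, no sway cycles")
    minima, _ = find_peaks(-shoulders, prominence=prominence)
    if len(minima) < 2:
        raise NoCyclesError(
            f"only {len(minima)} cycle boundaries found, need at least 2")
    return CycleSegmentation(boundaries=minima, rate=trial.rate)


def select_cycles(seg: CycleSegmentation,
                  n: int = CYCLES_PER_TRIAL) -> CycleSegmentation | None:
    """Discard the first cycle and keep the subsequent ``n``.

    Returns ``None`` when fewer than ``n`` cycles remain after dropping the
    first — the trial is then discarded from analysis (a reported outcome,
    not an error).
    """
    remaining = seg.n_cycles - 1
    if remaining < n:
        return None
    return CycleSegmentation(boundaries=seg.boundaries[1:n + 2], rate=seg.rate)


def sway_amplitude(trial: UniformTrial, seg: CycleSegmentation) -> float:
    """Mean medio-lateral excursion of the lower back over the cycles.

    Per cycle: the peak-to-peak ML excursion of the lower-back landmark;
    the returned amplitude is the mean over the selected cycles, metres.
    """
    if seg.n_cycles < 1:
        raise ValueError("empty cycle segmentation")
    x = trial.segment("lower_back")[:, 0]
    return float(np.mean([np.ptp(x[sl]) for sl in seg.cycle_slices()]))


def sway_frequency(trial: UniformTrial) -> float:
    """Dominant frequency (Hz) of the lower-back ML power spectrum.

    Periodogram of the linearly detrended, Hann-windowed signal over the
    full trial; the zero-frequency bin is excluded.
    """
    if trial.duration < 4.0:
        raise ValueError("need at least 4 s of data for a frequency estimate")
    x = trial.segment("lower_back")[:, 0]
    freqs, power = periodogram(x, fs=trial.rate, window="hann",
                               detrend="linear")
    nonzero = freqs > 0
    return float(freqs[nonzero][np.argmax(power[nonzero])])


def time_normalize(trial: UniformTrial, seg: CycleSegmentation) -> np.ndarray:
    """Normalize ten cycles to 30 frames each -> (300, 18) posture block.

    Each cycle's 18 coordinate signals are interpolated onto 30 equally
    spaced phase points over that cycle (phases 0, 1/30, ..., 29/30 —
    left-closed, right-open, so consecutive cycles do not duplicate the
    boundary frame).  All 18 signals share the same time base, preserving
    inter-segment phase lags.
    """
    if seg.n_cycles != CYCLES_PER_TRIAL:
        raise ValueError(
            f"time_normalize requires exactly {CYCLES_PER_TRIAL} cycles, "
            f"got {seg.n_cycles}")
    frontal = trial.frontal_matrix()
    frame_idx = np.arange(frontal.shape[0], dtype=float)
    blocks = []
    for a, b in zip(seg.boundaries[:-1], seg.boundaries[1:]):
        phase_pos = a + (b - a) * np.arange(FRAMES_PER_CYCLE) / FRAMES_PER_CYCLE
        block = np.column_stack([
            np.interp(phase_pos, frame_idx, frontal[:, k])
            for k in range(frontal.shape[1])
        ])
        blocks.append(block)
    out = np.concatenate(blocks, axis=0)
    assert out.shape == (FRAMES_PER_TRIAL, POSTURE_DIM)
    return out


@dataclass
class PreprocessedTrial:
    """Outcome of preprocessing one trial (frames is None when discarded)."""

    trial_id: str
    subject_id: str
    group: str
    condition_id: int
    discarded: bool
    reason: str = ""
    frames: np.ndarray | None = None  # (300, 18) when retained
    amplitude: float = np.nan  # metres
    frequency: float = np.nan  # Hz


def preprocess_trial(trial: RawTrial, rate: float = 30.0,
                     n_select: int = CYCLES_PER_TRIAL) -> PreprocessedTrial:
    """Run the full preprocessing chain on one raw trial."""
    meta = dict(trial_id=trial.trial_id, subject_id=trial.subject_id,
                group=trial.group, condition_id=trial.condition_id)
    uniform = reduce_to_frontal(resample_uniform(trial, rate=rate))
    try:
        seg = detect_cycles(uniform)
    except NoCyclesError as exc:
        return PreprocessedTrial(**meta, discarded=True, reason=str(exc))
    selected = select_cycles(seg, n=n_select)
    if selected is None:
        return PreprocessedTrial(
            **meta, discarded=True,
            reason=f"fewer than {n_select} sway cycles after discarding the first")
    return PreprocessedTrial(
        **meta, discarded=False,
        frames=time_normalize(uniform, selected),
        amplitude=sway_amplitude(uniform, selected),
        frequency=sway_frequency(uniform))


@dataclass
class PostureArray:
    """3-D posture array: trials I x frames J=300 x coordinates K=18."""

    values: np.ndarray  # (I, 300, 18), metres
    index: pd.DataFrame  # one row per retained trial

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (
                FRAMES_PER_TRIAL, POSTURE_DIM):
            raise ValueError(
                f"posture array must be (I, {FRAMES_PER_TRIAL}, {POSTURE_DIM})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("posture array contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: trial_id, frame (1-based), coord (1-based), value."""
        I, J, K = self.values.shape
        trial_ids = np.repeat(self.index["trial_id"].to_numpy(), J * K)
        frames = np.tile(np.repeat(np.arange(1, J + 1), K), I)
        coords = np.tile(np.arange(1, K + 1), I * J)
        return pd.DataFrame({
            "trial_id": trial_ids, "frame": frames, "coord": coords,
            "value": self.values.ravel()})

    def save(self, values_path: str | Path, index_path: str | Path) -> None:
        self.to_long_frame().to_csv(values_path, index=False)
        self.index.to_csv(index_path, index=False)

    @classmethod
    def load(cls, values_path: str | Path, index_path: str | Path) -> "PostureArray":
        index = pd.read_csv(index_path)
        long = pd.read_csv(values_path)
        I = len(index)
        values = long["value"].to_numpy().reshape(I, FRAMES_PER_TRIAL, POSTURE_DIM)
        return cls(values=values, index=index)


def preprocess_cohort(
    trials: Sequence[RawTrial], rate: float = 30.0,
    n_select: int = CYCLES_PER_TRIAL,
) -> tuple[PostureArray, pd.DataFrame]:
    """Preprocess every trial; assemble retained trials into a PostureArray.

    Returns the posture array and a per-trial metrics table (trial_id,
    subject_id, group, condition_id, amplitude_m, frequency_hz, discarded,
    reason) covering all input trials, discarded ones included.
    """
    results = [preprocess_trial(t, rate=rate, n_select=n_select) for t in trials]
    metrics = pd.DataFrame([{
        "trial_id": r.trial_id, "subject_id": r.subject_id, "group": r.group,
        "condition_id": r.condition_id, "amplitude_m": r.amplitude,
        "frequency_hz": r.frequency, "discarded": r.discarded,
        "reason": r.reason,
    } for r in results])
    retained = [r for r in results if not r.discarded]
    if not retained:
        raise NoCyclesError("no trials retained after preprocessing")
    values = np.stack([r.frames for r in retained])
    index = pd.DataFrame([{
        "trial_id": r.trial_id, "subject_id": r.subject_id, "group": r.group,
        "condition_id": r.condition_id,
    } for r in retained])
    return PostureArray(values=values, index=index), metrics
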