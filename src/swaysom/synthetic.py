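"""Synthetic lateral-sway cohorts with known ground truth.

Emulates markerless (Kinect-style) skeleton capture of a weight-shifting
balance exercise: 15 body segments tracked in 3-D at an irregular ~30 Hz,
while the subject repeatedly sways the trunk from the outermost-left to the
outermost-right position and back.  The generator drives nine frontal-plane
landmarks with a coupled planar kinematic chain — every segment's
medio-lateral excursion is an amplitude-scaled, phase-lagged copy of a base
oscillator, and vertical displacement follows an inverted-pendulum coupling
(drop proportional to 1 - cos of the lateral lean angle).

Cohorts carry the statistical structure the downstream analysis assumes:
two age groups ("young", "old") where the old archetype sways with smaller
amplitude, a lower achievable maximum frequency, and larger cycle-to-cycle
variability under the two demanding task conditions.  Every generative
parameter is recorded so parameter-recovery tests have a known answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

# Canonical segment order for the 15-segment skeleton.
SEGMENT_NAMES: tuple[str, ...] = (
    "head",
    "neck",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_hand",
    "right_hand",
    "lower_back",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_foot",
    "right_foot",
)

#: The nine frontal-plane landmarks retained for posture analysis.
FRONTAL_LANDMARKS: tuple[str, ...] = (
    "head",
    "neck",
    "left_shoulder",
    "right_shoulder",
    "lower_back",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
)

AXES: tuple[str, ...] = ("x", "y", "z")

# Rest pose (x medio-lateral, y vertical), metres, for a 1.0 stature scale.
_REST_POSE: dict[str, tuple[float, float]] = {
    "head": (0.00, 1.62),
    "neck": (0.00, 1.45),
    "left_shoulder": (-0.20, 1.40),
    "right_shoulder": (0.20, 1.40),
    "left_elbow": (-0.30, 1.15),
    "right_elbow": (0.30, 1.15),
    "left_hand": (-0.34, 0.95),
    "right_hand": (0.34, 0.95),
    "lower_back": (0.00, 1.00),
    "left_hip": (-0.12, 0.95),
    "right_hip": (0.12, 0.95),
    "left_knee": (-0.13, 0.50),
    "right_knee": (0.13, 0.50),
    "left_foot": (-0.15, 0.05),
    "right_foot": (0.15, 0.05),
}

# Medio-lateral gain per segment relative to the lower-back oscillator.
# Upper body overshoots the pelvis (trunk lean), knees move little, feet
# stay planted.
_ML_GAIN: dict[str, float] = {
    "head": 1.40,
    "neck": 1.32,
    "left_shoulder": 1.25,
    "right_shoulder": 1.25,
    "left_elbow": 1.25,
    "right_elbow": 1.25,
    "left_hand": 1.25,
    "right_hand": 1.25,
    "lower_back": 1.00,
    "left_hip": 0.85,
    "right_hip": 0.85,
    "left_knee": 0.35,
    "right_knee": 0.35,
    "left_foot": 0.05,
    "right_foot": 0.05,
}

# Phase lead (fraction of a cycle) per segment: head/shoulders lead the hips.
_UPPER = ("head", "neck", "left_shoulder", "right_shoulder",
          "left_elbow", "right_elbow", "left_hand", "right_hand")


@dataclass(frozen=True)
class SubjectSpec:
    """Generative parameters for one simulated subject."""

    subject_id: str
    group: str  # "young" | "old"
    stature_scale: float  # dimensionless anthropometric multiplier, > 0
    base_amplitude: float  # metres, lower-back ML half-excursion, > 0
    base_frequency: float  # Hz, self-selected sway frequency, > 0
    variability_level: float  # cycle-to-cycle jitter SD as fraction of amplitude
    seed: int

    def __post_init__(self) -> None:
        if self.group not in ("young", "old"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.base_frequency <= 0 or self.base_amplitude <= 0:
            raise ValueError("base_frequency and base_amplitude must be > 0")
        if self.variability_level < 0:
            raise ValueError("variability_level must be >= 0")
        if self.stature_scale <= 0:
            raise ValueError("stature_scale must be > 0")


@dataclass(frozen=True)
class ConditionSpec:
    """One exergame task condition."""

    condition_id: int
    amplitude_multiplier: float
    frequency_multiplier: float
    leg_lift: bool
    label: str

    def __post_init__(self) -> None:
        if not 1 <= self.condition_id <= 5:
            raise ValueError("condition_id must be in 1..5")
        if self.amplitude_multiplier <= 0 or self.frequency_multiplier <= 0:
            raise ValueError("multipliers must be > 0")


#: The five task conditions, mirroring a neutral game, doubled game speed,
#: maximum sway frequency, a contralateral leg lift, and maximum amplitude.
DEFAULT_CONDITIONS: dict[int, ConditionSpec] = {
    1: ConditionSpec(1, 1.00, 1.00, False, "neutral"),
    2: ConditionSpec(2, 1.00, 1.15, False, "increased game speed"),
    3: ConditionSpec(3, 0.90, 1.80, False, "maximum sway frequency"),
    4: ConditionSpec(4, 1.00, 0.90, True, "leg lifted"),
    5: ConditionSpec(5, 1.60, 0.90, False, "maximum sway amplitude"),
}

#: The two conditions under which the old archetype is more variable.
COMPLEX_CONDITIONS: tuple[int, ...] = (3, 5)


@dataclass(frozen=True)
class GroupParams:
    """Population means/SDs from which subject parameters are drawn."""

    amplitude_mean: float
    amplitude_sd: float
    frequency_mean: float
    frequency_sd: float
    variability_mean: float
    variability_sd: float
    stature_mean: float = 1.0
    stature_sd: float = 0.04


@dataclass(frozen=True)
class PopulationParams:
    """Group-level generative structure of the simulated cohort.

    Group effects are confined to the two complex conditions (maximum sway
    frequency, maximum sway amplitude): there the old archetype reaches
    only 0.8x the amplitude and 0.8x the frequency of the young group and
    shows 1.5x the cycle-to-cycle variability.  In the remaining
    conditions both groups draw from identical distributions, so the
    neutral condition carries no group signal.
    """

    young: GroupParams = GroupParams(
        amplitude_mean=0.10, amplitude_sd=0.010,
        frequency_mean=0.45, frequency_sd=0.04,
        variability_mean=0.05, variability_sd=0.008,
    )
    old: GroupParams = GroupParams(
        amplitude_mean=0.10, amplitude_sd=0.010,
        frequency_mean=0.45, frequency_sd=0.04,
        variability_mean=0.05, variability_sd=0.008,
    )
    old_complex_amplitude_factor: float = 0.8
    old_max_frequency_factor: float = 0.8
    old_complex_variability_factor: float = 1.5
    complex_conditions: tuple[int, ...] = COMPLEX_CONDITIONS

    def for_group(self, group: str) -> GroupParams:
        return self.young if group == "young" else self.old


DEFAULT_POPULATION = PopulationParams()


@dataclass
class RawTrial:
    """One irregularly sampled 15-segment 3-D skeleton recording."""

    trial_id: str
    subject_id: str
    condition_id: int
    group: str
    timestamps: np.ndarray  # (n,) seconds, strictly increasing
    positions: np.ndarray  # (n, 15, 3) metres, axes (x ML, y vertical, z sagittal)
    segment_names: tuple[str, ...] = SEGMENT_NAMES

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1] != len(self.segment_names):
            raise ValueError("positions must be (n_frames, n_segments, 3)")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def mean_rate(self) -> float:
        return (self.n_frames - 1) / (self.timestamps[-1] - self.timestamps[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: time_s then {segment}_{x,y,z} columns."""
        cols: dict[str, np.ndarray] = {"time_s": self.timestamps}
        for s, name in enumerate(self.segment_names):
            for a, axis in enumerate(AXES):
                cols[f"{name}_{axis}"] = self.positions[:, s, a]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, trial_id: str, subject_id: str = "",
                   condition_id: int = 1, group: str = "young") -> "RawTrial":
        pos = np.stack(
            [np.column_stack([df[f"{name}_{axis}"].to_numpy() for axis in AXES])
             for name in SEGMENT_NAMES],
            axis=1,
        )
        return cls(trial_id=trial_id, subject_id=subject_id,
                   condition_id=condition_id, group=group,
                   timestamps=df["time_s"].to_numpy(), positions=pos)


def generate_subject_specs(
    n_young: int,
    n_old: int,
    population: PopulationParams | None = None,
    seed: int = 0,
) -> list[SubjectSpec]:
    """Draw subject-level parameters for a cohort of the two age groups.

    Deterministic for a fixed seed.  Draws are truncated away from zero so
    every spec satisfies its own invariants.
    """
    if n_young < 0 or n_old < 0:
        raise ValueError("subject counts must be non-negative")
    population = population or DEFAULT_POPULATION
    rng = np.random.default_rng(seed)
    specs: list[SubjectSpec] = []
    for group, n in (("young", n_young), ("old", n_old)):
        p = population.for_group(group)
        prefix = "Y" if group == "young" else "O"
        for i in range(n):
            amp = max(0.02, rng.normal(p.amplitude_mean, p.amplitude_sd))
            freq = max(0.15, rng.normal(p.frequency_mean, p.frequency_sd))
            var = max(0.0, rng.normal(p.variability_mean, p.variability_sd))
            stature = max(0.7, rng.normal(p.stature_mean, p.stature_sd))
            specs.append(SubjectSpec(
                subject_id=f"{prefix}{i + 1:02d}",
                group=group,
                stature_scale=stature,
                base_amplitude=amp,
                base_frequency=freq,
                variability_level=var,
                seed=int(rng.integers(0, 2**31 - 1)),
            ))
    return specs


def effective_parameters(
    subject: SubjectSpec,
    condition: ConditionSpec,
    population: PopulationParams | None = None,
) -> tuple[float, float, float]:
    """Resolve (amplitude, frequency, variability) for a subject x condition.

    Applies the old-archetype modifiers, which are confined to the complex
    conditions: reduced achievable amplitude and frequency, and inflated
    cycle-to-cycle variability.
    """
    population = population or DEFAULT_POPULATION
    amp = subject.base_amplitude * condition.amplitude_multiplier
    freq = subject.base_frequency * condition.frequency_multiplier
    var = subject.variability_level
    if subject.group == "old" and \
            condition.condition_id in population.complex_conditions:
        amp *= population.old_complex_amplitude_factor
        freq *= population.old_max_frequency_factor
        var *= population.old_complex_variability_factor
    return amp, freq, var


def generate_trial(
    subject: SubjectSpec,
    condition: ConditionSpec,
    n_cycles: int = 12,
    seed: int = 0,
    *,
    rate: float = 30.0,
    timestamp_jitter: float = 0.005,
    noise_sd: float = 0.002,
    phase_lead: float = 0.03,
    n_extra_cycles: int = 2,
    population: PopulationParams | None = None,
    trial_id: str = "trial",
) -> RawTrial:
    """Simulate one lateral-sway trial.

    The lower-back ML coordinate performs ``n_cycles + n_extra_cycles``
    full left-right-left oscillations (a cycle starts and ends at the
    outermost-left position), so downstream discarding of the first cycle
    still leaves ``n_cycles``.  Per-cycle period and amplitude are
    perturbed with SD proportional to ``variability_level``; additive
    Gaussian sensor noise and +-5 ms timestamp jitter emulate the sensor.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if n_extra_cycles < 2:
        raise ValueError("need at least 2 extra cycles")
    rng = np.random.default_rng(seed)
    amp, freq, var = effective_parameters(subject, condition, population)

    total_cycles = n_cycles + n_extra_cycles
    base_period = 1.0 / freq
    periods = base_period * np.clip(
        1.0 + var * rng.standard_normal(total_cycles), 0.3, 3.0)
    amps = amp * np.clip(1.0 + var * rng.standard_normal(total_cycles), 0.1, 3.0)

    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    duration = boundaries[-1]

    n_samples = int(np.floor(duration * rate))
    t = np.arange(n_samples) / rate
    if timestamp_jitter > 0:
        t = t + rng.uniform(-timestamp_jitter, timestamp_jitter, n_samples)
        t[0] = abs(t[0])
    t = t[t < duration]

    # Continuous cycle phase and smoothly interpolated per-cycle amplitude.
    phase = np.interp(t, boundaries, np.arange(total_cycles + 1))
    midpoints = 0.5 * (boundaries[:-1] + boundaries[1:])
    amp_t = np.interp(t, midpoints, amps)

    stature = subject.stature_scale
    pend_len = 1.0 * stature  # effective inverted-pendulum length, metres

    n = len(t)
    positions = np.empty((n, len(SEGMENT_NAMES), 3))
    for s, name in enumerate(SEGMENT_NAMES):
        lead = phase_lead if name in _UPPER else 0.0
        # Outermost-left at integer phase: -cos starts each cycle at the left.
        disp = -amp_t * _ML_GAIN[name] * np.cos(2 * np.pi * (phase + lead))
        rest_x, rest_y = _REST_POSE[name]
        positions[:, s, 0] = rest_x * stature + disp
        positions[:, s, 1] = rest_y * stature - pend_len * (
            1.0 - np.cos(disp / pend_len))
        positions[:, s, 2] = 0.0

    if condition.leg_lift:
        # Lift the leg contralateral to the sway direction: sway right
        # (positive ML) lifts the left knee/foot and vice versa.
        x_base = -amp_t * np.cos(2 * np.pi * phase)
        lean = np.clip(x_base / np.maximum(amp_t, 1e-9), -1.0, 1.0)
        lift = 0.06 * stature
        for name, side in (("left_knee", 1.0), ("left_foot", 1.0),
                           ("right_knee", -1.0), ("right_foot", -1.0)):
            positions[:, SEGMENT_NAMES.index(name), 1] += lift * np.clip(
                side * lean, 0.0, 1.0)

    if noise_sd > 0:
        positions += rng.normal(0.0, noise_sd, positions.shape)

    return RawTrial(
        trial_id=trial_id,
        subject_id=subject.subject_id,
        condition_id=condition.condition_id,
        group=subject.group,
        timestamps=t,
        positions=positions,
    )


@dataclass
class CohortConfig:
    """Configuration of a simulated cohort.

    Defaults reproduce the study layout: 20 + 20 subjects, five conditions,
    two trials per condition (400 trials), of which 8 young and 14 old
    trials are "corrupted" — generated with too few sway cycles so the
    preprocessing discard rule removes them, leaving 378.
    """

    n_young: int = 20
    n_old: int = 20
    condition_ids: tuple[int, ...] = (1, 2, 3, 4, 5)
    trials_per_condition: int = 2
    n_cycles: int = 12
    corrupted_young: int = 8
    corrupted_old: int = 14
    corrupted_n_cycles: int = 5
    noise_sd: float = 0.002
    timestamp_jitter: float = 0.005
    seed: int = 0
    population: PopulationParams = field(default_factory=PopulationParams)
    conditions: dict[int, ConditionSpec] = field(
        default_factory=lambda: dict(DEFAULT_CONDITIONS))

    def __post_init__(self) -> None:
        for cid in self.condition_ids:
            if cid not in self.conditions:
                raise ConfigurationError(f"unknown condition id {cid}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "condition_ids" in raw:
            raw["condition_ids"] = tuple(raw["condition_ids"])
        return cls(**raw)


@dataclass
class CohortDataset:
    """A simulated cohort: raw trials, a manifest, and full ground truth."""

    trials: list[RawTrial]
    manifest: pd.DataFrame  # trial_id, subject_id, group, condition_id, repetition, corrupted
    ground_truth: dict

    def write_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for trial in self.trials:
            trial.to_frame().to_csv(out / f"{trial.trial_id}.csv", index=False,
                                    float_format="%.6f")
        self.manifest.to_csv(out / "manifest.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)

    @staticmethod
    def read_csv(in_dir: str | Path) -> "CohortDataset":
        in_dir = Path(in_dir)
        manifest = pd.read_csv(in_dir / "manifest.csv")
        trials = []
        for row in manifest.itertuples():
            df = pd.read_csv(in_dir / f"{row.trial_id}.csv")
            trials.append(RawTrial.from_frame(
                df, trial_id=row.trial_id, subject_id=row.subject_id,
                condition_id=int(row.condition_id), group=row.group))
        gt_path = in_dir / "ground_truth.json"
        gt = json.loads(gt_path.read_text()) if gt_path.exists() else {}
        return CohortDataset(trials=trials, manifest=manifest, ground_truth=gt)


def generate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Generate every trial of a cohort (subject x condition x repetition).

    A configurable number of trials per group is generated with too few
    sway cycles ("corrupted"), exercising the downstream discard rule.
    Fully deterministic for a fixed config.
    """
    config = config or CohortConfig()
    subjects = generate_subject_specs(
        config.n_young, config.n_old, config.population, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)

    rows = []
    layout = [
        (subj, cid, rep)
        for subj in subjects
        for cid in config.condition_ids
        for rep in range(1, config.trials_per_condition + 1)
    ]
    corrupted_ids: set[int] = set()
    for group, n_corr in (("young", config.corrupted_young),
                          ("old", config.corrupted_old)):
        group_idx = [i for i, (s, _, _) in enumerate(layout) if s.group == group]
        if n_corr > len(group_idx):
            raise ConfigurationError(
                f"cannot corrupt {n_corr} of {len(group_idx)} {group} trials")
        corrupted_ids.update(rng.choice(group_idx, size=n_corr, replace=False))

    trials: list[RawTrial] = []
    subject_rngs = {s.subject_id: np.random.default_rng(s.seed) for s in subjects}
    for i, (subj, cid, rep) in enumerate(layout):
        trial_id = f"{subj.subject_id}_c{cid}_r{rep}"
        corrupted = i in corrupted_ids
        n_cycles = config.corrupted_n_cycles if corrupted else config.n_cycles
        trial_seed = int(subject_rngs[subj.subject_id].integers(0, 2**31 - 1))
        trial = generate_trial(
            subj, config.conditions[cid], n_cycles=n_cycles, seed=trial_seed,
            noise_sd=config.noise_sd, timestamp_jitter=config.timestamp_jitter,
            population=config.population, trial_id=trial_id)
        trials.append(trial)
        rows.append({
            "trial_id": trial_id, "subject_id": subj.subject_id,
            "group": subj.group, "condition_id": cid, "repetition": rep,
            "corrupted": corrupted, "seed": trial_seed,
        })

    manifest = pd.DataFrame(rows)
    ground_truth = {
        "config": {
            "n_young": config.n_young, "n_old": config.n_old,
            "condition_ids": list(config.condition_ids),
            "trials_per_condition": config.trials_per_condition,
            "n_cycles": config.n_cycles,
            "corrupted_young": config.corrupted_young,
            "corrupted_old": config.corrupted_old,
            "corrupted_n_cycles": config.corrupted_n_cycles,
            "noise_sd": config.noise_sd,
            "timestamp_jitter": config.timestamp_jitter,
            "seed": config.seed,
        },
        "subjects": [dataclasses.asdict(s) for s in subjects],
        "conditions": {str(k): dataclasses.asdict(v)
                       for k, v in config.conditions.items()},
        "population": dataclasses.asdict(config.population),
    }
    return CohortDataset(trials=trials, manifest=manifest,
                         ground_truth=ground_truth)
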