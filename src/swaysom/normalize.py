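"""Amplitude-equalizing posture normalization.

Centering and rescaling remove between-subject differences in body size and
sway magnitude while keeping the within-trial movement structure: each
trial's mean posture is subtracted (centering), the mean absolute excursion
of every coordinate is measured per trial, and each coordinate is rescaled
by the ratio of the cohort-wide mean amplitude to the trial's own, so that
after normalization every coordinate has the same mean amplitude in every
trial.  Differences in amplitude *between* coordinates (e.g. shoulder ML
versus knee vertical) are preserved — only between-trial differences are
equalized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateTrialError

AMPLITUDE_MODES = ("per_coordinate", "vector_norm")


def center_trial(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the trial's mean posture from every frame.

    Parameters
    ----------
    frames : (J, K) array of posture vectors for one trial.

    Returns
    -------
    centered : (J, K) array whose column means are zero.
    mean_posture : (K,) the subtracted mean posture.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2 or frames.shape[0] < 1:
        raise ValueError("frames must be a non-empty (J, K) array")
    mean_posture = frames.mean(axis=0)
    return frames - mean_posture, mean_posture


def segment_amplitudes(centered: np.ndarray,
                       mode: str = "per_coordinate") -> np.ndarray:
    """Mean amplitude of each coordinate over the frames of one trial.

    Default reading: the mean over frames of the absolute value of each
    centered coordinate, giving one amplitude per coordinate so the scale
    factors are well defined per coordinate.  ``mode="vector_norm"``
    instead uses the mean Euclidean norm of the whole centered posture
    vector, replicated across coordinates (an alternative reading of the
    amplitude definition; not the default).
    """
    centered = np.asarray(centered, dtype=float)
    if centered.ndim != 2 or centered.shape[0] < 1:
        raise ValueError("centered must be a non-empty (J, K) array")
    col_means = centered.mean(axis=0)
    col_sds = centered.std(axis=0)
    bad = np.abs(col_means) > 1e-6 * np.maximum(col_sds, 1e-300)
    if np.any(bad & (col_sds > 0)):
        warnings.warn("segment_amplitudes expects centered input "
                      "(column means are not ~0)", stacklevel=2)
    if mode == "per_coordinate":
        return np.abs(centered).mean(axis=0)
    if mode == "vector_norm":
        norm = float(np.linalg.norm(centered, axis=1).mean())
        return np.full(centered.shape[1], norm)
    raise ValueError(f"unknown amplitude mode {mode!r}")


@dataclass
class NormalizationModel:
    """Fitted amplitude-normalization model for a cohort of trials."""

    per_trial_means: np.ndarray  # (I, K) per-trial mean amplitudes, metres
    grand_means: np.ndarray  # (K,) cohort-wide mean amplitudes, metres
    scale_factors: np.ndarray  # (I, K) = grand_means / per_trial_means
    trial_mean_postures: np.ndarray  # (I, K) subtracted mean postures, metres
    mode: str = "per_coordinate"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "grand_means": self.grand_means.tolist(),
            "per_trial_means": self.per_trial_means.tolist(),
            "scale_factors": self.scale_factors.tolist(),
            "trial_mean_postures": self.trial_mean_postures.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            per_trial_means=np.asarray(payload["per_trial_means"]),
            grand_means=np.asarray(payload["grand_means"]),
            scale_factors=np.asarray(payload["scale_factors"]),
            trial_mean_postures=np.asarray(payload["trial_mean_postures"]),
            mode=payload.get("mode", "per_coordinate"),
        )


def fit_normalization(values: np.ndarray,
                      mode: str = "per_coordinate",
                      trial_ids: list[str] | None = None) -> NormalizationModel:
    """Fit the normalization model on the whole cohort.

    Parameters
    ----------
    values : (I, J, K) raw posture array (uncentered).

    The model pools all trials (both groups, all conditions) when forming
    the cohort-wide mean amplitudes; it can be persisted and applied with
    frozen grand means to held-out data.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("values must be an (I, J, K) array")
    I, J, K = values.shape
    mean_postures = values.mean(axis=1)  # (I, K)
    centered = values - mean_postures[:, None, :]
    if mode == "per_coordinate":
        per_trial = np.abs(centered).mean(axis=1)  # (I, K)
    elif mode == "vector_norm":
        per_trial = np.repeat(
            np.linalg.norm(centered, axis=2).mean(axis=1)[:, None], K, axis=1)
    else:
        raise ValueError(f"unknown amplitude mode {mode!r}")
    # a constant coordinate centers to rounding residue, not exactly 0
    tol = 1e-12 * (np.abs(values).max() + 1.0)
    zero = np.argwhere(per_trial <= tol)
    if len(zero):
        i, k = zero[0]
        name = trial_ids[i] if trial_ids else f"trial index {i}"
        raise DegenerateTrialError(
            f"zero mean amplitude for {name}, coordinate {k}: "
            "cannot form a scale factor")
    grand = per_trial.mean(axis=0)  # (K,)
    return NormalizationModel(
        per_trial_means=per_trial, grand_means=grand,
        scale_factors=grand / per_trial, trial_mean_postures=mean_postures,
        mode=mode)


@dataclass
class NormalizedArray:
    """Centered, amplitude-normalized posture array Psi (I x J x K)."""

    values: np.ndarray
    index: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (I, J, K)")

    def flatten(self) -> tuple[np.ndarray, pd.DataFrame]:
        return flatten_for_som(self.values, self.index)


def apply_normalization(values: np.ndarray, model: NormalizationModel,
                        validate: bool = True) -> NormalizedArray:
    """Center each trial and multiply by its per-coordinate scale factors.

    psi[i, j, k] = (p[i, j, k] - mean_j p[i, j, k]) * f[i, k].

    With ``validate=True`` the defining property is checked: for every
    trial and coordinate the mean absolute normalized value equals the
    cohort grand mean within 1e-9 relative (per-coordinate mode only).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[0] != model.scale_factors.shape[0] \
            or values.shape[2] != model.scale_factors.shape[1]:
        raise ValueError("values shape does not match the fitted model")
    centered = values - values.mean(axis=1, keepdims=True)
    psi = centered * model.scale_factors[:, None, :]
    if validate and model.mode == "per_coordinate":
        achieved = np.abs(psi).mean(axis=1)  # (I, K)
        rel = np.abs(achieved - model.grand_means) / model.grand_means
        if np.max(rel) > 1e-9:
            raise RuntimeError(
                "normalization post-condition violated: mean |psi| deviates "
                f"from the grand means by up to {np.max(rel):.3g} relative "
                "(was the model fitted on different data?)")
    return NormalizedArray(values=psi)


def normalize_with_grand_means(values: np.ndarray, grand_means: np.ndarray,
                               mode: str = "per_coordinate") -> np.ndarray:
    """Normalize trials against frozen cohort grand means.

    Centers each trial, measures its own per-coordinate amplitudes, and
    rescales to the given reference amplitudes.  Because the reference is
    frozen, the result is exactly invariant under rescaling a trial's raw
    coordinates by any positive constant; this is also the entry point for
    normalizing held-out data against a persisted model.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("values must be (I, J, K)")
    grand_means = np.asarray(grand_means, dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    if mode == "per_coordinate":
        per_trial = np.abs(centered).mean(axis=1)
    elif mode == "vector_norm":
        per_trial = np.repeat(
            np.linalg.norm(centered, axis=2).mean(axis=1)[:, None],
            values.shape[2], axis=1)
    else:
        raise ValueError(f"unknown amplitude mode {mode!r}")
    if np.any(per_trial <= 1e-12 * (np.abs(values).max() + 1.0)):
        raise DegenerateTrialError("zero mean amplitude in some coordinate")
    return centered * (grand_means / per_trial)[:, None, :]


def flatten_for_som(values: np.ndarray,
                    index: pd.DataFrame | None = None
                    ) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack an (I, J, K) array into the ((I*J), K) SOM input matrix.

    Row order is trial-major, frame-minor; the returned row index maps
    every row back to its (trial, frame) pair (0-based), so the mapping is
    invertible: row = trial * J + frame.
    """
    values = np.asarray(values, dtype=float)
    I, J, K = values.shape
    matrix = values.reshape(I * J, K)
    row_index = pd.DataFrame({
        "trial": np.repeat(np.arange(I), J),
        "frame": np.tile(np.arange(J), I),
    })
    if index is not None:
        row_index["trial_id"] = np.repeat(index["trial_id"].to_numpy(), J)
    return matrix, row_index
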