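"""Young/old classification of BMU trajectories.

Each trial's trajectory on the first map is flattened into a
600-dimensional vector (the 300 x-coordinates followed by the 300
y-coordinates).  The vectors from the conditions where the groups differ
in TTvar (by default the maximum-frequency and maximum-amplitude
conditions) form the input matrix of a second SOM with 600-dimensional
weights on the same 25 x 25 lattice; every trial is then represented by
its BMU coordinate on that second map.  A k-nearest-neighbour classifier
(k = 5, Euclidean distance, majority vote) is evaluated with repeated
stratified random 70/30 train/test splits (100 runs by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .som import SOMModel, TrainingSchedule, bmu_indices, data_range_of, init_som, train
from .som import BMUTrajectory

TRAJECTORY_DIM = 2 * BMUTrajectory.N_FRAMES  # 600
DEFAULT_CONDITIONS = (3, 5)


def build_trajectory_vectors(
    trajectories: list[BMUTrajectory],
    meta: pd.DataFrame,
    conditions: tuple[int, ...] = DEFAULT_CONDITIONS,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble the (I', 600) trajectory matrix S for selected conditions.

    ``meta`` must carry one row per trajectory (same order) with columns
    trial_id, group, condition_id.  Returns (S, group labels, trial ids)
    restricted to trials from the selected conditions.
    """
    if len(trajectories) != len(meta):
        raise ValueError("one metadata row per trajectory required")
    if len(conditions) == 0:
        raise ValueError("conditions selection must be non-empty")
    rows, labels, ids = [], [], []
    for traj, m in zip(trajectories, meta.itertuples()):
        if m.condition_id not in conditions:
            continue
        rows.append(np.concatenate([traj.nodes[:, 0], traj.nodes[:, 1]]))
        labels.append(m.group)
        ids.append(m.trial_id)
    if not rows:
        raise ValueError(f"no trials in conditions {conditions}")
    S = np.asarray(rows, dtype=float)
    assert S.shape[1] == TRAJECTORY_DIM
    return S, np.asarray(labels), ids


def train_second_som(
    S: np.ndarray,
    rows: int = 25,
    cols: int = 25,
    iterations: int = 1000,
    seed: int = 0,
    schedule: TrainingSchedule | None = None,
) -> tuple[SOMModel, np.ndarray]:
    """Train the trajectory-level SOM and map every trial onto it.

    Returns the trained model and each trial's BMU (x, y) lattice
    coordinates on the second map.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.size == 0:
        raise ValueError("S must be non-empty")
    schedule = schedule or TrainingSchedule(iterations=iterations)
    model = init_som(rows, cols, S.shape[1], data_range_of(S), seed=seed)
    model, _ = train(model, S, schedule=schedule)
    coords = model.coordinates[bmu_indices(model, S)]
    return model, coords


@dataclass
class ClassificationReport:
    """Repeated-split kNN evaluation summary."""

    accuracies: np.ndarray  # per-run fraction correct, in [0, 1]
    k: int
    train_fraction: float
    n_train: int
    n_test: int
    seed: int

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def runs(self) -> int:
        return len(self.accuracies)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "accuracies": self.accuracies.tolist(),
            "k": self.k, "train_fraction": self.train_fraction,
            "n_train": self.n_train, "n_test": self.n_test,
            "runs": self.runs, "seed": self.seed,
        }


def _stratified_split(labels: np.ndarray, train_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def knn_predict(train_x: np.ndarray, train_y: np.ndarray,
                test_x: np.ndarray, k: int) -> np.ndarray:
    """Majority-vote kNN with Euclidean distance.

    Vote ties are broken by the label of the single nearest neighbour.
    """
    d = cdist(np.atleast_2d(test_x), np.atleast_2d(train_x))
    order = np.argsort(d, axis=1, kind="stable")
    nearest = order[:, :k]
    preds = np.empty(len(test_x), dtype=train_y.dtype)
    for i, row in enumerate(nearest):
        votes, counts = np.unique(train_y[row], return_counts=True)
        top = counts.max()
        winners = votes[counts == top]
        if len(winners) == 1:
            preds[i] = winners[0]
        else:
            preds[i] = train_y[row[0]]  # nearest neighbour breaks the tie
    return preds


def knn_classify(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    train_fraction: float = 0.7,
    runs: int = 100,
    seed: int = 0,
) -> ClassificationReport:
    """Repeated stratified-random-split kNN evaluation.

    Per run: a seeded stratified 70/30 split, each test sample labelled by
    the majority of its k nearest training samples, accuracy = fraction
    correct.  The per-run accuracies are retained alongside their mean.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if len(features) != len(labels):
        raise ValueError("features and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    accuracies = np.empty(runs)
    n_train = n_test = 0
    for r in range(runs):
        train_idx, test_idx = _stratified_split(labels, train_fraction, rng)
        if k > len(train_idx):
            raise ValueError(f"k={k} exceeds training-set size {len(train_idx)}")
        preds = knn_predict(features[train_idx], labels[train_idx],
                            features[test_idx], k)
        accuracies[r] = float(np.mean(preds == labels[test_idx]))
        n_train, n_test = len(train_idx), len(test_idx)
    return ClassificationReport(accuracies=accuracies, k=k,
                                train_fraction=train_fraction,
                                n_train=n_train, n_test=n_test, seed=seed)
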