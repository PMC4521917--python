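"""Sequential (online) Kohonen self-organizing map.

A SOM projects K-dimensional input vectors onto a 2-D lattice of nodes,
each carrying a K-dimensional weight vector.  For every presented input the
best matching unit (BMU) — the node whose weights are nearest in Euclidean
distance — and its lattice neighbourhood are pulled toward the input:

    w(t+1) = w(t) + h(t) * eta(t) * (v - w(t))

with a Gaussian neighbourhood h shrinking around the BMU and a decaying
learning rate eta.  One iteration (epoch) presents every input vector once,
in a seeded shuffled order.  After training, a trial's successive posture
vectors map to a trajectory of BMU lattice coordinates.

Schedules: sigma decays linearly from max(rows, cols)/4 to 1 and eta from
0.5 to 0.01 over the configured number of epochs; both are exposed in the
training schedule so desk-scale runs can shrink the map, the data and the
epoch count without touching the algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class TrainingSchedule:
    """Epoch count and the linear decay schedules for sigma and eta."""

    iterations: int = 1000
    sigma_start: float | None = None  # default: max(rows, cols) / 4
    sigma_end: float = 1.0
    eta_start: float = 0.5
    eta_end: float = 0.01

    def sigma(self, t: int, rows: int, cols: int) -> float:
        start = self.sigma_start if self.sigma_start is not None \
            else max(rows, cols) / 4.0
        return _linear(start, self.sigma_end, t, self.iterations)

    def eta(self, t: int) -> float:
        return _linear(self.eta_start, self.eta_end, t, self.iterations)


def _linear(start: float, end: float, t: int, total: int) -> float:
    if total <= 1:
        return start
    frac = t / (total - 1)
    return start + (end - start) * frac


@dataclass
class SOMModel:
    """A rows x cols lattice of K-dimensional weight vectors.

    Node lattice coordinates are 0-based (x, y) = (column, row); the
    row-major node index is y * cols + x, which is also the BMU tie-break
    order (smallest index wins).
    """

    rows: int
    cols: int
    dim: int
    weights: np.ndarray  # (rows * cols, dim)
    seed: int = 0
    trained_epochs: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.rows * self.cols, self.dim):
            raise ValueError("weights must be (rows * cols, dim)")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def coordinates(self) -> np.ndarray:
        """(n_nodes, 2) integer (x, y) lattice coordinates, row-major."""
        ys, xs = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([xs, ys])

    def lattice_sq_distances(self) -> np.ndarray:
        """(n_nodes, n_nodes) squared Euclidean lattice distances."""
        c = self.coordinates.astype(float)
        return cdist(c, c, "sqeuclidean")

    def save(self, json_path: str | Path,
             weights_csv: str | Path | None = None) -> None:
        """Persist config as JSON and the weight table as CSV."""
        json_path = Path(json_path)
        if weights_csv is None:
            weights_csv = json_path.with_suffix(".weights.csv")
        coords = self.coordinates
        table = pd.DataFrame(self.weights,
                             columns=[f"w{k + 1}" for k in range(self.dim)])
        table.insert(0, "node_y", coords[:, 1])
        table.insert(0, "node_x", coords[:, 0])
        table.to_csv(weights_csv, index=False)
        json_path.write_text(json.dumps({
            "rows": self.rows, "cols": self.cols, "dim": self.dim,
            "seed": self.seed, "trained_epochs": self.trained_epochs,
            "weights_csv": str(Path(weights_csv).name),
        }))

    @classmethod
    def load(cls, json_path: str | Path) -> "SOMModel":
        json_path = Path(json_path)
        cfg = json.loads(json_path.read_text())
        table = pd.read_csv(json_path.parent / cfg["weights_csv"])
        weights = table[[f"w{k + 1}" for k in range(cfg["dim"])]].to_numpy()
        return cls(rows=cfg["rows"], cols=cfg["cols"], dim=cfg["dim"],
                   weights=weights, seed=cfg["seed"],
                   trained_epochs=cfg.get("trained_epochs", 0))


def data_range_of(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-coordinate (min, max) of a data matrix, for initialization."""
    data = np.asarray(data, dtype=float)
    return data.min(axis=0), data.max(axis=0)


def init_som(rows: int, cols: int, dim: int,
             data_range: tuple[np.ndarray, np.ndarray] | tuple[float, float],
             seed: int = 0) -> SOMModel:
    """Initialize a SOM with uniformly random weights within the data range."""
    if rows < 1 or cols < 1 or dim < 1:
        raise ValueError("rows, cols and dim must be >= 1")
    lo = np.broadcast_to(np.asarray(data_range[0], dtype=float), (dim,))
    hi = np.broadcast_to(np.asarray(data_range[1], dtype=float), (dim,))
    rng = np.random.default_rng(seed)
    weights = lo + rng.random((rows * cols, dim)) * (hi - lo)
    return SOMModel(rows=rows, cols=cols, dim=dim, weights=weights, seed=seed)


def bmu_indices(model: SOMModel, data: np.ndarray,
                chunk: int = 4096) -> np.ndarray:
    """Row-major BMU node index for every row of ``data`` (vectorized).

    Ties resolve to the smallest row-major index (argmin semantics).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != model.dim:
        raise ValueError(f"input dimension {data.shape[1]} != map dim {model.dim}")
    out = np.empty(len(data), dtype=int)
    for start in range(0, len(data), chunk):
        block = data[start:start + chunk]
        d2 = cdist(block, model.weights, "sqeuclidean")
        out[start:start + chunk] = np.argmin(d2, axis=1)
    return out


def find_bmu(model: SOMModel, vector: np.ndarray) -> tuple[int, int]:
    """Lattice coordinate (x, y) of the best matching unit for one vector."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (model.dim,):
        raise ValueError(f"vector must have dimension {model.dim}")
    idx = int(bmu_indices(model, vector[None, :])[0])
    x, y = model.coordinates[idx]
    return int(x), int(y)


def train(model: SOMModel, data: np.ndarray,
          schedule: TrainingSchedule | None = None,
          seed: int | None = None,
          record_qe: bool = True) -> tuple[SOMModel, list[float]]:
    """Train the map in place with sequential (online) updates.

    One iteration (epoch) presents all N input vectors once, in a freshly
    shuffled order; the BMU and its Gaussian lattice neighbourhood move
    toward each input.  Returns the model and the quantization-error trace
    (initial value followed by one value per epoch when ``record_qe``).
    """
    schedule = schedule or TrainingSchedule()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("training data must be non-empty")
    if data.shape[1] != model.dim:
        raise ValueError(f"data dimension {data.shape[1]} != map dim {model.dim}")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    lat_d2 = model.lattice_sq_distances()
    weights = model.weights
    trace: list[float] = []
    if record_qe:
        trace.append(quantization_error(model, data))
    n = len(data)
    for t in range(schedule.iterations):
        sigma = schedule.sigma(t, model.rows, model.cols)
        eta = schedule.eta(t)
        inv_two_sigma2 = 1.0 / (2.0 * sigma * sigma)
        order = rng.permutation(n)
        for i in order:
            v = data[i]
            diff = v - weights
            bmu = int(np.argmin(np.einsum("nk,nk->n", diff, diff)))
            h = np.exp(-lat_d2[bmu] * inv_two_sigma2)
            weights += (eta * h)[:, None] * diff
        model.trained_epochs += 1
        if record_qe:
            trace.append(quantization_error(model, data))
    return model, trace


def quantization_error(model: SOMModel, data: np.ndarray) -> float:
    """Mean Euclidean distance from inputs to their BMUs' weights."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("data must be non-empty")
    total = 0.0
    chunk = 4096
    for start in range(0, len(data), chunk):
        block = data[start:start + chunk]
        d2 = cdist(block, model.weights, "sqeuclidean")
        total += float(np.sqrt(d2.min(axis=1)).sum())
    return total / len(data)


@dataclass
class BMUTrajectory:
    """Ordered BMU lattice coordinates of one trial's 300 posture vectors."""

    trial_id: str
    nodes: np.ndarray  # (300, 2) integer (x, y) lattice coordinates

    N_FRAMES = 300

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=int)
        if self.nodes.shape != (self.N_FRAMES, 2):
            raise ValueError(f"trajectory must have {self.N_FRAMES} (x, y) nodes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial_id": self.trial_id,
            "frame": np.arange(1, self.N_FRAMES + 1),
            "node_x": self.nodes[:, 0],
            "node_y": self.nodes[:, 1],
        })


def map_trial(model: SOMModel, frames: np.ndarray,
              trial_id: str = "trial") -> BMUTrajectory:
    """Map a trial's 300 normalized posture vectors to its BMU trajectory."""
    frames = np.asarray(frames, dtype=float)
    if frames.shape != (BMUTrajectory.N_FRAMES, model.dim):
        raise ValueError(
            f"frames must be ({BMUTrajectory.N_FRAMES}, {model.dim}), "
            f"got {frames.shape}")
    idx = bmu_indices(model, frames)
    return BMUTrajectory(trial_id=trial_id, nodes=model.coordinates[idx])


def trajectories_to_frame(trajectories: list[BMUTrajectory]) -> pd.DataFrame:
    return pd.concat([t.to_frame() for t in trajectories], ignore_index=True)


def trajectories_from_frame(df: pd.DataFrame) -> list[BMUTrajectory]:
    out = []
    for trial_id, block in df.groupby("trial_id", sort=False):
        block = block.sort_values("frame")
        out.append(BMUTrajectory(
            trial_id=str(trial_id),
            nodes=block[["node_x", "node_y"]].to_numpy()))
    return out
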