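"""Movement-pattern variability from BMU trajectories.

A retained trial contributes ten sway cycles of 30 phase-matched BMU
lattice positions.  Total Trajectory Variability (TTvar) measures how far
apart the ten cycles are on the map: each of the 300 frames receives the
mean Euclidean lattice distance from its BMU to the phase-matched BMUs of
the nine other cycles, and TTvar is the sum of those 300 entries.  TTvar is
expressed in lattice-node distance and therefore has no physical units; it
is zero exactly when all ten cycles trace the same path.

Variability is also resolved over the cycle: per phase, the dispersion of
the ten BMU positions is summarized as an ellipse whose horizontal and
vertical radii are the standard errors of the mean of the x- and
y-coordinates (area = pi * h * v).  Phases are split into "sway endpoint"
phases — seven phases centred on each lateral turning point (the left turn
at the cycle boundary, the right turn at mid-cycle), 14 in total — and the
16 remaining "sway traveling" phases.

Group differences in TTvar are assessed with a Mann-Whitney U test (exact
enumeration for small samples, normal approximation with tie correction
otherwise).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, norm

N_CYCLES = 10
N_PHASES = 30
N_FRAMES = N_CYCLES * N_PHASES

# Endpoint windows: 7 phases centred on phase 1 (left turn, the cycle
# boundary by the cycle definition) and on phase 16 (right turn at
# mid-cycle), 1-based, wrapping across the cycle boundary.
_LEFT_ANCHOR = 1
_RIGHT_ANCHOR = 16
ENDPOINT_PHASES = frozenset(
    ((a - 1 + off) % N_PHASES) + 1
    for a in (_LEFT_ANCHOR, _RIGHT_ANCHOR)
    for off in range(-3, 4)
)
TRAVELING_PHASES = frozenset(range(1, N_PHASES + 1)) - ENDPOINT_PHASES
assert len(ENDPOINT_PHASES) == 14 and len(TRAVELING_PHASES) == 16


def _as_trajectory_nodes(traj) -> np.ndarray:
    nodes = traj.nodes if hasattr(traj, "nodes") else np.asarray(traj)
    nodes = np.asarray(nodes, dtype=float)
    if nodes.shape != (N_FRAMES, 2):
        raise ValueError(f"trajectory must be ({N_FRAMES}, 2), got {nodes.shape}")
    return nodes


def split_into_cycles(traj) -> np.ndarray:
    """Reshape a 300-frame trajectory into (10 cycles, 30 phases, 2)."""
    return _as_trajectory_nodes(traj).reshape(N_CYCLES, N_PHASES, 2)


def pairwise_phase_distance(cycles: np.ndarray, phase: int) -> float:
    """Mean Euclidean lattice distance over all 45 unordered cycle pairs
    at one phase (1-based, 1..30)."""
    cycles = np.asarray(cycles, dtype=float)
    if cycles.shape != (N_CYCLES, N_PHASES, 2):
        raise ValueError("cycles must be (10, 30, 2)")
    if not 1 <= phase <= N_PHASES:
        raise ValueError(f"phase must be in 1..{N_PHASES}")
    points = cycles[:, phase - 1, :]
    return float(pdist(points).mean())


@dataclass
class TTvarResult:
    """TTvar and its per-frame decomposition for one trial."""

    trial_id: str
    ttvar: float
    per_frame: np.ndarray  # (300,) mean distance to the 9 other cycles

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=float)
        if self.per_frame.shape != (N_FRAMES,):
            raise ValueError(f"per_frame must have {N_FRAMES} entries")


def ttvar(traj, trial_id: str | None = None) -> TTvarResult:
    """Total Trajectory Variability of one BMU trajectory.

    Frame j (cycle c, phase b) receives the mean Euclidean lattice distance
    from cycle c's BMU at phase b to the phase-b BMUs of the nine other
    cycles; TTvar is the sum of the 300 per-frame entries.  Zero exactly
    when all ten cycles coincide.
    """
    nodes = _as_trajectory_nodes(traj)
    cycles = nodes.reshape(N_CYCLES, N_PHASES, 2)
    per_frame = np.empty((N_CYCLES, N_PHASES))
    for b in range(N_PHASES):
        dmat = squareform(pdist(cycles[:, b, :]))  # (10, 10)
        per_frame[:, b] = dmat.sum(axis=1) / (N_CYCLES - 1)
    per_frame = per_frame.reshape(N_FRAMES)
    tid = trial_id if trial_id is not None else getattr(traj, "trial_id", "trial")
    return TTvarResult(trial_id=tid, ttvar=float(per_frame.sum()),
                       per_frame=per_frame)


def phase_of(phase: int) -> str:
    """Classify a 1-based cycle phase as 'endpoint' or 'traveling'."""
    if not 1 <= phase <= N_PHASES:
        raise ValueError(f"phase must be in 1..{N_PHASES}")
    return "endpoint" if phase in ENDPOINT_PHASES else "traveling"


def node_variability(cycles: np.ndarray) -> pd.DataFrame:
    """Per-phase variability ellipse of the ten BMU positions.

    Horizontal radius = SEM of the ten x-coordinates, vertical radius =
    SEM of the ten y-coordinates (sample SD / sqrt(10)); area = pi * h * v.
    """
    cycles = np.asarray(cycles, dtype=float)
    if cycles.shape != (N_CYCLES, N_PHASES, 2):
        raise ValueError("cycles must be (10, 30, 2)")
    sd = cycles.std(axis=0, ddof=1)  # (30, 2)
    sem = sd / np.sqrt(N_CYCLES)
    return pd.DataFrame({
        "phase": np.arange(1, N_PHASES + 1),
        "h_radius": sem[:, 0],
        "v_radius": sem[:, 1],
        "area": np.pi * sem[:, 0] * sem[:, 1],
        "phase_type": [phase_of(b) for b in range(1, N_PHASES + 1)],
    })


def phase_summary(ellipses: pd.DataFrame) -> pd.DataFrame:
    """Mean ellipse area and radii over the endpoint and traveling phases."""
    if len(ellipses) != N_PHASES:
        raise ValueError(f"need {N_PHASES} per-phase ellipses")
    out = (ellipses
           .groupby("phase_type", sort=True)[["area", "h_radius", "v_radius"]]
           .mean()
           .reset_index())
    return out


def mann_whitney_u(sample_a, sample_b,
                   method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U test (two-sided) with midrank tie handling.

    Returns (U, p) where U is the statistic for ``sample_a``.  For
    combined sample sizes up to 12 (or ``method="exact"``) the p-value is
    computed by full enumeration of group assignments; otherwise a normal
    approximation with tie correction and continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = len(a), len(b)
    n = na + nb
    ranks = rankdata(np.concatenate([a, b]))
    u_obs = float(ranks[:na].sum() - na * (na + 1) / 2)

    if method == "auto":
        method = "exact" if n <= 12 else "approx"
    if method == "exact":
        offset = na * (na + 1) / 2
        eps = 1e-9
        n_le = n_ge = total = 0
        for combo in itertools.combinations(range(n), na):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return u_obs, p
    if method != "approx":
        raise ValueError(f"unknown method {method!r}")
    mu = na * nb / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / np.sqrt(sigma2)
    return u_obs, float(min(1.0, 2.0 * norm.sf(abs(z))))


def ttvar_table(trajectories, index: pd.DataFrame) -> pd.DataFrame:
    """TTvar for every trajectory, joined with trial metadata.

    ``index`` must have one row per trajectory (trial_id, subject_id,
    group, condition_id) in the same order.
    """
    if len(trajectories) != len(index):
        raise ValueError("one metadata row per trajectory required")
    rows = []
    for traj, meta in zip(trajectories, index.itertuples()):
        res = ttvar(traj)
        rows.append({
            "trial_id": meta.trial_id, "subject_id": meta.subject_id,
            "group": meta.group, "condition_id": meta.condition_id,
            "ttvar": res.ttvar,
        })
    return pd.DataFrame(rows)


def group_comparison(ttvar_df: pd.DataFrame) -> dict[int, dict[str, float]]:
    """Per-condition young-vs-old Mann-Whitney comparison of TTvar."""
    out: dict[int, dict[str, float]] = {}
    for cid, block in ttvar_df.groupby("condition_id"):
        young = block.loc[block["group"] == "young", "ttvar"].to_numpy()
        old = block.loc[block["group"] == "old", "ttvar"].to_numpy()
        if len(young) == 0 or len(old) == 0:
            continue
        u, p = mann_whitney_u(old, young)
        out[int(cid)] = {
            "median_young": float(np.median(young)),
            "median_old": float(np.median(old)),
            "u": u, "p": p,
            "n_young": len(young), "n_old": len(old),
        }
    return out
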