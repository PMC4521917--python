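"""Basic visualization of BMU trajectories on the lattice."""

from __future__ import annotations

import numpy as np

from .variability import node_variability, split_into_cycles


def plot_trajectory(traj, ax=None, show_ellipses: bool = True):
    """Plot the mean cycle path of a BMU trajectory on the lattice.

    Draws the phase-wise mean position of the ten cycles, connected in
    phase order, with the per-phase SEM variability ellipses.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots()
    cycles = split_into_cycles(traj)
    mean_path = cycles.mean(axis=0)  # (30, 2)
    closed = np.vstack([mean_path, mean_path[:1]])
    ax.plot(closed[:, 0], closed[:, 1], "o-", ms=3, lw=1)
    if show_ellipses:
        for row in node_variability(cycles).itertuples():
            ax.add_patch(Ellipse(
                mean_path[row.phase - 1], 2 * row.h_radius, 2 * row.v_radius,
                fill=False, edgecolor="tab:blue", alpha=0.6))
    ax.set_xlabel("lattice x")
    ax.set_ylabel("lattice y")
    ax.set_aspect("equal")
    return ax
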