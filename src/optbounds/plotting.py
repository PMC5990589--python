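"""Policy-raster plotting (a convenience layer; CSV/JSON are the contract)."""

from __future__ import annotations

import numpy as np

from .mdp import TaskModel, lattice_arrays
from .solver import GO, PASS, Policy


def plot_policy(policy: Policy, model: TaskModel, ax=None, t_crop: int | None = 50):
    """Raster of optimal actions over the (t, x) lattice.

    Grey = wait, black = go, red = pass; off-lattice cells are white.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    T = policy.t_max if t_crop is None else min(t_crop, policy.t_max)
    grid = np.full((2 * T + 1, T + 1), np.nan)
    t_arr, x_arr = lattice_arrays(policy.t_max)
    mask = t_arr <= T
    grid[x_arr[mask] + T, t_arr[mask]] = policy.actions[mask]

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    cmap = ListedColormap(["0.8", "black", "tab:red"])
    ax.imshow(
        grid,
        origin="lower",
        aspect="auto",
        cmap=cmap,
        vmin=-0.5,
        vmax=2.5,
        extent=(-0.5, T + 0.5, -T - 0.5, T + 0.5),
        interpolation="nearest",
    )
    ax.set_xlabel("time step $t$")
    ax.set_ylabel("cumulative evidence $x = n_u - n_d$")
    return ax
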