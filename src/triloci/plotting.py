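"""Minimal inspection plots (not publication rendering)."""

from __future__ import annotations


from .density import DensityMap


def plot_density_map(dmap: DensityMap, ax=None, cmap="turbo"):
    """Contour rendering of one map with the point levels overlaid.

    Warm colors mark high density; the heavy contour is the 30% level
    boundary.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if dmap.f_grid is None:
        raise ValueError("map was built without a rendered grid")
    if ax is None:
        _, ax = plt.subplots()
    # de-standardize grid axes for display
    gx = dmap.grid_x * dmap.scale[0] + dmap.mean[0]
    gy = dmap.grid_y * dmap.scale[1] + dmap.mean[1]
    ax.contourf(gx, gy, dmap.f_grid.T, levels=10, cmap=cmap)
    u3 = dmap.levels <= 3
    ax.plot(dmap.points_raw[~u3, 0], dmap.points_raw[~u3, 1], ".", ms=2, color="0.6")
    ax.plot(dmap.points_raw[u3, 0], dmap.points_raw[u3, 1], ".", ms=3, color="k")
    ax.set_xlabel(f"{dmap.axis_i} (um)")
    ax.set_ylabel(f"{dmap.axis_j} (rad)")
    return ax
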