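"""Summary figures: polar tuning curves and primitive-space scatter."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = ["plot_polar_tuning", "plot_primitive_space", "plot_spacetime_map"]


def plot_polar_tuning(directions, responses, ax=None, label=None):
    """Polar plot of per-direction responses (closed curve)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    th = np.append(np.asarray(directions, dtype=float),
                   directions[0] if len(directions) else 0.0)
    r = np.append(np.maximum(np.asarray(responses, dtype=float), 0.0),
                  max(responses[0], 0.0) if len(responses) else 0.0)
    ax.plot(th, r, marker="o", label=label)
    ax.set_theta_zero_location("E")
    return ax


def plot_primitive_space(coords: Sequence, ax=None, inhibitory: bool = False,
                         threshold: float = 0.20):
    """Scatter circuits in primitive space with the presence ring.

    ``coords`` is a sequence of PrimitiveCoordinates; color encodes the
    DSI annotation where available.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    xs, ys, cs = [], [], []
    for c in coords:
        x = c.x_inh if inhibitory else c.x
        y = c.y_inh if inhibitory else c.y
        if x is None or y is None:
            continue
        xs.append(x)
        ys.append(y)
        cs.append(c.dsi if c.dsi is not None else 0.0)
    sc = ax.scatter(xs, ys, c=cs, cmap="viridis", s=30)
    ax.add_patch(plt.Circle((0, 0), threshold, fill=False, ls="--", color="gray"))
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    if inhibitory:
        ax.set_xlabel("anti-B&L  <->  B&L")
        ax.set_ylabel("tuned inhibition  <->  pause")
    else:
        ax.set_xlabel("anti-H&R  <->  H&R")
        ax.set_ylabel("amplitude  <->  alignment")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    plt.colorbar(sc, ax=ax, label="DSI")
    return ax


def plot_spacetime_map(st_map, ax=None):
    """Signed space-time map, depolarization green / hyperpolarization red."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vmax = np.abs(st_map.values).max() or 1.0
    im = ax.pcolormesh(st_map.bin_times, st_map.bar_positions, st_map.values,
                       cmap="PiYG", vmin=-vmax, vmax=vmax)
    ax.set_xlabel("time after bar onset (ms)")
    ax.set_ylabel("bar position (µm)")
    plt.colorbar(im, ax=ax, label="response (mV)")
    return ax
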