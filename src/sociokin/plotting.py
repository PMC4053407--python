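"""Basic plots: weighted association network coloured by social unit,
and lagged association rate curves with fitted social models."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import numpy as np  # noqa: E402

from .matrices import DyadicMatrix  # noqa: E402
from .network import Partition  # noqa: E402
from .temporal import LARCurve, SocialModel  # noqa: E402


def plot_network(m: DyadicMatrix, partition: Partition | None = None,
                 ax=None, seed: int = 0):
    """Spring-layout association network; edge width follows HWI, node
    colour follows social unit."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    g = nx.Graph()
    g.add_nodes_from(m.ids)
    iu = np.triu_indices(m.n, k=1)
    for i, j in zip(*iu):
        w = m.values[i, j]
        if np.isfinite(w) and w > 0:
            g.add_edge(m.ids[i], m.ids[j], weight=float(w))
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    colors = None
    if partition is not None:
        mem = partition.membership()
        colors = [mem.get(n, -1) for n in g.nodes]
    widths = [4.0 * g[u][v]["weight"] for u, v in g.edges]
    nx.draw_networkx(g, pos=pos, ax=ax, node_color=colors, cmap="tab10",
                     width=widths, font_size=7, node_size=180)
    ax.set_axis_off()
    return ax


def plot_lar(curve: LARCurve, model: SocialModel | None = None, ax=None):
    """LAR with jackknife error bars, the null association rate, and an
    optional fitted model curve (log-scaled lag axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(curve.lag_mid, curve.g, yerr=curve.se, fmt="o", ms=4,
                capsize=2, label="lagged association rate")
    ax.axhline(curve.null_rate, ls="--", color="grey", label="null rate")
    if model is not None:
        order = np.argsort(curve.lag_mid)
        ax.plot(curve.lag_mid[order], model.predict(curve.lag_mid[order]), "-",
                label=f"best model ({model.name})")
    ax.set_xscale("log")
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("association rate")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False, fontsize=8)
    return ax
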