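"""Static figures: taxa bars, NMDS scatter, indicator dot plot, network layout.

Each function draws on a provided or fresh matplotlib Axes and returns the
Figure; `save_standard_figures` writes the standard PNG set for a pipeline
output directory. Aesthetics are intentionally plain.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .diversity import OrdinationResult
from .tables_io import OtuTable

GROUP_COLORS = {"unexposed": "tab:red", "four_day": "tab:blue", "seven_day": "tab:green"}


def _color(group: str, i: int) -> str:
    return GROUP_COLORS.get(group, f"C{i}")


def taxa_bars(table: OtuTable, top: int = 10, ax=None):
    """Stacked relative-abundance bars of the `top` most abundant taxa."""
    ax = ax or plt.figure(figsize=(10, 4)).add_subplot()
    rel = table.relative_abundance()
    top_taxa = rel.mean(axis=0).nlargest(top).index
    rest = 1 - rel[top_taxa].sum(axis=1)
    bottom = np.zeros(table.n_samples)
    for taxon in top_taxa:
        ax.bar(range(table.n_samples), rel[taxon], bottom=bottom, label=str(taxon)[:24])
        bottom += rel[taxon].to_numpy()
    ax.bar(range(table.n_samples), rest, bottom=bottom, color="lightgrey", label="other")
    ax.set_xticks(range(table.n_samples))
    ax.set_xticklabels(table.sample_ids, rotation=90, fontsize=5)
    ax.set_ylabel("relative abundance")
    ax.legend(fontsize=6, ncol=2)
    return ax.figure


def nmds_plot(ordination: OrdinationResult, groups: pd.Series, ax=None):
    """2-D NMDS scatter colored by group, stress in the title."""
    ax = ax or plt.figure(figsize=(5, 5)).add_subplot()
    coords = ordination.coordinates
    for i, g in enumerate(pd.unique(groups.loc[coords.index])):
        pts = coords[groups.loc[coords.index] == g]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], label=g, color=_color(g, i), s=25)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.set_title(f"NMDS (stress = {ordination.stress:.3f})")
    ax.legend(fontsize=8)
    return ax.figure


def indicator_dotplot(results: pd.DataFrame, ax=None):
    """Indicator values per OTU; point size ~ class relative abundance,
    color ~ class frequency."""
    ax = ax or plt.figure(figsize=(6, max(2, 0.25 * len(results)))).add_subplot()
    if results.empty:
        ax.set_title("no indicators selected")
        return ax.figure
    order = results.sort_values(["class", "IV"])
    sizes = 2000 * order["class_relative_abundance"].clip(lower=1e-4)
    sc = ax.scatter(
        order["IV"], range(len(order)), s=sizes, c=order["class_frequency"],
        cmap="viridis", vmin=0, vmax=1,
    )
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order.index, fontsize=6)
    ax.set_xlabel("indicator value")
    ax.figure.colorbar(sc, ax=ax, label="class frequency")
    return ax.figure


def network_plot(net: nx.Graph, communities: list[set] | None = None, ax=None, seed: int = 0):
    """Spring layout; node size ~ degree, intra-community edges black,
    inter-community edges red."""
    ax = ax or plt.figure(figsize=(6, 6)).add_subplot()
    if net.number_of_nodes() == 0:
        ax.set_title("empty network")
        return ax.figure
    pos = nx.spring_layout(net, seed=seed)
    membership = {}
    if communities:
        membership = {v: i for i, c in enumerate(communities) for v in c}
    edge_colors = [
        "black" if membership.get(a) == membership.get(b) else "red"
        for a, b in net.edges
    ]
    node_sizes = [20 + 15 * net.degree(v) for v in net.nodes]
    node_colors = [membership.get(v, 0) for v in net.nodes]
    nx.draw_networkx_edges(net, pos, ax=ax, edge_color=edge_colors, width=0.6, alpha=0.6)
    nx.draw_networkx_nodes(
        net, pos, ax=ax, node_size=node_sizes, node_color=node_colors, cmap="tab20"
    )
    ax.set_axis_off()
    ax.set_title(net.graph.get("group") or "")
    return ax.figure


def save_standard_figures(
    table: OtuTable,
    ordination: OrdinationResult,
    indicator_results: pd.DataFrame,
    nets: dict[str, nx.Graph],
    out_dir: str | Path,
) -> list[Path]:
    """Write the standard PNG set; returns the written paths."""
    from .networks import greedy_communities

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fig in (
        ("taxa_bars.png", taxa_bars(table)),
        ("nmds.png", nmds_plot(ordination, table.groups)),
        ("indicators.png", indicator_dotplot(indicator_results)),
    ):
        path = out / name
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    for g, net in nets.items():
        fig = network_plot(net, greedy_communities(net))
        path = out / f"network_{g}.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
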