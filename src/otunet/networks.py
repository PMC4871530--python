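"""Per-group Spearman co-occurrence networks and topology comparison.

For each exposure group, Spearman rank correlations are computed for every
OTU pair; weak (|rho| < 0.5) or non-significant (p > 0.05 or q > 0.2)
correlations are filtered out, and the survivors form an undirected signed
network whose vertices are OTUs (weighted by group-mean abundance) and
whose edges carry the correlation coefficient. Topology is summarized with
degree, normalized betweenness centrality and greedy-modularity community
counts, and networks are compared across groups with Fisher's exact test on
edge signs, Mann-Whitney tests on centrality distributions, and shared-
vertex (Venn) counts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import holm_adjust, mann_whitney, storey_qvalues
from .tables_io import OtuTable

__all__ = [
    "spearman_matrix",
    "build_network",
    "betweenness",
    "greedy_communities",
    "NetworkSummary",
    "network_summary",
    "compare_networks",
    "group_networks",
    "venn_counts",
]


def spearman_matrix(table: OtuTable) -> pd.DataFrame:
    """All-pairs Spearman correlations within one group's samples.

    Midrank (average-rank) Spearman rho; two-sided p from the
    t = rho * sqrt((n-2)/(1-rho^2)) approximation on n-2 degrees of
    freedom; Storey q-values across all pairs of this matrix. OTUs with
    constant abundance are skipped (rho undefined for zero variance).

    Returns a frame with columns otu_a, otu_b, rho, p, q (one row per
    unordered pair).
    """
    n = table.n_samples
    if n < 4:
        raise ValueError("need at least four samples for correlation analysis")
    counts = table.counts
    variable = counts.columns[counts.nunique(axis=0) > 1]
    sub = counts[variable].to_numpy(dtype=float)
    if len(variable) < 2:
        return pd.DataFrame(columns=["otu_a", "otu_b", "rho", "p", "q"])

    rho, p = stats.spearmanr(sub)
    if np.ndim(rho) == 0:  # scipy returns scalars for exactly two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu = np.triu_indices(len(variable), k=1)
    records = pd.DataFrame(
        {
            "otu_a": np.asarray(variable)[iu[0]],
            "otu_b": np.asarray(variable)[iu[1]],
            "rho": rho[iu],
            "p": p[iu],
        }
    )
    records["q"] = storey_qvalues(records["p"].to_numpy())
    return records


def build_network(
    records: pd.DataFrame,
    rho_min: float = 0.5,
    p_max: float = 0.05,
    q_max: float = 0.2,
    group_abundances: pd.Series | None = None,
    group: str | None = None,
) -> nx.Graph:
    """Filter correlation records into a signed co-occurrence network.

    An edge survives iff |rho| >= rho_min, p <= p_max and q <= q_max.
    Self-correlations and duplicate (A,B)/(B,A) records are trimmed; OTUs
    with no surviving edge do not appear as vertices. The result is
    independent of record ordering.
    """
    g = nx.Graph(group=group)
    keep = records[
        (records["rho"].abs() >= rho_min)
        & (records["p"] <= p_max)
        & (records["q"] <= q_max)
    ]
    for row in keep.sort_values(["otu_a", "otu_b"]).itertuples():
        a, b = sorted((row.otu_a, row.otu_b))
        if a == b or g.has_edge(a, b):
            continue
        g.add_edge(
            a,
            b,
            rho=float(row.rho),
            p=float(row.p),
            q=float(row.q),
            sign="positive" if row.rho > 0 else "negative",
        )
    if group_abundances is not None:
        for v in g.nodes:
            g.nodes[v]["mean_abundance"] = float(group_abundances.get(v, np.nan))
    return g


def betweenness(net: nx.Graph) -> pd.Series:
    """Normalized betweenness centrality (Brandes) on the unweighted graph.

    Normalization divides by (n-1)(n-2)/2 pairs; disconnected pairs
    contribute nothing.
    """
    if net.number_of_nodes() == 0:
        return pd.Series(dtype=float, name="betweenness")
    bc = nx.betweenness_centrality(net, normalized=True, weight=None)
    return pd.Series(bc, name="betweenness").sort_index()


def greedy_communities(net: nx.Graph) -> list[set]:
    """Clauset-Newman-Moore greedy modularity communities.

    Runs on the unweighted, sign-stripped graph (modularity is undefined
    for negative weights). Communities are returned sorted by (size desc,
    smallest member) for deterministic output; every community lies within
    one connected component.
    """
    n = net.number_of_nodes()
    if n == 0:
        return []
    if net.number_of_edges() == 0:
        comms = [{v} for v in net.nodes]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(net, weight=None)]
    return sorted(comms, key=lambda c: (-len(c), min(c)))


@dataclass
class NetworkSummary:
    """Per-network topology summary (the usual network-properties table)."""

    group: str | None
    vertices: int
    total_edges: int
    positive_edges: int
    negative_edges: int
    mean_degree: float
    mean_betweenness: float
    vertices_with_negative_edge: int
    pct_vertices_with_negative_edge: float
    vertices_with_positive_edge: int
    pct_vertices_with_positive_edge: float
    communities: int

    def to_dict(self) -> dict:
        return asdict(self)


def network_summary(net: nx.Graph) -> NetworkSummary:
    """Compute the summary columns: counts, mean degree 2E/V, mean
    normalized betweenness, vertices with >=1 negative/positive edge and
    community count."""
    v = net.number_of_nodes()
    e = net.number_of_edges()
    group = net.graph.get("group")
    if v == 0:
        return NetworkSummary(group, 0, 0, 0, 0, 0.0, 0.0, 0, 0.0, 0, 0.0, 0)
    signs = nx.get_edge_attributes(net, "sign")
    pos = sum(1 for s in signs.values() if s == "positive")
    neg = e - pos
    with_neg = sum(
        1
        for n_ in net.nodes
        if any(net.edges[n_, m]["sign"] == "negative" for m in net.neighbors(n_))
    )
    with_pos = sum(
        1
        for n_ in net.nodes
        if any(net.edges[n_, m]["sign"] == "positive" for m in net.neighbors(n_))
    )
    bc = betweenness(net)
    return NetworkSummary(
        group=group,
        vertices=v,
        total_edges=e,
        positive_edges=pos,
        negative_edges=neg,
        mean_degree=2 * e / v,
        mean_betweenness=float(bc.mean()),
        vertices_with_negative_edge=with_neg,
        pct_vertices_with_negative_edge=100.0 * with_neg / v,
        vertices_with_positive_edge=with_pos,
        pct_vertices_with_positive_edge=100.0 * with_pos / v,
        communities=len(greedy_communities(net)),
    )


def edge_sign_fisher(a: NetworkSummary, b: NetworkSummary) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 positive/negative table."""
    table = [
        [a.positive_edges, a.negative_edges],
        [b.positive_edges, b.negative_edges],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def compare_networks(a: nx.Graph, b: nx.Graph) -> dict:
    """Pairwise topology comparison of two co-occurrence networks.

    Fisher's exact test on edge-sign proportions, Mann-Whitney tests on
    the per-vertex degree and betweenness distributions (vertices treated
    as observations), and shared/unique vertex counts.
    """
    if a.number_of_nodes() == 0 or b.number_of_nodes() == 0:
        raise ValueError("both networks must be non-empty")
    sa, sb = network_summary(a), network_summary(b)
    odds, fisher_p = edge_sign_fisher(sa, sb)
    deg_a = np.array([d for _, d in a.degree()], dtype=float)
    deg_b = np.array([d for _, d in b.degree()], dtype=float)
    _, degree_p = mann_whitney(deg_a, deg_b)
    _, betw_p = mann_whitney(betweenness(a).to_numpy(), betweenness(b).to_numpy())
    va, vb = set(a.nodes), set(b.nodes)
    return {
        "groups": (a.graph.get("group"), b.graph.get("group")),
        "fisher_odds_ratio": odds,
        "fisher_p": fisher_p,
        "degree_mw_p": degree_p,
        "betweenness_mw_p": betw_p,
        "shared_vertices": len(va & vb),
        "unique_to_a": len(va - vb),
        "unique_to_b": len(vb - va),
    }


def group_networks(
    table: OtuTable,
    rho_min: float = 0.5,
    p_max: float = 0.05,
    q_max: float = 0.2,
) -> dict[str, nx.Graph]:
    """Build one co-occurrence network per exposure group.

    q-values are computed within each group's correlation matrix
    separately (each network stands alone).
    """
    nets: dict[str, nx.Graph] = {}
    for g in pd.unique(table.groups):
        sub = table.select_group(g)
        records = spearman_matrix(sub)
        nets[g] = build_network(
            records,
            rho_min=rho_min,
            p_max=p_max,
            q_max=q_max,
            group_abundances=sub.counts.mean(axis=0),
            group=g,
        )
    return nets


def venn_counts(nets: dict[str, nx.Graph]) -> dict[str, int]:
    """Shared-vertex counts for every region of the group Venn diagram."""
    sets = {g: set(n.nodes) for g, n in nets.items()}
    labels = list(sets)
    out: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[g] for g in combo))
            outside = set.union(set(), *(sets[g] for g in labels if g not in combo))
            out["&".join(combo)] = len(inside - outside)
    return out


def export_graphml(net: nx.Graph, path) -> None:
    """Write the network as GraphML (attributes included)."""
    nx.write_graphml(net, path)


def pairwise_network_comparisons(nets: dict[str, nx.Graph]) -> pd.DataFrame:
    """All pairwise comparisons with Holm adjustment of the Fisher p-values."""
    rows = []
    for a, b in combinations(nets, 2):
        rows.append(compare_networks(nets[a], nets[b]))
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fisher_p_holm"] = holm_adjust(df["fisher_p"].to_numpy())
    return df
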