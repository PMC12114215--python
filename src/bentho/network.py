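"""Co-occurrence networks: Spearman edge screening, topology vs Erdős–Rényi
nulls, small-world coefficient, Louvain modules, and Zi–Pi node roles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import shortest_path

from .table import CommunityTable, prevalence_filter, transform

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class Network:
    """Undirected signed co-occurrence network."""

    graph: nx.Graph
    edges: pd.DataFrame  # source, target, rho, p, sign
    positive_fraction: float
    negative_fraction: float
    settings: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    table: CommunityTable,
    min_prevalence: float = 0.25,
    r_threshold: float = 0.7,
    p_threshold: float = 0.05,
    use: str = "relative",
) -> Network:
    """Build a co-occurrence network from a count table.

    Taxa present in more than ``min_prevalence`` of samples are screened
    pairwise by Spearman rank correlation (two-sided t-approximation p);
    edges require |rho| > ``r_threshold`` and p < ``p_threshold``.  Isolated
    nodes are dropped.
    """
    if table.n_samples < 10:
        warnings.warn("fewer than 10 samples: correlation screening is weak")
    filtered = prevalence_filter(table, min_prevalence)
    if filtered.n_taxa < 2:
        raise ValueError("fewer than two taxa pass the prevalence filter")
    data = transform(filtered, "relative") if use == "relative" else filtered
    x = data.matrix()
    rho, p = stats.spearmanr(x)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    taxa = np.asarray(filtered.taxon_ids)
    iu = np.triu_indices(len(taxa), 1)
    keep = (np.abs(rho[iu]) > r_threshold) & (p[iu] < p_threshold)
    edges = pd.DataFrame(
        {
            "source": taxa[iu[0][keep]],
            "target": taxa[iu[1][keep]],
            "rho": rho[iu][keep],
            "p": p[iu][keep],
        }
    )
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, rho=float(row.rho), sign=row.sign)
    n_pos = int((edges["sign"] == "positive").sum())
    n_edges = len(edges)
    return Network(
        graph=g,
        edges=edges,
        positive_fraction=n_pos / n_edges if n_edges else float("nan"),
        negative_fraction=1 - n_pos / n_edges if n_edges else float("nan"),
        settings={
            "min_prevalence": min_prevalence,
            "r_threshold": r_threshold,
            "p_threshold": p_threshold,
            "use": use,
        },
    )


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def _adjacency(net_or_graph) -> np.ndarray:
    if isinstance(net_or_graph, Network):
        g = net_or_graph.graph
    else:
        g = net_or_graph
    return nx.to_numpy_array(g, weight=None).astype(bool)


def topology_metrics(net_or_adj) -> dict:
    """AD, MD-free topology metrics from an adjacency matrix.

    average degree AD = 2E/V; graph density GD = 2E/(V(V−1)); clustering
    coefficient CC = mean local clustering (nodes of degree < 2 contribute
    0); average path length APL = mean shortest path over connected pairs;
    network diameter ND = longest shortest path within components.
    """
    adj = net_or_adj if isinstance(net_or_adj, np.ndarray) else _adjacency(net_or_adj)
    adj = adj.astype(float)
    v = adj.shape[0]
    deg = adj.sum(axis=0)
    e = deg.sum() / 2
    if e == 0:
        raise ValueError("network has no edges")
    triangles = ((adj @ adj) * adj).sum(axis=1) / 2.0
    possible = deg * (deg - 1) / 2.0
    local = np.divide(triangles, possible, out=np.zeros(v), where=possible > 0)
    dist = shortest_path(sparse.csr_matrix(adj), method="D", unweighted=True)
    finite = np.isfinite(dist) & ~np.eye(v, dtype=bool)
    apl = float(dist[finite].mean()) if finite.any() else float("nan")
    nd = float(dist[finite].max()) if finite.any() else float("nan")
    return {
        "n_nodes": int(v),
        "n_edges": int(e),
        "AD": float(2 * e / v),
        "GD": float(2 * e / (v * (v - 1))) if v > 1 else float("nan"),
        "CC": float(local.mean()),
        "APL": apl,
        "ND": nd,
    }


def _random_gnm_adjacency(v: int, e: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform G(V, E) random graph as a boolean adjacency matrix."""
    iu = np.triu_indices(v, 1)
    total = iu[0].size
    chosen = rng.choice(total, size=e, replace=False)
    adj = np.zeros((v, v), dtype=bool)
    adj[iu[0][chosen], iu[1][chosen]] = True
    return adj | adj.T


def topology_with_null(
    net: Network, n_random: int = 1000, seed: int | None = None
) -> dict:
    """Observed topology, Erdős–Rényi G(V, E) null means, and the
    small-world coefficient r = (CC/CC_rand)/(APL/APL_rand)."""
    obs = topology_metrics(net)
    v, e = obs["n_nodes"], obs["n_edges"]
    rng = np.random.default_rng(seed)
    cc = np.empty(n_random)
    apl = np.empty(n_random)
    nd = np.empty(n_random)
    for k in range(n_random):
        m = topology_metrics(_random_gnm_adjacency(v, e, rng))
        cc[k], apl[k], nd[k] = m["CC"], m["APL"], m["ND"]
    null_means = {
        "AD": float(2 * e / v),
        "GD": float(2 * e / (v * (v - 1))),
        "CC": float(cc.mean()),
        "APL": float(np.nanmean(apl)),
        "ND": float(np.nanmean(nd)),
    }
    if null_means["CC"] > 0 and null_means["APL"] > 0 and obs["APL"] > 0:
        small_world = (obs["CC"] / null_means["CC"]) / (obs["APL"] / null_means["APL"])
    else:
        small_world = float("nan")
        warnings.warn("small-world coefficient undefined for this ensemble")
    return {
        "observed": obs,
        "null_means": null_means,
        "small_world_r": float(small_world),
        "n_random": int(n_random),
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# modules and node roles
# ---------------------------------------------------------------------------

def detect_modules(
    net: Network, seed: int | None = None, resolution: float = 1.0
) -> tuple[dict, float]:
    """Louvain modules (unweighted Newman–Girvan modularity), seeded.

    Returns ``(node -> module index, modularity)``; module indices are
    ranked by descending module size.
    """
    g = net.graph
    if g.number_of_edges() < 1:
        return {n: 0 for n in g.nodes}, 0.0
    comms = nx.community.louvain_communities(g, seed=seed, resolution=resolution, weight=None)
    md = nx.community.modularity(g, comms, weight=None)
    ranked = sorted(comms, key=lambda s: (-len(s), sorted(s)[0]))
    assignment = {}
    for idx, members in enumerate(ranked):
        for node in members:
            assignment[node] = idx
    return assignment, float(md)


def major_modules(assignment: dict, top: int | None = None) -> pd.DataFrame:
    """Module sizes and node shares, largest first."""
    ser = pd.Series(assignment)
    sizes = ser.value_counts().sort_index().sort_values(ascending=False)
    out = pd.DataFrame({"module": sizes.index, "n_nodes": sizes.to_numpy()})
    out["share"] = out["n_nodes"] / len(ser)
    return out.head(top) if top else out


def classify_role(
    zi: float,
    pi: float,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> str:
    """Four-way Zi–Pi node classification (thresholds 2.5 and 0.62)."""
    if zi >= zi_threshold and pi >= pi_threshold:
        return "network hub"
    if zi >= zi_threshold:
        return "module hub"
    if pi >= pi_threshold:
        return "connector"
    return "peripheral"


def zi_pi(
    net: Network,
    modules: dict,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi = (k_within − mean_module)/sd_module (population sd over the node's
    module; modules with sd 0 give Zi = 0, flagged).  Pi = 1 − Σ_s
    (k_is/k_i)².  Categories: peripheral (Zi < 2.5, Pi < 0.62), connector
    (Zi < 2.5, Pi ≥ 0.62), module hub (Zi ≥ 2.5, Pi < 0.62), network hub
    (both ≥).  Connectors and hubs are flagged as keystone taxa.
    """
    g = net.graph
    nodes = list(g.nodes)
    mod = pd.Series({n: modules[n] for n in nodes})
    k_within = {}
    k_by_module = {}
    for n in nodes:
        per_mod: dict[int, int] = {}
        for nb in g.neighbors(n):
            per_mod[modules[nb]] = per_mod.get(modules[nb], 0) + 1
        k_by_module[n] = per_mod
        k_within[n] = per_mod.get(modules[n], 0)
    kw = pd.Series(k_within)
    stats_by_mod = kw.groupby(mod).agg(["mean", lambda s: s.std(ddof=0)])
    stats_by_mod.columns = ["mean", "sd"]
    rows = []
    for n in nodes:
        mu, sd = stats_by_mod.loc[mod[n]]
        zi = (kw[n] - mu) / sd if sd > 0 else 0.0
        degenerate = sd == 0
        k_total = g.degree(n)
        pi = 1.0 - sum((k / k_total) ** 2 for k in k_by_module[n].values())
        cat = classify_role(zi, pi, zi_threshold, pi_threshold)
        rows.append((n, int(mod[n]), float(zi), float(pi), cat, cat != "peripheral", degenerate))
    return pd.DataFrame(
        rows,
        columns=["node", "module", "Zi", "Pi", "category", "keystone", "sd_zero"],
    )


def write_graphml(net: Network, path, modules: dict | None = None) -> None:
    g = net.graph.copy()
    if modules:
        nx.set_node_attributes(g, modules, "module")
    nx.write_graphml(g, path)
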