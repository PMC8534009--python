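"""Centrality catalog and influence ranking for interaction networks.

Given an undirected protein-protein interaction network annotated with
expression fold changes and deletion-region flags, this module computes
a catalog of node-centrality measures, uses PCA on the normalised
node x measure matrix to pick the most informative measure (largest
|PC1 loading|, with PC1 sign-aligned to degree), clusters nodes with
Ward linkage choosing k by mean silhouette, compares clusterings by the
pairwise-co-membership Jaccard index, and ranks nodes to nominate the
most influential deletion-region gene.

Diffusion degree, the measure used for the final ranking, scores a node
by its own degree plus its neighbours' degrees, each weighted by a
propagation parameter lambda:

    DD(v) = lambda * d(v) + sum_{u in N(v)} lambda * d(u)

With lambda constant this is lambda * (d(v) + sum of neighbour degrees);
lambda only scales the scores, never the ranking.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

__all__ = [
    "InfluenceNetwork",
    "CentralityConfig",
    "ClusteringResult",
    "MeasureSelection",
    "CENTRALITY_CATALOG",
    "compute_centralities",
    "diffusion_degree",
    "select_informative_measure",
    "cluster_nodes",
    "jaccard_clustering_similarity",
    "rank_nodes",
]


@dataclass
class InfluenceNetwork:
    """Undirected simple interaction graph with node annotations.

    Node attributes: ``log2fc`` (expression fold change, DEL/WT) and
    ``in_deletion`` (deletion-region flag). Self-loops are stripped;
    analysis runs on the largest connected component, with a flag when
    the input was disconnected.
    """

    graph: nx.Graph
    was_disconnected: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        g = nx.Graph(self.graph)  # collapses multi-edges if any
        g.remove_edges_from(nx.selfloop_edges(g))
        if g.number_of_nodes() == 0:
            raise ValueError("empty graph")
        if not nx.is_connected(g):
            self.was_disconnected = True
            largest = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
            g = g.subgraph(largest).copy()
            warnings.warn("input network is disconnected; analysing the "
                          "largest connected component", stacklevel=2)
        self.graph = g

    @classmethod
    def from_edges(cls, edges, annotations: pd.DataFrame | None = None) -> "InfluenceNetwork":
        g = nx.Graph()
        g.add_edges_from(edges)
        nx.set_node_attributes(g, 0.0, "log2fc")
        nx.set_node_attributes(g, False, "in_deletion")
        if annotations is not None:
            for node, row in annotations.iterrows():
                if node in g:
                    if "log2fc" in row:
                        g.nodes[node]["log2fc"] = float(row["log2fc"])
                    if "in_deletion" in row:
                        g.nodes[node]["in_deletion"] = bool(row["in_deletion"])
        return cls(g)

    def node_table(self) -> pd.DataFrame:
        rows = {v: (self.graph.nodes[v].get("log2fc", 0.0),
                    bool(self.graph.nodes[v].get("in_deletion", False)))
                for v in self.graph.nodes}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=["log2fc", "in_deletion"])


@dataclass(frozen=True)
class CentralityConfig:
    """Configuration for the centrality stage.

    ``lambda_`` is the diffusion-degree propagation weight (> 0, constant
    across nodes). ``measures`` restricts the catalog; ``normalization``
    is applied column-wise before PCA/clustering.
    """

    lambda_: float = 1.0
    measures: tuple[str, ...] | None = None
    normalization: str = "zscore"

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.normalization not in ("zscore", "minmax"):
            raise ValueError("normalization must be 'zscore' or 'minmax'")


@dataclass
class ClusteringResult:
    labels: pd.Series
    k: int
    silhouette_by_k: dict[int, float]
    linkage: str = "ward"


@dataclass
class MeasureSelection:
    measure: str
    loadings: pd.Series
    explained_variance_ratio: np.ndarray
    tied_measures: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# measure implementations not provided by networkx


def diffusion_degree(net: InfluenceNetwork | nx.Graph, lambda_: float = 1.0) -> dict:
    """DD(v) = lambda * (d(v) + sum of neighbour degrees)."""
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    g = net.graph if isinstance(net, InfluenceNetwork) else net
    deg = dict(g.degree())
    return {v: lambda_ * (deg[v] + sum(deg[u] for u in g[v])) for v in g}


def _semi_local(g: nx.Graph) -> dict:
    """Semi-local centrality: CL(v) = sum_{u in N(v)} Q(u), where
    Q(u) = sum_{w in N(u)} N2(w) and N2(w) counts nodes within
    distance 2 of w (excluding w)."""
    n2 = {}
    for w in g:
        near = set(g[w])
        for u in list(near):
            near |= set(g[u])
        near.discard(w)
        n2[w] = len(near)
    q = {u: sum(n2[w] for w in g[u]) for u in g}
    return {v: float(sum(q[u] for u in g[v])) for v in g}


def _leverage(g: nx.Graph) -> dict:
    """Leverage centrality: mean of (d_v - d_u)/(d_v + d_u) over neighbours."""
    deg = dict(g.degree())
    out = {}
    for v in g:
        if deg[v] == 0:
            out[v] = 0.0
            continue
        out[v] = float(np.mean([(deg[v] - deg[u]) / (deg[v] + deg[u]) for u in g[v]]))
    return out


def _lobby(g: nx.Graph) -> dict:
    """Lobby (h-degree) index: largest k such that v has >= k neighbours
    of degree >= k."""
    deg = dict(g.degree())
    out = {}
    for v in g:
        nbr = sorted((deg[u] for u in g[v]), reverse=True)
        k = 0
        for i, d in enumerate(nbr, start=1):
            if d >= i:
                k = i
            else:
                break
        out[v] = float(k)
    return out


def _katz(g: nx.Graph) -> dict:
    lam_max = max(abs(np.linalg.eigvalsh(nx.to_numpy_array(g))))
    alpha = 0.85 / lam_max if lam_max > 0 else 0.1
    return nx.katz_centrality_numpy(g, alpha=alpha)


#: ordered catalog; order is the documented tie-break for measure selection
CENTRALITY_CATALOG: dict = {
    "degree": lambda g, cfg: nx.degree_centrality(g),
    "closeness": lambda g, cfg: nx.closeness_centrality(g),
    "harmonic": lambda g, cfg: nx.harmonic_centrality(g),
    "betweenness": lambda g, cfg: nx.betweenness_centrality(g),
    "eigenvector": lambda g, cfg: nx.eigenvector_centrality_numpy(g),
    "katz": lambda g, cfg: _katz(g),
    "pagerank": lambda g, cfg: nx.pagerank(g, alpha=0.85),
    "subgraph": lambda g, cfg: nx.subgraph_centrality(g),
    "semi_local": lambda g, cfg: _semi_local(g),
    "leverage": lambda g, cfg: _leverage(g),
    "lobby": lambda g, cfg: _lobby(g),
    "laplacian": lambda g, cfg: nx.laplacian_centrality(g),
    "diffusion_degree": lambda g, cfg: diffusion_degree(g, cfg.lambda_),
}


def _normalize_columns(df: pd.DataFrame, mode: str) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        col = out[c].to_numpy(dtype=float)
        scale = max(1.0, np.abs(col).max())
        if np.ptp(col) <= 1e-12 * scale:  # constant up to numerical jitter
            out[c] = 0.0
        elif mode == "zscore":
            out[c] = (col - col.mean()) / col.std()
        else:
            lo, hi = col.min(), col.max()
            out[c] = (col - lo) / (hi - lo)
    return out


def compute_centralities(net: InfluenceNetwork,
                         cfg: CentralityConfig | None = None) -> pd.DataFrame:
    """Node x measure score matrix over the centrality catalog.

    Columns are normalised per the config. Nodes are sorted by id so the
    matrix is invariant to input ordering.
    """
    cfg = cfg or CentralityConfig()
    g = net.graph
    if g.number_of_nodes() < 4:
        raise ValueError("need a connected component with at least 4 nodes")
    names = cfg.measures or tuple(CENTRALITY_CATALOG)
    unknown = [m for m in names if m not in CENTRALITY_CATALOG]
    if unknown:
        raise ValueError(f"unknown measures: {unknown}")
    nodes = sorted(g.nodes, key=str)
    data = {}
    for name in names:
        scores = CENTRALITY_CATALOG[name](g, cfg)
        data[name] = [float(scores[v]) for v in nodes]
    raw = pd.DataFrame(data, index=nodes)
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise ValueError(f"measures produced undefined values: {bad}")
    return _normalize_columns(raw, cfg.normalization)


def select_informative_measure(cm: pd.DataFrame) -> MeasureSelection:
    """Pick the measure with the largest |loading| on PC1.

    PCA runs on the (already normalised) node x measure matrix; PC1's
    sign is aligned so its scores correlate positively with the degree
    column (first column if degree is absent). Exact ties on |loading|
    are reported and broken by catalog order.
    """
    if cm.shape[1] < 2 or cm.shape[0] < 3:
        raise ValueError("need at least 2 measures and 3 nodes")
    x = cm.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("zero-variance centrality matrix")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    pc1_scores = u[:, 0] * s[0]
    loadings = vt[0]
    ref_col = cm.columns.get_loc("degree") if "degree" in cm.columns else 0
    ref = cm.iloc[:, ref_col].to_numpy(dtype=float)
    if np.std(ref) > 0 and np.corrcoef(pc1_scores, ref)[0, 1] < 0:
        pc1_scores, loadings = -pc1_scores, -loadings
    abs_load = np.abs(loadings)
    best = abs_load.max()
    tied = tuple(cm.columns[np.isclose(abs_load, best, rtol=1e-9, atol=1e-12)])
    var = s ** 2
    return MeasureSelection(
        measure=tied[0],
        loadings=pd.Series(loadings, index=cm.columns, name="pc1_loading"),
        explained_variance_ratio=var / var.sum(),
        tied_measures=tied if len(tied) > 1 else (),
    )


def cluster_nodes(cm: pd.DataFrame, k_range=None) -> ClusteringResult:
    """Ward-linkage agglomerative clustering with silhouette-optimal k."""
    n = cm.shape[0]
    if n < 4:
        raise ValueError("need at least 4 nodes to cluster")
    x = cm.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all rows identical: zero variance, nothing to cluster")
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range must lie within 2..n-1")
    sil = {}
    labels_by_k = {}
    for k in k_range:
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        lab = model.fit_predict(x)
        labels_by_k[k] = lab
        sil[k] = float(silhouette_score(x, lab)) if len(set(lab)) > 1 else -1.0
    best_k = max(sil, key=lambda k: (sil[k], -k))
    return ClusteringResult(
        labels=pd.Series(labels_by_k[best_k], index=cm.index, name="cluster"),
        k=best_k,
        silhouette_by_k=sil,
    )


def jaccard_clustering_similarity(a, b) -> float:
    """Jaccard index on co-clustered node pairs.

    |pairs together in both partitions| / |pairs together in either|.
    Two all-singleton partitions have no co-clustered pairs at all; they
    induce identical co-membership structure, so the index is 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    ct = pd.crosstab(a, b).to_numpy()
    t_both = comb(ct, 2).sum()
    t_a = comb(ct.sum(axis=1), 2).sum()
    t_b = comb(ct.sum(axis=0), 2).sum()
    union = t_a + t_b - t_both
    return 1.0 if union == 0 else float(t_both / union)


def rank_nodes(net: InfluenceNetwork, cfg: CentralityConfig | None = None,
               measure: str | None = None) -> pd.DataFrame:
    """Rank nodes by a centrality score (descending, lexicographic ties).

    Without an explicit ``measure`` the PCA-selected most informative one
    is used. The returned table carries the score, each node's expression
    fold change and deletion flag, and ``top_deletion`` marking the
    highest-ranked deletion-region node (the nominated influential gene).
    """
    cfg = cfg or CentralityConfig()
    cm = compute_centralities(net, cfg)
    if measure is None:
        measure = select_informative_measure(cm).measure
    elif measure not in CENTRALITY_CATALOG:
        raise ValueError(f"unknown measure: {measure}")
    raw = CENTRALITY_CATALOG[measure](net.graph, cfg)
    annot = net.node_table()
    out = pd.DataFrame({
        "score": pd.Series({v: float(raw[v]) for v in net.graph.nodes}),
        "log2fc": annot["log2fc"],
        "in_deletion": annot["in_deletion"],
    })
    # deterministic ordering: score descending, node id ascending on ties
    out = out.iloc[np.lexsort((out.index.astype(str), -out["score"].to_numpy()))]
    out["rank"] = np.arange(1, len(out) + 1)
    out["measure"] = measure
    out["top_deletion"] = False
    del_rows = out.index[out["in_deletion"]]
    if len(del_rows):
        out.loc[del_rows[0], "top_deletion"] = True
    return out
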