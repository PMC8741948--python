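"""Core-mycobiome extraction and Spearman co-occurrence networks.

The core set keeps OTUs present in at least a prevalence-threshold
fraction of all samples (default 75%).  Per plant type, every core OTU
pair gets a Spearman rho (average-rank ties) and a two-sided p; after
Benjamini-Hochberg correction over all pairs of that network, edges with
|rho| above the threshold (default 0.6) and q below alpha (default 0.01)
are kept.  Topology is computed on the unweighted, sign-blind graph; hub
taxa are the intersection of the top-2% by degree and by betweenness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable
from .ordination import bh_fdr

log = logging.getLogger(__name__)


@dataclass
class CoreSet:
    otu_ids: list
    prevalence: pd.Series            # per core OTU, fraction of samples present
    share_of_richness: float
    share_of_reads: float
    always_present_ids: list
    threshold: float

    def summary(self) -> dict:
        return {
            "n_core": len(self.otu_ids),
            "share_of_richness_pct": round(100 * self.share_of_richness, 1),
            "share_of_reads_pct": round(100 * self.share_of_reads, 1),
            "n_always_present": len(self.always_present_ids),
            "threshold": self.threshold,
        }


def core_mycobiome(table: CountTable, prevalence_threshold: float = 0.75) -> CoreSet:
    """Prevalence-filtered core: an OTU is kept iff it has nonzero count in
    >= ``prevalence_threshold`` of all pooled samples (boundary inclusive).
    Richness and read shares are relative to the full table."""
    if not 0 < prevalence_threshold <= 1:
        raise ValueError("prevalence threshold must be in (0, 1]")
    present = table.counts > 0
    prev = present.mean(axis=1)
    keep = prev[prev >= prevalence_threshold]
    total_reads = table.counts.to_numpy().sum()
    observed = (prev > 0).sum()
    core_ids = list(keep.index)
    return CoreSet(
        otu_ids=core_ids,
        prevalence=keep,
        share_of_richness=len(core_ids) / observed if observed else 0.0,
        share_of_reads=table.counts.loc[core_ids].to_numpy().sum() / total_reads
        if total_reads
        else 0.0,
        always_present_ids=list(prev[prev >= 1.0].index),
        threshold=prevalence_threshold,
    )


def richness_share_pct(n_core: int, n_total: int) -> float:
    """Core share of observed richness as the percentage printed in
    summaries (one decimal)."""
    return round(100.0 * n_core / n_total, 1)


def build_network(
    table: CountTable,
    r_threshold: float = 0.6,
    alpha: float = 0.01,
    annotations: pd.DataFrame | None = None,
    plant_type: str | None = None,
) -> nx.Graph:
    """Spearman co-occurrence network over the OTUs of ``table`` (already
    restricted to the core set and one plant-type stratum).

    Constant OTUs are excluded with a warning; BH-FDR is applied over all
    remaining pairs of this network only.  Edges satisfy |rho| > r_threshold
    AND q < alpha; nodes with no surviving edge are dropped.  Node
    attributes carry proportional abundance and, if ``annotations`` given,
    guild / trophic group / taxon.
    """
    if table.shape[1] < 4:
        raise ValueError("need >= 4 samples in the stratum")
    if table.shape[0] < 2:
        raise ValueError("need >= 2 OTUs")
    X = table.counts.to_numpy(float)
    keep = np.ptp(X, axis=1) > 0
    if (~keep).any():
        log.warning(
            "build_network: excluding %d constant OTU(s) from correlation", int((~keep).sum())
        )
    ids = [o for o, k in zip(table.otu_ids, keep) if k]
    X = X[keep]

    rho, pval = stats.spearmanr(X, axis=1)
    if np.isscalar(rho):  # two OTUs
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[0.0, pval], [pval, 0.0]])
    iu = np.triu_indices(len(ids), k=1)
    p_flat = pval[iu]
    q_flat = bh_fdr(np.nan_to_num(p_flat, nan=1.0))
    r_flat = rho[iu]

    g = nx.Graph()
    g.graph["plant_type"] = plant_type or ""
    g.graph["r_threshold"] = r_threshold
    g.graph["alpha"] = alpha
    prop = table.counts.sum(axis=1) / table.counts.to_numpy().sum()
    edge_mask = (np.abs(r_flat) > r_threshold) & (q_flat < alpha)
    for i, j, r, q in zip(iu[0][edge_mask], iu[1][edge_mask], r_flat[edge_mask], q_flat[edge_mask]):
        g.add_edge(ids[i], ids[j], r=float(r), q=float(q),
                   sign="positive" if r >= 0 else "negative")
    for node in g.nodes:
        g.nodes[node]["prop_abundance"] = float(prop[node])
        if annotations is not None and node in annotations.index:
            row = annotations.loc[node]
            g.nodes[node]["trophic_group"] = str(row.get("trophic_group", ""))
            g.nodes[node]["guild"] = str(row.get("guild", "") or "")
            g.nodes[node]["taxon"] = str(row.get("matched_taxon", "") or "")
    return g


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


def node_metrics(network: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness (shortest-path, unnormalized),
    closeness (classic definition within each connected component) and
    eigenvector centrality (largest component; 0 elsewhere), on the
    unweighted sign-blind graph."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    g = network
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    clo = nx.closeness_centrality(g, wf_improved=False)
    eig = {n: 0.0 for n in g.nodes}
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(comps[0])
    if giant.number_of_nodes() > 1:
        # dense principal eigenvector (robust on very small components)
        nodes = list(giant.nodes)
        A = nx.to_numpy_array(giant, nodelist=nodes)
        w, v = np.linalg.eigh(A)
        vec = v[:, np.argmax(w)]
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec) / np.linalg.norm(vec)
        eig.update(dict(zip(nodes, vec.tolist())))
    else:
        eig[next(iter(giant.nodes))] = 1.0
    out = pd.DataFrame(
        {"degree": deg, "betweenness": btw, "closeness": clo, "eigenvector": eig}
    )
    out.index.name = "otu_id"
    return out


def _louvain_modularity(g: nx.Graph, n_runs: int = 10, seed: int = 0) -> float:
    """Best Louvain modularity over ``n_runs`` seeded runs (resolution 1)."""
    best = -math.inf
    for k in range(n_runs):
        parts = nx.community.louvain_communities(g, seed=seed + k, resolution=1.0)
        best = max(best, nx.community.modularity(g, parts))
    return best


def network_metrics(network: nx.Graph, modularity_runs: int = 10, seed: int = 0) -> dict:
    """Whole-network topology on the unweighted graph.

    Average path length and diameter are computed over the largest
    connected component; density = 2E/(N(N-1)); clustering is the mean
    local clustering coefficient; modularity is the best of seeded Louvain
    runs."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    g = network
    n, e = g.number_of_nodes(), g.number_of_edges()
    signs = [d.get("sign", "positive") for _, _, d in g.edges(data=True)]
    pct_pos = 100.0 * sum(s == "positive" for s in signs) / e if e else float("nan")
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(comps[0])
    apl = (
        nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else float("nan")
    )
    diam = nx.diameter(giant) if giant.number_of_nodes() > 1 else 0
    return {
        "n_nodes": n,
        "n_edges": e,
        "pct_positive_edges": pct_pos,
        "average_degree": 2 * e / n,
        "average_path_length": apl,
        "diameter": diam,
        "density": nx.density(g),
        "modularity": _louvain_modularity(g, modularity_runs, seed) if e else float("nan"),
        "clustering_coefficient": nx.average_clustering(g),
        "n_components": len(comps),
        "largest_component": giant.number_of_nodes(),
    }


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------


@dataclass
class HubReport:
    hubs: list
    degree_cutoff: float
    betweenness_cutoff: float
    k: int
    top_degree: list
    top_betweenness: list
    rule: str = "intersection"


def _top_with_ties(values: pd.Series, k: int) -> tuple[list, float]:
    ranked = values.sort_values(ascending=False)
    cutoff = float(ranked.iloc[k - 1])
    return list(ranked[ranked >= cutoff].index), cutoff


def identify_hubs(metrics: pd.DataFrame, top_fraction: float = 0.02, rule: str = "intersection") -> HubReport:
    """Hub OTUs: the top ``ceil(top_fraction * N)`` by degree intersected
    (default) or unioned with the same top set by betweenness; ties at the
    rank-k value are included before combining."""
    if len(metrics) == 0:
        return HubReport([], float("nan"), float("nan"), 0, [], [], rule)
    k = math.ceil(top_fraction * len(metrics))
    top_deg, deg_cut = _top_with_ties(metrics["degree"], k)
    top_btw, btw_cut = _top_with_ties(metrics["betweenness"], k)
    if rule == "intersection":
        hubs = [o for o in top_deg if o in set(top_btw)]
    elif rule == "union":
        hubs = sorted(set(top_deg) | set(top_btw))
    else:
        raise ValueError(f"unknown hub rule {rule!r}")
    return HubReport(hubs, deg_cut, btw_cut, k, top_deg, top_btw, rule)


def compare_networks(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of node-level metrics between
    two networks (exact enumeration when both N <= 10, normal approximation
    with tie correction otherwise)."""
    if len(metrics_a) == 0 or len(metrics_b) == 0:
        raise ValueError("both networks must be non-empty")
    rows = []
    exact = len(metrics_a) <= 10 and len(metrics_b) <= 10
    for metric in ("degree", "betweenness", "closeness", "eigenvector"):
        x = metrics_a[metric].to_numpy(float)
        y = metrics_b[metric].to_numpy(float)
        method = "exact" if exact and not (len(np.unique(np.r_[x, y])) < len(x) + len(y)) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {"metric": metric, "statistic": float(res.statistic), "p": float(res.pvalue),
             "median_a": float(np.median(x)), "median_b": float(np.median(y)),
             "method": method}
        )
    return pd.DataFrame(rows).set_index("metric")
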