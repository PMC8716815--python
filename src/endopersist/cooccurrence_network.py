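"""Season-persistent co-occurrence networks and their graph properties.

Within each site x tissue x season slice, every taxon pair is tested
for Spearman correlation of abundances across the replicate samples;
pairs with |rho| above a threshold (0.8) and p below a threshold
(0.01) form that season's network. An association present in two or
more seasonal networks enters the combined persistence network, whose
structure is summarised by node/edge counts, edge density (ordered-pair
denominator E/(V(V-1))), global transitivity, diameter, and Freeman
centralizations of closeness, eigenvector and betweenness centrality.
Between-network structural dissimilarity is the Jaccard distance on
edge-identity sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

from .beta_composition import DistanceMatrix, NMDSResult, nmds
from .data_model import AbundanceTable

__all__ = [
    "EdgeRecord",
    "CombinedEdge",
    "CombinedNetwork",
    "NetworkProperties",
    "spearman_test",
    "season_network",
    "combine_networks",
    "network_properties",
    "network_dissimilarity",
    "ordinate_networks",
    "rare_nodes",
]


@dataclass(frozen=True)
class EdgeRecord:
    taxon_a: str
    taxon_b: str
    rho: float
    p: float

    def __post_init__(self) -> None:
        if self.taxon_a == self.taxon_b:
            raise ValueError("self-edges not allowed")

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"

    def identity(self, match_sign: bool = True):
        pair = tuple(sorted((self.taxon_a, self.taxon_b)))
        return pair + (self.sign,) if match_sign else pair


@dataclass
class CombinedEdge:
    taxon_a: str
    taxon_b: str
    sign: str
    season_set: frozenset[str]

    @property
    def season_count(self) -> int:
        return len(self.season_set)


@dataclass
class CombinedNetwork:
    nodes: list[str]
    edges: list[CombinedEdge]
    kept_ratio: tuple[int, int]  # (edges in >= min_seasons, edges in >= 1 season)
    min_seasons: int = 2

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.taxon_a,
                e.taxon_b,
                sign=e.sign,
                season_count=e.season_count,
                seasons=",".join(sorted(e.season_set)),
            )
        return g

    def edge_identities(self) -> set:
        return {
            tuple(sorted((e.taxon_a, e.taxon_b))) + (e.sign,) for e in self.edges
        }


@dataclass
class NetworkProperties:
    node_no: int
    edge_no: int
    edge_density: float
    transitivity: float
    diameter: int
    centralized_closeness: float
    centralized_eigenvector: float
    centralized_betweenness: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "node_no": self.node_no,
                "edge_no": self.edge_no,
                "edge_density": self.edge_density,
                "transitivity": self.transitivity,
                "diameter": self.diameter,
                "centralized_closeness": self.centralized_closeness,
                "centralized_eigenvector": self.centralized_eigenvector,
                "centralized_betweenness": self.centralized_betweenness,
            }
        )


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-n null
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations (tie-free null)."""
    base = np.arange(1, n + 1, dtype=float)
    var = base.var()
    mean = base.mean()
    vals = []
    for perm in permutations(base):
        cov = np.mean((base - mean) * (np.asarray(perm) - mean))
        vals.append(abs(cov / var))
    return np.sort(np.asarray(vals))


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = rx.std(), ry.std()
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def _approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * t_dist.sf(abs(t), df=n - 2))


def spearman_test(x, y, p_method: str = "auto") -> tuple[float, float]:
    """Two-sided Spearman correlation test.

    rho is computed from average-ranked data. The p-value is exact (full
    enumeration of the n! rank permutations) for n <= 9 when neither
    vector has ties, and a t-approximation otherwise; ``p_method`` may
    force ``"exact"`` (error on ties/large n) or ``"approx"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rx, ry = rankdata(x), rankdata(y)
    rho = _rho_from_ranks(rx, ry)
    ties = np.unique(rx).size < n or np.unique(ry).size < n
    if p_method == "exact" or (p_method == "auto" and n <= 9 and not ties):
        if ties:
            raise ValueError("exact p requires tie-free data")
        if n > 9:
            raise ValueError("exact p limited to n <= 9")
        null = _exact_null_abs_rho(n)
        p = float(np.mean(null >= abs(rho) - 1e-12))
    elif p_method in ("approx", "auto"):
        p = _approx_p(rho, n)
    else:
        raise ValueError(f"unknown p_method: {p_method}")
    return rho, p


# ---------------------------------------------------------------------------
# per-season networks and the combined persistence network
# ---------------------------------------------------------------------------

def season_network(
    table: AbundanceTable,
    rho_threshold: float = 0.8,
    p_threshold: float = 0.01,
    p_method: str = "approx",
    fdr_bh: bool = False,
) -> list[EdgeRecord]:
    """Co-occurrence edges within one site x tissue x season slice.

    All unordered taxon pairs are tested on their abundance vectors
    across the slice's samples; pairs with |rho| > ``rho_threshold``
    and p < ``p_threshold`` are kept. Zero-variance taxa are skipped.
    The default t-approximation p mirrors cor.test behaviour on tied
    count data (and is the only mode under which the default gate is
    reachable at n=5 replicates). ``fdr_bh`` applies Benjamini-Hochberg
    correction across all tested pairs before gating (off by default:
    the conventional gate uses raw p-values).
    """
    counts = table.counts.to_numpy(dtype=float)
    n = counts.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples to test correlations")
    variable = counts.std(axis=1) > 0
    idx = np.flatnonzero(variable)
    if idx.size < 2:
        return []
    ranks = np.apply_along_axis(rankdata, 1, counts[idx])
    with np.errstate(invalid="ignore"):
        rho_mat = np.corrcoef(ranks)
    taxa = [table.taxon_ids[i] for i in idx]
    edges: list[EdgeRecord] = []
    ii, jj = np.triu_indices(len(idx), 1)
    adjusted: dict[tuple[int, int], float] = {}
    if fdr_bh:
        from statsmodels.stats.multitest import multipletests

        rhos = rho_mat[ii, jj]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = rhos * np.sqrt((n - 2) / np.maximum(1.0 - rhos**2, 1e-300))
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
        pvals[np.abs(rhos) >= 1.0] = 0.0
        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
        adjusted = {(a, b): pa for a, b, pa in zip(ii, jj, p_adj)}
    strong = np.abs(rho_mat[ii, jj]) > rho_threshold
    for a, b in zip(ii[strong], jj[strong]):
        if fdr_bh:
            rho = float(rho_mat[a, b])
            p = float(adjusted[(a, b)])
            if p < p_threshold:
                ta_id, tb_id = sorted((taxa[a], taxa[b]))
                edges.append(EdgeRecord(ta_id, tb_id, rho, p))
            continue
        rho = float(rho_mat[a, b])
        if p_method == "approx":
            p = _approx_p(rho, n)
        else:
            ta, tb = ranks[a], ranks[b]
            ties = np.unique(ta).size < n or np.unique(tb).size < n
            if p_method == "auto" and n <= 9 and not ties:
                p = float(np.mean(_exact_null_abs_rho(n) >= abs(rho) - 1e-12))
            else:
                p = _approx_p(rho, n)
        if p < p_threshold:
            ta_id, tb_id = sorted((taxa[a], taxa[b]))
            edges.append(EdgeRecord(ta_id, tb_id, rho, p))
    return edges


def combine_networks(
    seasonal: dict[str, list[EdgeRecord]],
    min_seasons: int = 2,
    match_sign: bool = True,
) -> CombinedNetwork:
    """Keep associations present in at least ``min_seasons`` seasons.

    Edge identity is the unordered taxon pair, plus the correlation sign
    when ``match_sign`` (a positive and a negative association between
    the same taxa are distinct relationships). Nodes are exactly the
    endpoints of kept edges.
    """
    seasons = list(seasonal)
    if len(seasons) != len(set(seasons)):
        raise ValueError("duplicate season labels")
    if not 2 <= len(seasons) <= 4:
        raise ValueError("need 2-4 seasonal edge lists")
    occurrences: dict[tuple, set[str]] = {}
    signs: dict[tuple, str] = {}
    for season, edges in seasonal.items():
        for e in edges:
            ident = e.identity(match_sign)
            occurrences.setdefault(ident, set()).add(season)
            signs[ident] = e.sign
    kept = []
    for ident, secs in occurrences.items():
        if len(secs) >= min_seasons:
            a, b = ident[0], ident[1]
            kept.append(CombinedEdge(a, b, signs[ident], frozenset(secs)))
    nodes = sorted({e.taxon_a for e in kept} | {e.taxon_b for e in kept})
    return CombinedNetwork(nodes, kept, (len(kept), len(occurrences)), min_seasons)


# ---------------------------------------------------------------------------
# network properties (Table-style summary)
# ---------------------------------------------------------------------------

def _freeman(cent: dict, tmax: float) -> float:
    vals = np.asarray(list(cent.values()), dtype=float)
    if vals.size == 0 or tmax <= 0:
        return 0.0
    return float(np.sum(vals.max() - vals) / tmax)


def network_properties(net: CombinedNetwork | nx.Graph) -> NetworkProperties:
    """Node/edge counts, density, transitivity, diameter and centralizations.

    Edge density uses the ordered-pair denominator E/(V(V-1)) — the
    convention under which published node/edge counts reproduce their
    printed densities. Diameter is the longest finite shortest path
    (over connected pairs). Centralizations are Freeman-style
    sum(c_max - c_i) normalized by the theoretical maximum for a graph
    of that size; closeness is computed over reachable pairs.
    """
    g = net.to_graph() if isinstance(net, CombinedNetwork) else net
    v = g.number_of_nodes()
    e = g.number_of_edges()
    if v == 0:
        warnings.warn("empty graph: all network properties set to zero")
        return NetworkProperties(0, 0, 0.0, 0.0, 0, 0.0, 0.0, 0.0)
    density = e / (v * (v - 1)) if v > 1 else 0.0
    transitivity = nx.transitivity(g)
    diameter = 0
    for comp in nx.connected_components(g):
        if len(comp) > 1:
            ecc = nx.eccentricity(g.subgraph(comp))
            diameter = max(diameter, max(ecc.values()))
    if v > 2:
        closeness = nx.closeness_centrality(g, wf_improved=True)
        c_clo = _freeman(closeness, (v - 1) * (v - 2) / (2 * v - 3))
        try:
            eig = nx.eigenvector_centrality_numpy(g)
            mx = max(eig.values())
            eig = {k: val / mx for k, val in eig.items()}
        except Exception:  # defective adjacency on degenerate graphs
            eig = {k: 0.0 for k in g}
        c_eig = _freeman(eig, v - 1)
        btw = nx.betweenness_centrality(g, normalized=False)
        c_btw = _freeman(btw, (v - 1) ** 2 * (v - 2) / 2)
    else:
        c_clo = c_eig = c_btw = 0.0
    return NetworkProperties(
        v, e, density, transitivity, diameter, c_clo, c_eig, c_btw
    )


def network_dissimilarity(a, b, match_sign: bool = True) -> float:
    """Jaccard distance between the edge-identity sets of two networks."""
    ea = _edge_ident_set(a, match_sign)
    eb = _edge_ident_set(b, match_sign)
    union = ea | eb
    if not union:
        raise ValueError("both networks are empty")
    return 1.0 - len(ea & eb) / len(union)


def _edge_ident_set(net, match_sign: bool) -> set:
    if isinstance(net, CombinedNetwork):
        if match_sign:
            return net.edge_identities()
        return {tuple(sorted((e.taxon_a, e.taxon_b))) for e in net.edges}
    return {e.identity(match_sign) for e in net}


def ordinate_networks(
    networks: dict[str, object],
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
) -> NMDSResult:
    """NMDS ordination of between-network structural dissimilarities."""
    names = list(networks)
    if len(names) < 4:
        raise ValueError("need at least 4 networks to ordinate")
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = network_dissimilarity(
                networks[names[i]], networks[names[j]]
            )
    return nmds(DistanceMatrix(names, d), k=k, n_starts=n_starts, seed=seed)


def rare_nodes(
    net: CombinedNetwork,
    table: AbundanceTable,
    threshold: float = 0.005,
) -> dict[str, bool]:
    """Flag network nodes whose group-level mean relative abundance is rare.

    Returns taxon -> True when the taxon's mean relative abundance in
    ``table`` is below ``threshold`` (published combined networks were
    dominated by such rare taxa).
    """
    counts = table.counts.to_numpy(dtype=float)
    rel = counts / counts.sum(axis=0)
    mean_rel = pd.Series(rel.mean(axis=1), index=table.taxon_ids)
    return {
        node: bool(mean_rel.get(node, 0.0) < threshold) for node in net.nodes
    }


def edges_frame(edges: list[EdgeRecord]) -> pd.DataFrame:
    """Edge list as a TSV-ready DataFrame."""
    return pd.DataFrame(
        {
            "taxon_a": [e.taxon_a for e in edges],
            "taxon_b": [e.taxon_b for e in edges],
            "rho": [e.rho for e in edges],
            "p": [e.p for e in edges],
            "sign": [e.sign for e in edges],
        }
    )


def combined_frame(net: CombinedNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon_a": [e.taxon_a for e in net.edges],
            "taxon_b": [e.taxon_b for e in net.edges],
            "sign": [e.sign for e in net.edges],
            "seasons": [",".join(sorted(e.season_set)) for e in net.edges],
            "season_count": [e.season_count for e in net.edges],
        }
    )
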