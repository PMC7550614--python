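"""Protein-protein interaction modules and randomization-based statistics.

The interactome is an undirected simple graph of gene (protein) identifiers
filtered at a combined confidence score > 0.4.  A gene signature maps onto it
as a *module* — the induced subgraph on the mapped genes — whose edge count
is judged against random node sets of the same size (degree-binned sampling),
and whose distance to another module is summarized by an average
shortest-path closeness Z-score: z < -1.65 (one-sided normal, p < 0.05)
labels two modules "significantly close" in the network-medicine sense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

log = logging.getLogger(__name__)


class Interactome:
    """Confidence-filtered undirected PPI graph with cached distance structure.

    Nodes are gene identifiers; each edge carries a ``score`` attribute in
    (0, 1].  Self-loops and reversed duplicates are resolved at load time.
    """

    def __init__(self, graph: nx.Graph, min_confidence: float = 0.4):
        self.graph = graph
        self.min_confidence = min_confidence
        self.nodes: list[str] = sorted(graph.nodes)
        self._index = {g: i for i, g in enumerate(self.nodes)}
        self._dist: np.ndarray | None = None
        self._adj: csr_matrix | None = None
        self._bins: list[np.ndarray] | None = None
        self._node_bin: np.ndarray | None = None
        self._min_bin: int | None = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edge_table(cls, table: pd.DataFrame, min_confidence: float = 0.4) -> "Interactome":
        """Build from a 3-column (geneA, geneB, combined_score) frame.

        Edges at or below the confidence threshold and self-loops are
        dropped; reversed duplicates are merged keeping the maximum score.
        """
        if table.shape[1] < 3:
            raise ValueError("edge table needs 3 columns: geneA, geneB, score")
        a = table.iloc[:, 0].astype(str).to_numpy()
        b = table.iloc[:, 1].astype(str).to_numpy()
        s = pd.to_numeric(table.iloc[:, 2], errors="coerce").to_numpy(float)
        bad = np.flatnonzero(np.isnan(s))
        if len(bad):
            raise ValueError(f"malformed score at row {bad[0] + 1}")
        g = nx.Graph()
        n_loops = n_low = n_dup = 0
        for u, v, score in zip(a, b, s):
            if u == v:
                n_loops += 1
                continue
            if score <= min_confidence:
                n_low += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                g[u][v]["score"] = max(g[u][v]["score"], score)
            else:
                g.add_edge(u, v, score=score)
        log.info(
            "interactome: %d nodes, %d edges kept; dropped %d low-confidence, "
            "%d self-loops; merged %d duplicates",
            g.number_of_nodes(), g.number_of_edges(), n_low, n_loops, n_dup,
        )
        return cls(g, min_confidence)

    # -- cached structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index_of(self, genes) -> np.ndarray:
        return np.array([self._index[g] for g in genes], dtype=int)

    def adjacency(self) -> csr_matrix:
        if self._adj is None:
            self._adj = nx.to_scipy_sparse_array(
                self.graph, nodelist=self.nodes, weight=None, format="csr"
            )
        return self._adj

    def distances(self) -> np.ndarray:
        """All-pairs unweighted shortest-path matrix (inf = unreachable)."""
        if self._dist is None:
            self._dist = shortest_path(self.adjacency(), method="D", unweighted=True)
        return self._dist

    def degree_bins(self, min_bin_size: int | None = None) -> tuple[list[np.ndarray], np.ndarray]:
        """Group node indices into degree bins, merging low-degree bins upward
        until every bin holds at least ``min_bin_size`` nodes (or all nodes).

        The default bin size is 100 nodes, shrinking to a twentieth of
        the network on small graphs so upper-tail degrees stay matched
        there too.
        """
        if min_bin_size is None:
            min_bin_size = min(100, max(10, self.n_nodes // 20))
        if self._bins is None or self._min_bin != min_bin_size:
            deg = np.array([self.graph.degree(g) for g in self.nodes])
            order = np.argsort(deg, kind="stable")
            bins: list[np.ndarray] = []
            current: list[int] = []
            for pos, i in enumerate(order):
                current.append(i)
                boundary = (
                    pos == len(order) - 1
                    or deg[order[pos + 1]] != deg[i]
                )
                if boundary and len(current) >= min_bin_size:
                    bins.append(np.array(current))
                    current = []
            if current:
                if bins:
                    bins[-1] = np.concatenate([bins[-1], np.array(current)])
                else:
                    bins.append(np.array(current))
            node_bin = np.empty(self.n_nodes, dtype=int)
            for k, members in enumerate(bins):
                node_bin[members] = k
            self._bins, self._node_bin, self._min_bin = bins, node_bin, min_bin_size
        return self._bins, self._node_bin

    def sample_matched(
        self, idx: np.ndarray, rng: np.random.Generator,
        degree_binned: bool = True, min_bin_size: int | None = None,
    ) -> np.ndarray:
        """Draw a random node set of the same size, degree-matched by bins."""
        if not degree_binned:
            return rng.choice(self.n_nodes, size=len(idx), replace=False)
        bins, node_bin = self.degree_bins(min_bin_size)
        out = []
        counts = np.bincount(node_bin[idx], minlength=len(bins))
        for k, need in enumerate(counts):
            if need:
                out.append(rng.choice(bins[k], size=need, replace=False))
        return np.concatenate(out)


def load_interactome(path_or_table, min_confidence: float = 0.4) -> Interactome:
    """Read a (geneA, geneB, combined_score) TSV (or frame) into an Interactome."""
    if isinstance(path_or_table, pd.DataFrame):
        table = path_or_table
    else:
        table = pd.read_csv(path_or_table, sep="\t")
    return Interactome.from_edge_table(table, min_confidence)


@dataclass
class Module:
    """A signature mapped onto the interactome: induced subgraph + bookkeeping."""

    label: str
    mapped: list[str]
    unmapped: list[str]
    subgraph: nx.Graph

    @property
    def mapped_fraction(self) -> float:
        total = len(self.mapped) + len(self.unmapped)
        return round(100.0 * len(self.mapped) / total, 2) if total else 0.0

    @property
    def is_empty(self) -> bool:
        return len(self.mapped) == 0


@dataclass
class ModuleStats:
    n_nodes: int
    n_edges: int
    avg_degree: float          # 2E/N, internal to the module subgraph
    avg_clustering: float      # mean local clustering, 0 for degree < 2
    lcc_n_nodes: int
    lcc_n_edges: int
    degree: dict[str, int] = field(default_factory=dict)
    betweenness: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
            "avg_degree": self.avg_degree, "avg_clustering": self.avg_clustering,
            "lcc_n_nodes": self.lcc_n_nodes, "lcc_n_edges": self.lcc_n_edges,
        }


@dataclass
class EnrichmentResult:
    """Edge-count over-representation of a module vs random node sets."""

    observed_edges: int
    null_mean: float
    null_sd: float
    p_empirical: float
    z: float
    n_iterations: int


@dataclass
class ClosenessResult:
    """Average cross-module distance against a degree-matched random null."""

    label_a: str
    label_b: str
    d_obs: float
    mu_rand: float
    sigma_rand: float
    z: float
    n_iterations: int
    unreachable_fraction: float

    @property
    def significantly_close(self) -> bool:
        return self.z < -1.65

    def to_json_dict(self) -> dict:
        return {
            "modules": [self.label_a, self.label_b],
            "average_distance": self.d_obs,
            "random_distance": self.mu_rand,
            "random_sd": self.sigma_rand,
            "z_score": self.z,
            "n_iterations": self.n_iterations,
            "unreachable_fraction": self.unreachable_fraction,
            "significantly_close": self.significantly_close,
        }


def build_module(signature, net: Interactome) -> Module:
    """Map a signature (or plain gene collection) onto the interactome."""
    genes = sorted(signature.genes if hasattr(signature, "genes") else signature)
    if not genes:
        raise ValueError("signature is empty")
    label = getattr(signature, "label", "module")
    present = set(net.graph.nodes)
    mapped = [g for g in genes if g in present]
    unmapped = [g for g in genes if g not in present]
    if not mapped:
        log.warning("%s: no signature genes map onto the interactome", label)
        return Module(label, [], unmapped, nx.Graph())
    sub = net.graph.subgraph(mapped).copy()
    return Module(label, mapped, unmapped, sub)


def module_stats(m: Module) -> ModuleStats:
    """Internal degree, clustering, betweenness and LCC size of a module.

    Average degree is 2E/N on the induced subgraph; local clustering is 0 for
    nodes of degree < 2; betweenness is Brandes', normalized by
    (N-1)(N-2)/2.  All statistics are computed on the module subgraph, not
    the full interactome.
    """
    if m.is_empty:
        raise ValueError("empty module has no statistics")
    g = m.subgraph
    n, e = g.number_of_nodes(), g.number_of_edges()
    lcc = largest_connected_component(m)
    return ModuleStats(
        n_nodes=n,
        n_edges=e,
        avg_degree=2.0 * e / n,
        avg_clustering=nx.average_clustering(g, count_zeros=True) if n else 0.0,
        lcc_n_nodes=lcc.subgraph.number_of_nodes(),
        lcc_n_edges=lcc.subgraph.number_of_edges(),
        degree=dict(g.degree()),
        betweenness=nx.betweenness_centrality(g, normalized=True),
    )


def largest_connected_component(m: Module) -> Module:
    """Node-maximal connected component; size ties broken by the
    lexicographically smallest member gene."""
    if m.is_empty:
        raise ValueError("empty module")
    comps = [sorted(c) for c in nx.connected_components(m.subgraph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    chosen = comps[0]
    sub = m.subgraph.subgraph(chosen).copy()
    dropped = [g for g in m.mapped if g not in set(chosen)]
    return Module(m.label + "_LCC", chosen, m.unmapped + dropped, sub)


def _induced_edges(adj: csr_matrix, idx: np.ndarray) -> int:
    return int(adj[idx][:, idx].sum() // 2)


def edge_enrichment_test(
    m: Module,
    net: Interactome,
    n_iter: int = 10_000,
    seed: int | None = None,
    degree_binned: bool = True,
) -> EnrichmentResult:
    """Is the module denser than random node sets of the same size?

    The null draws ``n_iter`` node sets of identical size from the
    interactome (degree-binned by default) and counts induced edges.
    Empirical p uses add-one smoothing: (1 + #{null >= observed}) /
    (1 + n_iter), so the attainable minimum is 1/(n_iter + 1).
    """
    if n_iter < 100:
        raise ValueError(f"n_iter must be >= 100, got {n_iter}")
    if len(m.mapped) > net.n_nodes:
        raise ValueError("module larger than interactome")
    rng = np.random.default_rng(seed)
    adj = net.adjacency()
    idx = net.index_of(m.mapped)
    observed = _induced_edges(adj, idx)
    null = np.empty(n_iter)
    for i in range(n_iter):
        null[i] = _induced_edges(adj, net.sample_matched(idx, rng, degree_binned))
    mu, sd = null.mean(), null.std(ddof=1)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_iter)
    z = (observed - mu) / sd if sd > 0 else np.inf * np.sign(observed - mu)
    return EnrichmentResult(observed, mu, sd, p, z, n_iter)


def _cross_distance(
    dist: np.ndarray, ia: np.ndarray, ib: np.ndarray, convention: str
) -> tuple[float, float]:
    """Mean cross-set distance and the unreachable-pair fraction.

    ``all_pairs``: mean over all (a, b) pairs; a gene shared by both sets
    contributes distance 0 through its (g, g) pair.  ``closest``: for each
    node the minimum distance to the other set, averaged, symmetrized.
    """
    sub = dist[np.ix_(ia, ib)]
    finite = np.isfinite(sub)
    unreachable = 1.0 - finite.mean()
    if convention == "all_pairs":
        if not finite.any():
            raise ValueError("no reachable cross pair between the modules")
        return float(sub[finite].mean()), unreachable
    if convention == "closest":
        with np.errstate(invalid="ignore"):
            mins_a = np.min(np.where(finite, sub, np.inf), axis=1)
            mins_b = np.min(np.where(finite, sub, np.inf), axis=0)
        vals = np.concatenate([mins_a, mins_b])
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError("no reachable cross pair between the modules")
        return float(vals.mean()), unreachable
    raise ValueError(f"unknown distance convention {convention!r}")


def module_closeness(
    a: Module,
    b: Module,
    net: Interactome,
    n_iter: int = 1000,
    seed: int | None = None,
    convention: str = "all_pairs",
    degree_binned: bool = True,
) -> ClosenessResult:
    """Closeness of two modules in the interactome vs a random-set null.

    The observed statistic is the mean shortest-path length over reachable
    cross pairs (see ``_cross_distance``); the null repeats it for ``n_iter``
    degree-matched random node-set pairs of the same sizes, giving
    z = (d_obs - mu) / sigma.  z < -1.65 marks significant closeness
    (one-sided p < 0.05 under a normal null).
    """
    if a.is_empty or b.is_empty:
        raise ValueError("both modules must map at least one gene")
    if n_iter < 100:
        raise ValueError(f"n_iter must be >= 100, got {n_iter}")
    rng = np.random.default_rng(seed)
    dist = net.distances()
    ia, ib = net.index_of(a.mapped), net.index_of(b.mapped)
    d_obs, unreach = _cross_distance(dist, ia, ib, convention)
    null = np.empty(n_iter)
    for i in range(n_iter):
        ra = net.sample_matched(ia, rng, degree_binned)
        rb = net.sample_matched(ib, rng, degree_binned)
        null[i], _ = _cross_distance(dist, ra, rb, convention)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate null (zero variance); raise n_iter")
    return ClosenessResult(
        a.label, b.label, d_obs, mu, sd, (d_obs - mu) / sd, n_iter, unreach
    )
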