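"""GO-style over-representation analysis and Wang semantic similarity.

The Wang method scores the similarity of two ontology terms from their
positions in the GO graph: each term induces S-values over its ancestor
closure (S = 1 at the term itself, decaying multiplicatively through typed
edges with semantic contribution factors w_is_a = 0.8, w_part_of = 0.6, the
method's established constants), and the similarity of two terms is the
shared S-mass over the total.  Gene- and set-level similarities aggregate
term similarities with the best-match-average (BMA) strategy.

Over-representation uses the upper-tail hypergeometric test per term with
Benjamini-Hochberg FDR control across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

RELATIONS = ("is_a", "part_of")


@dataclass
class SemSimConfig:
    """Semantic contribution factors per edge type; BMA is the fixed
    combination strategy at the gene and set levels."""

    w_is_a: float = 0.8
    w_part_of: float = 0.6

    def __post_init__(self) -> None:
        for w in (self.w_is_a, self.w_part_of):
            if not 0 < w < 1:
                raise ValueError(f"contribution factors must be in (0,1), got {w}")

    def weight(self, relation: str) -> float:
        if relation == "is_a":
            return self.w_is_a
        if relation == "part_of":
            return self.w_part_of
        raise ValueError(f"unknown relation {relation!r}")


class OntologyDag:
    """Acyclic term graph with typed child -> parent edges (is_a / part_of)."""

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        self.graph = graph
        self.roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
        self._svalue_cache: dict[tuple, dict[str, float]] = {}
        for t in graph.nodes:
            if t not in self.roots and not any(
                nx.has_path(graph, t, r) for r in self.roots
            ):
                raise ValueError(f"term {t} cannot reach a root")

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def ancestor_closure(self, term: str) -> set[str]:
        """The term itself plus everything reachable along parent edges."""
        return {term} | nx.descendants(self.graph, term)


def parse_obo_subset(path) -> OntologyDag:
    """Parse a minimal OBO file (id / name / namespace / is_a /
    relationship: part_of) into an OntologyDag.

    Uses obonet for the stanza format; obsolete terms are skipped, relations
    other than is_a/part_of are ignored, parents that no [Term] stanza
    defines raise, and cycles raise naming the cycle.
    """
    import obonet

    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    for term, data in multi.nodes(data=True):
        g.add_node(term, **{k: data[k] for k in ("name", "namespace") if k in data})
    for child, parent, rel in multi.edges(keys=True):
        if rel not in RELATIONS:
            continue
        if "name" not in multi.nodes[parent]:
            raise ValueError(f"dangling parent {parent} (referenced by {child})")
        g.add_edge(child, parent, relation=rel)
    return OntologyDag(g)


def wang_svalues(term: str, dag: OntologyDag, cfg: SemSimConfig | None = None) -> dict[str, float]:
    """S-values of a term over its ancestor closure.

    S(term) = 1; for an ancestor t, S(t) is the maximum over child edges
    c -> t inside the closure of w(relation) * S(c) — a dynamic program over
    the closure in topological (child-before-parent) order.  The semantic
    value SV(term) is the sum of all S-values.
    """
    cfg = cfg or SemSimConfig()
    if term not in dag:
        raise KeyError(f"unknown term {term!r}")
    key = (term, cfg.w_is_a, cfg.w_part_of)
    cached = dag._svalue_cache.get(key)
    if cached is not None:
        return dict(cached)
    closure = dag.ancestor_closure(term)
    sub = dag.graph.subgraph(closure)
    s = {term: 1.0}
    for t in nx.topological_sort(sub):
        if t == term:
            continue
        best = 0.0
        for child, _, data in sub.in_edges(t, data=True):
            if child in s:
                best = max(best, cfg.weight(data["relation"]) * s[child])
        s[t] = best
    dag._svalue_cache[key] = dict(s)
    return s


def semantic_value(term: str, dag: OntologyDag, cfg: SemSimConfig | None = None) -> float:
    return sum(wang_svalues(term, dag, cfg).values())


def term_sim(a: str, b: str, dag: OntologyDag, cfg: SemSimConfig | None = None) -> float:
    """Wang similarity of two terms:
    sum over shared closure terms of (S_a + S_b) / (SV(a) + SV(b))."""
    cfg = cfg or SemSimConfig()
    na, nb = dag.namespace(a), dag.namespace(b)
    if na is not None and nb is not None and na != nb:
        raise ValueError(f"cross-namespace comparison: {a} ({na}) vs {b} ({nb})")
    sa = wang_svalues(a, dag, cfg)
    sb = wang_svalues(b, dag, cfg)
    common = set(sa) & set(sb)
    if not common:
        return 0.0
    return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))


def _bma(matrix: np.ndarray) -> float:
    """Best-match-average of an m x n similarity matrix:
    (sum of row maxima + sum of column maxima) / (m + n)."""
    m, n = matrix.shape
    return float((matrix.max(axis=1).sum() + matrix.max(axis=0).sum()) / (m + n))


def gene_sim(
    g1: str, g2: str, annotations: dict[str, set[str]],
    dag: OntologyDag, cfg: SemSimConfig | None = None,
) -> float:
    """BMA-combined Wang similarity over the two genes' annotation terms.

    Cross-namespace term pairs contribute 0 rather than raising, so genes
    annotated in several namespaces still compare.
    """
    cfg = cfg or SemSimConfig()
    for g in (g1, g2):
        if g not in annotations or not annotations[g]:
            raise KeyError(f"gene {g!r} has no annotations")
    ta, tb = sorted(annotations[g1]), sorted(annotations[g2])
    mat = np.zeros((len(ta), len(tb)))
    for i, x in enumerate(ta):
        for j, y in enumerate(tb):
            try:
                mat[i, j] = term_sim(x, y, dag, cfg)
            except ValueError:
                mat[i, j] = 0.0
    return _bma(mat)


def set_sim(
    set_a, set_b, annotations: dict[str, set[str]],
    dag: OntologyDag, cfg: SemSimConfig | None = None,
) -> float:
    """Set-level (cluster) similarity: BMA over the gene-pair similarity
    matrix.  Genes lacking annotations are excluded and counted in the log."""
    cfg = cfg or SemSimConfig()
    ga = sorted(g for g in set_a if annotations.get(g))
    gb = sorted(g for g in set_b if annotations.get(g))
    skipped = (len(list(set_a)) - len(ga)) + (len(list(set_b)) - len(gb))
    if skipped:
        log.info("set_sim: %d unannotated genes excluded", skipped)
    if not ga or not gb:
        raise ValueError("a set has no annotated genes")
    mat = np.zeros((len(ga), len(gb)))
    for i, x in enumerate(ga):
        for j, y in enumerate(gb):
            mat[i, j] = gene_sim(x, y, annotations, dag, cfg)
    return _bma(mat)


def ora(
    signature,
    universe,
    annotations: dict[str, set[str]],
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a gene set.

    For each term with at least ``min_term_size`` annotated genes in the
    universe: p = P(X >= k) with X ~ Hypergeom(N, K, n), where N is the
    universe size, K the term's universe count, n the signature size and k
    the overlap.  Benjamini-Hochberg q-values are computed across the tested
    terms; rows are sorted by (q, p).
    """
    sig = set(signature.genes if hasattr(signature, "genes") else signature)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not sig <= uni:
        raise ValueError(f"{len(sig - uni)} signature genes outside the universe")
    term_to_genes: dict[str, set[str]] = {}
    for g in uni:
        for t in annotations.get(g, ()):
            term_to_genes.setdefault(t, set()).add(g)
    rows = []
    N, n = len(uni), len(sig)
    for t, members in sorted(term_to_genes.items()):
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & sig)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": t, "k": k, "n": n, "K": K, "N": N, "p": p})
    if not rows:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "p", "q"])
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
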