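"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Emulates (i) a microarray-like log2 expression cohort with four overlapping
binary maternal conditions (PE, asthma, excess BMI, vitamin D insufficiency)
and planted additive condition effects sharing a core signature, (ii) a
degree-heterogeneous interactome with locally clustered planted modules,
(iii) a small single-rooted GO-like DAG with typed edges and gene
annotations, and (iv) a second-tissue ("placenta") two-group matrix
expressing a configurable fraction of the blood core signature with
concordant directions.

Default cohort sizes and prevalences mirror the discovery design this
package targets: N = 157 with 47 PE cases, 63 asthmatic, 104 with
BMI >= 25 kg/m^2 and 119 with 25OHD < 30 ng/mL.  Everything is reproducible
bit-for-bit from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .network import Interactome

CONDITIONS = ("PE", "asthma", "excess_BMI", "vitD_insufficient")

#: discovery-cohort condition frequencies (47, 63, 104 and 119 of 157)
DEFAULT_PREVALENCES = {
    "PE": 47 / 157,
    "asthma": 63 / 157,
    "excess_BMI": 104 / 157,
    "vitD_insufficient": 119 / 157,
}

#: planted signature sizes, ~1/16 of the real contrasts' DE counts
DEFAULT_SIGNATURE_SIZES = {
    "PE": 60,
    "asthma": 75,
    "excess_BMI": 68,
    "vitD_insufficient": 49,
}


@dataclass
class ExpressionStudy:
    """Normalized log2 expression (genes x samples) plus per-sample phenotypes.

    ``values`` is a frame indexed by gene with sample columns; ``phenotypes``
    is indexed by sample and carries the four binary condition flags plus any
    covariates.
    """

    values: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        # user-supplied matrices may carry missing values (the cross-tissue
        # expressed-in-all filter handles them); generated ones never do
        if not self.values.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        if list(self.values.columns) != list(self.phenotypes.index):
            raise ValueError("sample order mismatch between values and phenotypes")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CohortSpec:
    """Generator settings for one synthetic blood cohort.

    ``effect_size`` (delta) is the additive log2-scale shift applied, with a
    per-gene random sign, to samples positive for each condition a gene is
    planted in; the default equals 2x the measurement noise SD.  Per-gene
    baselines follow mean ~ U(baseline_mean_range) and biological
    SD ~ U(baseline_sd_range); sample noise is Gaussian with ``noise_sd``.
    """

    n_genes: int = 1000
    n_samples: int = 157
    condition_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    signature_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_SIZES))
    core_size: int = 15
    effect_size: float = 1.0
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    baseline_sd_range: tuple[float, float] = (0.1, 0.3)
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if set(self.condition_prevalences) != set(CONDITIONS):
            raise ValueError(f"prevalences must cover exactly {CONDITIONS}")
        if set(self.signature_sizes) != set(CONDITIONS):
            raise ValueError(f"signature sizes must cover exactly {CONDITIONS}")
        for c, p in self.condition_prevalences.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence for {c} must be in (0,1), got {p}")
        if self.core_size > min(self.signature_sizes.values()):
            raise ValueError(
                f"core_size {self.core_size} exceeds the smallest signature size "
                f"{min(self.signature_sizes.values())}"
            )
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        total_planted = self.core_size + sum(
            s - self.core_size for s in self.signature_sizes.values()
        )
        if total_planted > self.n_genes:
            raise ValueError(
                f"planted structure needs {total_planted} genes, have {self.n_genes}"
            )
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _empty_truth(genes: list[str]) -> pd.DataFrame:
    truth = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for c in CONDITIONS:
        truth[c] = False
    truth["direction"] = 0
    truth["effect"] = 0.0
    return truth


def plant_truth(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the planted membership table: a core set shared by all four
    conditions plus per-condition exclusive sets, disjoint outside the core.
    Direction is a random sign per gene, fixed across conditions."""
    genes = _gene_names(spec.n_genes)
    truth = _empty_truth(genes)
    need = spec.core_size + sum(
        s - spec.core_size for s in spec.signature_sizes.values()
    )
    chosen = rng.choice(spec.n_genes, size=need, replace=False)
    pos = 0
    core = chosen[:spec.core_size]
    pos = spec.core_size
    for c in CONDITIONS:
        extra = chosen[pos:pos + spec.signature_sizes[c] - spec.core_size]
        pos += len(extra)
        members = np.concatenate([core, extra])
        truth.iloc[members, truth.columns.get_loc(c)] = True
    planted = truth[list(CONDITIONS)].any(axis=1).to_numpy()
    signs = rng.choice([-1, 1], size=spec.n_genes)
    truth.loc[planted, "direction"] = signs[planted]
    truth.loc[planted, "effect"] = spec.effect_size * signs[planted]
    return truth


def core_genes(truth: pd.DataFrame) -> list[str]:
    """Genes planted in all four conditions."""
    mask = truth[list(CONDITIONS)].all(axis=1)
    return list(truth.index[mask])


def simulate_cohort(
    spec: CohortSpec, truth: pd.DataFrame | None = None
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Generate one cohort; returns (study, truth table).

    Condition flags are independent Bernoulli per sample.  Expression is
    baseline + biological variation + noise, and for each planted
    (gene, condition) pair, samples positive for that condition are shifted
    by the gene's signed effect — shifts stack additively across conditions.

    Passing an existing ``truth`` reuses the planted structure (for
    replication cohorts sharing the discovery truth) while drawing fresh
    samples from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if truth is None:
        truth = plant_truth(spec, rng)
    elif len(truth) != spec.n_genes:
        raise ValueError("supplied truth table does not match n_genes")
    genes = list(truth.index)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]

    flags = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for c in CONDITIONS:
        p = spec.condition_prevalences[c]
        col = rng.random(spec.n_samples) < p
        # guard: permutation DE needs both classes occupied
        if col.all():
            col[rng.integers(spec.n_samples)] = False
        if not col.any():
            col[rng.integers(spec.n_samples)] = True
        flags[c] = col.astype(int)

    lo, hi = spec.baseline_mean_range
    mu = rng.uniform(lo, hi, size=spec.n_genes)
    slo, shi = spec.baseline_sd_range
    gsd = rng.uniform(slo, shi, size=spec.n_genes)
    X = (
        mu[:, None]
        + gsd[:, None] * rng.standard_normal((spec.n_genes, spec.n_samples))
        + spec.noise_sd * rng.standard_normal((spec.n_genes, spec.n_samples))
    )
    effect = truth["effect"].to_numpy(float)
    for c in CONDITIONS:
        planted = truth[c].to_numpy(bool)
        pos = flags[c].to_numpy(bool)
        X[np.ix_(planted, pos)] += effect[planted][:, None]

    values = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionStudy(values, flags), truth


def simulate_interactome(
    n_nodes: int,
    model: str = "powerlaw_cluster",
    planted_modules: list[list[str]] | None = None,
    boost: float = 0.3,
    cross_boost: float = 0.0,
    seed: int = 0,
    genes: list[str] | None = None,
    attachment_edges: int = 3,
    triangle_p: float = 0.3,
    er_mean_degree: float = 6.0,
) -> Interactome:
    """Degree-heterogeneous undirected interactome with planted dense modules.

    ``boost`` is the extra within-module edge probability; ``cross_boost``
    likewise wires pairs *between* consecutive planted modules, making them
    close in the network.  Background edges carry combined confidence scores
    in (0.4, 0.95]; boosted edges in (0.7, 0.99] so the standard > 0.4
    confidence filter keeps the planted structure.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    names = genes if genes is not None else _gene_names(n_nodes)
    if len(names) != n_nodes:
        raise ValueError("genes list length must equal n_nodes")
    rng = np.random.default_rng(seed)
    nx_seed = int(rng.integers(2**31 - 1))
    if model == "powerlaw_cluster":
        g = nx.powerlaw_cluster_graph(n_nodes, attachment_edges, triangle_p, seed=nx_seed)
    elif model == "erdos_renyi":
        g = nx.gnp_random_graph(n_nodes, er_mean_degree / (n_nodes - 1), seed=nx_seed)
    else:
        raise ValueError(f"unknown interactome model {model!r}")
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    for u, v in g.edges:
        g[u][v]["score"] = float(rng.uniform(0.401, 0.95))

    planted_modules = planted_modules or []
    node_set = set(names)
    for mod in planted_modules:
        missing = set(mod) - node_set
        if missing:
            raise ValueError(f"planted genes not in the node set: {sorted(missing)[:5]}")
        mod = sorted(mod)
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                if not g.has_edge(mod[i], mod[j]) and rng.random() < boost:
                    g.add_edge(mod[i], mod[j], score=float(rng.uniform(0.7, 0.99)))
    if cross_boost > 0:
        for a, b in zip(planted_modules, planted_modules[1:]):
            for u in sorted(a):
                for v in sorted(b):
                    if u != v and not g.has_edge(u, v) and rng.random() < cross_boost:
                        g.add_edge(u, v, score=float(rng.uniform(0.7, 0.99)))
    g.add_nodes_from(names)  # keep isolated nodes addressable
    return Interactome(g, min_confidence=0.4)


def simulate_ontology(
    n_terms: int,
    max_depth: int = 4,
    part_of_fraction: float = 0.2,
    genes: list[str] | None = None,
    annotations_per_gene: int = 3,
    seed: int = 0,
    second_parent_p: float = 0.25,
    namespace: str = "biological_process",
):
    """Single-rooted acyclic GO-like DAG plus a gene annotation table.

    Terms are assigned depths 1..max_depth; each non-root term gets one
    typed parent (``part_of`` with probability ``part_of_fraction``, else
    ``is_a``) at the previous depth, plus possibly a second parent at any
    shallower depth (a DAG, not a tree).  Each gene receives exactly
    ``annotations_per_gene`` distinct non-root terms.

    Returns ``(OntologyDag, annotations)`` with annotations a dict
    gene -> set of term ids.
    """
    from .ontology import OntologyDag

    if n_terms < 2:
        raise ValueError("n_terms must be >= 2")
    if annotations_per_gene > n_terms - 1:
        raise ValueError("annotations_per_gene exceeds available terms")
    rng = np.random.default_rng(seed)
    ids = [f"T:{i:07d}" for i in range(n_terms)]
    root = ids[0]
    dag = nx.DiGraph()
    depth = {root: 0}
    dag.add_node(root, name="root", namespace=namespace)
    by_depth: dict[int, list[str]] = {0: [root]}
    for k, term in enumerate(ids[1:], start=1):
        d = 1 if max_depth <= 1 else 1 + int(rng.integers(max_depth))
        while d > 1 and not by_depth.get(d - 1):
            d -= 1
        depth[term] = d
        dag.add_node(term, name=f"term {k}", namespace=namespace)
        parent = by_depth[d - 1][int(rng.integers(len(by_depth[d - 1])))]
        rel = "part_of" if rng.random() < part_of_fraction else "is_a"
        dag.add_edge(term, parent, relation=rel)
        if d > 1 and rng.random() < second_parent_p:
            shallower = [t for t, dd in depth.items() if dd < d and t != parent]
            extra = shallower[int(rng.integers(len(shallower)))]
            rel2 = "part_of" if rng.random() < part_of_fraction else "is_a"
            dag.add_edge(term, extra, relation=rel2)
        by_depth.setdefault(d, []).append(term)

    annotations: dict[str, set[str]] = {}
    if genes:
        non_root = np.array(ids[1:])
        for gname in genes:
            picks = rng.choice(len(non_root), size=annotations_per_gene, replace=False)
            annotations[gname] = set(non_root[picks])
    return OntologyDag(dag), annotations


def simulate_placenta(
    blood_truth: pd.DataFrame,
    concordance: float = 0.41,
    n_samples: int = 60,
    seed: int = 0,
    baseline_mean_range: tuple[float, float] = (6.0, 12.0),
    baseline_sd_range: tuple[float, float] = (0.1, 0.3),
    noise_sd: float = 0.5,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """A second-tissue two-group (PE vs control) cohort over the same genes.

    A ``concordance`` fraction of the blood core signature (round-half-even)
    is planted with the blood direction and effect; everything else is null.
    The default concordance of 0.41 mirrors the fraction of the blood
    overlap signature the study observed as differentially expressed in
    term placenta.
    """
    if not 0 <= concordance <= 1:
        raise ValueError(f"concordance must be in [0, 1], got {concordance}")
    rng = np.random.default_rng(seed)
    genes = list(blood_truth.index)
    core = core_genes(blood_truth)
    n_plant = round(concordance * len(core))
    picked = sorted(
        np.array(core)[rng.choice(len(core), size=n_plant, replace=False)]
    ) if n_plant else []

    truth = _empty_truth(genes)
    truth.loc[picked, "PE"] = True
    truth.loc[picked, "direction"] = blood_truth.loc[picked, "direction"]
    truth.loc[picked, "effect"] = blood_truth.loc[picked, "effect"]

    samples = [f"P{i:04d}" for i in range(n_samples)]
    flags = pd.DataFrame(index=pd.Index(samples, name="sample"))
    case = np.zeros(n_samples, bool)
    case[:n_samples // 2] = True
    flags["PE"] = case.astype(int)
    for c in CONDITIONS[1:]:
        flags[c] = 0

    lo, hi = baseline_mean_range
    mu = rng.uniform(lo, hi, size=len(genes))
    slo, shi = baseline_sd_range
    gsd = rng.uniform(slo, shi, size=len(genes))
    X = (
        mu[:, None]
        + gsd[:, None] * rng.standard_normal((len(genes), n_samples))
        + noise_sd * rng.standard_normal((len(genes), n_samples))
    )
    planted = truth["PE"].to_numpy(bool)
    X[np.ix_(planted, case)] += truth["effect"].to_numpy(float)[planted][:, None]
    values = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionStudy(values, flags), truth


def replication_spec(spec: CohortSpec, n_samples: int, seed: int) -> CohortSpec:
    """A spec for a replication cohort sharing the discovery planted truth."""
    return replace(spec, n_samples=n_samples, seed=seed)
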