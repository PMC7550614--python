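"""Flat-file readers and writers: TSV matrices, signatures, edge lists,
minimal OBO, and run manifests.  All outputs are plain text."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .rankprod import DEResult
from .signatures import GeneSignature
from .simulate import CONDITIONS, ExpressionStudy


def write_study(study: ExpressionStudy, outdir, prefix: str) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vpath = outdir / f"{prefix}_expression.tsv"
    ppath = outdir / f"{prefix}_phenotypes.tsv"
    study.values.to_csv(vpath, sep="\t", float_format="%.6g")
    study.phenotypes.to_csv(ppath, sep="\t")
    return vpath, ppath


def read_study(values_path, phenotypes_path) -> ExpressionStudy:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    phenotypes = pd.read_csv(phenotypes_path, sep="\t", index_col=0)
    phenotypes.index = phenotypes.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionStudy(values, phenotypes)


def write_truth(truth: pd.DataFrame, path) -> Path:
    path = Path(path)
    truth.to_csv(path, sep="\t")
    return path


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col=0)
    for c in CONDITIONS:
        truth[c] = truth[c].astype(bool)
    return truth


def write_de_result(result: DEResult, path) -> Path:
    cols = ["RP_up", "p_up", "pfp_up", "RP_down", "p_down", "pfp_down", "mean_log2_diff"]
    result.table[cols].to_csv(Path(path), sep="\t", float_format="%.8g")
    return Path(path)


def read_de_result(path, condition: str = "?") -> DEResult:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return DEResult(condition, table, n_comparisons=0, n_permutations=0)


def write_signature(sig: GeneSignature, path) -> Path:
    frame = pd.DataFrame(
        sorted(sig.entries.items()), columns=["gene", "direction"]
    )
    frame.to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def read_signature(path, label: str | None = None, provenance: str = "discovery") -> GeneSignature:
    frame = pd.read_csv(path, sep="\t")
    entries = dict(zip(frame["gene"].astype(str), frame["direction"]))
    return GeneSignature(label or Path(path).stem, entries, provenance)


def write_interactome_tsv(net, path) -> Path:
    rows = [
        (u, v, f"{d['score']:.4f}")
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    frame = pd.DataFrame(rows, columns=["geneA", "geneB", "combined_score"])
    frame.to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def write_obo(dag, path) -> Path:
    """Serialize an OntologyDag as minimal OBO [Term] stanzas."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.graph.nodes):
        data = dag.graph.nodes[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {data.get('name', term)}")
        if data.get("namespace"):
            lines.append(f"namespace: {data['namespace']}")
        for _, parent, edata in sorted(dag.graph.out_edges(term, data=True)):
            if edata["relation"] == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: part_of {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
    return Path(path)


def write_annotations(annotations: dict[str, set[str]], path) -> Path:
    rows = [(g, t) for g in sorted(annotations) for t in sorted(annotations[g])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def read_annotations(path) -> dict[str, set[str]]:
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for g, t in zip(frame["gene"].astype(str), frame["term"].astype(str)):
        out.setdefault(g, set()).add(t)
    return out


def write_graphml(graph, path) -> Path:
    import networkx as nx

    nx.write_graphml(graph, Path(path))
    return Path(path)


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path) -> Path:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return Path(path)
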