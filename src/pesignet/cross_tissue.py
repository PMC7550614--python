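"""Replication of a blood-derived overlap signature in a second tissue.

The overlap signature is first filtered to genes with an expression value in
every sample of the second-tissue (placenta analog) matrix, the matrix gets
a genome-wide rank-product permutation analysis, signature genes called at a
two-sided permutation p < alpha survive, and the surviving subset is
re-mapped onto the interactome for module statistics and LCC size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import network
from .rankprod import PairingScheme, permutation_pfp
from .signatures import GeneSignature

log = logging.getLogger(__name__)


@dataclass
class TissueReplicationReport:
    n_signature: int
    n_expressed_in_all: int
    n_de: int
    de_signature: GeneSignature
    module_stats: network.ModuleStats | None
    lcc_size: int
    n_mapped: int

    def to_json_dict(self) -> dict:
        return {
            "n_signature": self.n_signature,
            "n_expressed_in_all": self.n_expressed_in_all,
            "n_de": self.n_de,
            "de_fraction_pct": round(100.0 * self.n_de / self.n_signature, 1)
            if self.n_signature else 0.0,
            "n_mapped": self.n_mapped,
            "lcc_size": self.lcc_size,
            "module": self.module_stats.to_json_dict() if self.module_stats else None,
        }


def expressed_in_all(signature, study) -> list[str]:
    """Signature genes present in the matrix with a non-missing value in
    every sample."""
    genes = signature.genes if hasattr(signature, "genes") else set(signature)
    complete = study.values.notna().all(axis=1)
    return sorted(g for g in genes if g in study.values.index and complete.get(g, False))


def tissue_replication(
    signature: GeneSignature,
    study,
    group_flag: str = "PE",
    alpha: float = 0.05,
    B: int = 100,
    seed: int | None = None,
    net: network.Interactome | None = None,
    scheme: PairingScheme | None = None,
    use_pfp: bool = False,
) -> TissueReplicationReport:
    """Test the signature's differential expression in a second tissue.

    DE is computed on the full matrix (rank statistics stay genome-wide) and
    then intersected with the signature's expressed-in-all subset.  A gene
    is called at two-sided permutation p = min(1, 2*min(p_up, p_down)) <
    alpha (or pfp < alpha with ``use_pfp``), with its direction from the
    smaller one-tailed p.  The called subset maps onto ``net`` when given.
    """
    expressed = expressed_in_all(signature, study)
    result = permutation_pfp(study, group_flag, scheme=scheme, B=B, seed=seed)
    tab = result.table
    entries: dict[str, str] = {}
    for g in expressed:
        row = tab.loc[g]
        if use_pfp:
            hit = min(row["pfp_up"], row["pfp_down"]) < alpha
        else:
            hit = min(1.0, 2.0 * min(row["p_up"], row["p_down"])) < alpha
        if hit:
            entries[g] = "up" if row["p_up"] <= row["p_down"] else "down"
    de_sig = GeneSignature(signature.label, entries, provenance="placenta")

    stats = None
    lcc_size = 0
    n_mapped = 0
    if net is not None and entries:
        module = network.build_module(de_sig, net)
        n_mapped = len(module.mapped)
        if not module.is_empty:
            stats = network.module_stats(module)
            lcc_size = stats.lcc_n_nodes
    return TissueReplicationReport(
        n_signature=len(signature),
        n_expressed_in_all=len(expressed),
        n_de=len(entries),
        de_signature=de_sig,
        module_stats=stats,
        lcc_size=lcc_size,
        n_mapped=n_mapped,
    )


def map_ids(
    genes,
    mapping: pd.DataFrame,
    expression: pd.DataFrame | None = None,
) -> tuple[list[str], list[str]]:
    """Translate identifiers through a 2-column (source, target) table.

    Returns ``(translated, unmapped)``.  When several sources collapse onto
    one target, the source with the highest mean expression wins if an
    expression matrix is supplied, else the first occurrence (logged).
    """
    if mapping is None or len(mapping) == 0:
        raise ValueError("empty mapping table")
    src = mapping.iloc[:, 0].astype(str)
    tgt = mapping.iloc[:, 1].astype(str)
    lookup = dict(zip(src, tgt))
    genes = list(genes)
    unmapped = [g for g in genes if g not in lookup]
    by_target: dict[str, list[str]] = {}
    for g in genes:
        if g in lookup:
            by_target.setdefault(lookup[g], []).append(g)
    translated = []
    n_collisions = 0
    for target in by_target:
        sources = by_target[target]
        if len(sources) > 1:
            n_collisions += 1
            if expression is not None:
                means = {s: expression.loc[s].mean() for s in sources if s in expression.index}
                if means:
                    sources = [max(means, key=means.get)]
        translated.append(target)
    if n_collisions:
        log.info("map_ids: %d many-to-one collisions collapsed", n_collisions)
    return sorted(translated), unmapped
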