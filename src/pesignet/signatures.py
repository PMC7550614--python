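"""Gene signatures: replication filtering, four-way intersection, sensitivity overlap.

A signature is a directed gene set (each gene labelled up or down) tied to one
study condition.  Discovery signatures are filtered by a replication cohort's
permutation p-values, the four replicated signatures are intersected to give
the overlapping (core) signature, and a sensitivity contrast (all-conditions
vs none) is compared against that overlap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")


@dataclass
class GeneSignature:
    """A directed gene set for one condition.

    Parameters
    ----------
    label : condition name (e.g. ``"PE"``).
    entries : mapping gene -> direction (``"up"`` or ``"down"``).
    provenance : one of ``discovery``, ``replicated``, ``overlap``, ``placenta``.
    """

    label: str
    entries: dict[str, str] = field(default_factory=dict)
    provenance: str = "discovery"

    def __post_init__(self) -> None:
        bad = {d for d in self.entries.values()} - set(DIRECTIONS)
        if bad:
            raise ValueError(f"invalid directions {sorted(bad)}; allowed: {DIRECTIONS}")

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def direction(self, gene: str) -> str:
        return self.entries[gene]

    def upregulated(self) -> set[str]:
        return {g for g, d in self.entries.items() if d == "up"}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries


@dataclass
class IntersectionReport:
    """Exclusive membership counts for every non-empty subset of four signatures.

    ``exclusive_counts`` maps a sorted tuple of condition labels to the number
    of genes found in exactly those signatures (UpSet-style counts); they
    partition the union.  ``overlap`` is the four-way intersection as a
    signature, with directions taken from the reference (PE) signature.
    ``discordant`` lists overlap genes whose direction disagrees between
    signatures.
    """

    labels: tuple[str, ...]
    exclusive_counts: dict[tuple[str, ...], int]
    overlap: GeneSignature
    discordant: list[str]

    def count(self, *labels: str) -> int:
        return self.exclusive_counts.get(tuple(sorted(labels)), 0)

    def union_size(self) -> int:
        return sum(self.exclusive_counts.values())

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "exclusive_counts": {
                "+".join(k): v for k, v in sorted(self.exclusive_counts.items())
            },
            "overlap_size": len(self.overlap),
            "overlap_upregulated": len(self.overlap.upregulated()),
            "discordant": sorted(self.discordant),
        }


def replicate_signature(
    discovery: GeneSignature,
    replication,
    alpha: float = 0.05,
    require_direction: bool = True,
) -> GeneSignature:
    """Filter a discovery signature by a replication cohort's DE result.

    A discovery gene is retained when its two-sided replication p-value,
    ``min(1, 2 * min(p_up, p_down))``, is below ``alpha`` and (optionally) the
    replication direction matches the discovery direction.  Rank-product
    p-values are one-tailed per direction, so the doubling is the standard
    two-sided reading.  Genes absent from the replication result are dropped
    and logged.

    ``replication`` is a DE result exposing a ``table`` frame indexed by gene
    with ``p_up``, ``p_down`` and ``mean_log2_diff`` columns.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    tab = replication.table
    kept: dict[str, str] = {}
    missing = []
    for gene, direction in discovery.entries.items():
        if gene not in tab.index:
            missing.append(gene)
            continue
        row = tab.loc[gene]
        p_two = min(1.0, 2.0 * min(row["p_up"], row["p_down"]))
        if p_two >= alpha:
            continue
        if row["p_up"] < row["p_down"]:
            rep_dir = "up"
        elif row["p_down"] < row["p_up"]:
            rep_dir = "down"
        else:  # tie: fall back on the sign of the mean difference
            rep_dir = "up" if row["mean_log2_diff"] >= 0 else "down"
        if require_direction and rep_dir != direction:
            continue
        kept[gene] = direction
    if missing:
        log.info(
            "%s: %d discovery genes missing from replication result, dropped",
            discovery.label, len(missing),
        )
    return GeneSignature(discovery.label, kept, provenance="replicated")


def intersect_signatures(signatures: list[GeneSignature]) -> IntersectionReport:
    """Exclusive (UpSet) intersection counts of exactly four signatures.

    Membership is by gene symbol; direction is ignored for membership.  The
    overlap signature takes directions from the PE signature when present
    (else the first), and genes whose direction differs between any pair of
    signatures are reported as discordant.
    """
    if len(signatures) != 4:
        raise ValueError(f"expected exactly four signatures, got {len(signatures)}")
    labels = tuple(s.label for s in signatures)
    if len(set(labels)) != 4:
        raise ValueError(f"duplicate signature labels: {labels}")

    membership: dict[str, frozenset[str]] = {}
    for s in signatures:
        for g in s.genes:
            membership[g] = membership.get(g, frozenset()) | {s.label}

    exclusive: dict[tuple[str, ...], int] = {}
    for r in range(1, 5):
        for combo in itertools.combinations(sorted(labels), r):
            exclusive[combo] = 0
    for subset in membership.values():
        exclusive[tuple(sorted(subset))] += 1

    reference = next((s for s in signatures if s.label == "PE"), signatures[0])
    full = frozenset(labels)
    overlap_genes = sorted(g for g, m in membership.items() if m == full)
    entries = {g: reference.direction(g) for g in overlap_genes}
    discordant = [
        g for g in overlap_genes
        if len({s.direction(g) for s in signatures}) > 1
    ]
    if discordant:
        log.info("%d overlap genes have discordant directions", len(discordant))
    overlap = GeneSignature("overlap", entries, provenance="overlap")
    return IntersectionReport(labels, exclusive, overlap, discordant)


def sensitivity_overlap(
    all_vs_none: GeneSignature, overlap: GeneSignature
) -> tuple[int, int]:
    """Fraction of the overlap signature recovered by the all-vs-none contrast.

    Returns ``(percentage, shared_count)`` where the percentage is
    ``100 * |all_vs_none ∩ overlap| / |overlap|`` rounded to the nearest
    integer.
    """
    if len(overlap) == 0:
        raise ValueError("overlap signature is empty")
    shared = len(all_vs_none.genes & overlap.genes)
    pct = round(100.0 * shared / len(overlap))
    return pct, shared
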