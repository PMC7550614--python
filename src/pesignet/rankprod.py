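"""Rank Product differential expression with permutation p-values and pfp.

Two-class unpaired design.  For each of K case-control sample pairings the
per-gene log2 expression difference is ranked across genes (rank 1 = most
upregulated for the "up" analysis; the ordering is mirrored for "down").
The rank product RP_g = (prod_k r_gk)^(1/K) is small for genes consistently
at the top of the fold-change ranking.  Significance comes from permuting the
class labels B times: the per-gene p-value pools the permuted RP values of
all genes, and the percentage of false prediction (pfp) divides the expected
number of false positives at a gene's RP cutoff by its rank position — an
FDR-like quantity, thresholded at 0.05 to call DE genes.

The non-parametric rank statistic is robust to small, heterogeneous cohorts,
which is why it suits early-pregnancy peripheral-blood microarray contrasts
with a few dozen samples per arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signatures import GeneSignature

log = logging.getLogger(__name__)


@dataclass
class PairingScheme:
    """How case-control sample pairings are formed in the unpaired design.

    ``all_pairs`` uses every one of the n_case * n_control pairings when that
    count is at most ``n_pairs_cap``, and otherwise falls back to
    ``n_pairs_cap`` seeded random pairings (``sampled`` forces the latter).
    """

    mode: str = "all_pairs"
    n_pairs_cap: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("all_pairs", "sampled"):
            raise ValueError(f"unknown pairing mode {self.mode!r}")
        if self.n_pairs_cap < 1:
            raise ValueError("n_pairs_cap must be >= 1")
        if self.mode == "sampled" and self.seed is None:
            raise ValueError("sampled pairing requires a seed")


@dataclass
class DEResult:
    """Per-gene rank-product statistics for one two-class contrast.

    ``table`` is indexed by gene with columns RP_up, rank_up, p_up, pfp_up,
    RP_down, rank_down, p_down, pfp_down, mean_log2_diff.  pfp values are
    stored unclipped (they may exceed 1); clip at 1 for display.
    """

    condition: str
    table: pd.DataFrame
    n_comparisons: int
    n_permutations: int
    warnings: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def residualize(study, covariates: list[str]):
    """Project out known covariates from every gene's expression values.

    Replaces each gene's values with residuals from an ordinary least-squares
    fit on the named phenotype columns plus an intercept.  A stand-in for
    heterogeneity adjustment when nuisance structure is measured rather than
    inferred.  With no covariates the study is returned unchanged.
    """
    from .simulate import ExpressionStudy

    if not covariates:
        return study
    for c in covariates:
        if c not in study.phenotypes.columns:
            raise KeyError(f"covariate {c!r} not in phenotype table")
        if study.phenotypes[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    X = np.column_stack(
        [np.ones(study.n_samples)]
        + [pd.to_numeric(study.phenotypes[c]).to_numpy(float) for c in covariates]
    )
    Y = study.values.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    values = pd.DataFrame(resid, index=study.values.index, columns=study.values.columns)
    return ExpressionStudy(values=values, phenotypes=study.phenotypes.copy())


def _split_indices(study, condition: str) -> tuple[np.ndarray, np.ndarray]:
    flags = study.phenotypes[condition].astype(bool).to_numpy()
    case = np.flatnonzero(flags)
    ctrl = np.flatnonzero(~flags)
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError(
            f"condition {condition!r} has an empty class "
            f"({len(case)} cases, {len(ctrl)} controls)"
        )
    return case, ctrl


def _pairings(
    n_case: int, n_ctrl: int, scheme: PairingScheme, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray]:
    """Return (case_sel, ctrl_sel): positions into the case/control index
    arrays for each of the K comparisons."""
    total = n_case * n_ctrl
    if scheme.mode == "all_pairs" and total <= scheme.n_pairs_cap:
        ci, gi = np.meshgrid(np.arange(n_case), np.arange(n_ctrl), indexing="ij")
        return ci.ravel(), gi.ravel()
    if rng is None:
        rng = np.random.default_rng(scheme.seed)
    k = min(scheme.n_pairs_cap, total)
    flat = rng.choice(total, size=k, replace=False)
    return flat // n_ctrl, flat % n_ctrl


def _rank_desc(D: np.ndarray) -> np.ndarray:
    """Column-wise descending ranks (1 = largest), average ranks on ties.

    Fast path assigns ordinal ranks via a single stable argsort; columns
    that actually contain ties (rare for continuous expression values) are
    re-ranked with scipy's average method.
    """
    G, K = D.shape
    order = np.argsort(-D, axis=0)
    ranks = np.empty((G, K))
    cols = np.arange(K)[None, :]
    ranks[order, cols] = np.arange(1, G + 1, dtype=float)[:, None]
    sorted_vals = np.take_along_axis(D, order, axis=0)
    tied = np.flatnonzero((sorted_vals[1:] == sorted_vals[:-1]).any(axis=0))
    if tied.size:
        ranks[:, tied] = rankdata(-D[:, tied], axis=0, method="average")
    return ranks


def _up_ranks(X: np.ndarray, case_cols, ctrl_cols, case_sel, ctrl_sel) -> np.ndarray:
    """Genes x K matrix of per-comparison ranks; rank 1 = largest difference.

    Ties take average ranks, so down-ranks are n_genes + 1 - up-ranks.
    """
    diffs = X[:, case_cols[case_sel]] - X[:, ctrl_cols[ctrl_sel]]
    return _rank_desc(diffs)


def fold_change_ranks(study, condition: str, scheme: PairingScheme | None = None) -> np.ndarray:
    """Up-regulation rank matrix (genes x K) for one condition contrast."""
    scheme = scheme or PairingScheme()
    case, ctrl = _split_indices(study, condition)
    case_sel, ctrl_sel = _pairings(len(case), len(ctrl), scheme, None)
    return _up_ranks(study.values.to_numpy(float), case, ctrl, case_sel, ctrl_sel)


def rank_product(rank_matrix: np.ndarray) -> np.ndarray:
    """Geometric mean of ranks per gene, computed in log space."""
    rank_matrix = np.asarray(rank_matrix, float)
    if rank_matrix.size == 0:
        raise ValueError("empty rank matrix")
    if rank_matrix.ndim == 1:
        rank_matrix = rank_matrix[:, None]
    if np.any(rank_matrix < 1):
        raise ValueError("ranks must be >= 1")
    # round the log mean: distinct rank multisets differ by far more than
    # 1e-12 here, while accumulated float error stays well below it, so
    # genuinely equal RP values compare as exactly equal downstream
    return np.exp(np.round(np.mean(np.log(rank_matrix), axis=1), 12))


def permutation_pfp(
    study,
    condition: str,
    scheme: PairingScheme | None = None,
    B: int = 100,
    seed: int | None = None,
) -> DEResult:
    """Rank-product permutation analysis for one condition.

    Permutes the class labels ``B`` times, recomputing the rank product each
    time with the same pairing scheme.  Every permutation contributes its RP
    values under *both* orderings to one pooled null (they are
    mirror-exchangeable under the null, so pooling doubles the null sample
    and makes swapping the class labels exchange the up/down results
    exactly on balanced designs).  For a gene with observed statistic RP_g
    at rank position r in the observed ordering:

    * ``p_g = (1 + #{pooled permuted RP <= RP_g}) / (1 + 2 * B * n_genes)``
      (add-one smoothed, never zero);
    * ``pfp_g = (count / (2 * B)) / r`` — expected false positives at the
      gene's cutoff divided by its position, estimating the false
      prediction rate.

    Up- and down-regulation are analysed independently on mirrored orderings.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    scheme = scheme or PairingScheme()
    case, ctrl = _split_indices(study, condition)
    n1, n2 = len(case), len(ctrl)
    n = n1 + n2
    genes = list(study.values.index)
    G = len(genes)
    if B * G > 500_000_000:
        raise ValueError(f"B * n_genes = {B * G} too large; lower B")
    warnings: list[str] = []
    if n1 < 2 or n2 < 2:
        msg = f"class sizes {n1} vs {n2}: permutation null is very coarse"
        warnings.append(msg)
        log.warning(msg)

    X = study.values.to_numpy(float)
    rng = np.random.default_rng(seed)
    case_sel, ctrl_sel = _pairings(n1, n2, scheme, rng)
    K = len(case_sel)

    obs_up = _up_ranks(X, case, ctrl, case_sel, ctrl_sel)
    rp_up = rank_product(obs_up)
    rp_down = rank_product(G + 1 - obs_up)

    null = np.empty(2 * B * G)
    for b in range(B):
        order = rng.permutation(n)
        p_case, p_ctrl = order[:n1], order[n1:]
        if scheme.mode == "sampled" or n1 * n2 > scheme.n_pairs_cap:
            case_sel, ctrl_sel = _pairings(n1, n2, scheme, rng)
        up = _up_ranks(X, p_case, p_ctrl, case_sel, ctrl_sel)
        null[2 * b * G:(2 * b + 1) * G] = rank_product(up)
        null[(2 * b + 1) * G:(2 * b + 2) * G] = rank_product(G + 1 - up)
    null.sort()

    def _p_pfp(rp: np.ndarray) -> tuple[np.ndarray, ...]:
        count = np.searchsorted(null, rp, side="right").astype(float)
        p = (1.0 + count) / (1.0 + 2 * B * G)
        order = np.argsort(rp, kind="stable")
        rank_pos = np.empty(G)
        rank_pos[order] = np.arange(1, G + 1)
        pfp = (count / (2 * B)) / rank_pos
        return p, pfp, rank_pos

    p_up, pfp_up, rank_up = _p_pfp(rp_up)
    p_down, pfp_down, rank_down = _p_pfp(rp_down)
    mean_diff = X[:, case].mean(axis=1) - X[:, ctrl].mean(axis=1)

    table = pd.DataFrame(
        {
            "RP_up": rp_up, "rank_up": rank_up, "p_up": p_up, "pfp_up": pfp_up,
            "RP_down": rp_down, "rank_down": rank_down,
            "p_down": p_down, "pfp_down": pfp_down,
            "mean_log2_diff": mean_diff,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEResult(condition, table, n_comparisons=K, n_permutations=B,
                    warnings=warnings)


def call_de(result: DEResult, pfp_threshold: float = 0.05) -> GeneSignature:
    """Call DE genes at a pfp threshold, split by direction.

    A gene is "up" if pfp_up < threshold, "down" if pfp_down < threshold.
    The pathological case of a gene passing both is excluded and logged.
    """
    tab = result.table
    up = tab.index[tab["pfp_up"] < pfp_threshold]
    down = tab.index[tab["pfp_down"] < pfp_threshold]
    both = set(up) & set(down)
    if both:
        log.warning(
            "%s: %d genes pass pfp<%g in both directions; excluded",
            result.condition, len(both), pfp_threshold,
        )
    entries = {g: "up" for g in up if g not in both}
    entries.update({g: "down" for g in down if g not in both})
    return GeneSignature(result.condition, entries, provenance="discovery")
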