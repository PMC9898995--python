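"""Single-sample gene-set enrichment scoring and the permutation-null validation.

For one sample, genes are ordered by decreasing expression (ties broken by
symbol) and assigned ranks r = N, N-1, ..., 1.  Walking down that ordering the
score accumulates the difference between the weighted in-set empirical CDF
(weights r^alpha, normalized by the in-set total) and the uniform out-of-set
CDF.  Summing the running difference over all N positions collapses to the
closed form

    score = sum_{g in S} r_g^(1+alpha) / sum_{g in S} r_g^alpha
            - sum_{g not in S} r_g / (N - |S|)

because rank r_g equals the number of positions whose running sum includes
gene g.  The closed form makes scoring a matrix product over many gene sets,
which is what the 1000-set permutation null needs.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SignatureCollection

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SsgseaProfile:
    """Per-sample enrichment scores of one gene set."""

    name: str
    scores: pd.Series  # indexed by sample id
    alpha: float


def _rank_matrix(data: pd.DataFrame) -> np.ndarray:
    """Per-sample ranks r in {N..1} by decreasing expression, ties by symbol."""
    n_genes = data.shape[0]
    genes = np.asarray(data.index)
    name_order = np.argsort(genes, kind="stable")
    ranks = np.empty(data.shape, dtype=float)
    values = data.to_numpy()
    for j in range(data.shape[1]):
        # sort by (-value, symbol): lexsort with primary key last
        order = name_order[np.argsort(-values[name_order, j], kind="stable")]
        ranks[order, j] = np.arange(n_genes, 0, -1)
    return ranks


def _score_membership(ranks: np.ndarray, membership: np.ndarray, alpha: float) -> np.ndarray:
    """Scores for boolean membership rows (sets x genes) against rank columns."""
    n_genes = ranks.shape[0]
    r_alpha = ranks ** alpha
    r_alpha1 = ranks ** (1.0 + alpha)
    total_rank = n_genes * (n_genes + 1) / 2.0
    z = membership.astype(float)
    m = z.sum(axis=1, keepdims=True)
    num = z @ r_alpha1
    den = z @ r_alpha
    out_mean = (total_rank - z @ ranks) / (n_genes - m)
    return num / den - out_mean


def ssgsea_score(sample_expression, gene_set, alpha: float = 0.25) -> float:
    """ssGSEA score of one gene set in one sample.

    ``sample_expression`` maps gene symbol -> expression (dict or Series).
    The set must intersect the measured genes and must not cover all of them.
    """
    expr = pd.Series(sample_expression, dtype=float)
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError("gene set does not intersect the measured genes")
    if len(set(present)) >= expr.size:
        raise ValueError("gene set covers every measured gene; out-of-set CDF undefined")
    ranks = _rank_matrix(expr.to_frame("s"))
    member = np.isin(np.asarray(expr.index), present)[None, :]
    return float(_score_membership(ranks, member, alpha)[0, 0])


def ssgsea_matrix(
    matrix: ExpressionMatrix,
    sets: SignatureCollection,
    alpha: float = 0.25,
) -> list[SsgseaProfile]:
    """Score every set of a collection in every sample of a matrix.

    Set genes absent from the matrix are dropped (count logged); a set losing
    all its genes is skipped with a warning.
    """
    ranks = _rank_matrix(matrix.data)
    gene_index = {g: i for i, g in enumerate(matrix.data.index)}
    profiles: list[SsgseaProfile] = []
    rows = []
    names = []
    for name in sets:
        genes = sets[name]
        present = [g for g in genes if g in gene_index]
        dropped = len(genes) - len(present)
        if dropped:
            logger.info("set %s: %d/%d genes absent from matrix", name, dropped, len(genes))
        if not present:
            warnings.warn(f"gene set {name!r} has no genes in the matrix; skipped")
            continue
        if len(present) >= matrix.n_genes:
            warnings.warn(f"gene set {name!r} covers all measured genes; skipped")
            continue
        row = np.zeros(matrix.n_genes, dtype=bool)
        row[[gene_index[g] for g in present]] = True
        rows.append(row)
        names.append(name)
    if rows:
        scores = _score_membership(ranks, np.asarray(rows), alpha)
        for name, row in zip(names, scores):
            profiles.append(
                SsgseaProfile(name=name, scores=pd.Series(row, index=matrix.samples), alpha=alpha)
            )
    return profiles


def ssgsea_single_set(matrix: ExpressionMatrix, gene_set, alpha: float = 0.25) -> pd.Series:
    """Convenience: per-sample scores of one gene list."""
    coll = SignatureCollection(sets={"set": list(dict.fromkeys(gene_set))})
    profiles = ssgsea_matrix(matrix, coll, alpha=alpha)
    if not profiles:
        raise ValueError("gene set could not be scored on this matrix")
    return profiles[0].scores


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have n <= 8 and there are no ties;
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclasses.dataclass
class PermutationReport:
    """Observed signature effect against a random same-size gene-set null."""

    observed_mean_diff: float
    observed_p: float
    background: list  # n_perm (mean_diff, wilcoxon_p) pairs
    empirical_p: float
    n_perm: int
    signature_size: int


def permutation_null(
    matrix: ExpressionMatrix,
    signature,
    n_perm: int = 1000,
    alpha: float = 0.25,
    seed: int = 0,
    case_label: str = "LN",
    control_label: str = "control",
) -> PermutationReport:
    """Validate a signature's case-control ssGSEA separation against random sets.

    Random same-size gene sets are drawn uniformly without replacement from the
    matrix's gene universe; each is ssGSEA-scored and its case-minus-control
    mean difference recorded.  ``empirical_p`` uses the add-one convention
    (1 + #{background >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = np.asarray(matrix.data.index)
    present = [g for g in signature if g in set(matrix.genes)]
    if not present or len(present) >= matrix.n_genes:
        raise ValueError("signature invalid for ssGSEA on this matrix")
    case_idx = [matrix.samples.index(s) for s in matrix.samples_in_group(case_label)]
    ctrl_idx = [matrix.samples.index(s) for s in matrix.samples_in_group(control_label)]
    if not case_idx or not ctrl_idx:
        raise ValueError("case/control labels missing from matrix")

    ranks = _rank_matrix(matrix.data)
    gene_pos = {g: i for i, g in enumerate(genes)}
    obs_row = np.zeros(matrix.n_genes, dtype=bool)
    obs_row[[gene_pos[g] for g in present]] = True
    obs_scores = _score_membership(ranks, obs_row[None, :], alpha)[0]
    obs_diff = float(obs_scores[case_idx].mean() - obs_scores[ctrl_idx].mean())
    _, obs_p = wilcoxon_rank_sum(obs_scores[case_idx], obs_scores[ctrl_idx])

    rng = np.random.default_rng(seed)
    member = np.zeros((n_perm, matrix.n_genes), dtype=bool)
    for i in range(n_perm):
        member[i, rng.choice(matrix.n_genes, size=len(present), replace=False)] = True
    bg_scores = _score_membership(ranks, member, alpha)
    bg_diff = bg_scores[:, case_idx].mean(axis=1) - bg_scores[:, ctrl_idx].mean(axis=1)
    background = []
    for i in range(n_perm):
        _, p = wilcoxon_rank_sum(bg_scores[i, case_idx], bg_scores[i, ctrl_idx])
        background.append((float(bg_diff[i]), float(p)))
    empirical_p = (1 + int(np.sum(bg_diff >= obs_diff))) / (n_perm + 1)
    return PermutationReport(
        observed_mean_diff=obs_diff,
        observed_p=float(obs_p),
        background=background,
        empirical_p=float(empirical_p),
        n_perm=n_perm,
        signature_size=len(present),
    )


def signed_logp(p: float, higher_in_case: bool) -> float:
    """-log10(p), signed by the direction of regulation (case-higher positive)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p == 0:
        warnings.warn("p = 0; signed log-p capped at 308")
        value = 308.0
    else:
        value = -np.log10(p)
    return float(value if higher_in_case else -value)


def immune_correlation(
    matrix: ExpressionMatrix,
    immune_sets: SignatureCollection,
    target_gene: str,
    alpha: float = 0.25,
) -> dict:
    """Spearman rho between each immune set's ssGSEA profile and a gene's expression."""
    from .clustering import spearman_rho

    if target_gene not in matrix.data.index:
        raise ValueError(f"target gene {target_gene!r} not in matrix")
    target = matrix.data.loc[target_gene].to_numpy()
    if np.allclose(target, target[0]):
        warnings.warn(f"{target_gene} has constant expression; correlations undefined")
        return {name: float("nan") for name in immune_sets}
    out = {}
    for profile in ssgsea_matrix(matrix, immune_sets, alpha=alpha):
        out[profile.name] = spearman_rho(profile.scores.to_numpy(), target)
    return out
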