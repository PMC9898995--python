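"""Two-group differential expression with empirical-Bayes moderated t-statistics.

The moderated statistic shrinks per-gene sample variances toward a common prior
estimated by method of moments on the log sample variances.  Writing s2_g for
the pooled two-group variance of gene g on d residual degrees of freedom, the
model is s2_g | sigma2_g ~ sigma2_g * chi2_d / d with an inverse-chi-square
prior sigma2_g ~ s0^2 * d0 / chi2_{d0}.  The hyperparameters (d0, s0^2) solve

    mean(e_g)            = log(s0^2) + psi(d0/2) - log(d0/2)
    var(e_g) - psi'(d/2) = psi'(d0/2)

where e_g = log(s2_g) - psi(d/2) + log(d/2) and psi, psi' are the digamma and
trigamma functions.  The posterior variance is the precision-weighted blend
(d0*s0^2 + d*s2_g)/(d0 + d) and the moderated t is referred to a t
distribution on d + d0 degrees of freedom.  Setting the prior df to zero
recovers the ordinary pooled-variance two-sample t-test exactly.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import special, stats

from .clustering import spearman_rho
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class DEGResult:
    gene: str
    logfc: float
    t_mod: float
    p: float
    q: float
    direction: str  # "up" | "down"


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior df d0, prior variance s0^2)."""
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1)) if n > 1 else 0.0
    e_var -= float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


def moderated_t_test(
    matrix: ExpressionMatrix,
    case_label: str,
    control_label: str,
    prior_df: float | None = None,
) -> list[DEGResult]:
    """Moderated two-group t-test per gene, with BH-adjusted q-values.

    ``logfc`` is mean(case) - mean(control) on the (log2) input scale.
    ``prior_df`` overrides the estimated prior degrees of freedom; 0 gives the
    ordinary pooled-variance t-test.
    """
    case = matrix.values_for(case_label).to_numpy()
    ctrl = matrix.values_for(control_label).to_numpy()
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    df = float(n1 + n2 - 2)
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    zero = s2 <= 0
    if zero.any():
        positive = s2[~zero]
        floor = positive.min() if positive.size else 1e-8
        warnings.warn(f"{int(zero.sum())} zero-variance genes; variance floored")
        s2 = np.where(zero, floor, s2)

    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.exp(np.mean(np.log(s2)))) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        total_df = np.inf
    elif d0 == 0:
        s2_post = s2
        total_df = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = df + d0

    logfc = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = logfc / se
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=total_df)
    q = bh_adjust(p)
    return [
        DEGResult(
            gene=g,
            logfc=float(fc),
            t_mod=float(ti),
            p=float(pi),
            q=float(qi),
            direction="up" if fc >= 0 else "down",
        )
        for g, fc, ti, pi, qi in zip(matrix.genes, logfc, t, p, q)
    ]


def significant_degs(results: list[DEGResult], alpha: float = 0.05) -> list[DEGResult]:
    """DEGs at BH q < alpha (no logFC threshold)."""
    return [r for r in results if r.q < alpha]


def deg_table(results: list[DEGResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
    ).set_index("gene")


@dataclasses.dataclass
class VennSummary:
    """Region counts for a multi-set DEG intersection."""

    set_sizes: dict
    pairwise: dict          # frozenset({a, b}) -> |A ∩ B|
    common: list            # genes in the full intersection (sorted)

    @property
    def n_common(self) -> int:
        return len(self.common)


def intersect_deg_sets(named_sets: dict) -> VennSummary:
    """Per-set sizes, pairwise intersections and the full-intersection gene list."""
    if not named_sets or len(named_sets) < 2:
        raise ValueError("need at least two named gene sets")
    sets = {name: set(genes) for name, genes in named_sets.items()}
    names = list(sets)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[frozenset((a, b))] = len(sets[a] & sets[b])
    common: set = set.intersection(*sets.values())
    return VennSummary(
        set_sizes={n: len(s) for n, s in sets.items()},
        pairwise=pairwise,
        common=sorted(common),
    )


def logfc_concordance(a: list[DEGResult], b: list[DEGResult]) -> float:
    """Spearman rho between log-fold-changes on the shared-gene intersection."""
    fa = {r.gene: r.logfc for r in a}
    fb = {r.gene: r.logfc for r in b}
    shared = [g for g in fa if g in fb]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    return spearman_rho([fa[g] for g in shared], [fb[g] for g in shared])


def flag_mislabeled_samples(matrix: ExpressionMatrix, deg_genes) -> list:
    """Samples whose label contradicts their expression cluster.

    Samples are clustered on DEG-gene expression (average linkage on
    1 - Pearson correlation), cut into two clusters; each cluster takes its
    majority label and samples disagreeing with their cluster's majority are
    returned.
    """
    genes = [g for g in deg_genes if g in matrix.data.index]
    if len(genes) < 10:
        raise ValueError("need >= 10 DEG genes present in the matrix")
    if len(set(matrix.labels.values())) < 2:
        raise ValueError("both group labels must be present")
    x = matrix.data.loc[genes].to_numpy().T  # samples x genes
    corr = np.corrcoef(x)
    dist = ssd.squareform(1.0 - corr, checks=False)
    link = sch.linkage(dist, method="average")
    assign = sch.fcluster(link, t=2, criterion="maxclust")
    samples = matrix.samples
    if len(set(assign)) < 2:
        warnings.warn("all samples fell into one cluster; nothing flagged")
        return []
    flagged = []
    majority = {}
    for c in set(assign):
        members = [s for s, a in zip(samples, assign) if a == c]
        labels = [matrix.labels[s] for s in members]
        majority[c] = max(set(labels), key=labels.count)
    if len(set(majority.values())) == 1:
        warnings.warn("both clusters share the same majority label")
    for s, a in zip(samples, assign):
        if matrix.labels[s] != majority[a]:
            flagged.append(s)
    if len(flagged) > 0.25 * len(samples):
        warnings.warn(
            f"{len(flagged)}/{len(samples)} samples contradict their cluster; "
            "labels may be unrelated to expression"
        )
    return flagged
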