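"""Per-cluster treatment-response models: SMOTE-balanced, cross-validated LASSO.

For each disease-defining cluster, features are restricted to the cluster's
panel genes, the cohort is split 8:2 with stratification, the minority class of
the training set is oversampled to balance (Chawla-style SMOTE), and an
L1-penalized logistic regression is tuned over a decreasing lambda path by
ten-fold cross-validated binomial deviance.  Models are scored by ROC AUC
(Mann-Whitney estimator) with DeLong confidence intervals on the training,
held-out and entire sets, and by confusion-matrix metrics on an external
validation cohort.  The positive class is "responder" throughout.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .clustering import DdcModel
from .config import RunConfig
from .diffexpr import DEGResult
from .hubs import HubScoreTable, all_centralities, top_k_aggregate
from .io import ExpressionMatrix, GeneNetwork

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "responder"
NEGATIVE_LABEL = "non-responder"


@dataclasses.dataclass
class ResponseCohort:
    """A panel expression matrix with binary responder / non-responder labels."""

    matrix: ExpressionMatrix
    timepoint: str = "at_flare"

    def __post_init__(self) -> None:
        observed = set(self.matrix.labels.values())
        if observed != {POSITIVE_LABEL, NEGATIVE_LABEL}:
            raise ValueError(
                f"labels must be exactly {{{POSITIVE_LABEL!r}, {NEGATIVE_LABEL!r}}}; "
                f"got {sorted(observed)}"
            )

    @property
    def samples(self) -> list:
        return self.matrix.samples

    def y(self, sample_ids=None) -> np.ndarray:
        ids = self.matrix.samples if sample_ids is None else list(sample_ids)
        return np.array([1 if self.matrix.labels[s] == POSITIVE_LABEL else 0 for s in ids])

    def features(self, genes, sample_ids=None) -> np.ndarray:
        ids = self.matrix.samples if sample_ids is None else list(sample_ids)
        return self.matrix.data.loc[list(genes), ids].to_numpy().T  # samples x genes


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def response_deg_overlap(
    response_degs: list[DEGResult],
    ddc: DdcModel,
    logfc_threshold: float = 1.0,
) -> dict:
    """Per-cluster share of threshold-passing response DEGs, and the fraction
    of those DEGs that are up-regulated in non-responders.

    ``response_degs`` must come from a non-responder (case) vs responder
    (control) contrast, so direction "up" reads "up in non-responders".
    """
    passing = [
        r for r in response_degs
        if abs(r.logfc) >= logfc_threshold and r.gene in ddc.assignment
    ]
    out = {c: (0.0, 0.0) for c in ddc.cluster_ids}
    if not passing:
        warnings.warn("no response DEG passes the |logFC| threshold")
        return out
    total = len(passing)
    for c in ddc.cluster_ids:
        members = [r for r in passing if ddc.assignment[r.gene] == c]
        if not members:
            continue
        frac = len(members) / total
        frac_up = sum(r.direction == "up" for r in members) / len(members)
        out[c] = (frac, frac_up)
    return out


def split_train_test(
    cohort: ResponseCohort, ratio: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Stratified random split of sample ids, preserving class proportions."""
    y = cohort.y()
    if min(np.bincount(y, minlength=2)) < 5:
        raise ValueError("need at least 5 samples per class")
    train, test = train_test_split(
        cohort.samples,
        train_size=ratio,
        stratify=y,
        random_state=int(seed) % (2**32 - 1),
    )
    for part, name in ((train, "train"), (test, "test")):
        labels = {cohort.matrix.labels[s] for s in part}
        if len(labels) < 2:
            raise ValueError(f"{name} split lost a class; adjust the ratio")
    return list(train), list(test)


def smote(
    features: np.ndarray, labels: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Chawla-style SMOTE to a 1:1 class balance.

    Each synthetic sample interpolates between a random minority sample and
    one of its k nearest minority neighbors (Euclidean), with a single
    uniform interpolation weight per synthetic vector.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_needed = int(n_maj - n_min)
    if n_needed == 0:
        return features, labels
    if n_min < 2:
        raise ValueError("need at least 2 minority samples for SMOTE")
    if n_min <= k:
        warnings.warn(f"minority count {n_min} <= k={k}; k reduced to {n_min - 1}")
        k = n_min - 1
    x_min = features[labels == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    _, nbr_idx = nn.kneighbors(x_min)  # first neighbor is the point itself
    rng = np.random.default_rng(seed)
    synthetic = np.empty((n_needed, features.shape[1]))
    for i in range(n_needed):
        base = rng.integers(n_min)
        nbr = nbr_idx[base, 1 + rng.integers(k)]
        u = rng.random()
        synthetic[i] = x_min[base] + u * (x_min[nbr] - x_min[base])
    out_x = np.vstack([features, synthetic])
    out_y = np.concatenate([labels, np.full(n_needed, minority, dtype=labels.dtype)])
    return out_x, out_y


@dataclasses.dataclass
class LassoFit:
    """An L1 logistic path with cross-validated deviance and the chosen fit."""

    gene_names: list
    lambda_path: np.ndarray
    cv_deviance: np.ndarray      # mean held-out binomial deviance per lambda
    cv_deviance_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    selected_genes: list         # genes with non-zero coefficients at the chosen lambda
    coefficients: dict           # gene -> coefficient on the ORIGINAL feature scale
    intercept: float
    model: LogisticRegression    # fitted at the chosen lambda (standardized space)
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = (np.asarray(features, dtype=float) - self.feature_mean) / self.feature_sd
        return self.model.predict_proba(z)[:, 1]


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _path_fits(z: np.ndarray, y: np.ndarray, path: np.ndarray, tol: float = 1e-4):
    """Warm-started L1 fits down a decreasing lambda path; yields one clf per lambda."""
    clf = LogisticRegression(
        penalty="l1", C=1.0, solver="saga", warm_start=True, max_iter=2000, tol=tol,
        random_state=0,
    )
    n = z.shape[0]
    for lam in path:
        clf.C = 1.0 / (n * lam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(z, y)
        yield clf


def lasso_cv(
    features: np.ndarray,
    labels: np.ndarray,
    gene_names: list,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 40,
    lambda_min_ratio: float = 0.01,
    rule: str = "min",
) -> LassoFit:
    """L1 logistic regression over a decreasing lambda path, tuned by CV deviance.

    Features are standardized internally; coefficients are reported on the
    original scale.  ``rule`` is "min" (deviance-minimizing lambda) or "1se".
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = x.shape[0]
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError("need at least `folds` samples per class")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    lam_max = float(np.max(np.abs(z.T @ (y - y.mean()))) / n)
    lam_max = max(lam_max, 1e-4)
    path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(seed) % (2**32 - 1))
    dev = np.zeros((folds, n_lambda))
    for f, (tr, te) in enumerate(skf.split(z, y)):
        for j, clf in enumerate(_path_fits(z[tr], y[tr], path)):
            dev[f, j] = _binomial_deviance(y[te], clf.predict_proba(z[te])[:, 1])
    dev_mean = dev.mean(axis=0)
    dev_se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    j_min = int(np.argmin(dev_mean))
    lam_min = float(path[j_min])
    within = dev_mean <= dev_mean[j_min] + dev_se[j_min]
    lam_1se = float(path[np.argmax(within)])  # largest lambda within one SE

    lam_star = lam_min if rule == "min" else lam_1se
    j_star = int(np.argmin(np.abs(path - lam_star)))
    for final in _path_fits(z, y, path[: j_star + 1], tol=1e-6):
        pass
    coef_std = final.coef_[0]
    coef_orig = coef_std / sd
    intercept = float(final.intercept_[0] - np.sum(coef_std * mu / sd))
    selected = [g for g, c in zip(gene_names, coef_std) if c != 0.0]
    return LassoFit(
        gene_names=list(gene_names),
        lambda_path=path,
        cv_deviance=dev_mean,
        cv_deviance_se=dev_se,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        selected_genes=selected,
        coefficients={g: float(c) for g, c in zip(gene_names, coef_orig) if c != 0.0},
        intercept=intercept,
        model=final,
        feature_mean=mu,
        feature_sd=sd,
    )


def rank_selected_genes(
    g: GeneNetwork,
    selected,
    k: int = 10,
    seed: int = 0,
    epc_iters: int = 100,
    epsilon: float = 1.7,
    response_degs: list | None = None,
    min_methods: int = 4,
) -> HubScoreTable:
    """Hub re-ranking of LASSO-selected genes on their induced subnetwork.

    Genes are flagged as top-regulatory when they appear in at least
    ``min_methods`` of the five top-k lists AND are response DEGs.
    """
    nodes = [v for v in selected if v in g]
    sub = g.subgraph(nodes)
    if sub.number_of_nodes() == 0 or sub.number_of_edges() == 0:
        raise ValueError("induced subgraph of the selected genes is empty")
    tables = all_centralities(sub, epc_iters=epc_iters, seed=seed, epsilon=epsilon)
    agg = top_k_aggregate(tables, k=k, min_degree=0)
    if response_degs is not None:
        deg_genes = {r.gene for r in response_degs}
        agg.flagged = [
            v for v in agg.table.index
            if agg.table.at[v, "selected_count"] >= min_methods and v in deg_genes
        ]
        if not agg.flagged:
            warnings.warn("no selected gene is both high-rank and a response DEG")
    return agg


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC estimator; ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_ci_delong(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong (structural-components) Wald interval for the AUC, clipped to [0,1].

    Perfect separation has zero component variance; the interval degenerates to
    (AUC, AUC) with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = pos.size, neg.size
    if m < 2 or n < 2:
        raise ValueError("need at least 2 samples per class")
    # psi(x, y) = 1 if x > y, 0.5 if tied, else 0; structural components
    cmp_matrix = (pos[:, None] > neg[None, :]).astype(float)
    cmp_matrix += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp_matrix.mean())
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    var = s10 / m + s01 / n
    if var <= 0:
        warnings.warn("zero DeLong variance (perfect separation); degenerate interval")
        return auc, auc
    zq = stats.norm.ppf(0.5 + level / 2.0)
    half = zq * np.sqrt(var)
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


@dataclasses.dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float


def classification_metrics(predicted, labels) -> ConfusionMetrics:
    """Confusion matrix and accuracy/precision/recall/F1 (positive = responder)."""
    pred = np.asarray(predicted, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.size != y.size:
        raise ValueError("predicted and labels must have equal length")
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = (tp + tn) / y.size
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision undefined")
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan") if np.isnan(precision) or np.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ConfusionMetrics(tp, fp, tn, fn, float(accuracy), float(precision),
                            float(recall), float(f1))


@dataclasses.dataclass
class ModelReport:
    """Evaluation of one cluster's response model."""

    cluster: int
    n_genes: int
    selected_genes: list
    coefficients: dict
    intercept: float
    lambda_min: float
    auc_train: float
    ci_train: tuple
    auc_test: float
    ci_test: tuple
    auc_all: float
    ci_all: tuple
    validation: ConfusionMetrics | None
    seed: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# the per-cluster pipeline
# ---------------------------------------------------------------------------

def _fit_one_cluster(
    cohort: ResponseCohort,
    validation: ResponseCohort | None,
    genes: list,
    cluster_id: int,
    cfg: RunConfig,
    seed: int,
) -> ModelReport:
    train_ids, test_ids = split_train_test(cohort, ratio=cfg.split_ratio, seed=seed)
    assert not set(train_ids) & set(test_ids)
    x_train = cohort.features(genes, train_ids)
    y_train = cohort.y(train_ids)
    x_bal, y_bal = smote(x_train, y_train, k=cfg.smote_k, seed=seed)
    fit = lasso_cv(
        x_bal, y_bal, genes, folds=cfg.cv_folds, seed=seed,
    )
    p_train = fit.predict_proba(x_bal)
    p_test = fit.predict_proba(cohort.features(genes, test_ids))
    p_all = fit.predict_proba(cohort.features(genes))
    y_test = cohort.y(test_ids)
    y_all = cohort.y()

    report = ModelReport(
        cluster=cluster_id,
        n_genes=len(genes),
        selected_genes=fit.selected_genes,
        coefficients=fit.coefficients,
        intercept=fit.intercept,
        lambda_min=fit.lambda_min,
        auc_train=roc_auc(p_train, y_bal),
        ci_train=auc_ci_delong(p_train, y_bal),
        auc_test=roc_auc(p_test, y_test),
        ci_test=auc_ci_delong(p_test, y_test),
        auc_all=roc_auc(p_all, y_all),
        ci_all=auc_ci_delong(p_all, y_all),
        validation=None,
        seed=seed,
    )
    if validation is not None:
        shared = [g for g in genes if g in validation.matrix.data.index]
        if len(shared) != len(genes):
            raise ValueError(
                f"validation cohort is missing {len(genes) - len(shared)} cluster genes"
            )
        p_val = fit.predict_proba(validation.features(genes))
        report.validation = classification_metrics((p_val >= 0.5).astype(int),
                                                   validation.y())
    return report


def run_per_cluster_models(
    cohort: ResponseCohort,
    validation: ResponseCohort | None,
    ddc: DdcModel,
    cfg: RunConfig | None = None,
    seed: int | None = None,
) -> list[ModelReport]:
    """Fit and evaluate one response model per disease-defining cluster.

    Reports are sorted by descending held-out (test) AUC.  Clusters with fewer
    than two genes present in the cohort are skipped with a warning.
    """
    cfg = cfg or RunConfig()
    seed = cfg.seed if seed is None else seed
    reports = []
    for cid in ddc.cluster_ids:
        genes = [g for g in ddc.genes_in_cluster(cid) if g in cohort.matrix.data.index]
        if len(genes) < 2:
            warnings.warn(f"cluster {cid}: fewer than 2 genes in cohort; skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports.append(_fit_one_cluster(cohort, validation, genes, cid, cfg, seed))
        logger.info("cluster %d: test AUC %.3f (%d genes selected)",
                    cid, reports[-1].auc_test, len(reports[-1].selected_genes))
    reports.sort(key=lambda r: -r.auc_test)
    return reports


def summary_table(reports: list[ModelReport]) -> pd.DataFrame:
    """Tables S3/S4-shaped summary: one row per cluster model."""
    rows = []
    for r in reports:
        row = {
            "cluster": r.cluster,
            "n_genes": r.n_genes,
            "n_selected": len(r.selected_genes),
            "auc_train": r.auc_train,
            "ci_train_low": r.ci_train[0], "ci_train_high": r.ci_train[1],
            "auc_test": r.auc_test,
            "ci_test_low": r.ci_test[0], "ci_test_high": r.ci_test[1],
            "auc_all": r.auc_all,
            "ci_all_low": r.ci_all[0], "ci_all_high": r.ci_all[1],
        }
        if r.validation is not None:
            row.update(
                accuracy=r.validation.accuracy, precision=r.validation.precision,
                recall=r.validation.recall, f1=r.validation.f1,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------

class ClusterResponseModel:
    """Per-cluster response prediction as a fit-once modelling object.

    Parameters mirror :func:`run_per_cluster_models`; ``fit`` returns a
    :class:`ClusterResponseResults` carrying the per-cluster reports.
    """

    def __init__(
        self,
        cohort: ResponseCohort,
        ddc: DdcModel,
        validation: ResponseCohort | None = None,
        network: GeneNetwork | None = None,
        config: RunConfig | None = None,
    ):
        self.cohort = cohort
        self.ddc = ddc
        self.validation = validation
        self.network = network
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        labels: dict,
        assignment: dict,
        dataset_id: str = "cohort",
        **kwargs,
    ) -> "ClusterResponseModel":
        """Build from a genes x samples DataFrame, a label map and a gene ->
        cluster assignment."""
        matrix = ExpressionMatrix(dataset_id, "panel", data, labels)
        cohort = ResponseCohort(matrix)
        k = max(assignment.values())
        ddc = DdcModel(
            k=k, assignment=dict(assignment), centroids=np.empty((0, 0)),
            total_wss=float("nan"), wss_curve={}, chosen_k=k, seed=0,
        )
        return cls(cohort, ddc, **kwargs)

    def fit(self, seed: int | None = None) -> "ClusterResponseResults":
        reports = run_per_cluster_models(
            self.cohort, self.validation, self.ddc, self.config, seed=seed
        )
        return ClusterResponseResults(self, reports)


class ClusterResponseResults:
    """Fitted per-cluster models with their evaluation metrics."""

    def __init__(self, model: ClusterResponseModel, reports: list[ModelReport]):
        self.model = model
        self.reports = reports

    @property
    def best(self) -> ModelReport:
        return self.reports[0]

    def summary(self) -> str:
        table = summary_table(self.reports)
        lines = [
            "Per-cluster treatment-response models (sorted by test AUC)",
            "=" * 60,
            table.round(3).to_string(),
            "",
            f"Best cluster: {self.best.cluster} "
            f"(test AUC {self.best.auc_test:.3f}, "
            f"{len(self.best.selected_genes)} genes selected)",
        ]
        return "\n".join(lines)
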