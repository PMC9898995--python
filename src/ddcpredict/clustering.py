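"""Disease-defining clusters: correlation projection of signature activity onto a
targeted gene panel, followed by K-means with a second-elbow rule for k.

Each retained dataset contributes one column of Spearman correlations between
the per-sample ssGSEA activity of the signature and the expression of each
panel gene; rows (panel genes) are the observations K-means clusters.  A
dataset missing more than ``max_missing`` signature genes is excluded outright,
mirroring the rule that removed a blood cohort with six missing genes.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .io import ExpressionMatrix
from .ssgsea import ssgsea_single_set

logger = logging.getLogger(__name__)


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks (ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclasses.dataclass
class CorrelationProfile:
    """Panel-gene x dataset matrix of rho against signature activity."""

    rho: pd.DataFrame            # rows: panel genes; columns: dataset ids; NaN = missing
    excluded_datasets: dict      # dataset id -> reason

    @property
    def genes(self) -> list:
        return list(self.rho.index)

    @property
    def datasets(self) -> list:
        return list(self.rho.columns)

    def imputed(self) -> pd.DataFrame:
        """Row-mean imputation of missing rho entries (for clustering)."""
        filled = self.rho.apply(lambda row: row.fillna(row.mean()), axis=1)
        if filled.isna().any().any():
            raise ValueError("panel genes with no rho in any retained dataset")
        return filled


def build_correlation_profile(
    panel_sets: list[ExpressionMatrix],
    signature,
    panel_genes,
    alpha: float = 0.25,
    max_missing: int = 5,
) -> CorrelationProfile:
    """One rho column per retained dataset: signature ssGSEA vs each panel gene.

    A dataset missing more than ``max_missing`` signature genes is excluded and
    the reason recorded.  Panel genes absent from a retained dataset (or with
    constant expression) get NaN entries, row-mean imputed at clustering time.
    """
    if not panel_sets:
        raise ValueError("need at least one panel dataset")
    signature = list(dict.fromkeys(signature))
    panel_genes = list(dict.fromkeys(panel_genes))
    columns = {}
    excluded = {}
    for ds in panel_sets:
        if ds.n_samples < 4:
            raise ValueError(f"dataset {ds.dataset_id}: need >= 4 samples")
        missing = [g for g in signature if g not in ds.data.index]
        if len(missing) > max_missing:
            reason = f"{len(missing)} missing signature genes (> {max_missing})"
            excluded[ds.dataset_id] = reason
            logger.info("excluding %s: %s", ds.dataset_id, reason)
            continue
        scores = ssgsea_single_set(ds, [g for g in signature if g in ds.data.index], alpha=alpha)
        col = {}
        for g in panel_genes:
            if g not in ds.data.index:
                col[g] = np.nan
                continue
            expr = ds.data.loc[g].to_numpy()
            try:
                col[g] = spearman_rho(scores.to_numpy(), expr)
            except ValueError:
                warnings.warn(f"{ds.dataset_id}: gene {g} constant; rho set to NaN")
                col[g] = np.nan
        columns[ds.dataset_id] = col
    if not columns:
        raise ValueError("all panel datasets were excluded")
    rho = pd.DataFrame(columns, index=panel_genes, dtype=float)
    return CorrelationProfile(rho=rho, excluded_datasets=excluded)


@dataclasses.dataclass
class DdcModel:
    """Fitted K-means partition of panel genes into disease-defining clusters."""

    k: int
    assignment: dict             # gene -> cluster id, 1..k
    centroids: np.ndarray
    total_wss: float
    wss_curve: dict              # k -> total within-cluster sum of squares
    chosen_k: int
    seed: int

    def genes_in_cluster(self, cluster_id: int) -> list:
        return [g for g, c in self.assignment.items() if c == cluster_id]

    @property
    def cluster_ids(self) -> list:
        return sorted(set(self.assignment.values()))

    def assignment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.assignment), "cluster": list(self.assignment.values())}
        ).set_index("gene")


def _fit_kmeans(x: np.ndarray, k: int, seed: int, n_restarts: int) -> KMeans:
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=int(seed) % (2**32 - 1))
    km.fit(x)
    return km


def kmeans_cluster(
    profile: CorrelationProfile,
    k: int,
    seed: int = 0,
    n_restarts: int = 25,
    standardize: bool = False,
) -> DdcModel:
    """Lloyd's algorithm with k-means++ seeding, best of ``n_restarts`` by WSS."""
    x = profile.imputed().to_numpy()
    if not 2 <= k <= x.shape[0]:
        raise ValueError("k must lie in [2, number of profiled genes]")
    if standardize:
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=1, keepdims=True)) / sd
    km = _fit_kmeans(x, k, seed, n_restarts)
    assignment = {g: int(c) + 1 for g, c in zip(profile.genes, km.labels_)}
    return DdcModel(
        k=k,
        assignment=assignment,
        centroids=km.cluster_centers_,
        total_wss=float(km.inertia_),
        wss_curve={k: float(km.inertia_)},
        chosen_k=k,
        seed=seed,
    )


def wss_curve(
    profile: CorrelationProfile,
    k_max: int = 15,
    seed: int = 0,
    n_restarts: int = 25,
) -> dict:
    """Total within-cluster sum of squares for k = 1 .. k_max."""
    x = profile.imputed().to_numpy()
    k_max = min(k_max, x.shape[0])
    curve = {1: float(((x - x.mean(axis=0)) ** 2).sum())}
    for k in range(2, k_max + 1):
        curve[k] = float(_fit_kmeans(x, k, seed, n_restarts).inertia_)
    return curve


def elbow_select(wss: dict, which_elbow: int = 2) -> int:
    """Pick k at the ``which_elbow``-th elbow of a WSS curve.

    Elbows are local maxima of the discrete second difference
    WSS(k-1) + WSS(k+1) - 2 WSS(k) (positive curvature), in increasing k.
    If fewer elbows exist, the last one is returned with a warning.
    """
    if which_elbow < 1:
        raise ValueError("which_elbow must be >= 1")
    ks = sorted(wss)
    if len(ks) < 5 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a consecutive-k WSS curve of length >= 5")
    vals = np.array([wss[k] for k in ks], dtype=float)
    rel_increase = np.diff(vals) > 1e-6 * np.abs(vals[:-1])
    if rel_increase.any():
        raise ValueError("WSS curve is not non-increasing; check the k-means fits")
    curv = vals[:-2] + vals[2:] - 2.0 * vals[1:-1]  # curvature at ks[1:-1]
    elbows = []
    for i in range(curv.size):
        left_ok = i == 0 or curv[i] > curv[i - 1]
        right_ok = i == curv.size - 1 or curv[i] >= curv[i + 1]
        if curv[i] > 0 and left_ok and right_ok:
            elbows.append(ks[i + 1])
    if not elbows:
        raise ValueError("no elbow found in the WSS curve")
    if which_elbow > len(elbows):
        warnings.warn(
            f"only {len(elbows)} elbow(s) found; returning the last one"
        )
        return elbows[-1]
    return elbows[which_elbow - 1]


def fit_ddc(
    profile: CorrelationProfile,
    k: int | str = 8,
    seed: int = 0,
    n_restarts: int = 25,
    k_max: int = 15,
    which_elbow: int = 2,
) -> DdcModel:
    """Cluster the profile at fixed k, or choose k by the second-elbow rule."""
    curve = wss_curve(profile, k_max=k_max, seed=seed, n_restarts=n_restarts)
    if k == "auto":
        chosen = elbow_select(curve, which_elbow=which_elbow)
    else:
        chosen = int(k)
    model = kmeans_cluster(profile, chosen, seed=seed, n_restarts=n_restarts)
    model.wss_curve = curve
    model.chosen_k = chosen
    logger.info("DDC clustering: k=%d, total WSS=%.3f", chosen, model.total_wss)
    return model
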