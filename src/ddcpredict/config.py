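"""Run configuration: every tunable constant of the pipeline in one place."""
from __future__ import annotations

import dataclasses

import yaml


@dataclasses.dataclass
class McodeParams:
    """MCODE complex-detection parameters (plugin defaults)."""

    vwp: float = 0.2          # vertex weight percentage: admit w >= (1-vwp)*seed weight
    haircut: bool = True      # strip singly-connected module nodes (2-core)
    fluff: bool = False       # optionally add dense-neighbourhood boundary nodes
    fluff_density: float = 0.2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.vwp < 1:
            raise ValueError("vwp must lie in (0, 1)")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclasses.dataclass
class RunConfig:
    """All pipeline constants.

    Defaults reproduce the published analysis choices: DDG modules require an
    MCODE score > 3 and > 5 nodes; hub aggregation keeps the top 10 genes per
    centrality and drops genes with degree < 10; the permutation null uses
    1000 random same-size gene sets; clustering uses k = 8 (or ``"auto"`` for
    the second-elbow rule); response models use an 8:2 stratified split, SMOTE
    with k = 5, and tenfold cross-validated LASSO.
    """

    seed: int = 0
    alpha_ssgsea: float = 0.25
    epsilon_dmnc: float = 1.7
    mcode: McodeParams = dataclasses.field(default_factory=McodeParams)
    min_mcode_score: float = 3.0
    min_module_nodes: int = 5
    hub_topk: int = 10
    min_degree_keep: int = 10
    epc_iters: int = 100
    n_perm: int = 1000
    k_clusters: int | str = 8
    max_missing_genes: int = 5
    split_ratio: float = 0.8
    smote_k: int = 5
    cv_folds: int = 10
    logfc_threshold_response: float = 1.0
    alpha_bh: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.mcode, dict):
            self.mcode = McodeParams(**self.mcode)
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if isinstance(self.k_clusters, str) and self.k_clusters != "auto":
            raise ValueError('k_clusters must be an integer or "auto"')

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
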