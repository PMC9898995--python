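"""End-to-end orchestration of the synthetic study, with a reproducibility manifest.

Stage order: simulate -> differential expression -> network hubs (MCODE +
centralities -> DDG signature) -> permutation-null validation -> correlation
projection + K-means (DDCs) -> per-cluster response models.  One master seed
deterministically spawns per-stage seeds; every intermediate artifact is a
plain-text file, and the manifest records a SHA-256 digest of each output so a
re-run with the same config can be verified byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import build_correlation_profile, fit_ddc
from .config import RunConfig
from .diffexpr import deg_table, intersect_deg_sets, moderated_t_test, significant_degs
from .hubs import all_centralities, mcode_modules, select_ddgs, top_k_aggregate
from .io import ExpressionMatrix, write_edge_list
from .response import (
    ClusterResponseModel,
    ResponseCohort,
    summary_table,
)
from .ssgsea import permutation_null
from .synthetic import (
    simulate_discovery_datasets,
    simulate_network,
    simulate_panel_cohort,
    simulate_response_cohort,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineManifest:
    config: dict
    stage_seeds: dict
    digests: dict       # relative path -> sha256
    versions: dict
    elapsed: dict

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _spawn_seeds(master: int, names: list) -> dict:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig | str | Path, out_dir) -> PipelineManifest:
    """Run the full synthetic study under one config; returns the manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed, ["simulate", "network", "panel", "response",
                                       "validation", "permtest", "ddc", "respond"])
    digests: dict = {}
    elapsed: dict = {}

    def _record(path: Path) -> None:
        digests[str(path.relative_to(out))] = _sha256(path)

    def _stage(name):
        t0 = time.time()
        def done():
            elapsed[name] = round(time.time() - t0, 3)
            logger.info("stage %s finished in %.2fs (seed %s)", name, elapsed[name],
                        seeds.get(name))
        return done

    # --- simulate ----------------------------------------------------------
    done = _stage("simulate")
    discovery, truth = simulate_discovery_datasets(seed=seeds["simulate"])
    for m in discovery:
        p = out / f"{m.dataset_id}_expression.tsv"
        m.write(p, out / f"{m.dataset_id}_labels.tsv")
        _record(p)
        _record(out / f"{m.dataset_id}_labels.tsv")
    done()

    # --- differential expression ------------------------------------------
    done = _stage("deg")
    deg_results = {}
    for m in discovery:
        res = moderated_t_test(m, "LN", "control")
        deg_results[m.dataset_id] = res
        p = out / f"{m.dataset_id}_degs.tsv"
        deg_table(res).to_csv(p, sep="\t")
        _record(p)
    sig = {ds: significant_degs(res, config.alpha_bh) for ds, res in deg_results.items()}
    venn = intersect_deg_sets({ds: [r.gene for r in rs] for ds, rs in sig.items()})
    common = set(venn.common)
    direction = {}
    for rs in deg_results.values():
        for r in rs:
            if r.gene in common:
                direction.setdefault(r.gene, []).append(r.direction)
    common_up = sorted(g for g, d in direction.items() if d.count("up") > len(d) / 2)
    common_down = sorted(g for g in common if g not in common_up)
    done()

    # --- network + hubs -----------------------------------------------------
    done = _stage("network")
    hub_up = [g for g in truth.planted_hub_genes if g in common_up]
    hub_down = [g for g in truth.planted_hub_down_genes if g in common_down]
    network, _ = simulate_network(
        node_names=common_up + common_down,
        planted_on=[hub_up, hub_down],
        background_p=0.02,
        seed=seeds["network"],
    )
    p = out / "network_edges.tsv"
    write_edge_list(network, p)
    _record(p)
    up_mods = mcode_modules(network.subgraph(common_up), config.mcode)
    down_mods = mcode_modules(network.subgraph(common_down), config.mcode)
    ddgs = select_ddgs(up_mods, down_mods, config.min_mcode_score, config.min_module_nodes)
    p = out / "ddg_signature.gmt"
    ddgs.write(p)
    _record(p)
    tables = all_centralities(
        network.subgraph(ddgs["DDG"]), epc_iters=config.epc_iters, seed=seeds["network"],
        epsilon=config.epsilon_dmnc,
    )
    hub_table = top_k_aggregate(tables, k=config.hub_topk, min_degree=config.min_degree_keep)
    p = out / "hub_scores.tsv"
    hub_table.table.to_csv(p, sep="\t")
    _record(p)
    done()

    # --- permutation test ---------------------------------------------------
    done = _stage("permtest")
    report = permutation_null(
        discovery[0], ddgs["DDG"], n_perm=config.n_perm,
        alpha=config.alpha_ssgsea, seed=seeds["permtest"],
    )
    p = out / "permutation_report.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "observed_mean_diff": report.observed_mean_diff,
                "observed_p": report.observed_p,
                "empirical_p": report.empirical_p,
                "n_perm": report.n_perm,
                "signature_size": report.signature_size,
            },
            fh, indent=2, sort_keys=True,
        )
    _record(p)
    done()

    # --- DDC clustering -----------------------------------------------------
    done = _stage("ddc")
    panel_sets, panel_truth = simulate_panel_cohort(
        signature=ddgs["DDG"], seed=seeds["panel"]
    )
    panel_genes = [g for b in sorted(panel_truth.planted_blocks)
                   for g in panel_truth.planted_blocks[b]]
    profile = build_correlation_profile(
        panel_sets, ddgs["DDG"], panel_genes,
        alpha=config.alpha_ssgsea, max_missing=config.max_missing_genes,
    )
    p = out / "correlation_profile.tsv"
    profile.rho.to_csv(p, sep="\t", float_format="%.6f")
    _record(p)
    ddc = fit_ddc(profile, k=config.k_clusters, seed=seeds["ddc"])
    p = out / "ddc_assignment.tsv"
    ddc.assignment_table().to_csv(p, sep="\t")
    _record(p)
    p = out / "wss_curve.csv"
    pd.Series(ddc.wss_curve, name="wss").rename_axis("k").to_csv(p)
    _record(p)
    done()

    # --- response models ----------------------------------------------------
    done = _stage("respond")
    cohort_matrix, resp_truth = simulate_response_cohort(seed=seeds["response"])
    val_matrix, _ = simulate_response_cohort(
        n_patients=60, reuse=resp_truth, cohort_id="VAL", seed=seeds["validation"]
    )
    cohort = ResponseCohort(cohort_matrix)
    validation = ResponseCohort(val_matrix)
    # the fitted DDC assignment projects directly: the response cohort measures
    # the same panel genes the profile was built on
    results = ClusterResponseModel(
        cohort, ddc, validation=validation, config=config
    ).fit(seed=seeds["respond"])
    p = out / "model_reports.json"
    with open(p, "w") as fh:
        json.dump([r.to_dict() for r in results.reports], fh, indent=2,
                  sort_keys=True, default=str)
    _record(p)
    p = out / "model_summary.csv"
    summary_table(results.reports).to_csv(p, float_format="%.6f")
    _record(p)
    done()

    manifest = PipelineManifest(
        config=dataclasses.asdict(config),
        stage_seeds=seeds,
        digests=digests,
        versions={"ddcpredict": __version__},
        elapsed=elapsed,
    )
    manifest.write(out / "manifest.json")
    return manifest
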