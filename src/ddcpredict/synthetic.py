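"""Synthetic study generators with machine-checkable ground truth.

The generators emulate the statistical structure the pipeline assumes:

* multi-dataset case/control expression matrices sharing a planted DEG program
  and a latent "hub program" — a per-sample activity variable, higher in cases,
  that additively drives the planted hub genes;
* targeted-panel cohorts whose genes fall into correlation blocks tied to the
  hub activity with block-specific strength (some blocks near zero), consistent
  across datasets up to compartment-specific attenuation;
* a response-labelled flare cohort with a configurable class imbalance
  (default 2.76:1 responders to non-responders) whose labels follow a logistic
  model with non-zero coefficients confined to one panel block, most oriented
  so the genes are up-regulated in non-responders;
* interaction networks: Erdős–Rényi background with planted near-cliques.

Every generator is deterministic given its seed.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneNetwork

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth planted by the generators (all fields machine-checkable)."""

    planted_degs_up: dict = dataclasses.field(default_factory=dict)    # gene -> log2 effect
    planted_degs_down: dict = dataclasses.field(default_factory=dict)  # gene -> log2 effect (<0)
    planted_hub_genes: list = dataclasses.field(default_factory=list)
    planted_hub_down_genes: list = dataclasses.field(default_factory=list)
    planted_modules: list = dataclasses.field(default_factory=list)    # (frozenset, density)
    planted_blocks: dict = dataclasses.field(default_factory=dict)     # block id -> gene list
    block_rhos: dict = dataclasses.field(default_factory=dict)         # block id -> target rho
    planted_predictive_genes: dict = dataclasses.field(default_factory=dict)  # gene -> coef
    block_of_predictive_genes: int | None = None


def _gene_names(prefix: str, n: int) -> list:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# discovery datasets
# ---------------------------------------------------------------------------

def simulate_discovery_datasets(
    n_datasets: int = 3,
    n_genes: int = 2000,
    n_case: int = 30,
    n_control: int = 30,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    n_deg_up: int = 80,
    n_deg_down: int = 40,
    n_hub_up: int = 30,
    n_hub_down: int = 10,
    hub_effect: float = 1.0,
    activity_shift: float = 2.0,
    seed: int = 0,
) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """Case/control matrices across datasets with a shared planted DEG program.

    Baseline expression is gene-specific Normal noise around a per-gene mean
    shared across datasets; planted up/down DEGs are shifted by ±effect_size
    in cases; hub genes are additively driven by a latent activity variable
    (N(0,1) in controls, N(activity_shift,1) in cases) with loading
    ±hub_effect.  Hub genes are disjoint from the ordinary DEG lists so the
    two programs are separately checkable.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("sample counts must be positive")
    if n_genes < 50:
        raise ValueError("need n_genes >= 50")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(seed)
    genes = _gene_names("G", n_genes)
    n_special = n_deg_up + n_deg_down + n_hub_up + n_hub_down
    if n_special > n_genes:
        raise ValueError("planted gene programs exceed the gene universe")
    special = list(rng.choice(n_genes, size=n_special, replace=False))
    up_idx = special[:n_deg_up]
    down_idx = special[n_deg_up:n_deg_up + n_deg_down]
    hub_up_idx = special[n_deg_up + n_deg_down:n_deg_up + n_deg_down + n_hub_up]
    hub_down_idx = special[n_deg_up + n_deg_down + n_hub_up:]

    base_mean = rng.normal(7.0, 1.5, size=n_genes)
    compartments = ["glomeruli", "tubulointerstitium", "kidney", "blood"]
    matrices = []
    for d in range(n_datasets):
        n = n_case + n_control
        samples = [f"DS{d + 1}_s{i + 1:03d}" for i in range(n)]
        is_case = np.array([1] * n_case + [0] * n_control)
        values = base_mean[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n))
        values[up_idx, :] += effect_size * is_case[None, :]
        values[down_idx, :] -= effect_size * is_case[None, :]
        activity = rng.normal(0.0, 1.0, size=n) + activity_shift * is_case
        values[hub_up_idx, :] += hub_effect * activity[None, :]
        values[hub_down_idx, :] -= hub_effect * activity[None, :]
        labels = {s: ("LN" if c else "control") for s, c in zip(samples, is_case)}
        matrices.append(
            ExpressionMatrix(
                dataset_id=f"DS{d + 1}",
                compartment=compartments[d % len(compartments)],
                data=pd.DataFrame(values, index=genes, columns=samples),
                labels=labels,
            )
        )
    truth = SyntheticTruth(
        planted_degs_up={genes[i]: effect_size for i in up_idx},
        planted_degs_down={genes[i]: -effect_size for i in down_idx},
        planted_hub_genes=[genes[i] for i in hub_up_idx],
        planted_hub_down_genes=[genes[i] for i in hub_down_idx],
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# panel cohort
# ---------------------------------------------------------------------------

# default: eight block correlations evenly spanning strong positive to strong
# negative, so between-block spacing is uniform and the elbow of the WSS curve
# is informative about the true block count
DEFAULT_BLOCK_RHOS = tuple(round(r, 3) for r in np.linspace(0.8, -0.8, 8))


def simulate_panel_cohort(
    n_panel_genes: int = 520,
    n_blocks: int = 8,
    n_samples_per_dataset: tuple = (120, 120, 120, 120, 120),
    block_rhos: tuple = DEFAULT_BLOCK_RHOS,
    dataset_attenuation: tuple | None = None,
    signature: list | None = None,
    n_signature: int = 40,
    n_background: int = 300,
    signature_loading: float = 1.0,
    signature_noise_sd: float = 0.6,
    activity_shift: float = 2.0,
    missing_in: tuple | None = None,
    seed: int = 0,
) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """Panel cohorts with planted correlation blocks tied to the hub program.

    Each dataset draws a latent activity per sample (case samples shifted by
    ``activity_shift``); signature genes load on the activity so their ssGSEA
    score is a faithful proxy; each panel gene in block b is generated as
    rho_b * attenuation_d * a + noise so its correlation with the activity hits
    the block target.  ``dataset_attenuation`` defaults to 1.0 for the first
    three ("tissue") datasets and 0.75 for the rest ("blood"), so block
    profiles differ by compartment rather than being collinear.
    ``missing_in = (dataset_index, m)`` removes m signature genes from that
    dataset to exercise the dataset-exclusion rule.
    """
    if n_blocks < 2:
        raise ValueError("need n_blocks >= 2")
    if len(block_rhos) != n_blocks:
        raise ValueError("block_rhos length must equal n_blocks")
    if any(abs(r) >= 1 for r in block_rhos):
        raise ValueError("block rhos must lie in (-1, 1)")
    if n_panel_genes < 2 * n_blocks:
        raise ValueError("block sizes would fall below 2")
    rng = np.random.default_rng(seed)
    if dataset_attenuation is None:
        dataset_attenuation = tuple(
            1.0 if d < 3 else 0.75 for d in range(len(n_samples_per_dataset))
        )
    if len(dataset_attenuation) != len(n_samples_per_dataset):
        raise ValueError("dataset_attenuation length mismatch")

    if signature is None:
        signature = _gene_names("HUB", n_signature)
    panel_genes = _gene_names("PNL", n_panel_genes)
    background = _gene_names("BKG", n_background)
    # near-even partition of panel genes into blocks
    sizes = np.full(n_blocks, n_panel_genes // n_blocks)
    sizes[: n_panel_genes % n_blocks] += 1
    blocks, start = {}, 0
    for b in range(n_blocks):
        blocks[b + 1] = panel_genes[start:start + sizes[b]]
        start += sizes[b]

    compartments = ["glomeruli", "tubulointerstitium", "kidney", "blood", "blood"]
    matrices = []
    for d, n in enumerate(n_samples_per_dataset):
        samples = [f"PD{d + 1}_s{i + 1:03d}" for i in range(n)]
        n_case = n // 2
        is_case = np.array([1] * n_case + [0] * (n - n_case))
        activity = rng.normal(0.0, 1.0, size=n) + activity_shift * is_case
        a_std = (activity - activity.mean()) / activity.std()

        sig_vals = (
            6.0
            + signature_loading * activity[None, :]
            + rng.normal(0.0, signature_noise_sd, size=(len(signature), n))
        )
        bkg_vals = rng.normal(7.0, 1.0, size=(len(background), n))
        panel_vals = np.empty((n_panel_genes, n))
        row = 0
        for b in range(n_blocks):
            rho = block_rhos[b] * dataset_attenuation[d]
            nb = sizes[b]
            noise = rng.normal(0.0, 1.0, size=(nb, n))
            panel_vals[row:row + nb] = (
                7.0 + rho * a_std[None, :] + np.sqrt(1.0 - rho**2) * noise
            )
            row += nb
        data = pd.DataFrame(
            np.vstack([sig_vals, bkg_vals, panel_vals]),
            index=list(signature) + background + panel_genes,
            columns=samples,
        )
        if missing_in is not None and missing_in[0] == d:
            drop = list(signature)[: missing_in[1]]
            data = data.drop(index=drop)
        labels = {s: ("LN" if c else "control") for s, c in zip(samples, is_case)}
        matrices.append(
            ExpressionMatrix(
                dataset_id=f"PD{d + 1}",
                compartment=compartments[d % len(compartments)],
                data=data,
                labels=labels,
            )
        )
    truth = SyntheticTruth(
        planted_hub_genes=list(signature),
        planted_blocks=blocks,
        block_rhos={b + 1: block_rhos[b] for b in range(n_blocks)},
    )
    return matrices, truth


# ---------------------------------------------------------------------------
# response cohort
# ---------------------------------------------------------------------------

def _tune_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept such that mean sigmoid(b0 + eta) hits the target prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        prev = float(np.mean(1.0 / (1.0 + np.exp(-(mid + eta)))))
        if prev < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_response_cohort(
    n_patients: int = 200,
    imbalance: float = 2.76,
    predictive_block: int = 6,
    n_predictive: int = 5,
    coef_scale: float = 2.0,
    frac_up_in_nonresponders: float = 0.8,
    n_panel_genes: int = 520,
    n_blocks: int = 8,
    block_rhos: tuple = DEFAULT_BLOCK_RHOS,
    cohort_id: str = "RESP",
    timepoint: str = "at_flare",
    reuse: SyntheticTruth | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """A response-labelled panel cohort with predictive genes in one block.

    Labels follow a logistic model whose non-zero coefficients live only on
    ``n_predictive`` genes of ``predictive_block``; a fraction
    ``frac_up_in_nonresponders`` of the coefficients is oriented so those genes
    are up-regulated in non-responders.  The marginal responder:non-responder
    ratio is tuned to ``imbalance`` by the intercept, not by subsampling.
    Passing ``reuse`` re-applies a previous cohort's blocks and coefficients,
    which is how an independent validation cohort is generated.
    """
    if imbalance <= 1:
        raise ValueError("imbalance must exceed 1")
    rng = np.random.default_rng(seed)

    if reuse is not None:
        blocks = reuse.planted_blocks
        rhos = reuse.block_rhos
        coefs = dict(reuse.planted_predictive_genes)
        predictive_block = reuse.block_of_predictive_genes
    else:
        panel_genes = _gene_names("PNL", n_panel_genes)
        sizes = np.full(n_blocks, n_panel_genes // n_blocks)
        sizes[: n_panel_genes % n_blocks] += 1
        blocks, start = {}, 0
        for b in range(n_blocks):
            blocks[b + 1] = panel_genes[start:start + sizes[b]]
            start += sizes[b]
        rhos = {b + 1: block_rhos[b] for b in range(n_blocks)}
        if predictive_block not in blocks:
            raise ValueError(f"predictive_block {predictive_block} not in 1..{n_blocks}")
        if n_predictive > len(blocks[predictive_block]):
            raise ValueError("n_predictive exceeds the predictive block size")
        chosen = rng.choice(blocks[predictive_block], size=n_predictive, replace=False)
        n_down = int(round(frac_up_in_nonresponders * n_predictive))
        coefs = {}
        for i, g in enumerate(chosen):
            # negative coefficient w.r.t. responder = up-regulated in non-responders
            sign = -1.0 if i < n_down else 1.0
            coefs[g] = sign * coef_scale

    all_genes = [g for b in sorted(blocks) for g in blocks[b]]
    samples = [f"{cohort_id}_p{i + 1:03d}" for i in range(n_patients)]
    activity = rng.normal(0.0, 1.0, size=n_patients)
    values = np.empty((len(all_genes), n_patients))
    row = 0
    for b in sorted(blocks):
        nb = len(blocks[b])
        rho = rhos[b]
        noise = rng.normal(0.0, 1.0, size=(nb, n_patients))
        values[row:row + nb] = 7.0 + rho * activity[None, :] + np.sqrt(1.0 - rho**2) * noise
        row += nb
    data = pd.DataFrame(values, index=all_genes, columns=samples)

    eta = np.zeros(n_patients)
    for g, beta in coefs.items():
        x = data.loc[g].to_numpy()
        eta += beta * (x - x.mean()) / x.std()
    target = imbalance / (1.0 + imbalance)
    b0 = _tune_intercept(eta, target)
    prob = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    for attempt in range(100):
        y = rng.random(n_patients) < prob
        if 0 < y.sum() < n_patients:
            break
        warnings.warn("degenerate single-class label draw; resampling")
    else:
        raise ValueError("could not draw a two-class cohort in 100 attempts")
    labels = {s: ("responder" if yi else "non-responder") for s, yi in zip(samples, y)}

    matrix = ExpressionMatrix(
        dataset_id=cohort_id, compartment="panel", data=data, labels=labels
    )
    truth = SyntheticTruth(
        planted_blocks=blocks,
        block_rhos=rhos,
        planted_predictive_genes=coefs,
        block_of_predictive_genes=predictive_block,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def simulate_network(
    n_nodes: int = 200,
    background_p: float = 0.02,
    planted_clique_sizes: tuple = (8, 6),
    clique_p: float = 1.0,
    node_names: list | None = None,
    planted_on: list | None = None,
    seed: int = 0,
) -> tuple[GeneNetwork, SyntheticTruth]:
    """Erdős–Rényi background with planted near-cliques on disjoint node sets.

    ``planted_on`` optionally pins each planted module to an explicit node set
    (sizes then come from those sets); otherwise modules occupy the first
    nodes.  Overlapping planted sets are a hard error.
    """
    if not 0 <= background_p <= 0.2:
        raise ValueError("background_p must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    if node_names is None:
        node_names = _gene_names("N", n_nodes)
    else:
        node_names = list(node_names)
        n_nodes = len(node_names)

    if planted_on is not None:
        planted_sets = [list(s) for s in planted_on]
    else:
        planted_sets, start = [], 0
        for size in planted_clique_sizes:
            planted_sets.append(node_names[start:start + size])
            start += size
        if start > n_nodes:
            raise ValueError("planted cliques exceed the node universe")
    for s in planted_sets:
        if len(s) < 4:
            raise ValueError("planted module sizes must be >= 4")
        if not set(s) <= set(node_names):
            raise ValueError("planted module nodes must belong to the network")
    flat = [n for s in planted_sets for n in s]
    if len(flat) != len(set(flat)):
        raise ValueError("planted module node sets overlap")

    g = nx.Graph()
    g.add_nodes_from(node_names)
    idx = {n: i for i, n in enumerate(node_names)}
    if background_p > 0:
        for i, a in enumerate(node_names):
            draws = rng.random(n_nodes - i - 1)
            for j, keep in enumerate(draws < background_p, start=i + 1):
                if keep:
                    g.add_edge(a, node_names[j])
    modules = []
    for s in planted_sets:
        for i in range(len(s)):
            for j in range(i + 1, len(s)):
                if clique_p >= 1.0 or rng.random() < clique_p:
                    g.add_edge(s[i], s[j])
        sub = g.subgraph(s)
        n = len(s)
        density = 2.0 * sub.number_of_edges() / (n * (n - 1))
        modules.append((frozenset(s), density))
    truth = SyntheticTruth(planted_modules=modules)
    return g, truth
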