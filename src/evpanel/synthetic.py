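"""Synthetic plasma-EV proteomics cohorts and companion reference data.

The generator emulates the statistical structure of a small case/control
EV proteomic discovery study so that every downstream stage is testable
without access to clinical data:

* a 13-case / 15-control cohort of ~640 proteins whose log2 abundances
  follow a two-component mixture — a small high-abundance mode (classical
  plasma proteins) above the log2 = 12 partition cutoff and a large
  low-abundance mode below it;
* spectral-count-like nonnegative linear abundances, drawn as
  ``2**(protein base level + per-sample noise)``;
* intensity-dependent dropout: low-abundance proteins are undetected
  (recorded as exact 0) in a given sample with a probability that decays
  logistically with the underlying log2 intensity, calibrated so that a
  protein sitting at the low-mode center drops out at exactly
  ``dropout_rate``.  Detection therefore improves with abundance, as in
  real spectral counting, and high-abundance proteins essentially never
  drop out.  Dropout depends only on intensity, so with no planted effects
  case and control samples remain exchangeable;
* planted up-in-case proteins (case values multiplied by
  ``2**planted_log2fc`` before dropout) with a subset additionally forced
  case-exclusive (zeroed in every control sample);
* reference sets (cell-line EV proteome with a controlled overlap
  fraction; an unfractionated-plasma proteome with independent
  abundances), NTA particle-size samples (log-normal, parameterized by the
  modal diameter), and an Erdős–Rényi background interaction graph with a
  denser planted module.

Every generator consumes a single explicitly seeded pseudo-random stream;
identical seeds reproduce outputs bitwise.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as evio
from .matrix import CASE, CTRL, AbundanceMatrix, write_abundance_matrix
from .qc import SizeDistribution

__all__ = [
    "ConfigError",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_reference_sets",
    "generate_particle_sizes",
    "generate_background_graph",
    "write_cohort",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclasses.dataclass
class CohortConfig:
    """Study-design parameters of the simulated cohort.

    Defaults mirror the discovery-study conditions: 13 cases vs 15
    controls, 640 proteins with 80 in the high-abundance mode, 108 planted
    up-in-case proteins of which 21 are case-exclusive.  Location/scale
    parameters are on the log2-intensity scale.
    """

    n_case: int = 13
    n_ctrl: int = 15
    n_proteins: int = 640
    frac_high_abundance: float = 80 / 640
    high_mean: float = 15.5
    low_mean: float = 7.0
    sd: float = 1.2           # between-protein spread within each mode
    noise_sd: float = 0.8     # within-protein, between-sample variation
    dropout_rate: float = 0.2
    dropout_width: float = 1.0  # log2 units; steepness of the detection curve
    n_diff: int = 108
    planted_log2fc: float = 2.0
    n_exclusive: int = 21
    protein_length_range: tuple[int, int] = (100, 2000)
    seed: int = 0

    def __post_init__(self) -> None:
        for field in ("n_case", "n_ctrl", "n_proteins", "n_diff", "n_exclusive"):
            if getattr(self, field) < 0:
                raise ConfigError(f"{field} must be >= 0")
        if not self.n_exclusive <= self.n_diff <= self.n_proteins:
            raise ConfigError("need n_exclusive <= n_diff <= n_proteins")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if not 0 <= self.frac_high_abundance <= 1:
            raise ConfigError("frac_high_abundance must be in [0, 1]")
        for field in ("sd", "noise_sd", "dropout_width"):
            if getattr(self, field) < 0:
                raise ConfigError(f"{field} must be >= 0")
        lo, hi = self.protein_length_range
        if not 0 < lo <= hi:
            raise ConfigError("protein_length_range must be positive and ordered")


@dataclasses.dataclass
class SyntheticCohort:
    """Generated matrix plus ground truth for recovery tests."""

    matrix: AbundanceMatrix
    truth_diff: set[str]
    truth_exclusive: set[str]
    lengths: dict[str, int]
    config: CohortConfig


def _gene_names(n: int, prefix: str = "GENE") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_p, n_s = config.n_proteins, config.n_case + config.n_ctrl
    genes = _gene_names(n_p)
    samples = [f"case{i + 1:02d}" for i in range(config.n_case)] + [
        f"ctrl{i + 1:02d}" for i in range(config.n_ctrl)
    ]
    groups = dict(zip(samples, [CASE] * config.n_case + [CTRL] * config.n_ctrl))
    case_cols = np.arange(config.n_case)
    ctrl_cols = np.arange(config.n_case, n_s)

    n_high = int(round(config.frac_high_abundance * n_p))
    is_high = np.zeros(n_p, dtype=bool)
    is_high[:n_high] = True

    base = np.where(is_high, config.high_mean, config.low_mean) + config.sd * rng.normal(size=n_p)
    log2_vals = base[:, None] + config.noise_sd * rng.normal(size=(n_p, n_s))

    low_idx = np.flatnonzero(~is_high)
    pool = low_idx if low_idx.size >= config.n_diff else np.arange(n_p)
    diff_idx = rng.choice(pool, size=config.n_diff, replace=False)
    excl_idx = diff_idx[: config.n_exclusive]
    log2_vals[np.ix_(diff_idx, case_cols)] += config.planted_log2fc

    linear = np.exp2(log2_vals)

    if config.dropout_rate > 0:
        # logistic detection curve in log2 intensity, anchored so that the
        # low-mode center is detected with probability 1 - dropout_rate
        v50 = config.low_mean - config.dropout_width * math.log(
            (1 - config.dropout_rate) / config.dropout_rate
        )
        p_detect = 1.0 / (1.0 + np.exp(-(log2_vals - v50) / config.dropout_width))
        detected = rng.random(size=(n_p, n_s)) < p_detect
        linear = linear * detected

    linear[np.ix_(excl_idx, ctrl_cols)] = 0.0

    data = pd.DataFrame(linear, index=pd.Index(genes, name="gene"), columns=samples)
    matrix = AbundanceMatrix(data, groups, scale="linear")
    lengths = {
        g: int(l)
        for g, l in zip(
            genes,
            rng.integers(
                config.protein_length_range[0], config.protein_length_range[1] + 1, size=n_p
            ),
        )
    }
    return SyntheticCohort(
        matrix=matrix,
        truth_diff={genes[i] for i in diff_idx},
        truth_exclusive={genes[i] for i in excl_idx},
        lengths=lengths,
        config=config,
    )


def generate_reference_sets(
    cohort: SyntheticCohort,
    overlap_frac: float = 0.42,
    n_extra: int = 300,
    plasma_frac: float = 0.59,
    seed: int = 0,
) -> tuple[set[str], dict[str, float]]:
    """Companion reference datasets with controlled overlap.

    Returns a cell-line EV gene set containing ``round(overlap_frac * n)``
    cohort genes plus ``n_extra`` novel symbols, and an
    unfractionated-plasma reference mapping ``round(plasma_frac * n)``
    cohort genes to independent linear abundances.
    """
    if not 0 <= overlap_frac <= 1:
        raise ConfigError("overlap_frac must be in [0, 1]")
    if not 0 <= plasma_frac <= 1:
        raise ConfigError("plasma_frac must be in [0, 1]")
    if n_extra < 0:
        raise ConfigError("n_extra must be >= 0")
    rng = np.random.default_rng(seed)
    genes = cohort.matrix.genes
    n_overlap = int(round(overlap_frac * len(genes)))
    cellline = set(rng.choice(genes, size=n_overlap, replace=False))
    cellline |= set(_gene_names(n_extra, prefix="CLEV"))
    n_plasma = int(round(plasma_frac * len(genes)))
    plasma_genes = rng.choice(genes, size=n_plasma, replace=False)
    plasma_ref = {
        g: float(np.exp2(rng.normal(10.0, 2.0))) for g in plasma_genes
    }
    return cellline, plasma_ref


def generate_particle_sizes(
    modal_nm: float = 88.0,
    spread: float = 0.35,
    n: int = 10_000,
    seed: int = 0,
    concentration: float = 1.2e9,
    dilution_factor: float = 1000.0,
) -> SizeDistribution:
    """Log-normal particle diameters whose mode equals ``modal_nm``.

    For LogNormal(mu, sigma) the mode is exp(mu - sigma^2), so
    ``mu = ln(modal_nm) + spread**2`` with ``sigma = spread``.  ``spread``
    of 0 collapses to a point mass at the mode.
    """
    if modal_nm <= 0:
        raise ConfigError("modal_nm must be positive")
    if n <= 0:
        raise ConfigError("n must be positive")
    if spread < 0:
        raise ConfigError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    mu = math.log(modal_nm) + spread**2
    diameters = np.exp(mu + spread * rng.normal(size=n))
    return SizeDistribution(
        diameters=diameters,
        concentration=concentration,
        dilution_factor=dilution_factor,
    )


def generate_background_graph(
    n_nodes: int = 200,
    edge_prob: float = 0.02,
    module_nodes: int = 30,
    module_prob: float = 0.30,
    seed: int = 0,
    node_names: list[str] | None = None,
) -> nx.Graph:
    """Erdős–Rényi background with a denser planted module.

    The module occupies the first ``module_nodes`` nodes; pairs inside it
    connect with probability ``max(edge_prob, module_prob)``, all other
    pairs with ``edge_prob``.  The module's node list is stored in
    ``graph.graph["module_nodes"]``.
    """
    if not 0 <= edge_prob <= 1 or not 0 <= module_prob <= 1:
        raise ConfigError("edge_prob and module_prob must be probabilities")
    if not 0 <= module_nodes <= n_nodes:
        raise ConfigError("module_nodes must be <= n_nodes")
    if node_names is None:
        node_names = _gene_names(n_nodes)
    elif len(node_names) != n_nodes:
        raise ConfigError("node_names must have length n_nodes")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    in_module = (iu < module_nodes) & (ju < module_nodes)
    probs = np.where(in_module, max(edge_prob, module_prob), edge_prob)
    keep = rng.random(iu.size) < probs
    graph = nx.Graph()
    graph.add_nodes_from(node_names)
    graph.add_edges_from(
        (node_names[i], node_names[j]) for i, j in zip(iu[keep], ju[keep])
    )
    graph.graph["module_nodes"] = node_names[:module_nodes]
    return graph


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write matrix, truth sets and lengths in their plain-text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "truth_diff": outdir / "truth_diff.txt",
        "truth_exclusive": outdir / "truth_exclusive.txt",
        "lengths": outdir / "lengths.tsv",
    }
    write_abundance_matrix(cohort.matrix, paths["matrix"])
    evio.write_gene_set(cohort.truth_diff, paths["truth_diff"])
    evio.write_gene_set(cohort.truth_exclusive, paths["truth_exclusive"])
    evio.write_lengths(cohort.lengths, paths["lengths"])
    return paths
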