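"""End-to-end discovery workflow.

Runs the full analysis on one configuration: abundance partitioning ->
differential expression -> tiered filtering -> reference-set integration ->
NSAF enrichment -> clustering -> marker-panel ROC -> network enrichment,
writing every stage product plus a machine-readable summary JSON.  Inputs
are either files (matrix, lengths, reference sets, graph, annotations,
particle sizes) or, when no matrix is supplied, a synthetic cohort drawn
from a :class:`~evpanel.synthetic.CohortConfig`, in which case matched
reference sets, a background graph whose planted module sits inside the
planted differential proteins, and NTA size samples are simulated too.

Every random procedure consumes a seed derived from the single configured
seed, and all seeds are recorded in the report, so rerunning the same
configuration reproduces the summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.metrics import rand_score

from . import __version__
from . import io as evio
from .cluster import cut_tree, pearson_distance_matrix, to_newick, ward_linkage
from .differential import (
    FilterConfig,
    apply_filter_cascade,
    differential_table,
    write_differential_table,
)
from .integrate import intersect_with_reference, novel_vs_reference, nsaf_enrichment, venn_partition
from .matrix import (
    CASE,
    CTRL,
    AbundanceMatrix,
    compute_nsaf,
    log2_transform,
    partition_by_abundance,
    read_abundance_matrix,
)
from .network import clustering_coefficient, edge_enrichment, filter_edges_by_score, term_enrichment
from .panel import bootstrap_auc_ci, fit_panel, panel_auc, roc_result
from .qc import SizeDistribution, qc_report
from .synthetic import (
    CohortConfig,
    generate_background_graph,
    generate_cohort,
    generate_particle_sizes,
    generate_reference_sets,
    write_cohort,
)

__all__ = ["PipelineConfig", "DiscoveryReport", "run_full_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Inputs and settings for one full pipeline run."""

    outdir: str
    seed: int = 0
    # file inputs; any left None is simulated (matrix) or skipped (others)
    matrix_path: str | None = None
    lengths_path: str | None = None
    cellline_path: str | None = None
    plasma_ref_path: str | None = None
    graph_path: str | None = None
    annotations_path: str | None = None
    sizes_path: str | None = None
    total_protein_ug: float | None = None
    input_plasma_ml: float | None = None
    cohort: CohortConfig | None = None
    filter: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    log2_cutoff: float = 12.0
    cluster_k: int = 2
    markers: list[str] | None = None  # None -> auto top-n_markers by AUC
    n_markers: int = 4
    n_boot: int = 2000
    n_perm: int = 10_000
    min_edge_score: float | None = None
    nsaf_threshold: float = 10.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        if raw.get("cohort") is not None and not isinstance(raw["cohort"], CohortConfig):
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if raw.get("filter") is not None and not isinstance(raw["filter"], FilterConfig):
            f = dict(raw["filter"])
            for key in ("fold_tiers", "inclusive_tiers"):
                if key in f:
                    f[key] = tuple(f[key])
            raw["filter"] = FilterConfig(**f)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass
class DiscoveryReport:
    """Aggregated, JSON-serializable results of one pipeline run."""

    qc: dict | None
    partition: dict
    differential: dict
    integration: dict | None
    nsaf: dict | None
    clustering: dict
    markers: dict | None
    network: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    fields = config.to_dict()
    fields.pop("outdir")  # where results land does not change what they are
    blob = json.dumps(fields, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _plasma_nsaf(plasma_ref: Mapping[str, float], lengths: Mapping[str, float] | None) -> dict[str, float]:
    """Single-run NSAF over an unfractionated-plasma abundance mapping."""
    rates = {}
    for gene, val in plasma_ref.items():
        length = float(lengths.get(gene, 1.0)) if lengths else 1.0
        rates[str(gene).upper()] = float(val) / length
    total = sum(rates.values())
    if total == 0:
        return {g: 0.0 for g in rates}
    return {g: r / total for g, r in rates.items()}


def run_full_pipeline(config: PipelineConfig) -> DiscoveryReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        "references": (config.seed + 1) % 2**31,
        "sizes": (config.seed + 2) % 2**31,
        "graph": (config.seed + 3) % 2**31,
        "bootstrap": (config.seed + 4) % 2**31,
        "permutation": (config.seed + 5) % 2**31,
    }

    # ---- inputs: load or simulate -------------------------------------
    simulated = config.matrix_path is None
    truth_diff: set[str] = set()
    if simulated:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
        write_cohort(cohort, outdir / "cohort")
        matrix = cohort.matrix
        lengths: Mapping[str, float] | None = cohort.lengths
        truth_diff = cohort.truth_diff
    else:
        matrix = read_abundance_matrix(config.matrix_path)
        lengths = evio.read_lengths(config.lengths_path) if config.lengths_path else None

    cellline: set[str] | None = None
    plasma_ref: Mapping[str, float] | None = None
    if simulated:
        cellline, plasma_ref = generate_reference_sets(cohort, seed=seeds["references"])
        evio.write_gene_set(cellline, outdir / "cohort" / "cellline_set.txt")
        evio.write_lengths(plasma_ref, outdir / "cohort" / "plasma_ref.tsv")
    if config.cellline_path:
        cellline = evio.read_gene_set(config.cellline_path)
    if config.plasma_ref_path:
        plasma_ref = evio.read_lengths(config.plasma_ref_path)

    # ---- QC ------------------------------------------------------------
    qc_dict = None
    if config.sizes_path:
        dist = SizeDistribution(evio.read_sizes(config.sizes_path))
        qc = qc_report(dist, config.total_protein_ug, config.input_plasma_ml)
        qc_dict = qc.to_dict()
    elif simulated:
        dist = generate_particle_sizes(seed=seeds["sizes"])
        qc = qc_report(dist, total_protein_ug=75.0, input_plasma_ml=1.0)
        qc_dict = qc.to_dict()
    if qc_dict is not None:
        (outdir / "qc.json").write_text(json.dumps(qc_dict, indent=2, sort_keys=True))

    # ---- partition -----------------------------------------------------
    log_matrix = log2_transform(matrix)
    part = partition_by_abundance(log_matrix, cutoff=config.log2_cutoff)
    partition_dict = {"cutoff": config.log2_cutoff, "n_high": part.n_high, "n_low": part.n_low}

    # ---- differential + cascade ---------------------------------------
    records = differential_table(matrix)
    write_differential_table(records, outdir / "differential.tsv")
    cascade = apply_filter_cascade(records, config.filter)
    evio.write_gmt(
        {f"tier_{t:g}": genes for t, genes in cascade.tiers.items()},
        outdir / "tiers.gmt",
    )
    n_sig = sum(1 for r in records if r.p_value < config.filter.alpha)
    differential_dict = {
        "alpha": config.filter.alpha,
        "n_significant": n_sig,
        "tier_counts": {f"{t:g}": len(g) for t, g in cascade.tiers.items()},
        "tier_exclusive_counts": {f"{t:g}": c for t, c in cascade.exclusive_counts.items()},
    }

    # ---- integration ----------------------------------------------------
    case_identified = matrix.detected_genes(CASE)
    ctrl_identified = matrix.detected_genes(CTRL)
    venn = venn_partition(case_identified, ctrl_identified)
    integration_dict: dict = {
        "n_total_identified": len(matrix.detected_genes()),
        "n_case_identified": len(case_identified),
        "n_ctrl_identified": len(ctrl_identified),
        "venn": {
            "only_case": len(venn.only_a),
            "shared": len(venn.shared),
            "only_ctrl": len(venn.only_b),
        },
    }
    if cellline and case_identified:
        count, pct = intersect_with_reference(case_identified, cellline)
        integration_dict["cellline_overlap"] = {"count": count, "percent": pct}
        low_case = {g for g in case_identified if g in part.low}
        if low_case:
            count_low, pct_low = intersect_with_reference(low_case, cellline)
            integration_dict["cellline_overlap_low_abundance"] = {
                "query_size": len(low_case),
                "count": count_low,
                "percent": pct_low,
            }
    if plasma_ref and case_identified:
        count, pct = novel_vs_reference(case_identified, set(plasma_ref))
        integration_dict["novel_vs_plasma"] = {"count": count, "percent": pct}
    (outdir / "integration.json").write_text(json.dumps(integration_dict, indent=2, sort_keys=True))

    # ---- NSAF enrichment of the top tier --------------------------------
    nsaf_dict = None
    top_tier = config.filter.fold_tiers[-1]
    tier_genes = sorted(cascade.tiers[top_tier])
    if plasma_ref is not None and tier_genes:
        nsaf = compute_nsaf(matrix, lengths)
        ev_case_means = nsaf.sample_means(matrix.case_samples)
        ev_map = {g: float(ev_case_means[g]) for g in tier_genes}
        plasma_map = _plasma_nsaf(plasma_ref, lengths)
        enr_records, n_above = nsaf_enrichment(ev_map, plasma_map, config.nsaf_threshold)
        nsaf_dict = {
            "threshold": config.nsaf_threshold,
            "tier": top_tier,
            "n_evaluated": len(enr_records),
            "n_above_threshold": n_above,
            "n_ev_only": sum(1 for r in enr_records if r.ev_only),
        }

    # ---- clustering -----------------------------------------------------
    dist = pearson_distance_matrix(log_matrix, axis="samples")
    dend = ward_linkage(dist)
    (outdir / "samples.newick").write_text(to_newick(dend) + "\n")
    assignment = cut_tree(dend, config.cluster_k)
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("sample\tcluster\n")
        for s in matrix.samples:
            fh.write(f"{s}\t{assignment[s]}\n")
    labels_true = [matrix.groups[s] for s in matrix.samples]
    labels_pred = [assignment[s] for s in matrix.samples]
    clustering_dict = {
        "k": config.cluster_k,
        "rand_index": float(
            rand_score([1 if l == CASE else 0 for l in labels_true], labels_pred)
        ),
        "linkage": dend.linkage_method,
        "distance": dend.distance_method,
    }

    # ---- markers + panel -------------------------------------------------
    markers_dict = None
    if config.markers is not None:
        selected = list(config.markers)
    else:
        by_auc = sorted(
            (r for r in records if r.gene in cascade.tiers[top_tier]),
            key=lambda r: (-r.auc, r.gene),
        )
        selected = [r.gene for r in by_auc[: config.n_markers]]
    if selected:
        per_marker = {}
        for gene in selected:
            roc = roc_result(matrix.values_for(gene, CASE), matrix.values_for(gene, CTRL), gene)
            per_marker[gene] = roc.auc
            np.savetxt(
                outdir / f"roc_{gene}.tsv",
                np.column_stack([roc.thresholds, roc.fpr, roc.tpr]),
                delimiter="\t",
                header="threshold\tfpr\ttpr",
                comments="",
            )
        model = fit_panel(matrix, selected)
        roc = panel_auc(model, matrix)
        ci = bootstrap_auc_ci(
            matrix, selected, n_boot=config.n_boot, seed=seeds["bootstrap"]
        )
        (outdir / "panel.json").write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True))
        markers_dict = {
            "selected": selected,
            "auto_selected": config.markers is None,
            "per_marker_auc": per_marker,
            "panel_auc": roc.auc,
            "panel_auc_ci": list(ci),
            "n_boot": config.n_boot,
            "combiner": model.combiner,
            "truth_recovered": sorted(set(selected) & truth_diff) if simulated else None,
        }

    # ---- network ---------------------------------------------------------
    network_dict = None
    if config.graph_path:
        graph = evio.read_edge_list(config.graph_path)
    elif simulated:
        ordered = sorted(truth_diff) + sorted(set(matrix.genes) - truth_diff)
        graph = generate_background_graph(
            n_nodes=len(ordered),
            module_nodes=min(30, len(truth_diff)),
            seed=seeds["graph"],
            node_names=ordered,
        )
        evio.write_edge_list(graph, outdir / "cohort" / "graph.tsv")
    else:
        graph = None
    if graph is not None and tier_genes:
        if config.min_edge_score is not None:
            graph = filter_edges_by_score(graph, config.min_edge_score)
        query = [g for g in tier_genes if g in graph]
        if len(query) >= 3:
            enr = edge_enrichment(graph, query, n_perm=config.n_perm, seed=seeds["permutation"])
            network_dict = enr.to_dict()
            network_dict["clustering_coefficient"] = clustering_coefficient(graph, query)
            if config.annotations_path:
                annotations = evio.read_gmt(config.annotations_path)
                terms = term_enrichment(set(query), annotations, set(graph.nodes))
                network_dict["top_terms"] = [
                    {"term": t.term, "overlap": t.overlap, "p": t.p_value, "q": t.q_value}
                    for t in terms[:10]
                ]

    report = DiscoveryReport(
        qc=qc_dict,
        partition=partition_dict,
        differential=differential_dict,
        integration=integration_dict,
        nsaf=nsaf_dict,
        clustering=clustering_dict,
        markers=markers_dict,
        network=network_dict,
        provenance={
            "seed": config.seed,
            "derived_seeds": seeds,
            "config_hash": _config_hash(config),
            "evpanel_version": __version__,
            "simulated_inputs": simulated,
        },
    )
    (outdir / "summary.json").write_text(report.to_json())
    return report
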