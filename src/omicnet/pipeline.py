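"""End-to-end workflow orchestration.

``run_pipeline`` executes the full multistage analysis: count/metabolite QC
-> differential expression -> per-group PCIT networks (gene and metabolite
layers) -> DE-anchored filtering -> topology and hub calls -> union reference
network -> differential connectivity -> unique targets -> combined-layer
PCIT gene-metabolite pairs -> variance filter -> interaction-model scan ->
route overlap -> optional pathway over-representation. Every intermediate is
written as TSV/SIF under the output directory together with a JSON manifest
of stage counts; outputs are byte-identical across reruns with the same
config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import diffexpr, enrichment, integration, qc, topology
from .matrix import FeatureMatrix, ValidationError, read_feature_matrix, read_phenotype_map
from .pcit import CorrelationNetwork, correlation_matrix, filter_network, pcit_network
from .simulate import SimulationSpec, generate

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds default to the published analysis values."""

    gene_path: str | None = None
    metab_path: str | None = None
    phenotype_path: str | None = None
    sim_spec: SimulationSpec | None = None

    alpha: float = 0.05
    lfc_min: float = 0.5
    r_gene: float = 0.99
    r_metab: float = 0.90
    r_gm: float = 0.75
    rsd_max: float = 0.15
    z_crit: float = 1.96
    variance_drop: float = 0.05
    min_mean_cpm: float = 1.0
    presence_cpm: float = 1.0
    min_presence_fraction: float = 0.5

    reference: str = "NP"
    hub_mode: str = "practical"
    require_de_anchor: bool = True
    metabolite_universe: str = "pre_qc"  # or "qc"
    intlim_genes: str = "de_and_targets"  # or "all"
    intlim_metabolites: str = "de_and_targets"  # or "all"
    external_deg_path: str | None = None
    external_dem_path: str | None = None
    gene_gmt: str | None = None
    metab_gmt: str | None = None

    outdir: str = "omicnet_run"
    seed: int = 0

    def validate(self) -> None:
        for name in ("r_gene", "r_metab", "r_gm"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValidationError(f"alpha={self.alpha} outside (0, 1]")
        if not 0 <= self.variance_drop < 1:
            raise ValidationError("variance_drop outside [0, 1)")
        if self.rsd_max < 0 or self.lfc_min < 0 or self.z_crit < 0:
            raise ValidationError("thresholds must be non-negative")
        if self.hub_mode not in ("practical", "paper"):
            raise ValidationError(f"unknown hub_mode {self.hub_mode!r}")
        if self.metabolite_universe not in ("pre_qc", "qc"):
            raise ValidationError("metabolite_universe must be 'pre_qc' or 'qc'")
        have_files = self.gene_path and self.metab_path and self.phenotype_path
        if not have_files and self.sim_spec is None:
            raise ValidationError("provide input paths or a simulation spec")

    def config_hash(self) -> str:
        # outdir does not affect the analysis; keep hashes comparable across runs
        payload = {
            k: v for k, v in asdict(self).items() if k not in ("sim_spec", "outdir")
        }
        if self.sim_spec is not None:
            payload["sim_spec"] = repr(self.sim_spec)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the manifest dict (also written as JSON).

    In-memory stage results are attached under the ``"results"`` key (not
    serialized). A failing stage aborts the run: the partial manifest, with
    the failing stage named under ``"error"``, is still written before the
    exception propagates.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}, "seed": config.seed}
    try:
        _execute(config, out, manifest)
    except Exception as exc:
        manifest["error"] = {
            "stage": manifest.pop("_current_stage", "input"),
            "message": str(exc),
        }
        _write_manifest(manifest, out)
        raise
    manifest.pop("_current_stage", None)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(
            {k: v for k, v in manifest.items() if k != "results"},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def _execute(config: PipelineConfig, out: Path, manifest: dict) -> None:
    stages = manifest["stages"]
    results: dict = {}
    manifest["_current_stage"] = "input"

    # ---- stage 1: inputs -------------------------------------------------
    if config.sim_spec is not None:
        spec = config.sim_spec
        genes_raw, metab_raw, truth = generate(spec)
        results["truth"] = truth
        _write(
            pd.DataFrame(
                sorted(truth.de_features.items()), columns=["feature_id", "log2fc"]
            ),
            out / "truth_de.tsv",
        )
        _write(
            pd.DataFrame(
                sorted(truth.rewired_nodes.items()), columns=["feature_id", "gated_group"]
            ),
            out / "truth_rewired.tsv",
        )
        _write(
            pd.DataFrame(
                [(p.gene, p.metabolite, p.b2, p.b4) for p in truth.gm_pairs],
                columns=["gene_id", "metabolite_id", "b2", "b4"],
            ),
            out / "truth_gm_pairs.tsv",
        )
    else:
        pheno = read_phenotype_map(config.phenotype_path)
        genes_raw = read_feature_matrix(config.gene_path, "gene", pheno, config.reference)
        metab_raw = read_feature_matrix(
            config.metab_path, "metabolite", pheno, config.reference
        )
    groups = genes_raw.groups  # reference first
    ref, other = groups
    stages["input"] = {
        "n_genes": genes_raw.n_features,
        "n_metabolites": metab_raw.n_features,
        "n_samples": genes_raw.n_samples,
    }

    manifest["_current_stage"] = "qc"
    # ---- stage 2: QC -----------------------------------------------------
    genes_f, gene_report = qc.filter_counts(
        genes_raw,
        min_mean_cpm=config.min_mean_cpm,
        presence_cpm=config.presence_cpm,
        min_presence_fraction=config.min_presence_fraction,
    )
    gene_report.write(out / "gene_filter_report.tsv")
    gene_log = qc.log2_cpm(genes_f)
    gene_log.write(out / "genes_log2cpm.tsv")

    metab_log, metab_report = qc.metabolite_qc(metab_raw, rsd_max=config.rsd_max)
    metab_report.write(out / "metabolite_filter_report.tsv")
    stages["qc"] = {
        "genes_retained": gene_report.n_retained,
        "metabolites_retained_union": metab_report.n_retained,
        "metabolites_retained_per_group": {
            g: len(ids) for g, ids in metab_report.group_retained_ids.items()
        },
    }

    manifest["_current_stage"] = "de"
    # ---- stage 3: differential expression --------------------------------
    de_table = diffexpr.differential_test(genes_f, config.alpha, config.lfc_min)
    diffexpr.write_table(de_table, out / "de_genes.tsv")
    if config.external_deg_path:
        degs = diffexpr.load_external_calls(
            config.external_deg_path, set(genes_f.feature_ids)
        )
    else:
        degs = diffexpr.call_significant(de_table, config.alpha, config.lfc_min)

    # metabolite DE runs on the full log-normalized table; the RSD filter is a
    # stability criterion for the co-expression networks, not for DE calling
    dem_table = diffexpr.differential_test(
        qc.log_normalize(metab_raw), config.alpha, config.lfc_min, transform="log2"
    )
    diffexpr.write_table(dem_table, out / "de_metabolites.tsv")
    if config.external_dem_path:
        dems = diffexpr.load_external_calls(
            config.external_dem_path, set(metab_raw.feature_ids)
        )
    else:
        dems = diffexpr.call_significant(dem_table, config.alpha, config.lfc_min)
    stages["de"] = {"n_degs": len(degs), "n_dems": len(dems)}

    manifest["_current_stage"] = "networks"
    # ---- stage 4: per-group PCIT networks + filtering + topology ---------
    nets: dict[tuple[str, str], CorrelationNetwork] = {}
    hubs: dict[tuple[str, str], set[str]] = {}
    for layer, matrix, de_set, r_min in (
        ("gene", gene_log, degs, config.r_gene),
        ("metabolite", metab_log, dems, config.r_metab),
    ):
        for group in groups:
            mat = matrix
            if layer == "metabolite":
                keep = metab_report.group_retained_ids[group]
                mat = matrix.subset_features(
                    [f for f in matrix.feature_ids if f in set(keep)]
                )
            corr = correlation_matrix(mat, group)
            raw_net = pcit_network(corr, kinds=layer, group=group, layer=layer)
            net = filter_network(
                raw_net, de_set, r_min, require_de=config.require_de_anchor
            )
            nets[(layer, group)] = net
            tag = f"{layer}_{group.replace('-', '')}"
            net.write_tsv(out / f"network_{tag}.tsv")
            net.write_sif(out / f"network_{tag}.sif")
            topo = topology.topology_table(net)
            _write(topo, out / f"topology_{tag}.tsv")
            hubs[(layer, group)] = topology.call_hubs(topo, mode=config.hub_mode)
            stages.setdefault("networks", {})[tag] = {
                "n_pcit_pairs": int(raw_net.edges["significant"].sum()),
                "n_edges_filtered": net.n_edges,
                "n_nodes": len(net.connected_nodes()),
                "n_hubs": len(hubs[(layer, group)]),
            }

    manifest["_current_stage"] = "diffconn"
    # ---- stage 5: union reference networks + differential connectivity ---
    targets = {g: integration.TargetSet(group=g) for g in groups}
    for layer in ("gene", "metabolite"):
        net_ref, net_other = nets[(layer, ref)], nets[(layer, other)]
        u_nodes, u_edges = topology.union_reference_network(net_ref, net_other)
        _write(u_nodes, out / f"union_{layer}_nodes.tsv")
        _write(u_edges, out / f"union_{layer}_edges.tsv")
        topology.write_union_sif(u_edges, out / f"union_{layer}.sif")
        dc = topology.differential_connectivity(net_ref, net_other, config.z_crit)
        _write(dc, out / f"diffconn_{layer}.tsv")
        stages.setdefault("diffconn", {})[layer] = {
            "n_union_nodes": len(u_nodes),
            "n_union_edges": len(u_edges),
            "n_gain": int((dc["call"] == "gain").sum()),
            "n_loss": int((dc["call"] == "loss").sum()),
        }
        # gain = more connected in the reference network
        gain = set(dc.loc[dc["call"] == "gain", "node_id"])
        loss = set(dc.loc[dc["call"] == "loss", "node_id"])
        targets[ref].hubs |= hubs[(layer, ref)]
        targets[other].hubs |= hubs[(layer, other)]
        targets[ref].differentially_connected |= gain
        targets[other].differentially_connected |= loss

    excl_ref, excl_other, shared = integration.unique_targets(
        targets[ref], targets[other]
    )
    exclusive = {ref: excl_ref, other: excl_other}
    for g in groups:
        _write(targets[g].provenance(), out / f"targets_{g.replace('-', '')}.tsv")
    stages["targets"] = {
        "n_ref": len(targets[ref].members),
        "n_other": len(targets[other].members),
        "n_shared": len(shared),
        "n_exclusive_ref": len(excl_ref),
        "n_exclusive_other": len(excl_other),
    }

    manifest["_current_stage"] = "pcit_pairs"
    # ---- stage 6: combined-layer PCIT gene-metabolite pairs --------------
    if config.metabolite_universe == "pre_qc":
        metab_int = qc.log_normalize(metab_raw)
    else:
        metab_int = metab_log
    pcit_pairs_by_group = {}
    for group in groups:
        cross = integration.combined_pcit_network(gene_log, metab_int, group)
        pairs = integration.select_gm_pairs(cross, exclusive[group], config.r_gm)
        pcit_pairs_by_group[group] = pairs
        _write(pairs, out / f"gm_pairs_pcit_{group.replace('-', '')}.tsv")
    pcit_pairs = pd.concat(pcit_pairs_by_group.values(), ignore_index=True)
    stages["pcit_pairs"] = {
        g.replace("-", ""): len(p) for g, p in pcit_pairs_by_group.items()
    }

    manifest["_current_stage"] = "intlim"
    # ---- stage 7: interaction-model scan ---------------------------------
    if config.intlim_genes == "de_and_targets":
        net_genes = set()
        for group in groups:
            net_genes |= nets[("gene", group)].connected_nodes()
        gene_univ = sorted(
            (degs | net_genes | {t for t in targets[ref].members | targets[other].members})
            & set(gene_log.feature_ids)
        )
    else:
        gene_univ = gene_log.feature_ids
    if config.intlim_metabolites == "de_and_targets":
        net_metabs = set()
        for group in groups:
            net_metabs |= nets[("metabolite", group)].connected_nodes()
        metab_univ = sorted(
            (dems | net_metabs | (targets[ref].members | targets[other].members))
            & set(metab_int.feature_ids)
        )
    else:
        metab_univ = metab_int.feature_ids
    gene_candidates = (
        integration.variance_filter(
            gene_log.subset_features(gene_univ), config.variance_drop
        )
        if gene_univ
        else gene_log.subset_features([])
    )
    intlim = integration.intlim_scan(
        gene_candidates,
        metab_int,
        gene_ids=gene_candidates.feature_ids,
        metab_ids=metab_univ,
        alpha=config.alpha,
    )
    _write(intlim, out / "gm_pairs_intlim.tsv")
    stages["intlim"] = {
        "n_candidate_genes": gene_candidates.n_features,
        "n_candidate_metabolites": len(metab_univ),
        "n_pairs_tested": len(intlim),
        "n_significant": int(intlim["significant"].sum()),
    }

    manifest["_current_stage"] = "overlap"
    # ---- stage 8: route overlap ------------------------------------------
    overlap = integration.overlap_pairs(pcit_pairs, intlim)
    _write(overlap, out / "gm_pairs_overlap.tsv")
    stages["overlap"] = {"n_pairs": len(overlap)}

    manifest["_current_stage"] = "enrichment"
    # ---- stage 9: optional enrichment ------------------------------------
    if config.gene_gmt:
        annot = enrichment.read_gmt(config.gene_gmt, universe=genes_f.feature_ids)
        for group in groups:
            query = (targets[group].members | degs) & set(genes_f.feature_ids)
            if query:
                ora = enrichment.hypergeometric_ora(query, annot, config.alpha)
                _write(ora, out / f"ora_genes_{group.replace('-', '')}.tsv")
                stages.setdefault("ora", {})[group.replace("-", "")] = int(
                    ora["significant"].sum()
                )
        if config.metab_gmt and len(overlap):
            mannot = enrichment.read_gmt(
                config.metab_gmt, universe=metab_raw.feature_ids
            )
            joint = enrichment.joint_pathway(
                set(overlap["gene_id"]), set(overlap["metabolite_id"]), annot, mannot,
                config.alpha,
            )
            _write(joint, out / "joint_pathway.tsv")
            stages["joint_pathway"] = {"n_significant": int(joint["significant"].sum())}

    results.update(
        {
            "genes_filtered": genes_f,
            "gene_log": gene_log,
            "metab_log": metab_log,
            "de_table": de_table,
            "dem_table": dem_table,
            "degs": degs,
            "dems": dems,
            "networks": nets,
            "hubs": hubs,
            "targets": targets,
            "exclusive": exclusive,
            "pcit_pairs": pcit_pairs,
            "intlim": intlim,
            "overlap": overlap,
        }
    )
    manifest["results"] = results
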