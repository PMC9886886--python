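"""End-to-end orchestration of the network → modules → classification →
infiltration → enrichment pipeline from a single YAML config.

Stages run in a fixed order, each writing its tables into the run
directory; a JSON manifest records input hashes, parameters, package
version and the seed, so a rerun with identical inputs reproduces
byte-identical tables.  The global seed fans out to per-stage seeds by a
stable SeedSequence derivation, keeping stages individually re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, data_io
from .consensus import assign_and_validate, consensus_cluster
from .enrichment import ora
from .modules import mcl_cluster, score_modules, select_top
from .neighbors import compare_groups, extract_neighbor_network, group_coexpression_values
from .network import annotate_categories, build_coexpression_edges, categorize, intersect_with_ppi, log2_transform
from .ssgsea import differential_scores, gene_score_correlation, ssgsea

log = logging.getLogger(__name__)

STAGES = ("build-network", "categorize", "pdnc", "modules", "consensus", "ssgsea", "enrich")

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and resampling parameters of a full run."""

    expression: str
    groups: str
    ppi: str
    pd_genes: str
    immune_genes: str
    signatures: str
    output_dir: str
    annotation: str | None = None
    universe: str | None = None
    validation_expression: str | None = None
    validation_groups: str | None = None
    log2: bool = False
    pseudocount: float = 0.0
    r_min: float = 0.7
    q_max: float = 0.05
    core_categories: tuple[str, ...] = ("PD", "immune-PD")
    min_core: int = 6
    top_k: int = 5
    inflation: float = 2.0
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    consensus_k: int = 2
    n_resamples: int = 1000
    item_frac: float = 0.8
    alpha: float = 0.25
    p_max: float = 0.05
    min_overlap: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("core_categories", "k_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        required = {
            "expression": self.expression,
            "groups": self.groups,
            "ppi": self.ppi,
            "pd_genes": self.pd_genes,
            "immune_genes": self.immune_genes,
            "signatures": self.signatures,
        }
        optional = {
            "annotation": self.annotation,
            "universe": self.universe,
            "validation_expression": self.validation_expression,
            "validation_groups": self.validation_groups,
        }
        for name, p in required.items():
            if not Path(p).is_file():
                raise FileNotFoundError(f"config field {name!r}: no such file: {p}")
        for name, p in optional.items():
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"config field {name!r}: no such file: {p}")

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed below 2^31 derived from the global seed."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory containing the manifest."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    groups = data_io.read_groups_tsv(config.groups)
    em = data_io.read_expression_tsv(config.expression, groups)
    if config.log2:
        em = log2_transform(em, config.pseudocount)
    ppi = data_io.read_edge_list(config.ppi)
    pd_genes = data_io.read_gene_list(config.pd_genes)
    immune_genes = data_io.read_gene_list(config.immune_genes)
    signatures = data_io.read_gmt(config.signatures)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "inputs": {
            name: _sha256(p)
            for name, p in (
                ("expression", config.expression),
                ("groups", config.groups),
                ("ppi", config.ppi),
                ("pd_genes", config.pd_genes),
                ("immune_genes", config.immune_genes),
                ("signatures", config.signatures),
            )
        },
        "stages": [],
    }

    def done(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        log.info("stage %s complete: %s", stage, info)

    try:
        coexpr = build_coexpression_edges(em, config.r_min, config.q_max)
        net = intersect_with_ppi(coexpr, ppi)
        coexpr.to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
        done("build-network", coexpr_edges=len(coexpr), common_nodes=net.number_of_nodes(),
             common_edges=net.number_of_edges())

        categories, counts = categorize(net.nodes, pd_genes, immune_genes)
        annotate_categories(net, categories)
        data_io.write_network(net, out / "common_network.graphml", "graphml")
        data_io.write_network(net, out / "common_network.sif", "sif")
        data_io.write_category_tsv(categories, out / "categories.tsv")
        done("categorize", counts=dict(counts))

        nn = extract_neighbor_network(net, categories, config.core_categories)
        data_io.write_network(nn.graph, out / "pdnc.graphml", "graphml")
        grouped = group_coexpression_values(nn)
        if sum(len(v) for v in grouped.values()) > 0 and len(grouped) >= 2:
            table, cdfs = compare_groups(grouped)
            table.to_csv(out / "pdnc_group_tests.tsv", sep="\t", index=False)
            cdf_rows = [
                (cat, float(xv), float(fv))
                for cat, cdf in cdfs.items()
                for xv, fv in zip(cdf.support, cdf.fractions)
            ]
            pd.DataFrame(cdf_rows, columns=["category", "r", "cdf"]).to_csv(
                out / "pdnc_cdf.tsv", sep="\t", index=False
            )
        done("pdnc", cores=len(nn.core_nodes), neighbors=len(nn.neighbor_nodes),
             edges=nn.graph.number_of_edges())

        if net.number_of_nodes() > 0:
            clusters = mcl_cluster(net, inflation=config.inflation)
        else:
            clusters = []
        mods = score_modules(clusters, categories, net, config.min_core)
        top, pooled = select_top(mods, config.top_k)
        score_rows = [
            (i + 1, len(m.members), m.core_count, m.density, m.score, ",".join(m.members))
            for i, m in enumerate(mods)
        ]
        pd.DataFrame(
            score_rows, columns=["rank", "size", "core_count", "density", "score", "members"]
        ).to_csv(out / "module_scores.tsv", sep="\t", index=False)
        for i, m in enumerate(top):
            data_io.write_gene_list(m.members, out / f"module_{i + 1}_genes.txt")
        data_io.write_gene_list(pooled, out / "module_all_genes.txt")
        done("modules", clusters=len(clusters), modules=len(mods), selected=len(top),
             pooled_genes=len(pooled))

        cc_summary: dict = {}
        if pooled and len(em.subset_genes(pooled).values) > 0:
            cc = consensus_cluster(
                em.subset_genes(pooled), config.k_range, config.n_resamples,
                config.item_frac, seed=config.stage_seed("consensus"),
            )
            for k, mat in cc.matrices.items():
                pd.DataFrame(mat, index=cc.sample_ids, columns=cc.sample_ids).to_csv(
                    out / f"consensus_K{k}.tsv", sep="\t"
                )
            pd.DataFrame(
                {"K": list(cc.areas), "area": list(cc.areas.values()),
                 "delta_area": [cc.delta_areas[k] for k in cc.areas]}
            ).to_csv(out / "consensus_cdf_area.tsv", sep="\t", index=False)
            cc_summary = {"chosen_k": cc.chosen_k}
            if config.validation_expression:
                vgroups = data_io.read_groups_tsv(config.validation_groups)
                vem = data_io.read_expression_tsv(config.validation_expression, vgroups)
                val = assign_and_validate(
                    em, vem, sorted(pooled), config.consensus_k,
                    n_resamples=config.n_resamples, item_frac=config.item_frac,
                    seed=config.stage_seed("consensus"),
                )
                cc_summary["train_ari"] = val["cohorts"]["train"]["ari"]
                cc_summary["test_ari"] = val["cohorts"]["test"]["ari"]
        done("consensus", **cc_summary)

        scores = ssgsea(em, signatures, alpha=config.alpha, normalize=True)
        scores.to_csv(out / "ssgsea_scores.tsv", sep="\t")
        diff = differential_scores(scores, em.groups)
        diff.to_csv(out / "ssgsea_differential.tsv", sep="\t")
        significant = [s for s in diff.index if diff.loc[s, "q"] < 0.05]
        if pooled and significant:
            r, p, tier = gene_score_correlation(
                em.subset_genes(pooled), scores[significant]
            )
            r.to_csv(out / "gene_cell_correlation_r.tsv", sep="\t")
            tier.to_csv(out / "gene_cell_correlation_tier.tsv", sep="\t")
        done("ssgsea", n_sets=scores.shape[1], n_significant=len(significant))

        enr_info: dict = {}
        if config.annotation and config.universe and pooled:
            annotation = data_io.read_gmt(config.annotation)
            universe = data_io.read_gene_list(config.universe)
            table = ora(pooled, annotation, universe, config.p_max, config.min_overlap)
            table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            enr_info["terms_retained"] = len(table)
        done("enrich", **enr_info)
    except Exception as exc:
        stage = STAGES[len(manifest["stages"])] if len(manifest["stages"]) < len(STAGES) else "?"
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
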