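"""End-to-end orchestration: QC -> networks -> rewiring -> pathway scores.

A :class:`PipelineConfig` (loadable from YAML) collects all file paths
and thresholds.  :func:`run_all` executes the stages in order and writes
deterministic, machine-readable outputs (TSV/JSON) plus a run manifest.
All randomness flows from a single root seed; per-purpose child seeds
are derived by hashing stable token strings into the seed sequence so
that adding a stage never perturbs earlier stages' random streams.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import ExpressionDataset, differential_expression, remove_outlier_samples
from .network import build_network, topology_summary
from .pathways import GeneSetCollection, crosstalk_frequency, ipc_clusters, score_pathways
from .rewiring import (differential_correlation_strength, edge_rewiring,
                       flag_rewired, permutation_dc_test, select_disease_genes)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "child_seed"]


def child_seed(root: int, *tokens: str) -> int:
    """Deterministic child seed for one purpose, derived from the root seed."""
    h = zlib.crc32("/".join(tokens).encode())
    return int(np.random.SeedSequence([root, h]).generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    expression_path: str
    sample_path: str
    gmt_path: str | None = None
    signalling_tags_path: str | None = None
    control_stage: str = "N"
    disease_stages: list[str] = field(default_factory=list)
    r_min: float = 0.5
    fdr_max: float = 0.05
    de_lfc: float = 1.0
    de_alpha: float = 0.05
    dc_alpha: float = 0.01
    dc_select_alpha: float = 0.05
    eg_threshold: int | str = 70
    fisher_alpha: float = 0.05
    enrich_alpha: float = 0.05
    outlier_z_cut: float = -2.5
    permutations: int = 1000
    seed: int = 0
    out_dir: str = "rewirenet_out"

    def validate(self) -> None:
        if self.control_stage in self.disease_stages:
            raise ValueError("control stage listed among disease stages")
        for name, lo, hi, v in [("r_min", 0, 1, self.r_min),
                                ("fdr_max", 0, 1, self.fdr_max),
                                ("de_alpha", 0, 1, self.de_alpha),
                                ("dc_alpha", 0, 1, self.dc_alpha),
                                ("dc_select_alpha", 0, 1, self.dc_select_alpha),
                                ("fisher_alpha", 0, 1, self.fisher_alpha),
                                ("enrich_alpha", 0, 1, self.enrich_alpha)]:
            if not (lo <= v <= hi):
                raise ValueError(f"{name} = {v} outside [{lo}, {hi}]")
        if self.permutations < 100:
            raise ValueError("need at least 100 permutations")
        for p in [self.expression_path, self.sample_path, self.gmt_path,
                  self.signalling_tags_path]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline and return the run manifest (also written to JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: v for k, v in asdict(config).items()},
                      "stages": {}, "status": "RUNNING"}
    t0 = time.time()
    try:
        data = ExpressionDataset.from_tsv(config.expression_path, config.sample_path,
                                          config.control_stage)
        disease_stages = config.disease_stages or data.disease_stages

        data, qc_report = remove_outlier_samples(data, z_cut=config.outlier_z_cut)
        qc_report.to_csv(out / "qc_samples.tsv", sep="\t", index=False)
        manifest["samples_after_qc"] = {s: len(data.stage_samples(s)) for s in data.stages}

        networks = {}
        topo_rows = []
        for stage in [config.control_stage, *disease_stages]:
            net = build_network(data, stage, r_min=config.r_min, fdr_max=config.fdr_max)
            networks[stage] = net
            net.edge_list().to_csv(out / f"edges_{stage}.tsv", sep="\t", index=False)
            topo_rows.append(topology_summary(net).to_dict())
        with open(out / "topology.json", "w") as fh:
            json.dump(topo_rows, fh, indent=2)

        collection = None
        if config.gmt_path:
            collection = GeneSetCollection.from_gmt(config.gmt_path, data.genes)
        tags = None
        if config.signalling_tags_path:
            tags = [l.strip() for l in open(config.signalling_tags_path) if l.strip()]

        control_net = networks[config.control_stage]
        for stage in disease_stages:
            t_stage = time.time()
            de = differential_expression(data, stage, lfc_cut=config.de_lfc,
                                         alpha=config.de_alpha)
            de.to_csv(out / f"de_{stage}.tsv", sep="\t", index=False)

            dc = permutation_dc_test(data, config.control_stage, stage,
                                     t=config.permutations,
                                     seed=child_seed(config.seed, "perm", stage),
                                     dc_alpha=config.dc_alpha,
                                     r_min=config.r_min, fdr_max=config.fdr_max)
            dc.to_csv(out / f"dc_{stage}.tsv", sep="\t", index=False)

            rw = edge_rewiring(control_net, networks[stage])
            rw = flag_rewired(rw, dc, dc_select_alpha=config.dc_select_alpha,
                              eg_threshold=config.eg_threshold)
            rw.to_csv(out / f"rewiring_{stage}.tsv", sep="\t", index=False)

            zeta = select_disease_genes(rw, de, stage)
            zeta.to_frame().to_csv(out / f"disease_genes_{stage}.tsv", sep="\t", index=False)
            with open(out / f"disease_genes_{stage}.txt", "w") as fh:
                fh.write("\n".join(sorted(zeta.genes)) + "\n")

            values, hist = differential_correlation_strength(control_net, networks[stage], zeta)
            hist.to_csv(out / f"diff_correlation_hist_{stage}.tsv", sep="\t", index=False)

            stage_manifest = {
                "n_edges": networks[stage].n_edges,
                "n_de": int((de["flag"] != "neutral").sum()),
                "n_dc_significant": int(dc["significant"].sum()),
                "n_rewired": int(rw["rewired"].sum()),
                "n_disease_genes": len(zeta),
                "fraction_rewired_not_de": zeta.fraction_rewired_not_de,
                "eg_threshold_used": rw.attrs.get("eg_threshold"),
            }
            if collection is not None and len(zeta):
                scores, graph = score_pathways(zeta, collection, networks[stage],
                                               control_net,
                                               enrich_alpha=config.enrich_alpha,
                                               fisher_alpha=config.fisher_alpha,
                                               signalling_tags=tags)
                scores.to_csv(out / f"pathway_scores_{stage}.tsv", sep="\t", index=False)
                graph.edges.to_csv(out / f"crosstalk_edges_{stage}.tsv", sep="\t", index=False)
                cf = crosstalk_frequency(graph)
                cf.rename_axis("gene_id").reset_index().to_csv(
                    out / f"crosstalk_frequency_{stage}.tsv", sep="\t", index=False)
                ipc = ipc_clusters(graph, networks[stage])
                ipc.to_json(out / f"ipc_{stage}.json", orient="records", indent=2)
                stage_manifest["n_enriched_pathways"] = int(scores["enriched"].sum())
            stage_manifest["wall_time_s"] = round(time.time() - t_stage, 2)
            manifest["stages"][stage] = stage_manifest
        manifest["status"] = "OK"
    except Exception as exc:  # record failure, keep partial outputs
        manifest["status"] = "FAILED"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    manifest["wall_time_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
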