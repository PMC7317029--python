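"""End-to-end pipeline driver.

A single YAML config names every input file and all stage parameters; a master
seed deterministically derives one seed per stage (stage_seed =
master_seed + STAGE_OFFSETS[stage], documented below), so a rerun with the
same config reproduces identical output hashes for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, enrichment, expression, hit_calling, network, qc
from . import score_db as sdb
from . import tracks as trk
from .categories import NETWORK_SEED_CATEGORIES
from .exceptions import InvalidArgumentError

log = logging.getLogger("clonescreen.pipeline")

#: Fixed per-stage seed offsets (the declared seed-splitting rule).
STAGE_OFFSETS = {"qc": 101, "cluster_lines": 211, "cluster_categories": 223,
                 "network": 307, "de": 401}

STAGE_ORDER = ["aggregate", "qc", "hits", "cluster_lines",
               "cluster_categories", "network", "tracks", "de"]

#: Input files each stage requires (config keys).
STAGE_INPUTS = {
    "aggregate": ["scores"],
    "qc": ["scores"],
    "hits": ["scores"],
    "cluster_lines": ["scores"],
    "cluster_categories": ["scores"],
    "network": ["scores", "edges"],
    "tracks": ["tracks"],
    "de": ["expr", "samples"],
}


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    scores: str | None = None
    edges: str | None = None
    tracks: str | None = None
    expr: str | None = None
    samples: str | None = None
    annotation: str | None = None
    stages: list = field(default_factory=lambda: list(STAGE_ORDER))
    scale: tuple = sdb.DEFAULT_SCALE
    hit_categories: tuple = NETWORK_SEED_CATEGORIES
    quantile_method: str = "linear"
    qc_n_perm: int = 1000
    qc_alpha: float = 0.05
    cluster_k_min: int = 2
    cluster_k_max: int = 10
    consensus_k_min: int = 2
    consensus_k_max: int = 6
    consensus_resamples: int = 200
    consensus_subsample: float = 0.8
    mcode_vwp: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    mcode_fluff_density: float = 0.2
    de_p: float = 0.01
    de_fc: float = 1.5
    track_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.scale = tuple(cfg.scale)
        cfg.hit_categories = tuple(cfg.hit_categories)
        return cfg

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGE_ORDER]
        if bad:
            raise InvalidArgumentError(f"unknown stages: {bad}")
        for stage in self.stages:
            for key in STAGE_INPUTS[stage]:
                path = getattr(self, key)
                if path is None or not Path(path).exists():
                    raise InvalidArgumentError(
                        f"stage {stage!r} requires input {key!r} "
                        f"({path!r} missing)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    stages = [s for s in STAGE_ORDER if s in config.stages]

    table = matrix = hit_table = None
    for stage in stages:
        t0 = time.monotonic()
        log.info("stage %s: start", stage)
        try:
            outputs = {}
            seed = config.seed + STAGE_OFFSETS.get(stage, 0)
            if stage == "aggregate":
                table = sdb.read_scores(config.scores, scale=config.scale)
                matrix = sdb.aggregate(table)
                path = out_dir / "matrix.tsv"
                sdb.write_matrix(matrix, path)
                outputs["matrix"] = path
            elif stage == "qc":
                table = table or sdb.read_scores(config.scores, scale=config.scale)
                matrix = matrix or sdb.aggregate(table)
                agr = qc.scorer_agreement(table)
                rep = qc.rnai_pair_concordance(matrix, n_perm=config.qc_n_perm,
                                               alpha=config.qc_alpha, seed=seed)
                p1 = out_dir / "scorer_agreement.tsv"
                agr.to_csv(p1, sep="\t", index=False)
                p2 = out_dir / "concordance.tsv"
                rep.table.to_csv(p2, sep="\t", index=False)
                (out_dir / "concordance_summary.json").write_text(json.dumps({
                    "n_genes_two_lines": rep.n_genes_two_lines,
                    "n_concordant": rep.n_concordant,
                    "fraction": rep.fraction}, indent=2))
                outputs.update(scorer_agreement=p1, concordance=p2,
                               concordance_summary=out_dir / "concordance_summary.json")
            elif stage == "hits":
                table = table or sdb.read_scores(config.scores, scale=config.scale)
                matrix = matrix or sdb.aggregate(table)
                hit_table = hit_calling.call_hits(
                    matrix, quantile_method=config.quantile_method)
                p1 = out_dir / "hits.tsv"
                hit_table.to_frame().to_csv(p1, sep="\t", index=False)
                p2 = out_dir / "hit_counts.tsv"
                hit_table.counts().to_csv(p2, sep="\t", index=False)
                outputs.update(hits=p1, hit_counts=p2)
            elif stage == "cluster_lines":
                table = table or sdb.read_scores(config.scores, scale=config.scale)
                matrix = matrix or sdb.aggregate(table)
                scaled, _ = clustering.row_scale(matrix.matrix)
                k, curve = clustering.select_k(
                    scaled, config.cluster_k_min,
                    min(config.cluster_k_max, len(scaled) - 1), seed=seed)
                res = clustering.hierarchical(scaled, k)
                p1 = out_dir / "line_clusters.tsv"
                pd.DataFrame({"line_id": res.labels.index,
                              "cluster": res.labels.values}).to_csv(
                    p1, sep="\t", index=False)
                p2 = out_dir / "line_cluster_heatmap.tsv"
                scaled.loc[res.leaf_order].to_csv(p2, sep="\t")
                p3 = out_dir / "line_cluster_bic.tsv"
                curve.rename_axis("k").to_csv(p3, sep="\t")
                outputs.update(clusters=p1, heatmap=p2, bic=p3)
            elif stage == "cluster_categories":
                table = table or sdb.read_scores(config.scores, scale=config.scale)
                matrix = matrix or sdb.aggregate(table)
                res = clustering.consensus(
                    matrix.matrix.T, k_min=config.consensus_k_min,
                    k_max=config.consensus_k_max,
                    n_resamples=config.consensus_resamples,
                    subsample_frac=config.consensus_subsample, seed=seed)
                p1 = out_dir / "category_clusters.tsv"
                pd.DataFrame({"category": res.labels.index,
                              "cluster": res.labels.values}).to_csv(
                    p1, sep="\t", index=False)
                p2 = out_dir / "category_consensus.tsv"
                res.consensus[res.k].to_csv(p2, sep="\t")
                outputs.update(clusters=p1, consensus=p2)
            elif stage == "network":
                table = table or sdb.read_scores(config.scores, scale=config.scale)
                matrix = matrix or sdb.aggregate(table)
                if hit_table is None:
                    hit_table = hit_calling.call_hits(
                        matrix, quantile_method=config.quantile_method)
                combined = hit_calling.combine_hits(
                    hit_table, config.hit_categories, "enhancer")
                hit_map = {r["gene_id"]: r["categories"]
                           for _, r in combined.iterrows()}
                lethal_genes = {table.line_to_gene.get(l) for l in
                                table.lethal_lines} - {None} - set(hit_map)
                edges = network.read_edges(config.edges)
                g = network.build_network(hit_map, lethal_genes, edges)
                p1 = out_dir / "network_edges.tsv"
                network.write_edge_list(g, p1)
                complexes = network.mcode_complexes(
                    g, vwp=config.mcode_vwp, haircut=config.mcode_haircut,
                    fluff=config.mcode_fluff,
                    fluff_density=config.mcode_fluff_density)
                p2 = out_dir / "mcode_complexes.tsv"
                pd.DataFrame([{"rank": i + 1, "seed": c.seed, "size": c.size,
                               "density": c.density, "score": c.score,
                               "members": ",".join(sorted(c.members))}
                              for i, c in enumerate(complexes)]).to_csv(
                    p2, sep="\t", index=False)
                outputs.update(edges=p1, complexes=p2)
                if config.annotation:
                    annot = enrichment.read_annotation(config.annotation)
                    universe = set(matrix.genes)
                    genes_in = set(hit_map) & universe
                    enr = enrichment.enrich(genes_in, universe, annot)
                    p3 = out_dir / "network_enrichment.tsv"
                    enr.to_csv(p3, sep="\t", index=False)
                    outputs["enrichment"] = p3
            elif stage == "tracks":
                track_list = trk.read_tracks(config.tracks)
                stats_df = trk.stats_frame(track_list)
                p1 = out_dir / "track_stats.tsv"
                stats_df.to_csv(p1, sep="\t", index=False)
                verdicts = {}
                all_stats = [trk.track_stats(t) for t in track_list]
                by_geno: dict[str, list] = {}
                for s in all_stats:
                    by_geno.setdefault(s.genotype, []).append(s)
                for geno, group in sorted(by_geno.items()):
                    if len(group) >= 3:
                        verdicts[geno] = trk.directionality_test(
                            group, alpha=config.track_alpha)
                p2 = out_dir / "directionality.json"
                p2.write_text(json.dumps(verdicts, indent=2))
                outputs.update(stats=p1, directionality=p2)
            elif stage == "de":
                expr = expression.read_expression(config.expr)
                sheet = expression.read_samples(config.samples)
                res = expression.de_test(expr, sheet)
                passed = expression.de_filter(res, p_thresh=config.de_p,
                                              fc_thresh=config.de_fc)
                p1 = out_dir / "de_results.tsv"
                res.to_csv(p1, sep="\t")
                p2 = out_dir / "de_genes.tsv"
                passed.to_csv(p2, sep="\t")
                outputs.update(results=p1, genes=p2)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

        # timings are logged, not put in the manifest, so reruns hash identically
        manifest["stages"][stage] = {
            "seed": config.seed + STAGE_OFFSETS.get(stage, 0),
            "inputs": {k: _sha256(Path(getattr(config, k)))
                       for k in STAGE_INPUTS[stage]},
            "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
        }
        log.info("stage %s: done (%.2fs)", stage, time.monotonic() - t0)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest
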