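"""End-to-end orchestration: simulate -> qc -> normalize -> de -> meta ->
enrich/network, with a machine-readable JSON run manifest.

Every stage writes plain TSV outputs into the run directory; the manifest
records the seed, thresholds, per-stage row counts and SHA-256 hashes of the
written files, so two runs with identical config and seed are byte-identical
and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .containers import CountMatrix, validate_roi_meta
from .de import DEG_DOWN, DEG_UP, ModelSpec, run_de
from .enrichment import enrich
from .meta import (correlation_cluster, fc_profiles, meta_up_down, pca_scores,
                   profile_similarity, venn_table)
from .network import annotate_drugs, build_network, graph_tables, shared_drug_report
from .normalize import q3_normalize
from .qc import apply_qc, compute_loq, filter_targets, segment_qc
from .simulate import (CohortConfig, generate_cohort, generate_edge_and_drug_tables,
                       generate_gene_sets)

log = logging.getLogger("arteryscope")

STAGES = ("simulate", "qc", "normalize", "de", "meta", "enrich_network")


@dataclass
class RunConfig:
    """All thresholds and paths of one pipeline run.

    Defaults equal the stated analysis cut-offs: Q3 >= 2 and >= 1% detection
    per ROI, targets above LOQ in >= 10% of ROIs, DEG at |FC| > 2 with BH
    p < 0.01, EASE < 0.05, interaction confidence >= 0.900, approved drugs
    only. ``loq_pseudocount`` shifts negative-probe counts before the
    log-geometric statistics (count data contain zeros).
    """

    outdir: str = "run"
    seed: int = 0
    counts_path: Optional[str] = None
    meta_path: Optional[str] = None
    gene_sets_path: Optional[str] = None
    edges_path: Optional[str] = None
    drugs_path: Optional[str] = None
    q3_min: float = 2.0
    frac_min: float = 0.01
    min_roi_frac: float = 0.10
    raw_reads_min: float = 1e6
    loq_pseudocount: float = 1.0
    alpha: float = 0.01
    fc_threshold: float = 2.0
    de_pseudocount: float = 1.0
    adjust_scope: str = "layer"
    ease_alpha: float = 0.05
    min_score: float = 0.900
    keep_components: int = 2
    approved_only: bool = True
    min_r: float = 0.95
    cohort: dict = field(default_factory=dict)
    version: str = "0.1.0"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        overrides = dict(self.cohort)
        if "layers" in overrides:
            overrides["layers"] = tuple(overrides["layers"])
        if "de_spec" in overrides:
            overrides["de_spec"] = {
                k: [tuple(e) for e in v] for k, v in overrides["de_spec"].items()
            }
        overrides.setdefault("seed", self.seed)
        return CohortConfig(**overrides)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files: Dict[str, str] = {}

    def write(self, name: str, writer) -> Path:
        path = self.outdir / name
        writer(path)
        self.files[name] = _sha256(path)
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir)
    manifest: dict = {
        "version": config.version, "seed": config.seed,
        "config": asdict(config), "stages": [],
    }

    def stage(name: str, **counts) -> None:
        log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))
        manifest["stages"].append({"name": name, **counts})

    # --- simulate (or load) -------------------------------------------------
    for attr in ("counts_path", "meta_path", "gene_sets_path", "edges_path",
                 "drugs_path"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{attr}: missing input file {p}")
    if config.counts_path:
        matrix = aio.read_counts(config.counts_path)
        meta = aio.read_roi_meta(config.meta_path)
        truth = None
    else:
        cohort_cfg = config.cohort_config()
        matrix, meta, truth = generate_cohort(cohort_cfg)
        run.write("truth.tsv", lambda p: aio.write_table(truth, p, index=False))
    validate_roi_meta(meta, rois=matrix.rois)
    run.write("counts.tsv", lambda p: aio.write_counts(matrix, p))
    run.write("roi_meta.tsv", lambda p: aio.write_roi_meta(meta, p))

    if config.gene_sets_path:
        gene_sets = aio.read_gmt(config.gene_sets_path)
    elif truth is not None:
        gene_sets = generate_gene_sets(truth, seed=config.seed + 1)
        run.write("gene_sets.gmt", lambda p: aio.write_gmt(gene_sets, p))
    else:
        gene_sets = {}
    if config.edges_path:
        edges = aio.read_edge_table(config.edges_path)
        drugs = aio.read_drug_table(config.drugs_path)
    elif truth is not None:
        edges, drugs = generate_edge_and_drug_tables(
            list(matrix.targets[~matrix.is_negprobe]), truth, seed=config.seed + 2)
        run.write("edges.tsv", lambda p: aio.write_table(edges, p, index=False))
        run.write("drugs.tsv", lambda p: aio.write_table(drugs, p, index=False))
    else:
        edges = pd.DataFrame(columns=["geneA", "geneB", "score"])
        drugs = pd.DataFrame(columns=["gene", "drug", "approved"])
    stage("simulate", n_targets=len(matrix.targets), n_rois=len(matrix.rois))

    # --- qc -----------------------------------------------------------------
    loq = compute_loq(matrix, pseudocount=config.loq_pseudocount)
    raw_reads = meta["raw_reads"] if "raw_reads" in meta.columns else None
    qc_report = segment_qc(
        matrix, loq, q3_min=config.q3_min, frac_min=config.frac_min,
        raw_reads_min=config.raw_reads_min, raw_reads=raw_reads)
    targets = filter_targets(matrix, loq, qc_report, min_roi_frac=config.min_roi_frac)
    filtered = apply_qc(matrix, loq, qc_report, targets)
    run.write("loq.tsv", lambda p: aio.write_table(loq, p))
    run.write("qc_report.tsv", lambda p: aio.write_table(qc_report, p))
    run.write("retained_targets.tsv", lambda p: aio.write_table(
        pd.DataFrame({"target": targets}), p, index=False))
    stage("qc", n_rois_retained=len(filtered.rois), n_targets_retained=len(targets))

    # --- normalize ----------------------------------------------------------
    gene_counts = filtered.gene_counts
    normalized, factors = q3_normalize(gene_counts)
    run.write("normalized.tsv", lambda p: aio.write_table(normalized, p))
    run.write("q3_factors.tsv", lambda p: aio.write_table(factors.to_frame(), p))
    stage("normalize", n_genes=normalized.shape[0], n_rois=normalized.shape[1])

    # --- de -----------------------------------------------------------------
    meta_kept = meta.loc[list(normalized.columns)]
    spec = ModelSpec(alpha=config.alpha, fc_threshold=config.fc_threshold,
                     pseudocount=config.de_pseudocount,
                     adjust_scope=config.adjust_scope)
    de_results = run_de(normalized, meta_kept, spec)
    deg_counts = {}
    for layer, table in de_results.items():
        out = table.copy()
        out.index.name = "gene"
        run.write(f"de_{layer}.tsv", lambda p, t=out: aio.write_table(t, p))
        deg_counts[layer] = int((table["deg"] != "ns").sum())
    stage("de", **{f"degs_{k}": v for k, v in deg_counts.items()})

    # --- meta ---------------------------------------------------------------
    deg_sets = {
        layer: set(t.index[t["deg"] != "ns"]) for layer, t in de_results.items()
    }
    venn_layers = {k: v for k, v in deg_sets.items() if k != "PVAT"} \
        if len(deg_sets) > 2 else deg_sets
    if len(venn_layers) >= 2:
        vt = venn_table(venn_layers)
        run.write("venn.tsv", lambda p: aio.write_table(vt, p, index=False))
    up, down, conflict = meta_up_down(de_results)
    meta_sets = pd.DataFrame(
        [{"set": "up", "count": len(up), "genes": ",".join(sorted(up))},
         {"set": "down", "count": len(down), "genes": ",".join(sorted(down))},
         {"set": "conflict", "count": len(conflict), "genes": ",".join(sorted(conflict))}]
    )
    run.write("meta_sets.tsv", lambda p: aio.write_table(meta_sets, p, index=False))

    profiles = fc_profiles(de_results)
    seed_gene = None
    complete = profiles.dropna()
    candidates = sorted(up & set(complete.index))
    if candidates:
        seed_gene = max(candidates, key=lambda g: (complete.loc[g].abs().max(), g))
        sim = profile_similarity(profiles, seed_gene, min_r=config.min_r)
        run.write("profile_similarity.tsv",
                  lambda p: aio.write_table(sim, p, index=False))

    corr, _, order = correlation_cluster(normalized)
    run.write("roi_correlation.tsv", lambda p: aio.write_table(corr, p))
    pca_rows = []
    for layer in dict.fromkeys(meta_kept["layer"]):
        rois = [r for r in normalized.columns if meta_kept.loc[r, "layer"] == layer]
        if len(rois) < 3:
            continue
        scores, explained = pca_scores(normalized[rois])
        scores["layer"] = layer
        scores["explained_pc1"] = explained[0]
        scores["explained_pc2"] = explained[1] if len(explained) > 1 else np.nan
        pca_rows.append(scores)
    if pca_rows:
        pca_all = pd.concat(pca_rows)
        pca_all.index.name = "roi"
        run.write("pca_scores.tsv", lambda p: aio.write_table(pca_all, p))
    stage("meta", meta_up=len(up), meta_down=len(down), conflict=len(conflict),
          seed_gene=seed_gene or "")

    # --- enrich / network ---------------------------------------------------
    universe = list(normalized.index)
    enrich_rows = []
    if gene_sets:
        for layer, table in de_results.items():
            for direction in (DEG_UP, DEG_DOWN):
                query = sorted(table.index[table["deg"] == direction])
                if not query:
                    continue
                res = enrich(query, gene_sets, universe, alpha=config.ease_alpha)
                t = res.table.copy()
                t.insert(0, "layer", layer)
                t.insert(1, "direction", direction)
                enrich_rows.append(t)
    if enrich_rows:
        enrichment_table = pd.concat(enrich_rows, ignore_index=True)
        run.write("enrichment.tsv",
                  lambda p: aio.write_table(enrichment_table, p, index=False))
        n_enriched = int(enrichment_table["enriched"].sum())
    else:
        n_enriched = 0

    layer_graphs = {}
    for layer, degs in deg_sets.items():
        if not degs:
            continue
        g = build_network(edges, degs, min_score=config.min_score,
                          keep_components=config.keep_components)
        annotate_drugs(g, drugs, approved_only=config.approved_only)
        layer_graphs[layer] = g
        tables = graph_tables(g)
        run.write(f"network_{layer}_nodes.tsv",
                  lambda p, t=tables["nodes"]: aio.write_table(t, p, index=False))
        run.write(f"network_{layer}_edges.tsv",
                  lambda p, t=tables["edges"]: aio.write_table(t, p, index=False))
    shared = shared_drug_report(layer_graphs)
    run.write("shared_drugs.tsv", lambda p: aio.write_table(shared, p, index=False))
    stage("enrich_network", n_enriched_sets=n_enriched,
          n_networks=len(layer_graphs), n_shared_drugs=len(shared))

    manifest["files"] = run.files
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
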