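"""End-to-end orchestration of the endotype analysis.

Stages, in order: ingest or simulate counts -> gene filtering ->
median-of-ratios normalization -> VST -> full-cohort differential
expression -> mRMR top-50 -> step-up panel -> clinical-score comparison ->
mapper graph -> endotype groups (+ low-mortality merge) -> per-group DE and
models -> between/within-group enrichment -> clinical comparisons ->
report bundle on disk (TSV/JSON/GraphML) with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import __version__
from .de import clinical_compare, contrast_between_groups, de_table
from .enrichment import GeneSetCollection, gsea_preranked, rank_genes, read_gmt
from .mapper import MapperConfig, build_mapper_groups, merge_low_mortality
from .matrix import CountMatrix
from .models import (
    ModelReport,
    compare_with_clinical_score,
    mrmr_rank,
    stepup_select,
    stratified_models,
)
from .preprocess import preprocess_counts
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

_LINKAGE_METHODS = {"mcquitty": "weighted", "ward": "ward"}


def order_rows_for_heatmap(
    matrix, distance: str = "manhattan", linkage_method: str = "mcquitty"
) -> list[int]:
    """Row order from agglomerative clustering of the rows.

    distance: "manhattan"; linkage_method: "mcquitty" (WPGMA) or "ward".
    Returns leaf positions (indices into the input rows).
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(arr).any():
        raise ValueError("NaN entries not allowed")
    if distance != "manhattan":
        raise ValueError("only the manhattan distance is supported")
    if linkage_method not in _LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGE_METHODS)}")
    tree = linkage(pdist(arr, metric="cityblock"), method=_LINKAGE_METHODS[linkage_method])
    return [int(i) for i in leaves_list(tree)]


@dataclass
class ModelSettings:
    repeats: int = 10
    folds: int = 10
    n_mrmr: int = 50
    max_panel: int = 50
    de_significance: float = 0.05


@dataclass
class EnrichmentSettings:
    gmt_path: str | None = None
    n_perm: int = 1000
    min_size: int = 5
    max_size: int = 500


@dataclass
class PipelineConfig:
    """Exactly one of (counts_tsv + annotation_tsv + cohort_csv) or
    ``simulation`` must be provided."""

    counts_tsv: str | None = None
    annotation_tsv: str | None = None
    cohort_csv: str | None = None
    simulation: SimulationConfig | None = None
    mapper: MapperConfig = field(default_factory=MapperConfig)
    models: ModelSettings = field(default_factory=ModelSettings)
    enrichment: EnrichmentSettings = field(default_factory=EnrichmentSettings)
    cpm_threshold: float = 10.0
    min_deaths_for_merge: int = 10
    seed: int = 0
    out_dir: str = "endoscope_out"

    def validate(self) -> None:
        has_paths = all(
            p is not None for p in (self.counts_tsv, self.annotation_tsv, self.cohort_csv)
        )
        if has_paths == (self.simulation is not None):
            raise ValueError(
                "config must provide exactly one of input paths or a simulation block"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        mapper = raw.pop("mapper", None)
        models = raw.pop("models", None)
        enrich = raw.pop("enrichment", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim is not None else None,
            mapper=MapperConfig(**mapper) if mapper else MapperConfig(),
            models=ModelSettings(**models) if models else ModelSettings(),
            enrichment=EnrichmentSettings(**enrich) if enrich else EnrichmentSettings(),
            **raw,
        )
        cfg.validate()
        return cfg

    def manifest_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _graph_to_json(graph) -> dict:
    return {
        "nodes": [
            {"id": n.node_id, "bin": list(n.bin_index), "patients": sorted(n.patients)}
            for n in graph.nodes
        ],
        "edges": [{"a": a, "b": b, "shared": w} for a, b, w in graph.edges],
    }


def _graph_to_graphml(graph, path) -> None:
    g = nx.Graph()
    for n in graph.nodes:
        g.add_node(n.node_id, size=len(n.patients), bin=str(n.bin_index))
    for a, b, w in graph.edges:
        g.add_edge(a, b, weight=w)
    nx.write_graphml(g, path)


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict
    de_full: pd.DataFrame
    groups: object
    full_model: ModelReport
    group_models: list[ModelReport]
    union_features: list[str]
    enrichment_tables: dict[str, pd.DataFrame]
    clinical: list


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write the report bundle to disk."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        if cfg.simulation is not None:
            counts, cohort, _truth = simulate_cohort(cfg.simulation)
        else:
            counts = CountMatrix.from_tsv(cfg.counts_tsv, cfg.annotation_tsv)
            cohort = pd.read_csv(cfg.cohort_csv, index_col=0)
        logger.info("ingest: %d genes x %d patients", counts.n_genes, counts.n_patients)

        stage = "preprocess"
        expr, size_factors, filtered = preprocess_counts(counts, cfg.cpm_threshold)
        logger.info(
            "preprocess: %d genes retained for %d patients",
            len(expr.gene_ids), len(expr.patient_ids),
        )

        mortality = cohort["mortality_28d"].dropna().astype(int)
        X = expr.values.T  # patients x genes

        stage = "differential_expression"
        de_full = de_table(expr, mortality)
        n_sig = int((de_full["p_adjusted"] <= cfg.models.de_significance).sum())
        logger.info("differential expression: %d significant genes", n_sig)

        stage = "feature_selection"
        sig = de_full[de_full["p_value"] <= cfg.models.de_significance]["gene_id"].tolist()
        candidates = sig if len(sig) >= cfg.models.n_mrmr else de_full["gene_id"].tolist()
        ranked = mrmr_rank(
            X.loc[mortality.index], mortality, m=cfg.models.n_mrmr, candidates=candidates
        )
        ranked_genes = ranked["gene_id"].tolist()

        stage = "stepup_panel"
        n_star, curve = stepup_select(
            X.loc[mortality.index], mortality, ranked_genes,
            max_n=cfg.models.max_panel, repeats=cfg.models.repeats,
            folds=cfg.models.folds, seed=cfg.seed,
        )
        panel = ranked_genes[:n_star]
        logger.info("step-up panel: %d transcripts", n_star)

        stage = "clinical_comparison_model"
        full_model = compare_with_clinical_score(
            X.loc[mortality.index], mortality, panel, cohort["qsofa"],
            repeats=cfg.models.repeats, folds=cfg.models.folds, seed=cfg.seed,
        )
        full_model.stepup_curve = curve

        stage = "mapper"
        graph, raw_groups = build_mapper_groups(expr, cfg.mapper)
        stage = "group_merge"
        groups = merge_low_mortality(raw_groups, cohort, cfg.min_deaths_for_merge)
        groups = groups.with_mortality(cohort["mortality_28d"])
        logger.info(
            "mapper: %d nodes, %d groups, shared fraction %.3f",
            len(graph.nodes), len(groups.groups), groups.shared_fraction,
        )

        stage = "stratified_models"
        try:
            group_models, union_features = stratified_models(
                X.loc[mortality.index], mortality, groups, ranked_genes,
                max_n=cfg.models.max_panel, repeats=cfg.models.repeats,
                folds=cfg.models.folds, seed=cfg.seed,
            )
        except ValueError as err:
            logger.warning("stratified models unavailable: %s", err)
            group_models, union_features = [], []

        stage = "enrichment"
        if cfg.enrichment.gmt_path:
            collection = read_gmt(cfg.enrichment.gmt_path)
        elif cfg.simulation is not None:
            from .synthetic import synthetic_hallmark_collection

            collection = synthetic_hallmark_collection(expr.gene_ids, _truth)
        else:
            collection = _default_gene_sets(expr.gene_ids)
        enrichment_tables: dict[str, pd.DataFrame] = {}
        ranked_full = rank_genes(de_full, mode="all")
        enrichment_tables["full_cohort_mortality"] = gsea_preranked(
            ranked_full, collection, n_perm=cfg.enrichment.n_perm,
            min_size=cfg.enrichment.min_size, max_size=cfg.enrichment.max_size,
            seed=cfg.seed,
        )
        group_ids = list(groups.groups)
        for i, ga in enumerate(group_ids):
            for gb in group_ids[i + 1 :]:
                try:
                    de_pair = contrast_between_groups(expr, groups, (ga, gb))
                    ranked_pair = rank_genes(de_pair, mode="significant_only")
                    enrichment_tables[f"between_{ga}_vs_{gb}"] = gsea_preranked(
                        ranked_pair, collection, n_perm=cfg.enrichment.n_perm,
                        min_size=cfg.enrichment.min_size,
                        max_size=cfg.enrichment.max_size, seed=cfg.seed,
                    )
                except ValueError as err:
                    logger.info("enrichment %s vs %s skipped: %s", ga, gb, err)
        for gid in group_ids:
            try:
                members = [p for p in groups.exclusive_members(gid) if p in mortality.index]
                de_within = de_table(expr, mortality.loc[members])
                enrichment_tables[f"within_{gid}_mortality"] = gsea_preranked(
                    rank_genes(de_within, mode="all"), collection,
                    n_perm=cfg.enrichment.n_perm, min_size=cfg.enrichment.min_size,
                    max_size=cfg.enrichment.max_size, seed=cfg.seed,
                )
            except ValueError as err:
                logger.info("within-group enrichment for %s skipped: %s", gid, err)

        stage = "clinical_compare"
        clinical = clinical_compare(cohort, groups)

        stage = "report"
        manifest = {
            "config_hash": cfg.manifest_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "n_genes_input": counts.n_genes,
            "n_genes_retained": int(len(expr.gene_ids)),
            "n_patients": int(counts.n_patients),
            "n_significant_genes": n_sig,
            "panel_size": n_star,
            "n_groups": len(groups.groups),
            "shared_fraction": groups.shared_fraction,
            "group_mortality": groups.mortality,
        }
        _write_bundle(
            out, manifest, cfg, expr, size_factors, de_full, graph, groups,
            full_model, group_models, union_features, enrichment_tables, clinical,
        )
        return ReportBundle(
            out, manifest, de_full, groups, full_model, group_models,
            union_features, enrichment_tables, clinical,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def _default_gene_sets(gene_ids, n_sets: int = 25, set_size: int = 40) -> GeneSetCollection:
    """Deterministic fallback collection built from the analyzed genes."""
    from .enrichment import GeneSet

    ids = sorted(gene_ids)
    rng = np.random.default_rng(2026)
    sets = []
    for i in range(n_sets):
        pick = rng.choice(len(ids), size=min(set_size, len(ids) // 2), replace=False)
        sets.append(
            GeneSet(f"SET_{i:02d}", "auto-generated", frozenset(ids[j] for j in pick))
        )
    return GeneSetCollection(sets)


def _write_bundle(
    out, manifest, cfg, expr, size_factors, de_full, graph, groups,
    full_model, group_models, union_features, enrichment_tables, clinical,
) -> None:
    de_full.to_csv(out / "de_full_cohort.tsv", sep="\t", index=False)
    rows = []
    for patient, gid in sorted(groups.exclusive.items()):
        in_groups = sorted(g for g, m in groups.groups.items() if patient in m)
        rows.append(
            {"patient_id": patient, "groups": "+".join(in_groups), "exclusive": gid}
        )
    pd.DataFrame(rows).to_csv(out / "group_assignments.tsv", sep="\t", index=False)
    _graph_to_graphml(graph, out / "mapper_graph.graphml")
    (out / "mapper_graph.json").write_text(json.dumps(_graph_to_json(graph)))
    reports = [full_model.to_dict()] + [m.to_dict() for m in group_models]
    (out / "model_reports.json").write_text(json.dumps(reports, indent=1))
    (out / "union_features.json").write_text(json.dumps(union_features))
    for name, table in enrichment_tables.items():
        table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
    clin_rows = []
    for comparison in clinical:
        for side_a, side_b, diff, p in comparison.pairwise:
            clin_rows.append(
                {
                    "feature": comparison.feature, "anova_p": comparison.anova_p,
                    "side_a": side_a, "side_b": side_b,
                    "mean_difference": diff, "p_value": p,
                }
            )
    pd.DataFrame(clin_rows).to_csv(out / "clinical_comparisons.tsv", sep="\t", index=False)
    sig = de_full[de_full["p_adjusted"] <= cfg.models.de_significance]
    heat_genes = sig["gene_id"].tolist()[:200]
    if len(heat_genes) >= 2:
        sub = expr.values.loc[heat_genes]
        order = order_rows_for_heatmap(sub.to_numpy())
        pd.Series(
            [heat_genes[i] for i in order], name="gene_id"
        ).to_csv(out / "heatmap_row_order.tsv", sep="\t", index=False)
    size_factors.to_csv(out / "size_factors.tsv", sep="\t")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
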