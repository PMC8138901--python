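"""End-to-end orchestration of the expression-morphometry pipeline.

Stage order: load (or synthesize) inputs -> longitudinal sandwich GLM ->
regional t summary -> probe filtering / collapsing / regionization ->
gene-wise Spearman screen with BH-FDR and percentile cutoffs -> top/bottom
tail Fisher enrichment -> sensitivity variants. Every output is written as
plain text under the configured output directory together with a run log
(parameter echo, config hash, seed, record counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from ._validate import ValidationError, require
from .association import (RegionalDifferenceMap, SpearmanScreen,
                          percentile_thresholds, summarize_tmap)
from .config import PipelineConfig
from .enrichment import GeneSetCatalog, fisher_enrichment, select_top_genes
from .expression import (AtlasSpec, DonorExpressionBundle, assign_samples,
                         collapse_probes, filter_probes,
                         select_analysis_regions, regionize)
from .glm import LongitudinalDataset, SandwichGLM
from .synthetic import (CatalogSpec, CohortSpec, ExpressionSpec, gen_scenario)

logger = logging.getLogger(__name__)


@dataclass
class PipelineState:
    """Everything the association stages need, kept for variant reruns."""

    config: PipelineConfig
    dataset: LongitudinalDataset
    bundle: DonorExpressionBundle          # whitelist-filtered
    atlas: AtlasSpec
    catalog: GeneSetCatalog
    whitelist: list[str]
    gene_by_sample: pd.DataFrame = None
    assignment: pd.Series = None
    selection: object = None
    truth: dict = field(default_factory=dict)


@dataclass
class PipelineRun:
    state: PipelineState
    tmap: pd.Series
    diff_map: RegionalDifferenceMap
    expr_regions: pd.DataFrame             # genes x retained regions
    association: pd.DataFrame
    thresholds: dict
    enrichment: dict[str, pd.DataFrame]    # tail -> table
    variants: dict[str, object] = field(default_factory=dict)
    log: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# input loading
# ---------------------------------------------------------------------------

def load_inputs(config: PipelineConfig) -> PipelineState:
    """Materialize the input bundle (from files or the synthetic generator)."""
    config.validate()
    if config.mode == "synthetic":
        syn = dict(config.synthetic)
        cohort = CohortSpec(**syn.get("cohort", {}))
        expression = ExpressionSpec(**syn.get("expression", {}))
        catalog = CatalogSpec(**syn.get("catalog", {}))
        scenario = gen_scenario(config.seed, cohort=cohort,
                                expression=expression, catalog=catalog,
                                n_regions=syn.get("n_regions", 46))
        dataset, atlas = scenario.dataset, scenario.atlas
        raw_bundle, whitelist = scenario.bundle, scenario.whitelist
        cat = scenario.catalog
        truth = {"causal_genes": scenario.causal_genes,
                 "effect_map": scenario.effect_map,
                 "assignment": scenario.assignment}
    else:
        f = config.files
        dataset = gio.read_dataset(f["scan_table"], f["responses"])
        raw_bundle = gio.read_bundle(f["probes"], f["samples"], f["expr"])
        whitelist = gio.read_whitelist(f["whitelist"])
        atlas = gio.read_atlas(f["atlas_regions"], f.get("atlas_labels"),
                               f.get("atlas_label_map"))
        cat = gio.read_gmt(f["gmt"])
        truth = {}

    bundle = filter_probes(raw_bundle, whitelist)
    n_genes = bundle.probes["gene_symbol"].nunique()
    logger.info("input manifest: %d scans / %d subjects, %d probes -> "
                "%d whitelisted genes, %d samples, %d catalog sets",
                len(dataset.scans), dataset.n_subjects, len(raw_bundle.probes),
                n_genes, len(bundle.samples), len(cat))
    state = PipelineState(config=config, dataset=dataset, bundle=bundle,
                          atlas=atlas, catalog=cat, whitelist=list(whitelist),
                          truth=truth)
    state.gene_by_sample = collapse_probes(bundle)
    state.assignment = assign_samples(bundle.samples, atlas,
                                      max_dist_mm=config.max_dist_mm)
    state.selection = select_analysis_regions(atlas)
    return state


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _fit_and_summarize(state: PipelineState, *, case_group=None,
                       scan_mask=None, drop_covariates=()):
    cfg = state.config
    dataset = state.dataset
    if scan_mask is not None:
        dataset = dataset.subset(scan_mask)
        for grp in (case_group or cfg.case_group, cfg.control_group):
            n = dataset.scans.loc[dataset.scans["group"] == grp,
                                  "subject_id"].nunique()
            if n < 2:
                raise ValidationError(
                    f"variant leaves {n} subject(s) in group {grp!r}")
    model = SandwichGLM(case_group=case_group or cfg.case_group,
                        control_group=cfg.control_group,
                        drop_covariates=tuple(drop_covariates))
    model.fit(dataset)
    tmap = model.tmap("group")
    diff = summarize_tmap(tmap, mode=cfg.summary_mode)
    return model, tmap, diff


def _screen(expr_regions: pd.DataFrame, diff: RegionalDifferenceMap,
            min_regions: int = 3):
    common = [r for r in expr_regions.columns if r in set(diff.values.index)]
    if len(common) < min_regions:
        raise ValidationError(
            f"only {len(common)} regions shared between expression and "
            "difference map")
    screen = SpearmanScreen().fit(expr_regions[common],
                                  diff.values.loc[common])
    return screen


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def run_variant(state: PipelineState, expr_regions: pd.DataFrame,
                diff: RegionalDifferenceMap, variant: dict):
    """One sensitivity rerun; returns an association table (or rho table)."""
    kind = variant["kind"]
    if kind == "exclude_regions":
        excluded = set(variant.get("regions", []))
        keep = [r for r in expr_regions.columns if r not in excluded]
        if len(keep) < 3:
            raise ValidationError("variant leaves fewer than 3 regions")
        sub_diff = RegionalDifferenceMap(values=diff.values.loc[
            [r for r in diff.values.index if r not in excluded]],
            mode=diff.mode, contrast=diff.contrast)
        return _screen(expr_regions[keep], sub_diff).association_

    if kind == "male_only":
        mask = state.dataset.scans["sex"] == 1
        _, _, sub_diff = _fit_and_summarize(state, scan_mask=mask,
                                            drop_covariates=("sex",))
        return _screen(expr_regions, sub_diff).association_

    if kind == "recovered":
        _, _, sub_diff = _fit_and_summarize(state, case_group="recovered")
        return _screen(expr_regions, sub_diff).association_

    if kind == "per_donor":
        rows = {}
        donors = state.bundle.samples["donor_id"]
        for donor in sorted(donors.unique()):
            mat = regionize(state.gene_by_sample, state.assignment,
                            state.selection, donors=donors, scope=donor,
                            min_samples=state.config.min_samples)
            try:
                rows[donor] = _screen(mat.values, diff).rho_
            except ValidationError as err:
                logger.warning("donor %s skipped: %s", donor, err)
        require(len(rows) > 0, "no donor had enough regions for the screen")
        return pd.DataFrame(rows).T.rename_axis("donor")

    raise ValidationError(f"unknown sensitivity variant {kind!r}")


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineRun:
    """Execute every stage and write the result bundle to disk."""
    state = load_inputs(config)
    cfg = state.config
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model, tmap, diff = _fit_and_summarize(state)
    expr = regionize(state.gene_by_sample, state.assignment, state.selection,
                     donors=state.bundle.samples["donor_id"], scope="pooled",
                     min_samples=cfg.min_samples)

    screen = _screen(expr.values, diff)
    assoc = screen.association_
    thresholds = percentile_thresholds(screen.rho_.to_numpy(),
                                       *cfg.percentiles)

    background = list(assoc.index)
    enrichment_tables = {}
    for tail in ("positive", "negative"):
        selected = select_top_genes(assoc, cfg.fraction, tail)
        enrichment_tables[tail] = fisher_enrichment(
            selected, state.catalog, background,
            min_category=cfg.min_category)

    variants = {}
    for variant in cfg.variants:
        vid = variant.get("id", variant["kind"])
        variants[vid] = run_variant(state, expr.values, diff, variant)

    # ---- cluster-extent simulation (optional stage) ----
    cluster_result = None
    if cfg.cluster_sim:
        from .clustersim import NoiseModel, cluster_threshold
        cs = dict(cfg.cluster_sim)
        model_keys = {"shape", "voxel_size", "fwhm", "sidedness",
                      "connectivity"}
        nm = NoiseModel(**{k: tuple(v) if k == "shape" else v
                           for k, v in cs.items() if k in model_keys})
        cluster_result = cluster_threshold(
            nm, voxel_p=cs.get("voxel_p", 0.005),
            alpha=cs.get("alpha", 0.05), n_iter=cs.get("n_iter", 1000),
            seed=cfg.seed)

    log = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_scans": len(state.dataset.scans),
        "n_subjects": state.dataset.n_subjects,
        "n_probes_whitelisted": len(state.bundle.probes),
        "n_genes_universe": int(state.bundle.probes["gene_symbol"].nunique()),
        "n_genes_tested": len(assoc),
        "n_regions_analysis": len(state.selection.regions),
        "n_regions_tested": screen.n_regions_,
        "regions_dropped": expr.dropped_regions,
        "genes_excluded_constant": screen.excluded_,
        "parameters": cfg.to_dict(),
    }
    if cluster_result is not None:
        log["cluster_k_min"] = cluster_result.k_min

    # ---- write the result bundle ----
    gio.write_association(model.result_.beta.T, out / "glm_coefficients.tsv")
    gio.write_association(tmap.to_frame(), out / "tmap.tsv")
    gio.write_association(diff.values.to_frame(), out / "diff_map.tsv")
    gio.write_association(expr.values, out / "region_expression.tsv")
    gio.write_json({"scope": expr.scope,
                    "sample_counts": expr.sample_counts.to_dict(),
                    "dropped_regions": expr.dropped_regions},
                   out / "region_expression.json")
    gio.write_association(assoc, out / "gene_association.tsv")
    gio.write_json(thresholds, out / "thresholds.json")
    for tail, table in enrichment_tables.items():
        gio.write_association(table.set_index("category"),
                              out / f"enrichment_{tail}.tsv")
    for vid, table in variants.items():
        gio.write_association(table, out / "variants" / f"{vid}.tsv")
    if cluster_result is not None:
        gio.write_json({"k_min": cluster_result.k_min,
                        "voxel_p": cluster_result.voxel_p,
                        "alpha": cluster_result.alpha,
                        "exceedance": {str(k): v for k, v in
                                       cluster_result.exceedance.items()}},
                       out / "cluster_threshold.json")
    gio.write_json(log, out / "run_log.json")

    if cfg.make_plots:
        from .plotting import plot_rho_distribution
        plot_rho_distribution(assoc["rho"], thresholds,
                              out / "rho_distribution.png")

    return PipelineRun(state=state, tmap=tmap, diff_map=diff,
                       expr_regions=expr.values, association=assoc,
                       thresholds=thresholds, enrichment=enrichment_tables,
                       variants=variants, log=log)
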