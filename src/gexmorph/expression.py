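"""Donor expression bundles and their reduction to a gene-by-region matrix.

Microarray-style donor expression data arrives as a probe-by-sample matrix
with probe-to-gene annotations and stereotaxic (MNI mm) sample coordinates.
Turning this into a per-region expression map follows four rules, applied
in order:

1. probes whose gene symbol is not on an approved-symbol whitelist are
   discarded (``filter_probes``);
2. probes of the same gene are averaged per sample (``collapse_probes``);
3. samples are mapped to atlas regions, either through a precomputed
   assignment table or by looking the coordinate up in a label volume with
   a nearest-labeled-voxel fallback (``assign_samples``);
4. each retained region is summarized by the *median* over its assigned
   samples (``regionize``), either pooling all donors or per donor.

The analysis-region rule — left-hemisphere supratentorial regions plus the
right cerebellum collapsed to a single region — lives in
``select_analysis_regions``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._validate import ValidationError, require

logger = logging.getLogger(__name__)

#: analysis-region id used for the merged right cerebellum
CEREBELLUM_R_ID = "cerebellum_R"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DonorExpressionBundle:
    """Probe-level expression for a set of spatially localized brain samples.

    Attributes
    ----------
    probes : DataFrame indexed by probe id with a ``gene_symbol`` column.
    samples : DataFrame indexed by sample id with columns ``donor_id``,
        ``x``, ``y``, ``z`` (MNI mm) and optionally ``structure`` (a region
        label recorded at sampling time).
    expr : DataFrame, probes x samples, normalized log-intensity (unitless).
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    expr: pd.DataFrame

    def validate(self) -> "DonorExpressionBundle":
        require(self.expr.index.equals(self.probes.index),
                "expression rows do not match the probe table")
        require(self.expr.columns.equals(self.samples.index),
                "expression columns do not match the sample table")
        coords = self.samples[["x", "y", "z"]].to_numpy(float)
        require(bool(np.isfinite(coords).all()),
                "sample coordinates contain non-finite values")
        require(not self.expr.isna().any().any(),
                "expression matrix contains missing values")
        return self

    @property
    def donors(self) -> list:
        return sorted(self.samples["donor_id"].unique().tolist())

    @property
    def gene_universe(self) -> list[str]:
        return sorted(self.probes["gene_symbol"].unique().tolist())


@dataclass
class AtlasSpec:
    """Region metadata plus one of two ways to localize a sample.

    ``regions`` must contain columns ``name``, ``hemisphere`` (L/R/NA),
    ``supratentorial`` (bool) and ``cerebellum`` (bool), indexed by region id.
    Either ``label_img`` (a nibabel spatial image whose integer voxel values
    map to region ids through ``label_map``) or ``assignment`` (a precomputed
    sample id -> region id table) must be provided for sample assignment.
    """

    regions: pd.DataFrame
    label_img: object | None = None          # nibabel.Nifti1Image
    label_map: dict[int, str] = field(default_factory=dict)
    assignment: pd.Series | None = None      # sample id -> region id

    def validate(self) -> "AtlasSpec":
        require(self.regions.index.is_unique, "atlas region ids are not unique")
        for col in ("name", "hemisphere", "supratentorial", "cerebellum"):
            require(col in self.regions.columns,
                    f"atlas region table lacks required column {col!r}")
        if self.label_img is not None:
            unknown = set(self.label_map.values()) - set(self.regions.index)
            require(not unknown,
                    f"label map points at unknown region ids: {sorted(unknown)}")
        return self


@dataclass
class RegionSelection:
    """Ordered analysis regions and the original-id -> analysis-id mapping."""

    regions: list[str]
    region_map: dict[str, str]


@dataclass
class RegionExpressionMatrix:
    """Gene x analysis-region expression (median over contributing samples)."""

    values: pd.DataFrame                 # genes x regions
    sample_counts: pd.Series             # region -> n contributing samples
    scope: str                           # "pooled" or a donor id
    dropped_regions: list[str] = field(default_factory=list)

    def validate(self) -> "RegionExpressionMatrix":
        require(not self.values.isna().any().any(),
                "region expression matrix contains missing values")
        return self


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_probes(bundle: DonorExpressionBundle,
                  whitelist: set[str] | list[str]) -> DonorExpressionBundle:
    """Drop probes whose gene symbol is not on the approved-symbol whitelist.

    Emulates restricting the gene universe to symbols resolvable in a
    nomenclature database; the surviving unique symbols define the gene
    universe for everything downstream.
    """
    whitelist = set(whitelist)
    require(len(whitelist) > 0, "symbol whitelist is empty")
    keep = bundle.probes["gene_symbol"].isin(whitelist)
    if not keep.any():
        raise ValidationError("no probes survive the symbol whitelist")
    filtered = DonorExpressionBundle(
        probes=bundle.probes.loc[keep].copy(),
        samples=bundle.samples.copy(),
        expr=bundle.expr.loc[keep].copy(),
    )
    logger.info("probe filter: %d/%d probes kept, %d unique genes",
                int(keep.sum()), len(keep), filtered.probes["gene_symbol"].nunique())
    return filtered


def collapse_probes(bundle: DonorExpressionBundle) -> pd.DataFrame:
    """Average probes of the same gene per sample -> gene x sample matrix."""
    collapsed = bundle.expr.groupby(bundle.probes["gene_symbol"]).mean()
    collapsed.index.name = "gene"
    return collapsed


def assign_samples(samples: pd.DataFrame, atlas: AtlasSpec,
                   max_dist_mm: float = 3.0) -> pd.Series:
    """Map each sample to an atlas region id (NaN where unassignable).

    Table mode (``atlas.assignment`` given) passes the precomputed mapping
    through. Volume mode reads the label at the voxel containing the MNI
    coordinate; background hits fall back to the nearest labeled voxel
    center within ``max_dist_mm``. Coordinates outside the volume are left
    unassigned with a warning.
    """
    if atlas.assignment is not None:
        out = atlas.assignment.reindex(samples.index)
        missing = out.isna().sum()
        if missing:
            warnings.warn(f"{missing} samples absent from the atlas assignment table")
        return out.rename("region_id")

    require(atlas.label_img is not None,
            "atlas provides neither a label volume nor an assignment table")
    img = atlas.label_img
    labels = np.asanyarray(img.dataobj).astype(int)
    inv = np.linalg.inv(img.affine)
    coords = samples[["x", "y", "z"]].to_numpy(float)
    vox = (inv @ np.c_[coords, np.ones(len(coords))].T)[:3].T
    vox = np.rint(vox).astype(int)

    labeled_idx = np.argwhere(labels > 0)
    labeled_world = (img.affine @ np.c_[labeled_idx, np.ones(len(labeled_idx))].T)[:3].T
    from scipy.spatial import cKDTree
    tree = cKDTree(labeled_world) if len(labeled_world) else None

    assigned: list[object] = []
    n_out, n_far = 0, 0
    for i, v in enumerate(vox):
        if np.any(v < 0) or np.any(v >= labels.shape):
            assigned.append(np.nan)
            n_out += 1
            continue
        lab = labels[tuple(v)]
        if lab > 0:
            assigned.append(atlas.label_map.get(int(lab), np.nan))
            continue
        if tree is None:
            assigned.append(np.nan)
            continue
        d, j = tree.query(coords[i])
        if d <= max_dist_mm:
            lab = labels[tuple(labeled_idx[j])]
            assigned.append(atlas.label_map.get(int(lab), np.nan))
        else:
            assigned.append(np.nan)
            n_far += 1
    if n_out:
        warnings.warn(f"{n_out} sample coordinates fall outside the label volume")
    if n_far:
        logger.info("%d samples unassigned (no label within %.1f mm)", n_far, max_dist_mm)
    return pd.Series(assigned, index=samples.index, name="region_id")


def select_analysis_regions(atlas: AtlasSpec) -> RegionSelection:
    """Apply the left-supratentorial + right-cerebellum analysis-region rule.

    Retains every left-hemisphere supratentorial region (ordered by region
    id) and collapses all right-cerebellum labels into the single analysis
    region ``cerebellum_R``. With a 45-per-hemisphere supratentorial atlas
    plus cerebellar labels this yields 46 analysis regions.
    """
    reg = atlas.regions
    left = reg[(reg["hemisphere"] == "L") & reg["supratentorial"]
               & ~reg["cerebellum"]]
    if left.empty:
        raise ValidationError("atlas contains no left-hemisphere supratentorial regions")
    left_ids = sorted(left.index.tolist())
    mapping = {rid: rid for rid in left_ids}

    cb_right = reg[reg["cerebellum"] & (reg["hemisphere"] == "R")]
    regions = list(left_ids)
    if cb_right.empty:
        warnings.warn("atlas has no right-cerebellum label; proceeding with "
                      f"{len(regions)} supratentorial regions only")
    else:
        for rid in cb_right.index:
            mapping[rid] = CEREBELLUM_R_ID
        regions.append(CEREBELLUM_R_ID)
    return RegionSelection(regions=regions, region_map=mapping)


def regionize(gene_by_sample: pd.DataFrame, assignment: pd.Series,
              selection: RegionSelection, *,
              donors: pd.Series | None = None,
              scope: str = "pooled",
              min_samples: int = 1) -> RegionExpressionMatrix:
    """Summarize each analysis region by the median over its samples.

    ``scope='pooled'`` pools every donor's samples into one median per
    region; passing a donor id restricts to that donor's samples (the
    donor-variability analysis). Regions with fewer than ``min_samples``
    contributing samples are dropped with a warning; if none survive this
    is an error.
    """
    region_of = assignment.map(selection.region_map)
    keep = region_of.notna()
    if scope != "pooled":
        require(donors is not None, "per-donor scope requires a donor column")
        keep &= donors.reindex(assignment.index) == scope
    region_of = region_of[keep]

    cols, counts, dropped = {}, {}, []
    for rid in selection.regions:
        sample_ids = region_of.index[region_of == rid]
        if len(sample_ids) < min_samples or len(sample_ids) == 0:
            dropped.append(rid)
            continue
        cols[rid] = gene_by_sample[sample_ids].median(axis=1)
        counts[rid] = len(sample_ids)
    if dropped:
        warnings.warn(f"regions dropped for lack of samples ({scope}): {dropped}")
    if not cols:
        raise ValidationError("every analysis region was dropped during regionization")
    values = pd.DataFrame(cols)
    values.index.name = "gene"
    return RegionExpressionMatrix(
        values=values,
        sample_counts=pd.Series(counts, name="n_samples"),
        scope=scope,
        dropped_regions=dropped,
    ).validate()


def build_region_expression(bundle: DonorExpressionBundle, atlas: AtlasSpec,
                            whitelist: set[str] | list[str], *,
                            max_dist_mm: float = 3.0, scope: str = "pooled",
                            min_samples: int = 1) -> RegionExpressionMatrix:
    """Convenience chain: filter -> collapse -> assign -> regionize."""
    filtered = filter_probes(bundle, whitelist)
    gene_by_sample = collapse_probes(filtered)
    assignment = assign_samples(filtered.samples, atlas, max_dist_mm=max_dist_mm)
    selection = select_analysis_regions(atlas)
    donors = filtered.samples["donor_id"]
    return regionize(gene_by_sample, assignment, selection,
                     donors=donors, scope=scope, min_samples=min_samples)
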