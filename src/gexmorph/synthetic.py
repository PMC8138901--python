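"""Synthetic cohorts, donor expression bundles, atlases and gene-set catalogs.

Every downstream stage of the pipeline is exercised against data generated
here with *known ground truth*: the regional group-effect map a cohort is
built from, the list of "causal" genes whose regional expression tracks the
magnitude of that map, and the catalog categories deliberately packed with
causal genes.

Scale defaults are desk-sized (500 genes, 2 probes/gene, 3 samples/region,
46 analysis regions) while cohort defaults mirror a longitudinal pediatric
morphometry study: 44 controls / 26 persistent / 17 recovered subjects, one
to four visits each spaced a year apart, first-visit ages uniform on
3.0-10.8 years.

The causal-gene link is built in rank space: the standardized midrank of
|group effect| across regions is mixed with gene-specific spatial noise as

    signal_r = coupling * u_r + sqrt(1 - coupling^2) * v_r

so with rank-based correlation downstream the expected gene-map correlation
is controlled directly by ``coupling`` (exactly 1 when coupling = 1 and the
measurement noise vanishes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._validate import ValidationError, require
from .expression import CEREBELLUM_R_ID, AtlasSpec, DonorExpressionBundle
from .glm import GROUPS, LongitudinalDataset

#: the four named genes carried in every generated universe; the two causal
#: ones are coupled to the effect map, the two null ones are not.
NAMED_CAUSAL_GENES = ("GNPTG", "NAGPA")
NAMED_NULL_GENES = ("GNPTAB", "AP4E1")

DEFAULT_N_PER_GROUP = {"control": 44, "persistent": 26, "recovered": 17}

#: per-covariate contributions to regional GMV (volume units per covariate unit)
DEFAULT_COVARIATE_EFFECTS = {
    "sex": 0.010,          # boys minus girls
    "iq": 2.0e-4,
    "brain_size": 3.0e-4,  # per cm^3 of total brain volume
    "ses": 0.0,
    "age": -0.005,         # per year; childhood GMV decline
}

_COVARIATE_MEANS = {  # plausible pediatric-cohort population values
    "iq": (110.0, 14.0),
    "brain_size": (1150.0, 90.0),   # cm^3
    "ses": (50.0, 10.0),
}

_SEVERITY = {  # (mean, sd, low, high) of the severity instrument per group
    "persistent": (21.0, 8.3, 10.5, 48.0),
    "recovered": (13.0, 2.9, 7.0, 19.0),
}

_MALE_FRACTION = {"control": 21 / 44, "persistent": 18 / 26, "recovered": 9 / 17}


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Ground truth for a longitudinal cohort with regional GMV responses."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    visits_per_subject: int | tuple[int, int] = (1, 4)
    age_range: tuple[float, float] = (3.0, 10.8)
    effect_map: dict[str, float] | None = None        # persistent-group effect
    age_slope_map: dict[str, float] | None = None     # persistent x age effect
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    noise_sd: float = 0.05
    subject_sd: float = 0.05
    seed: int = 0

    def validate(self) -> "CohortSpec":
        require(len(self.n_per_group) > 0, "n_per_group: no groups specified")
        for grp, n in self.n_per_group.items():
            require(grp in GROUPS, f"n_per_group: unknown group {grp!r}")
            require(n >= 2, f"n_per_group[{grp!r}]: need >= 2 subjects, got {n}")
        lo, hi = _as_range(self.visits_per_subject)
        require(lo >= 1, f"visits_per_subject: need >= 1 visit, got {lo}")
        require(hi >= lo, "visits_per_subject: empty range")
        require(self.age_range[1] > self.age_range[0],
                "age_range: upper bound must exceed lower bound")
        require(self.noise_sd > 0, f"noise_sd must be > 0, got {self.noise_sd}")
        require(self.subject_sd >= 0,
                f"subject_sd must be >= 0, got {self.subject_sd}")
        return self


@dataclass
class ExpressionSpec:
    """Ground truth for a probe-level donor expression bundle."""

    n_genes: int = 500
    n_causal: int = 25
    probes_per_gene: int | tuple[int, int] = 2
    samples_per_region: int | tuple[int, int] = 3
    n_donors: int = 6
    coupling: float = 0.7
    expr_noise_sd: float = 0.5
    whitelist_fraction: float = 0.9
    n_whitelist: int | None = None
    seed: int = 0

    def validate(self) -> "ExpressionSpec":
        require(self.n_genes >= 1, "n_genes must be positive")
        require(0 <= self.n_causal <= self.n_genes,
                f"n_causal must lie in [0, n_genes], got {self.n_causal}")
        require(self.n_donors >= 1, f"n_donors must be >= 1, got {self.n_donors}")
        require(0.0 <= self.coupling <= 1.0,
                f"coupling must lie in [0, 1], got {self.coupling}")
        require(self.expr_noise_sd >= 0, "expr_noise_sd must be >= 0")
        require(0.0 < self.whitelist_fraction <= 1.0,
                "whitelist_fraction must lie in (0, 1]")
        return self


@dataclass
class CatalogSpec:
    """Ground truth for a gene-set catalog with planted enriched categories."""

    n_categories: int = 20
    category_size_range: tuple[int, int] = (5, 40)
    causal_enriched_categories: int = 2
    causal_member_fraction: float = 0.9   # >= 0.8 per the enrichment contract
    seed: int = 0

    def validate(self) -> "CatalogSpec":
        require(self.n_categories >= 1, "n_categories must be positive")
        lo, hi = self.category_size_range
        require(1 <= lo <= hi, "category_size_range must satisfy 1 <= lo <= hi")
        require(0 <= self.causal_enriched_categories <= self.n_categories,
                "causal_enriched_categories exceeds n_categories")
        require(0.8 <= self.causal_member_fraction <= 1.0,
                "causal_member_fraction must lie in [0.8, 1]")
        return self


def _as_range(v: int | tuple[int, int]) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def gen_atlas(n_per_hemisphere: int = 45, *, with_cerebellum: bool = True,
              shape: tuple[int, int, int] = (12, 12, 14),
              voxel_size: float = 10.0) -> AtlasSpec:
    """Build an AAL-like atlas: paired supratentorial regions + cerebellum.

    The label volume splits a small grid into contiguous blocks, left
    hemisphere at negative x. Region ids are ``L_region_01`` ... and
    ``R_region_01`` ..., plus ``cerebellum_L`` / ``cerebellum_R`` occupying
    the bottom z slab. The affine is diagonal with the grid center at the
    MNI origin, so left-hemisphere voxels have x < 0.
    """
    import nibabel as nib

    nx, ny, nz = shape
    nz_cb = max(2, nz // 5) if with_cerebellum else 0
    rows = []
    for hemi, prefix in (("L", "L_region"), ("R", "R_region")):
        for i in range(1, n_per_hemisphere + 1):
            rows.append((f"{prefix}_{i:02d}", f"{prefix.lower()} {i}", hemi,
                         True, False))
    if with_cerebellum:
        rows.append(("cerebellum_L", "left cerebellum", "L", False, True))
        rows.append((CEREBELLUM_R_ID, "right cerebellum", "R", False, True))
    regions = pd.DataFrame(rows, columns=["region_id", "name", "hemisphere",
                                          "supratentorial", "cerebellum"]
                           ).set_index("region_id")

    labels = np.zeros(shape, dtype=np.int16)
    label_map: dict[int, str] = {}
    next_label = 1

    def paint(voxel_list: np.ndarray, region_ids: list[str]) -> None:
        nonlocal next_label
        for rid, chunk in zip(region_ids,
                              np.array_split(voxel_list, len(region_ids))):
            for v in chunk:
                labels[tuple(v)] = next_label
            label_map[next_label] = rid
            next_label += 1

    half = nx // 2
    supra_z = range(nz_cb, nz)
    for hemi, xs in (("L", range(0, half)), ("R", range(half, nx))):
        vox = np.array([(x, y, z) for x in xs for y in range(ny)
                        for z in supra_z])
        ids = [r for r in regions.index
               if regions.loc[r, "hemisphere"] == hemi
               and regions.loc[r, "supratentorial"]]
        paint(vox, ids)
    if with_cerebellum:
        for hemi, xs, rid in (("L", range(0, half), "cerebellum_L"),
                              ("R", range(half, nx), CEREBELLUM_R_ID)):
            vox = np.array([(x, y, z) for x in xs for y in range(ny)
                            for z in range(nz_cb)])
            paint(vox, [rid])

    center = (np.asarray(shape) - 1) / 2.0
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -center * voxel_size
    img = nib.Nifti1Image(labels, affine)
    return AtlasSpec(regions=regions, label_img=img,
                     label_map=label_map).validate()


def default_regions(n: int = 46) -> list[str]:
    """The default analysis-region list: 45 left regions + right cerebellum."""
    regs = [f"L_region_{i:02d}" for i in range(1, n)]
    regs.append(CEREBELLUM_R_ID)
    return regs


def default_effect_map(regions: list[str], amplitude: float = 0.06,
                       ) -> dict[str, float]:
    """Linearly spaced effect magnitudes with alternating sign.

    Spreading |effect| evenly over regions gives the rank-space expression
    link a full dynamic range; alternating signs exercise the absolute-value
    summary the association stage relies on.
    """
    mags = np.linspace(0.0, amplitude, len(regions))
    return {r: float(m if i % 2 == 0 else -m)
            for i, (r, m) in enumerate(zip(regions, mags))}


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def gen_cohort(spec: CohortSpec, regions: list[str]) -> LongitudinalDataset:
    """Simulate a longitudinal cohort with regional GMV responses.

    Per scan and region the response is
    baseline + subject effect + covariate terms + group effect
    + group x (age - mean age) slope + Gaussian noise.
    Group effects apply to the persistent group only (the recovered group is
    generated effect-free, matching a case-control contrast that is specific
    to persistence).
    """
    spec.validate()
    require(len(regions) > 0, "regions: empty region list")
    effect = spec.effect_map or {}
    age_slope = spec.age_slope_map or {}
    rng = np.random.default_rng(spec.seed)
    R = len(regions)

    baseline = rng.uniform(0.4, 0.8, size=R)
    eff = np.array([effect.get(r, 0.0) for r in regions])
    slope = np.array([age_slope.get(r, 0.0) for r in regions])
    ce = spec.covariate_effects
    vlo, vhi = _as_range(spec.visits_per_subject)
    age_lo, age_hi = spec.age_range
    age_mid = 0.5 * (age_lo + age_hi)

    scan_rows, resp_rows = [], []
    for group in GROUPS:
        if group not in spec.n_per_group:
            continue
        for i in range(spec.n_per_group[group]):
            sid = f"{group[:4]}{i + 1:03d}"
            sex = float(rng.random() < _MALE_FRACTION.get(group, 0.5))
            iq = rng.normal(*_COVARIATE_MEANS["iq"])
            brain = rng.normal(*_COVARIATE_MEANS["brain_size"])
            ses = rng.normal(*_COVARIATE_MEANS["ses"])
            if group == "control":
                severity = np.nan
            else:
                m, s, lo, hi = _SEVERITY[group]
                severity = float(np.clip(rng.normal(m, s), lo, hi))
            subj_effect = rng.normal(0.0, spec.subject_sd, size=R)
            age0 = rng.uniform(age_lo, age_hi)
            n_visits = int(rng.integers(vlo, vhi + 1))
            for v in range(n_visits):
                age = age0 + v * 1.0       # ~12-month intervisit interval
                is_case = float(group == "persistent")
                y = (baseline + subj_effect
                     + is_case * eff
                     + is_case * slope * (age - age_mid)
                     + ce.get("sex", 0.0) * sex
                     + ce.get("iq", 0.0) * (iq - _COVARIATE_MEANS["iq"][0])
                     + ce.get("brain_size", 0.0)
                     * (brain - _COVARIATE_MEANS["brain_size"][0])
                     + ce.get("ses", 0.0) * (ses - _COVARIATE_MEANS["ses"][0])
                     + ce.get("age", 0.0) * (age - age_mid)
                     + rng.normal(0.0, spec.noise_sd, size=R))
                scan_rows.append((f"{sid}_v{v + 1}", sid, group, age, sex,
                                  iq, brain, ses, severity))
                resp_rows.append(y)

    scans = pd.DataFrame(scan_rows, columns=[
        "scan_id", "subject_id", "group", "age", "sex", "iq", "brain_size",
        "ses", "severity"]).set_index("scan_id")
    responses = pd.DataFrame(np.asarray(resp_rows), index=scans.index,
                             columns=regions)
    return LongitudinalDataset(scans=scans, responses=responses,
                               regions=list(regions)).validate()


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(spec: ExpressionSpec, regions: list[str],
                   effect_map: dict[str, float], *,
                   atlas: AtlasSpec | None = None,
                   ) -> tuple[DonorExpressionBundle, dict]:
    """Simulate a donor expression bundle coupled to a regional effect map.

    Returns the bundle plus a ground-truth dict with keys ``causal_genes``,
    ``whitelist`` and ``assignment`` (sample id -> region id). Causal genes'
    regional signal follows the standardized midrank of |effect| mixed with
    gene-specific spatial noise at the requested ``coupling``; null genes are
    spatially independent of the effect map. Probes of one gene share the
    gene signal plus a probe-specific offset; each sample adds Gaussian
    measurement noise. Sample coordinates are drawn inside the region's
    extent of the (synthetic) atlas label volume.
    """
    spec.validate()
    require(all(r in effect_map for r in regions),
            "effect_map does not cover every region")
    rng = np.random.default_rng(spec.seed)
    R = len(regions)

    genes = _gene_symbols(spec.n_genes, spec.n_causal)
    causal = set(genes[:spec.n_causal])

    # rank-space target: standardized midrank of |effect|
    mag = np.abs([effect_map[r] for r in regions])
    u = rankdata(mag)
    u = (u - u.mean()) / (u.std() if u.std() > 0 else 1.0)

    base = rng.normal(6.0, 1.0, size=spec.n_genes)       # log-intensity scale
    V = rng.normal(0.0, 1.0, size=(spec.n_genes, R))     # spatial noise
    cpl = spec.coupling
    is_causal = np.array([g in causal for g in genes])
    signal = np.where(is_causal[:, None],
                      cpl * u[None, :] + np.sqrt(1.0 - cpl ** 2) * V,
                      V)
    M = base[:, None] + signal                           # gene x region means

    # probes
    plo, phi = _as_range(spec.probes_per_gene)
    probe_rows, gene_of_probe = [], []
    for gi, g in enumerate(genes):
        for pi in range(int(rng.integers(plo, phi + 1))):
            probe_rows.append((f"probe_{g}_{pi + 1}", g))
            gene_of_probe.append(gi)
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "gene_symbol"]
                          ).set_index("probe_id")
    gene_of_probe = np.asarray(gene_of_probe)
    probe_offset = rng.normal(0.0, 0.3, size=len(probes))

    # samples: coordinates inside each region's atlas extent
    if atlas is None:
        atlas = gen_atlas()
    region_voxels = _voxels_by_region(atlas)
    slo, shi = _as_range(spec.samples_per_region)
    donors = [f"donor{d + 1}" for d in range(spec.n_donors)]
    sample_rows, sample_region = [], []
    vs = float(atlas.label_img.affine[0, 0])
    k = 0
    for r in regions:
        n_s = int(rng.integers(slo, shi + 1))
        vox = region_voxels.get(r)
        require(vox is not None and len(vox) > 0,
                f"atlas has no voxels for region {r!r}")
        for j in range(n_s):
            v = vox[rng.integers(len(vox))]
            world = atlas.label_img.affine @ np.append(v, 1.0)
            jitter = rng.uniform(-0.45 * vs, 0.45 * vs, size=3)
            donor = donors[(k + j) % spec.n_donors]
            sample_rows.append((f"sample_{k + j + 1:05d}", donor,
                                *(world[:3] + jitter)))
            sample_region.append(r)
        k += n_s
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "donor_id",
                                                 "x", "y", "z"]
                           ).set_index("sample_id")
    assignment = pd.Series(sample_region, index=samples.index,
                           name="region_id")
    samples["structure"] = assignment

    region_index = {r: i for i, r in enumerate(regions)}
    col_region = np.array([region_index[r] for r in sample_region])
    expr = (M[gene_of_probe][:, col_region]
            + probe_offset[:, None]
            + rng.normal(0.0, spec.expr_noise_sd,
                         size=(len(probes), len(samples))))
    expr = pd.DataFrame(expr, index=probes.index, columns=samples.index)

    bundle = DonorExpressionBundle(probes=probes, samples=samples,
                                   expr=expr).validate()
    truth = {
        "causal_genes": sorted(causal),
        "whitelist": _make_whitelist(spec, genes, causal),
        "assignment": assignment,
    }
    return bundle, truth


def _gene_symbols(n_genes: int, n_causal: int) -> list[str]:
    """Gene universe with the four named genes in their designated roles."""
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    for j, name in enumerate(NAMED_CAUSAL_GENES):
        if j < n_causal and j < n_genes:
            genes[j] = name
    for j, name in enumerate(NAMED_NULL_GENES):
        pos = n_causal + j
        if pos < n_genes:
            genes[pos] = name
    return genes


def _make_whitelist(spec: ExpressionSpec, genes: list[str],
                    causal: set[str]) -> list[str]:
    """Whitelist covering causal + named genes first, then remaining nulls."""
    n = (spec.n_whitelist if spec.n_whitelist is not None
         else int(round(spec.whitelist_fraction * len(genes))))
    require(1 <= n <= len(genes),
            f"whitelist size {n} outside [1, {len(genes)}]")
    priority = [g for g in genes
                if g in causal or g in NAMED_NULL_GENES]
    rest = [g for g in genes if g not in set(priority)]
    return sorted((priority + rest)[:n])


def _voxels_by_region(atlas: AtlasSpec) -> dict[str, np.ndarray]:
    labels = np.asanyarray(atlas.label_img.dataobj).astype(int)
    out: dict[str, np.ndarray] = {}
    for lab, rid in atlas.label_map.items():
        vox = np.argwhere(labels == lab)
        if rid in out:
            out[rid] = np.vstack([out[rid], vox])
        else:
            out[rid] = vox
    return out


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def gen_catalog(spec: CatalogSpec, genes: list[str],
                causal_genes: list[str]):
    """Simulate a gene-set catalog with planted causal-enriched categories.

    The first ``causal_enriched_categories`` categories draw at least 80%
    (default 90%) of their members from the causal set; the rest are drawn
    uniformly from the universe.
    """
    from .enrichment import GeneSet, GeneSetCatalog

    spec.validate()
    causal = sorted(set(causal_genes))
    universe = list(genes)
    if not set(causal) <= set(universe):
        raise ValidationError("causal_genes is not a subset of the gene universe")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.category_size_range
    require(hi <= len(universe), "category_size_range exceeds the gene universe")

    sets = []
    for ci in range(spec.n_categories):
        cid = f"GS{ci + 1:04d}"
        if ci < spec.causal_enriched_categories and causal:
            max_size = max(lo, int(len(causal) / spec.causal_member_fraction))
            size = int(rng.integers(lo, min(hi, max_size) + 1))
            n_causal = min(len(causal), max(1, int(np.ceil(
                spec.causal_member_fraction * size))))
            members = list(rng.choice(causal, size=n_causal, replace=False))
            others = [g for g in universe if g not in set(members)]
            n_fill = size - n_causal
            if n_fill > 0:
                members += list(rng.choice(others, size=n_fill, replace=False))
            name = f"planted enriched set {ci + 1}"
        else:
            size = int(rng.integers(lo, hi + 1))
            members = list(rng.choice(universe, size=size, replace=False))
            name = f"random set {ci + 1}"
        sets.append(GeneSet(id=cid, name=name, members=frozenset(members)))
    return GeneSetCatalog(sets=sets, source="synthetic",
                          enriched_ids=[s.id for s in
                                        sets[:spec.causal_enriched_categories]])


# ---------------------------------------------------------------------------
# one-call scenario
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A complete synthetic study: cohort, expression, atlas, catalog, truth."""

    dataset: LongitudinalDataset
    bundle: DonorExpressionBundle
    atlas: AtlasSpec
    catalog: object
    effect_map: dict[str, float]
    causal_genes: list[str]
    whitelist: list[str]
    assignment: pd.Series


def gen_scenario(seed: int = 0, *,
                 cohort: CohortSpec | None = None,
                 expression: ExpressionSpec | None = None,
                 catalog: CatalogSpec | None = None,
                 n_regions: int = 46) -> Scenario:
    """Generate a coherent study under one root seed (stage-wise substreams)."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    cohort = replace(cohort or CohortSpec(), seed=seeds[0])
    expression = replace(expression or ExpressionSpec(), seed=seeds[1])
    catalog = replace(catalog or CatalogSpec(), seed=seeds[2])

    atlas = gen_atlas()
    regions = default_regions(n_regions)
    effect_map = cohort.effect_map or default_effect_map(regions)
    cohort = replace(cohort, effect_map=effect_map)
    dataset = gen_cohort(cohort, regions)
    bundle, truth = gen_expression(expression, regions, effect_map,
                                   atlas=atlas)
    causal = truth["causal_genes"]
    universe = sorted(set(truth["whitelist"]))
    cat = gen_catalog(catalog, universe,
                      [g for g in causal if g in set(universe)])
    return Scenario(dataset=dataset, bundle=bundle, atlas=atlas, catalog=cat,
                    effect_map=effect_map, causal_genes=causal,
                    whitelist=truth["whitelist"], assignment=truth["assignment"])
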