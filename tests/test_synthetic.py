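"""Generator contracts: determinism, ground-truth recovery, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import gexmorph as gx
from gexmorph import ValidationError
from gexmorph.synthetic import (CatalogSpec, CohortSpec, ExpressionSpec,
                                default_effect_map, default_regions,
                                gen_atlas, gen_catalog, gen_cohort,
                                gen_expression)

REGIONS = default_regions(10)


def _regionized(bundle, truth, atlas):
    mat = gx.build_region_expression(bundle, atlas, truth["whitelist"])
    return mat.values


class TestCohort:
    def test_fixed_seed_is_bit_identical(self):
        spec = CohortSpec(n_per_group={"control": 5, "persistent": 4}, seed=3)
        a = gen_cohort(spec, REGIONS)
        b = gen_cohort(spec, REGIONS)
        pd.testing.assert_frame_equal(a.scans, b.scans)
        pd.testing.assert_frame_equal(a.responses, b.responses)

    def test_degenerate_noise_gives_constant_baseline(self):
        spec = CohortSpec(n_per_group={"control": 3, "persistent": 3},
                          noise_sd=1e-12, subject_sd=0.0,
                          covariate_effects={}, seed=0)
        ds = gen_cohort(spec, REGIONS)
        assert ds.responses.std(axis=0).max() < 1e-9

    def test_group_sizes_match_spec(self):
        spec = CohortSpec(n_per_group={"control": 44, "persistent": 26},
                          seed=0)
        ds = gen_cohort(spec, REGIONS)
        assert ds.n_subjects == 70
        per_group = ds.scans.groupby("group")["subject_id"].nunique()
        assert per_group["control"] == 44 and per_group["persistent"] == 26

    @pytest.mark.parametrize("bad, message", [
        (dict(n_per_group={"control": 1, "persistent": 4}), "n_per_group"),
        (dict(noise_sd=0.0), "noise_sd"),
        (dict(visits_per_subject=0), "visits_per_subject"),
        (dict(age_range=(10.0, 3.0)), "age_range"),
    ])
    def test_invalid_spec_names_field(self, bad, message):
        with pytest.raises(ValidationError, match=message):
            gen_cohort(CohortSpec(**bad), REGIONS)

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValidationError, match="regions"):
            gen_cohort(CohortSpec(), [])

    def test_group_effect_recovered_by_independent_ols(self):
        # parameter-recovery oracle: plain lstsq on the generated data
        regions = ["r1", "r2"]
        spec = CohortSpec(n_per_group={"control": 200, "persistent": 200},
                          effect_map={"r1": 0.5}, visits_per_subject=1,
                          seed=5)
        ds = gen_cohort(spec, regions)
        design = gx.build_design(ds)
        X = design.X.to_numpy()
        beta, *_ = np.linalg.lstsq(X, ds.responses["r1"].to_numpy(),
                                   rcond=None)
        b = beta[list(design.X.columns).index("group")]
        # SE from the independent OLS fit
        resid = ds.responses["r1"].to_numpy() - X @ beta
        sigma2 = resid @ resid / (len(resid) - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(b - 0.5) < 3 * se

    def test_ages_within_range_and_annual_spacing(self):
        spec = CohortSpec(n_per_group={"control": 10, "persistent": 10},
                          seed=2)
        ds = gen_cohort(spec, REGIONS)
        first = ds.scans.groupby("subject_id")["age"].min()
        assert (first >= 3.0).all() and (first <= 10.8).all()
        gaps = ds.scans.sort_values("age").groupby("subject_id")["age"].diff()
        assert np.allclose(gaps.dropna(), 1.0)

    def test_severity_only_for_stuttering_groups(self, scenario):
        scans = scenario.dataset.scans
        assert scans.loc[scans["group"] == "control", "severity"].isna().all()
        assert scans.loc[scans["group"] != "control", "severity"].notna().all()


class TestExpression:
    def test_perfect_coupling_zero_noise_gives_rho_one(self):
        regions = default_regions(46)
        effect = default_effect_map(regions)
        spec = ExpressionSpec(n_genes=5, n_causal=1, coupling=1.0,
                              expr_noise_sd=1e-12, seed=3)
        bundle, truth = gen_expression(spec, regions, effect)
        values = _regionized(bundle, truth, gen_atlas())
        gene = truth["causal_genes"][0]
        mag = np.abs([effect[r] for r in values.columns])
        rho = spearmanr(values.loc[gene], mag)[0]
        assert rho == pytest.approx(1.0)

    def test_zero_coupling_mean_rho_near_zero(self):
        regions = default_regions(20)
        effect = default_effect_map(regions)
        mag = np.abs([effect[r] for r in regions])
        rhos = []
        for seed in range(40):
            spec = ExpressionSpec(n_genes=10, n_causal=5, coupling=0.0,
                                  probes_per_gene=1, samples_per_region=1,
                                  whitelist_fraction=1.0, seed=seed)
            bundle, truth = gen_expression(spec, regions, effect)
            values = _regionized(bundle, truth, gen_atlas())
            for g in truth["causal_genes"]:
                rhos.append(spearmanr(values.loc[g], mag)[0])
        rhos = np.asarray(rhos)
        assert abs(rhos.mean()) < 2 * rhos.std() / np.sqrt(len(rhos))

    def test_coupling_monotonically_increases_causal_rho(self):
        regions = default_regions(30)
        effect = default_effect_map(regions)
        mag = np.abs([effect[r] for r in regions])
        means = []
        for coupling in (0.0, 0.5, 1.0):
            rhos = []
            for seed in range(10):
                spec = ExpressionSpec(n_genes=20, n_causal=10,
                                      coupling=coupling, seed=seed)
                bundle, truth = gen_expression(spec, regions, effect)
                values = _regionized(bundle, truth, gen_atlas())
                rhos += [spearmanr(values.loc[g], mag)[0]
                         for g in truth["causal_genes"]]
            means.append(np.mean(rhos))
        assert means[0] < means[1] < means[2]

    def test_donor_count(self, scenario):
        assert len(scenario.bundle.donors) == 6

    def test_probes_share_gene_signal(self, scenario):
        # two probes of one gene correlate strongly across samples
        probes = scenario.bundle.probes
        gene = probes["gene_symbol"].iloc[0]
        ids = probes.index[probes["gene_symbol"] == gene]
        if len(ids) >= 2:
            a, b = scenario.bundle.expr.loc[ids[0]], scenario.bundle.expr.loc[ids[1]]
            assert np.corrcoef(a, b)[0, 1] > 0.5

    def test_coupling_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="coupling"):
            gen_expression(ExpressionSpec(coupling=1.5), REGIONS,
                           {r: 0.0 for r in REGIONS})

    def test_effect_map_must_cover_regions(self):
        with pytest.raises(ValidationError, match="effect_map"):
            gen_expression(ExpressionSpec(), REGIONS, {REGIONS[0]: 1.0})

    def test_samples_fall_inside_their_region(self, scenario):
        recovered = gx.assign_samples(scenario.bundle.samples, scenario.atlas,
                                      max_dist_mm=0.0)
        assert (recovered == scenario.assignment).all()

    def test_named_genes_present_with_roles(self, scenario):
        universe = set(scenario.bundle.gene_universe)
        causal = set(scenario.causal_genes)
        assert {"GNPTG", "NAGPA", "GNPTAB", "AP4E1"} <= universe
        assert {"GNPTG", "NAGPA"} <= causal
        assert not ({"GNPTAB", "AP4E1"} & causal)


class TestCatalog:
    def test_universe_category_factor_is_one(self, toy_association):
        genes = list(toy_association.index)
        cat = gen_catalog(CatalogSpec(n_categories=1,
                                      category_size_range=(200, 200),
                                      causal_enriched_categories=0),
                          genes, [])
        selected = genes[:10]
        table = gx.fisher_enrichment(selected, cat, genes)
        assert table["factor"].iloc[0] == pytest.approx(1.0)

    def test_perfect_overlap(self):
        genes = [f"G{i}" for i in range(50)]
        causal = genes[:12]
        cat = gx.GeneSetCatalog(sets=[gx.GeneSet("c1", "causal set",
                                                 frozenset(causal))])
        table = gx.fisher_enrichment(causal, cat, genes)
        assert table["k"].iloc[0] == len(causal)

    def test_enriched_categories_are_mostly_causal(self):
        genes = [f"G{i}" for i in range(300)]
        causal = genes[:40]
        spec = CatalogSpec(n_categories=10, causal_enriched_categories=3,
                           category_size_range=(10, 30), seed=1)
        cat = gen_catalog(spec, genes, causal)
        for gs in cat.sets[:3]:
            frac = len(gs.members & set(causal)) / len(gs.members)
            assert frac >= 0.8

    def test_causal_not_subset_rejected(self):
        with pytest.raises(ValidationError, match="subset"):
            gen_catalog(CatalogSpec(), ["a", "b"], ["z"])

    def test_all_members_from_universe(self):
        genes = [f"G{i}" for i in range(100)]
        cat = gen_catalog(CatalogSpec(n_categories=8, seed=2), genes,
                          genes[:10])
        for gs in cat.sets:
            assert gs.members <= set(genes)
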