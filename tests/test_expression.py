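"""Probe filtering, aggregation, sample assignment, and regionization."""

import numpy as np
import pandas as pd
import pytest

import gexmorph as gx
from gexmorph import ValidationError
from gexmorph.expression import (AtlasSpec, DonorExpressionBundle,
                                 CEREBELLUM_R_ID, assign_samples,
                                 collapse_probes, filter_probes, regionize,
                                 select_analysis_regions)


def _toy_bundle(n_genes=10, probes_per_gene=2, n_samples=6, seed=0):
    rng = np.random.default_rng(seed)
    probe_rows = [(f"p{g}_{i}", f"G{g:03d}") for g in range(n_genes)
                  for i in range(probes_per_gene)]
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "gene_symbol"]
                          ).set_index("probe_id")
    samples = pd.DataFrame({
        "donor_id": ["d1"] * n_samples,
        "x": rng.uniform(-50, 0, n_samples),
        "y": rng.uniform(-50, 50, n_samples),
        "z": rng.uniform(-50, 50, n_samples),
    }, index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id"))
    expr = pd.DataFrame(rng.normal(6, 1, (len(probes), n_samples)),
                        index=probes.index, columns=samples.index)
    return DonorExpressionBundle(probes=probes, samples=samples,
                                 expr=expr).validate()


class TestFilterProbes:
    def test_full_whitelist_leaves_bundle_unchanged(self):
        bundle = _toy_bundle()
        out = filter_probes(bundle, bundle.gene_universe)
        pd.testing.assert_frame_equal(out.expr, bundle.expr)

    def test_partial_whitelist_counts(self):
        bundle = _toy_bundle(n_genes=10)
        out = filter_probes(bundle, [f"G{g:03d}" for g in range(7)])
        assert len(out.gene_universe) == 7

    def test_empty_survivors_rejected(self):
        with pytest.raises(ValidationError, match="whitelist|probes"):
            filter_probes(_toy_bundle(), ["NOPE"])

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            filter_probes(_toy_bundle(), [])


class TestCollapseProbes:
    def test_mean_of_two_probes(self):
        bundle = _toy_bundle(n_genes=1, probes_per_gene=2, n_samples=1)
        bundle.expr.iloc[:, 0] = [2.0, 4.0]
        assert collapse_probes(bundle).iloc[0, 0] == pytest.approx(3.0)

    def test_single_probe_passthrough(self):
        bundle = _toy_bundle(n_genes=3, probes_per_gene=1)
        out = collapse_probes(bundle)
        np.testing.assert_allclose(out.to_numpy(),
                                   bundle.expr.to_numpy())

    def test_matches_manual_groupby_mean(self):
        bundle = _toy_bundle(n_genes=3, probes_per_gene=2, n_samples=4)
        out = collapse_probes(bundle)
        for gene in out.index:
            ids = bundle.probes.index[bundle.probes["gene_symbol"] == gene]
            expected = bundle.expr.loc[ids].to_numpy().mean(axis=0)
            np.testing.assert_allclose(out.loc[gene].to_numpy(), expected)

    def test_invariant_to_probe_row_order(self):
        bundle = _toy_bundle(seed=3)
        perm = np.random.default_rng(0).permutation(len(bundle.probes))
        shuffled = DonorExpressionBundle(probes=bundle.probes.iloc[perm],
                                        samples=bundle.samples,
                                        expr=bundle.expr.iloc[perm])
        pd.testing.assert_frame_equal(collapse_probes(bundle).sort_index(),
                                      collapse_probes(shuffled).sort_index())


class TestAssignSamples:
    def test_volume_lookup_recovers_truth(self, scenario):
        out = assign_samples(scenario.bundle.samples, scenario.atlas)
        assert (out == scenario.assignment).all()

    def test_background_tolerance_semantics(self):
        import nibabel as nib
        labels = np.zeros((5, 5, 5), np.int16)
        labels[0, 0, 0] = 1
        atlas = AtlasSpec(
            regions=pd.DataFrame({"name": ["a"], "hemisphere": ["L"],
                                  "supratentorial": [True],
                                  "cerebellum": [False]},
                                 index=pd.Index(["L_a"], name="region_id")),
            label_img=nib.Nifti1Image(labels, np.eye(4)),
            label_map={1: "L_a"})
        # sample 2 mm from the labeled voxel center, in background
        samples = pd.DataFrame({"donor_id": ["d"], "x": [2.0], "y": [0.0],
                                "z": [0.0]},
                               index=pd.Index(["s"], name="sample_id"))
        assert assign_samples(samples, atlas, max_dist_mm=3.0)["s"] == "L_a"
        assert pd.isna(assign_samples(samples, atlas, max_dist_mm=1.0)["s"])

    def test_outside_volume_warns(self):
        import nibabel as nib
        labels = np.ones((3, 3, 3), np.int16)
        atlas = AtlasSpec(
            regions=pd.DataFrame({"name": ["a"], "hemisphere": ["L"],
                                  "supratentorial": [True],
                                  "cerebellum": [False]},
                                 index=pd.Index(["L_a"], name="region_id")),
            label_img=nib.Nifti1Image(labels, np.eye(4)),
            label_map={1: "L_a"})
        samples = pd.DataFrame({"donor_id": ["d"], "x": [99.0], "y": [0.0],
                                "z": [0.0]},
                               index=pd.Index(["s"], name="sample_id"))
        with pytest.warns(UserWarning, match="outside"):
            out = assign_samples(samples, atlas)
        assert pd.isna(out["s"])

    def test_matches_exhaustive_nearest_voxel_search(self):
        # sparse-label atlas so the nearest-voxel fallback is exercised
        import nibabel as nib
        rng = np.random.default_rng(5)
        labels = np.where(rng.random((8, 8, 8)) < 0.15,
                          rng.integers(1, 4, (8, 8, 8)), 0).astype(np.int16)
        regions = pd.DataFrame(
            {"name": list("abc"), "hemisphere": ["L"] * 3,
             "supratentorial": [True] * 3, "cerebellum": [False] * 3},
            index=pd.Index(["L_a", "L_b", "L_c"], name="region_id"))
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        atlas = AtlasSpec(regions=regions,
                          label_img=nib.Nifti1Image(labels, affine),
                          label_map={1: "L_a", 2: "L_b", 3: "L_c"})
        # strictly in-bounds world coordinates
        pts = rng.uniform(0.0, 7.0 * 2.0, size=(100, 3))
        samples = pd.DataFrame(pts, columns=["x", "y", "z"],
                               index=pd.Index([f"q{i}" for i in range(100)],
                                              name="sample_id"))
        samples.insert(0, "donor_id", "d")
        max_dist = 4.0
        got = assign_samples(samples, atlas, max_dist_mm=max_dist)

        labeled = np.argwhere(labels > 0)
        world = labeled * 2.0
        for i, sid in enumerate(samples.index):
            v = np.rint(pts[i] / 2.0).astype(int)
            if labels[tuple(v)] > 0:
                expected = atlas.label_map[int(labels[tuple(v)])]
            else:
                d = np.linalg.norm(world - pts[i], axis=1)
                j = int(np.argmin(d))
                expected = (atlas.label_map[int(labels[tuple(labeled[j])])]
                            if d[j] <= max_dist else None)
            if expected is None:
                assert pd.isna(got[sid])
            else:
                assert got[sid] == expected


class TestSelectAnalysisRegions:
    def test_aal_like_atlas_yields_46(self):
        selection = select_analysis_regions(gx.gen_atlas(45))
        assert len(selection.regions) == 46
        assert selection.regions[-1] == CEREBELLUM_R_ID
        assert selection.regions[:-1] == sorted(selection.regions[:-1])

    def test_no_cerebellum_yields_45_with_warning(self):
        atlas = gx.gen_atlas(45, with_cerebellum=False)
        with pytest.warns(UserWarning, match="cerebellum"):
            selection = select_analysis_regions(atlas)
        assert len(selection.regions) == 45

    def test_right_only_atlas_rejected(self):
        atlas = gx.gen_atlas(3)
        regions = atlas.regions[atlas.regions["hemisphere"] == "R"]
        with pytest.raises(ValidationError, match="left"):
            select_analysis_regions(AtlasSpec(regions=regions))

    def test_multiple_right_cerebellar_labels_merge_to_one(self):
        atlas = gx.gen_atlas(3)
        extra = pd.DataFrame(
            {"name": ["crus I", "crus II"], "hemisphere": ["R", "R"],
             "supratentorial": [False, False], "cerebellum": [True, True]},
            index=pd.Index(["cb_R_1", "cb_R_2"], name="region_id"))
        atlas.regions = pd.concat([atlas.regions, extra])
        selection = select_analysis_regions(atlas)
        assert selection.regions.count(CEREBELLUM_R_ID) == 1
        assert selection.region_map["cb_R_1"] == CEREBELLUM_R_ID
        assert selection.region_map["cb_R_2"] == CEREBELLUM_R_ID


class TestRegionize:
    def _inputs(self, values_by_region):
        regions = list(values_by_region)
        sample_ids, assignment, values = [], [], []
        for r, vals in values_by_region.items():
            for v in vals:
                sid = f"s{len(sample_ids)}"
                sample_ids.append(sid)
                assignment.append(r)
                values.append(v)
        gbs = pd.DataFrame([values], index=pd.Index(["g1"], name="gene"),
                           columns=sample_ids)
        assignment = pd.Series(assignment, index=sample_ids)
        selection = gx.RegionSelection(regions=regions,
                                       region_map={r: r for r in regions})
        return gbs, assignment, selection

    def test_median_is_robust_summary(self):
        gbs, assignment, selection = self._inputs({"rA": [1.0, 2.0, 10.0]})
        out = regionize(gbs, assignment, selection)
        assert out.values.loc["g1", "rA"] == pytest.approx(2.0)

    def test_single_sample_identity(self):
        gbs, assignment, selection = self._inputs({"rA": [3.3], "rB": [4.4]})
        out = regionize(gbs, assignment, selection)
        assert out.values.loc["g1", "rA"] == pytest.approx(3.3)
        assert out.values.loc["g1", "rB"] == pytest.approx(4.4)

    def test_matches_manual_groupby_median(self, scenario):
        gbs = collapse_probes(scenario.bundle)
        selection = select_analysis_regions(scenario.atlas)
        out = regionize(gbs, scenario.assignment, selection)
        rng = np.random.default_rng(0)
        for gene in rng.choice(gbs.index, 5, replace=False):
            for region in rng.choice(out.values.columns, 5, replace=False):
                ids = scenario.assignment.index[
                    scenario.assignment.map(selection.region_map) == region]
                expected = float(np.median(gbs.loc[gene, ids]))
                assert out.values.loc[gene, region] == pytest.approx(expected)

    def test_invariant_to_sample_column_order(self, scenario):
        gbs = collapse_probes(scenario.bundle)
        selection = select_analysis_regions(scenario.atlas)
        perm = np.random.default_rng(1).permutation(gbs.shape[1])
        out1 = regionize(gbs, scenario.assignment, selection)
        out2 = regionize(gbs.iloc[:, perm], scenario.assignment, selection)
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_median_resists_minority_outliers(self):
        gbs, assignment, selection = self._inputs({"rA": [1.0, 2.0, 3.0]})
        out1 = regionize(gbs, assignment, selection)
        gbs.iloc[0, 2] = 1e6  # corrupt 1 of 3 samples
        out2 = regionize(gbs, assignment, selection)
        assert out1.values.loc["g1", "rA"] == out2.values.loc["g1", "rA"]

    def test_pooled_equals_single_donor_when_one_donor(self):
        gbs, assignment, selection = self._inputs({"rA": [1.0, 5.0],
                                                   "rB": [2.0]})
        donors = pd.Series("d1", index=assignment.index)
        pooled = regionize(gbs, assignment, selection, donors=donors,
                           scope="pooled")
        single = regionize(gbs, assignment, selection, donors=donors,
                           scope="d1")
        pd.testing.assert_frame_equal(pooled.values, single.values)

    def test_underpopulated_region_dropped_with_warning(self):
        gbs, assignment, selection = self._inputs({"rA": [1.0, 2.0],
                                                   "rB": [3.0]})
        with pytest.warns(UserWarning, match="rB"):
            out = regionize(gbs, assignment, selection, min_samples=2)
        assert out.dropped_regions == ["rB"]

    def test_all_regions_dropped_is_error(self):
        gbs, assignment, selection = self._inputs({"rA": [1.0]})
        with pytest.raises(ValidationError, match="dropped"):
            regionize(gbs, assignment, selection, min_samples=5)
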