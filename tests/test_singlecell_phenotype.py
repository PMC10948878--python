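"""Cell filtering, standardization, batch correction, clustering, ratios."""

import numpy as np
import pandas as pd
import pytest

from uromet import singlecell_phenotype as sp
from uromet import synthetic_data as sd


@pytest.fixture(scope="module")
def processed(singlecell_sim):
    feat, kept = sp.preprocess_cells(singlecell_sim.cells, singlecell_sim.panel)
    return feat, kept


class TestPreprocess:
    def test_solidity_one_excluded(self, singlecell_sim, processed):
        _, kept = processed
        cells = singlecell_sim.cells
        assert (cells.loc[kept, "solidity"] != 1.0).all()
        assert len(kept) == (cells.solidity != 1.0).sum()

    def test_values_respect_cap_and_no_nans(self, singlecell_sim, processed):
        """Features equal the capped per-image z after global standardization."""
        feat, kept = processed
        x = feat.to_numpy()
        assert np.isfinite(x).all()
        assert np.abs(x.mean(axis=0)).max() < 1e-9  # globally centered
        assert np.allclose(x.std(axis=0), 1.0)  # globally scaled
        # independently re-derive: log1p -> per-image z -> cap -> standardize
        cells = singlecell_sim.cells.loc[kept]
        logx = np.log1p(cells[singlecell_sim.panel.all_markers].astype(float))
        z = logx.groupby(cells.image_id).transform(
            lambda v: (v - v.mean()) / v.std(ddof=0))
        z = z.fillna(0.0).clip(-3, 3)
        assert np.abs(z.to_numpy()).max() <= 3.0  # the cap itself
        expected = (z - z.mean()) / z.std(ddof=0)
        assert np.allclose(x, expected.to_numpy(), atol=1e-9)

    def test_cap_applied_before_global_scaling(self):
        panel = sp.PanelConfig(clustering_markers=["M"], functional_markers=[])
        vals = np.r_[np.ones(50), [1e6]]  # one extreme outlier
        cells = pd.DataFrame({
            "image_id": ["img"] * 51, "solidity": [0.9] * 51, "M": vals,
        })
        feat, kept = sp.preprocess_cells(cells, panel)
        z = feat["M"]
        # outlier capped to +3 in image-z, then globally standardized:
        # it cannot dominate beyond the capped range
        raw_z = (np.log1p(vals) - np.log1p(vals).mean()) / np.log1p(vals).std()
        assert raw_z.max() > 3  # uncapped would exceed
        capped = np.clip(raw_z, -3, 3)
        expected = (capped - capped.mean()) / capped.std()
        assert z.to_numpy() == pytest.approx(expected, abs=1e-9)

    def test_constant_marker_within_image_zero(self):
        panel = sp.PanelConfig(clustering_markers=["M"], functional_markers=[])
        cells = pd.DataFrame({"image_id": ["a"] * 4 + ["b"] * 4,
                              "solidity": [0.9] * 8,
                              "M": [5.0] * 4 + [1.0, 2.0, 3.0, 4.0]})
        feat, _ = sp.preprocess_cells(cells, panel)
        assert np.allclose(feat["M"].iloc[:4] - feat["M"].iloc[:4].mean(), 0.0)

    def test_single_cell_image_warns(self):
        panel = sp.PanelConfig(clustering_markers=["M"], functional_markers=[])
        cells = pd.DataFrame({"image_id": ["solo", "a", "a", "a"],
                              "solidity": [0.9] * 4, "M": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="single cell"):
            feat, kept = sp.preprocess_cells(cells, panel)
        assert len(kept) == 4

    def test_missing_channel_rejected(self, singlecell_sim):
        with pytest.raises(ValueError, match="missing panel channels"):
            sp.preprocess_cells(singlecell_sim.cells.drop(columns=["CD3"]),
                                singlecell_sim.panel)

    def test_functional_markers_cannot_cluster(self):
        with pytest.raises(ValueError):
            sp.PanelConfig(clustering_markers=["CD3", "Ki67"], functional_markers=["Ki67"])


class TestCorrectBatch:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(0)
        f = pd.DataFrame(rng.normal(size=(50, 4)))
        out = sp.correct_batch(f, ["b1"] * 50)
        pd.testing.assert_frame_equal(out, f)

    def test_location_shift_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (300, 6))
        b = rng.normal(0, 1, (300, 6)) + 2.0
        f = pd.DataFrame(np.vstack([a, b]))
        out = sp.correct_batch(f, ["b1"] * 300 + ["b2"] * 300)
        diff = out.iloc[:300].mean() - out.iloc[300:].mean()
        assert np.abs(diff).max() < 0.05

    def test_scale_factor_removed(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (400, 6))
        b = rng.normal(0, 2, (400, 6))
        f = pd.DataFrame(np.vstack([a, b]))
        out = sp.correct_batch(f, ["b1"] * 400 + ["b2"] * 400)
        ratio = out.iloc[:400].var() / out.iloc[400:].var()
        assert ((ratio > 0.9) & (ratio < 1.1)).all()

    def test_global_mean_preserved(self, processed, singlecell_sim):
        feat, kept = processed
        batches = singlecell_sim.cells.loc[kept, "batch_id"]
        out = sp.correct_batch(feat, batches)
        assert np.abs(out.mean() - feat.mean()).max() < 1e-6

    def test_singleton_batch_rejected(self):
        f = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            sp.correct_batch(f, ["b1", "b1", "b2"])


class TestClustering:
    def three_pop_features(self, n=900, seed=3):
        rng = np.random.default_rng(seed)
        centers = np.array([[0.0] * 6, [8.0] * 6, [-8.0, 8.0, -8.0, 8.0, -8.0, 8.0]])
        truth = np.repeat([0, 1, 2], n // 3)
        x = centers[truth] + rng.normal(0, 1, (n, 6))
        batches = np.array(["b1", "b2"] * (n // 2))
        return pd.DataFrame(x), batches, truth

    def test_separated_populations_pure(self):
        f, batches, truth = self.three_pop_features()
        labels = sp.embed_and_cluster(f, batches, n_pcs=5, seed=0)
        ct = pd.crosstab(labels, truth)
        purity = ct.max(axis=1).sum() / len(truth)
        assert purity >= 0.99

    def test_duplicates_co_assigned(self):
        f, batches, _ = self.three_pop_features(n=300)
        f2 = pd.concat([f, f], ignore_index=True)
        b2 = np.concatenate([batches, batches])
        labels = sp.embed_and_cluster(f2, b2, n_pcs=5, seed=1)
        assert (labels.iloc[:300].to_numpy() == labels.iloc[300:].to_numpy()).mean() > 0.99

    def test_near_zero_resolution_single_cluster(self):
        """On a connected neighbor graph, resolution -> 0 merges everything."""
        rng = np.random.default_rng(11)
        f = pd.DataFrame(rng.normal(0, 1, (300, 6)))  # one population
        batches = np.array(["b1", "b2"] * 150)
        labels = sp.embed_and_cluster(f, batches, n_pcs=5, resolution=1e-4, seed=2)
        assert labels.nunique() == 1

    def test_deterministic_given_seed(self):
        f, batches, _ = self.three_pop_features(n=300)
        a = sp.embed_and_cluster(f, batches, n_pcs=5, seed=7)
        b = sp.embed_and_cluster(f, batches, n_pcs=5, seed=7)
        assert (a == b).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            sp.embed_and_cluster(pd.DataFrame(np.zeros((5, 3))), ["b"] * 5, n_pcs=30)


class TestMetaclusters:
    def test_rule_matching(self, singlecell_sim):
        feat, kept = sp.preprocess_cells(singlecell_sim.cells, singlecell_sim.panel)
        truth = singlecell_sim.cells.loc[kept, "cell_id"].map(
            singlecell_sim.sim_truth.cell_population_labels)
        profiles = sp.cluster_profiles(feat, pd.Series(truth.to_numpy(), index=feat.index))
        meta = sp.assign_metaclusters(profiles.drop(columns="n_cells"),
                                      sp.default_metacluster_rules(), singlecell_sim.panel)
        assert meta["tumor_luminal"] == "Tumor (luminal)"
        assert meta["tumor_basal"] == "Tumor (basal)"
        assert meta["cd8_tcell"] == "CD8 T cell"
        assert meta["treg"] == "Treg"
        assert meta["macrophage"] == "Macrophage"

    def test_counts_sum_to_clustered_cells(self, processed):
        feat, _ = processed
        labels = pd.Series(np.arange(len(feat)) % 5, index=feat.index)
        prof = sp.cluster_profiles(feat, labels)
        assert prof.n_cells.sum() == len(feat)

    def test_unknown_marker_rejected(self, singlecell_sim):
        rules = [sp.MetaclusterRule("bad", ("NotAMarker",))]
        prof = pd.DataFrame({"CD3": [1.0]})
        with pytest.raises(ValueError, match="unknown markers"):
            sp.assign_metaclusters(prof, rules, singlecell_sim.panel)

    def test_unmatched_cluster_unassigned(self, singlecell_sim):
        markers = singlecell_sim.panel.all_markers
        prof = pd.DataFrame({m: [-1.0] for m in markers})
        meta = sp.assign_metaclusters(prof, sp.default_metacluster_rules(),
                                      singlecell_sim.panel)
        assert meta.iloc[0] == "unassigned"


class TestPlasticity:
    def cells(self, krt5, gata3):
        return pd.DataFrame({"sample_id": ["s"] * len(krt5),
                             "KRT5": krt5, "GATA3": gata3})

    def test_equal_expression_ratio_zero(self, singlecell_sim):
        c = self.cells([5.0, 1.0], [5.0, 1.0])
        per_cell, _ = sp.plasticity_ratio(c, singlecell_sim.panel)
        assert np.allclose(per_cell.log2_krt5_gata3, 0.0)

    def test_fourfold_ratio_two(self, singlecell_sim):
        c = self.cells([400.0], [100.0])
        per_cell, _ = sp.plasticity_ratio(c, singlecell_sim.panel, epsilon=1e-9)
        assert per_cell.log2_krt5_gata3.iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_channel_swap_antisymmetry(self, singlecell_sim):
        rng = np.random.default_rng(4)
        c = self.cells(rng.lognormal(1, 1, 100), rng.lognormal(1, 1, 100))
        fwd, _ = sp.plasticity_ratio(c, singlecell_sim.panel)
        swapped = sp.PanelConfig(
            clustering_markers=singlecell_sim.panel.clustering_markers,
            functional_markers=singlecell_sim.panel.functional_markers,
            krt5_channel="GATA3", gata3_channel="KRT5")
        rev, _ = sp.plasticity_ratio(c, swapped)
        assert np.allclose(fwd.log2_krt5_gata3, -rev.log2_krt5_gata3)

    def test_matched_samples_from_one_population_stable(self):
        res = sd.gen_singlecell_cohort(
            n_cells_per_image=1000, images_per_sample=1, seed=9,
            sample_ids=["pt_P", "pt_M"],
            population_weights={p: (1.0 if p == "tumor_basal" else 0.0)
                                for p in sd.default_population_profiles()},
        )
        _, per_sample = sp.plasticity_ratio(res.cells, res.panel)
        delta = per_sample.loc["pt_M", "median"] - per_sample.loc["pt_P", "median"]
        assert abs(delta) < 0.2

    def test_five_number_summary(self, singlecell_sim):
        c = self.cells([1.0, 2.0, 4.0, 8.0], [1.0, 1.0, 1.0, 1.0])
        _, per_sample = sp.plasticity_ratio(c, singlecell_sim.panel, epsilon=0.0)
        row = per_sample.loc["s"]
        assert row["min"] == pytest.approx(0.0) and row["max"] == pytest.approx(3.0)
        assert row["median"] == pytest.approx(1.5)


class TestInfiltration:
    def test_per_sample_means_and_group_test(self):
        rng = np.random.default_rng(5)
        rows = []
        for g, samples in (("inflamed", [f"i{k}" for k in range(5)]),
                           ("depleted", [f"d{k}" for k in range(5)])):
            lam = 30 if g == "inflamed" else 10
            for s in samples:
                for img in range(2):
                    n_cd8 = rng.poisson(lam)
                    rows += [dict(sample_id=s, image_id=f"{s}_{img}", mc="CD8 T cell")] * n_cd8
                    rows += [dict(sample_id=s, image_id=f"{s}_{img}", mc="Fibroblast")] * 20
        df = pd.DataFrame(rows)
        groups = {s: ("inflamed" if s.startswith("i") else "depleted")
                  for s in df.sample_id.unique()}
        per_image, per_sample, cmp = sp.infiltration_stats(
            df[["sample_id", "image_id"]], df["mc"], groups)
        row = cmp.set_index("metacluster").loc["CD8 T cell"]
        assert row.mean_inflamed > row.mean_depleted
        assert row.p < 0.05

    def test_image_means(self):
        df = pd.DataFrame({"sample_id": ["s"] * 8,
                           "image_id": ["a"] * 3 + ["b"] * 5})
        mc = pd.Series(["CD8 T cell"] * 8)
        groups = {"s": "inflamed", "t": "depleted"}
        # add a depleted sample with zero CD8 so the group test is defined
        df2 = pd.concat([df, pd.DataFrame({"sample_id": ["t"], "image_id": ["c"]})],
                        ignore_index=True)
        mc2 = pd.Series(["CD8 T cell"] * 8 + ["Fibroblast"])
        per_image, per_sample, cmp = sp.infiltration_stats(df2, mc2, groups)
        assert per_sample.loc["s", "CD8 T cell"] == pytest.approx(4.0)  # (3+5)/2
        assert per_sample.loc["t", "CD8 T cell"] == 0.0  # absent -> count 0
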