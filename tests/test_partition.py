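"""Clustering, marker annotation, and population summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from protoquant.partition import (
    ClusterResult,
    MarkerRule,
    MarkerRules,
    annotate_cell_types,
    cluster_mean_heatmap,
    default_marker_rules,
    hierarchical_cluster,
    kmeans_cluster,
    log_volume_normalize,
    population_summary,
)
from protoquant.pipeline import partition_study, quantify_study, simulate_study
from protoquant.quantify import FLAG_ABSENT, FLAG_QUANTIFIED, QuantMatrix


def quant_from_values(values: pd.DataFrame) -> QuantMatrix:
    flags = values.where(values.isna(), FLAG_QUANTIFIED).where(~values.isna(), FLAG_ABSENT)
    return QuantMatrix(values, flags)


class TestLogVolumeNormalize:
    def test_all_zero_areas_constant(self):
        areas = pd.DataFrame(0.0, index=["a", "b"], columns=["f1", "f2"])
        out = log_volume_normalize(areas, [5.0, 10.0], pseudocount=1.0)
        assert (out.to_numpy() == 0.0).all()  # log10(1)

    def test_larger_volume_lowers_values(self):
        areas = pd.DataFrame([[100.0, 10.0]], index=["a"], columns=["f1", "f2"])
        small = log_volume_normalize(areas, [5.0])
        large = log_volume_normalize(areas, [10.0])
        assert (large.to_numpy() < small.to_numpy()).all()

    def test_area_equal_volume_tends_to_zero(self):
        areas = pd.DataFrame([[7.0]], index=["a"], columns=["f1"])
        out = log_volume_normalize(areas, [7.0], pseudocount=1e-15)
        assert out.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_volume_rejected(self):
        areas = pd.DataFrame([[1.0]], index=["a"], columns=["f1"])
        with pytest.raises(ValueError, match="positive"):
            log_volume_normalize(areas, [0.0])


class TestHierarchicalCluster:
    def test_identical_cells_merge_at_zero(self):
        matrix = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        result = hierarchical_cluster(matrix)
        assert result.linkage[0, 2] == pytest.approx(0.0)

    def test_identical_pair_merges_first(self):
        matrix = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [50.0, 50.0]], index=["a", "b", "far"]
        )
        result = hierarchical_cluster(matrix)
        assert set(result.linkage[0, :2].astype(int)) == {0, 1}

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError, match="2 cells"):
            hierarchical_cluster(pd.DataFrame([[1.0]], index=["a"]))

    def test_idioblasts_form_one_subtree_when_noiseless(self, noiseless_leaf_study):
        study = noiseless_leaf_study
        quant = quantify_study(study)
        result = partition_study(study, quant, seed=0)
        hca = hierarchical_cluster(result["transformed"])
        truth = {c.cell_id: c.true_type for c in study.cells}
        ordered_types = [truth[c] for c in hca.ordered_labels()]
        positions = [i for i, t in enumerate(ordered_types) if t == "idioblast"]
        assert positions, "no idioblasts sampled"
        # contiguous block in the deterministic leaf ordering = one subtree
        assert positions == list(range(positions[0], positions[0] + len(positions)))

    def test_leaf_order_deterministic_and_newick_renders(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.normal(size=(12, 4)),
                              index=[f"c{i}" for i in range(12)])
        r1 = hierarchical_cluster(matrix)
        r2 = hierarchical_cluster(matrix.copy())
        assert r1.leaf_order == r2.leaf_order
        newick = r1.to_newick()
        assert newick.endswith(";") and newick.count("(") == 11


class TestKMeans:
    def _blobs(self, n_per=25, k=4, sep=30.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, truth = [], []
        for i in range(k):
            rows.append(rng.normal(loc=i * sep, scale=0.5, size=(n_per, 3)))
            truth += [i] * n_per
        return pd.DataFrame(np.vstack(rows)), np.array(truth)

    def test_k1_single_cluster_total_variance(self):
        matrix, _ = self._blobs(k=2)
        result = kmeans_cluster(matrix, k=1, standardize=False)
        assert set(result.labels) == {1}
        centered = matrix.to_numpy() - matrix.to_numpy().mean(axis=0)
        assert result.inertia == pytest.approx((centered**2).sum(), rel=1e-9)

    def test_separated_blobs_recovered_perfectly(self):
        matrix, truth = self._blobs()
        result = kmeans_cluster(matrix, k=4, seed=1)
        assert adjusted_rand_score(truth, result.labels) == 1.0

    def test_deterministic_given_seed(self):
        matrix, _ = self._blobs(seed=3)
        a = kmeans_cluster(matrix, k=4, seed=5)
        b = kmeans_cluster(matrix, k=4, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_exceeding_cells_rejected(self):
        matrix, _ = self._blobs(n_per=1, k=2)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(matrix, k=5)

    def test_labels_one_based(self):
        matrix, _ = self._blobs()
        result = kmeans_cluster(matrix, k=4, seed=2)
        assert result.labels.min() == 1 and result.labels.max() == 4


class TestMarkerAnnotation:
    def test_serpentine_marks_idioblast(self):
        values = pd.DataFrame(
            {"serpentine": [5.0, np.nan], "loganic acid": [np.nan, 40.0]},
            index=["c1", "c2"],
        )
        labels = annotate_cell_types(quant_from_values(values), default_marker_rules())
        assert labels["c1"] == "idioblast"
        assert labels["c2"] == "ipap"

    def test_priority_order_respected(self):
        values = pd.DataFrame(
            {"serpentine": [5.0], "loganic acid": [40.0]}, index=["c1"]
        )
        labels = annotate_cell_types(quant_from_values(values), default_marker_rules())
        assert labels["c1"] == "idioblast"  # serpentine rule precedes loganic acid

    def test_nothing_quantified_gets_fallback(self):
        values = pd.DataFrame(
            {"serpentine": [np.nan], "loganic acid": [np.nan]}, index=["c1"]
        )
        labels = annotate_cell_types(quant_from_values(values), default_marker_rules())
        assert labels["c1"] == "unassigned"

    def test_unknown_marker_rejected(self):
        values = pd.DataFrame({"serpentine": [1.0]}, index=["c1"])
        rules = MarkerRules((MarkerRule("ghost", 0.1, "x"),))
        with pytest.raises(ValueError, match="ghost"):
            annotate_cell_types(quant_from_values(values), rules)

    def test_noiseless_population_typing_recovers_truth(
        self, noiseless_leaf_study, noiseless_leaf_quant
    ):
        """Marker typing is exact for idioblast and IPAP classes without noise."""
        labels = annotate_cell_types(noiseless_leaf_quant, default_marker_rules())
        truth = {c.cell_id: c.true_type for c in noiseless_leaf_study.cells}
        for cell, label in labels.items():
            if truth[cell] == "idioblast":
                assert label == "idioblast"
            elif truth[cell] == "ipap":
                assert label == "ipap"
            else:
                assert label == "unassigned"


class TestPopulationSummary:
    def test_all_censored_gives_zero_fractions(self):
        values = pd.DataFrame({"secologanin": [np.nan, np.nan]}, index=["a", "b"])
        summary = population_summary(quant_from_values(values))
        row = summary["per_compound"].loc["secologanin"]
        assert row["fraction_quantified"] == 0.0
        assert np.isnan(row["max_mM"])

    def test_single_cell_median_equals_max(self):
        values = pd.DataFrame({"secologanin": [55.0]}, index=["a"])
        row = population_summary(quant_from_values(values))["per_compound"].loc[
            "secologanin"
        ]
        assert row["median_mM"] == row["max_mM"] == 55.0

    def test_total_alkaloid_bounds_constituents(self, library, noiseless_leaf_quant):
        summary = population_summary(noiseless_leaf_quant, library=library)
        totals = summary["per_cell"]["total_alkaloid"]
        filled = noiseless_leaf_quant.values_filled(0.0)
        alkaloids = [
            c.name for c in library
            if c.compound_class == "alkaloid" and c.name in filled.columns
        ]
        for name in alkaloids:
            assert (totals + 1e-9 >= filled[name]).all()
        assert ((totals >= 0) & (totals < 1e6)).all()

    def test_secologanin_rich_fraction_matches_generator(self, noiseless_leaf_quant):
        filled = noiseless_leaf_quant.values_filled(0.0)
        frac = (filled["secologanin"] >= 50.0).mean()
        n = len(filled)
        sd = np.sqrt(0.30 * 0.70 / n)
        assert abs(frac - 0.30) <= 3 * sd


class TestClusterMeanHeatmap:
    def test_single_cluster_equals_column_means(self):
        matrix = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"])
        out = cluster_mean_heatmap(matrix, [1, 1])
        np.testing.assert_allclose(out.loc[1].to_numpy(), [2.0, 3.0])

    def test_singleton_clusters_reproduce_matrix(self):
        matrix = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"])
        out = cluster_mean_heatmap(matrix, [1, 2])
        np.testing.assert_allclose(out.to_numpy(), matrix.to_numpy())

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(rng.normal(size=(10, 3)))
        labels = np.array([1, 2, 1, 3, 2, 1, 3, 2, 1, 3])
        perm = rng.permutation(10)
        out1 = cluster_mean_heatmap(matrix, labels)
        out2 = cluster_mean_heatmap(matrix.iloc[perm], labels[perm])
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy())

    def test_label_mismatch_rejected(self):
        matrix = pd.DataFrame([[1.0]], index=["a"])
        with pytest.raises(ValueError, match="label"):
            cluster_mean_heatmap(matrix, [1, 2])


class TestEndToEndPartition:
    def test_kmeans_on_noiseless_separated_population_is_perfect(self):
        """k-means with k = number of generated types recovers the truth
        exactly when every type always expresses its own marker set.

        The study presets are deliberately NOT this clean (presence
        probabilities below 1 make some cells of different types look
        identical); separability is constructed here, which is what the
        perfect-agreement invariant is about.
        """
        import dataclasses

        from protoquant.synthetic import (
            CellTypeSpec,
            InstrumentConfig,
            PopulationConfig,
            generate_population,
            simulate_calibration_series,
            simulate_measurement,
        )
        from protoquant.library import default_compound_library
        from protoquant.pipeline import SimulatedStudy, quantify_study

        types = (
            CellTypeSpec("t1", 0.25, (20.0, 40.0), {"serpentine": (1.0, (5.0, 20.0))}),
            CellTypeSpec("t2", 0.25, (20.0, 40.0), {"loganic acid": (1.0, (5.0, 20.0))}),
            CellTypeSpec("t3", 0.25, (20.0, 40.0), {"secologanin": (1.0, (50.0, 200.0))}),
            CellTypeSpec("t4", 0.25, (20.0, 40.0), {"mauritianin": (1.0, (5.0, 20.0))}),
        )
        config = PopulationConfig("leaf", "SA", types, n_cells=80, seed=21)
        library = default_compound_library()
        instrument = InstrumentConfig().noiseless()
        cells = generate_population(config)
        table, metadata = simulate_measurement(cells, instrument, library, seed=22)
        calibration = simulate_calibration_series(library, instrument=instrument, seed=23)
        study = SimulatedStudy(config, cells, table, metadata, calibration,
                               instrument, library)
        quant = quantify_study(study)
        result = partition_study(study, quant, k=4, seed=0)
        truth = [c.true_type for c in cells if c.cell_id in quant.cells]
        assert adjusted_rand_score(truth, result["kmeans"].labels) == 1.0
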