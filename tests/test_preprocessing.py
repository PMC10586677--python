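"""Filter rules, KNN imputation and stacking against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import omicstack as om
from omicstack.datatypes import OmicsLayer


def _layer(values, datatype="F1", annotation=None, prefix="f"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsLayer(
        [f"s{i}" for i in range(n)], [f"{prefix}{j}" for j in range(p)],
        values, datatype, annotation,
    )


class TestZeroFilter:
    def test_strict_threshold(self):
        vals = np.ones((10, 3))
        vals[:3, 0] = 0.0  # 30% zeros -> dropped
        vals[:2, 1] = 0.0  # exactly 20% -> retained
        out = om.drop_high_zero(_layer(vals))
        assert out.feature_ids == ["f1", "f2"]

    def test_identity_on_nonzero_layer(self):
        vals = np.arange(1, 21, dtype=float).reshape(4, 5)
        out = om.drop_high_zero(_layer(vals))
        assert out.feature_ids == [f"f{j}" for j in range(5)]
        np.testing.assert_array_equal(out.values, vals)

    def test_all_dropped_is_error(self):
        with pytest.raises(ValueError, match="every feature"):
            om.drop_high_zero(_layer(np.zeros((5, 2))))

    def test_wrong_datatype_rejected(self):
        with pytest.raises(ValueError):
            om.drop_high_zero(_layer(np.ones((4, 2)), datatype="F3"))


class TestMissingFilter:
    def test_strict_threshold(self):
        vals = np.ones((10, 3))
        vals[:2, 0] = np.nan  # 20% missing -> dropped
        vals[0, 1] = np.nan   # 10% exactly -> retained
        out = om.drop_high_missing(_layer(vals, "F4"))
        assert out.feature_ids == ["f1", "f2"]

    def test_identity_on_complete_layer(self):
        vals = np.random.default_rng(0).normal(size=(6, 4))
        out = om.drop_high_missing(_layer(vals, "F3"))
        np.testing.assert_array_equal(out.values, vals)


class TestSexChromosomeFilter:
    def test_drops_x_and_y_only(self):
        ann = {"f0": "chrX", "f1": "chr1", "f2": "chrY", "f3": "chr22"}
        out = om.drop_sex_chromosomes(_layer(np.ones((3, 4)), "F3", ann))
        assert out.feature_ids == ["f1", "f3"]

    def test_identity_without_sex_probes(self):
        ann = {"f0": "chr1", "f1": "chr2"}
        out = om.drop_sex_chromosomes(_layer(np.ones((3, 2)), "F3", ann))
        assert out.feature_ids == ["f0", "f1"]

    def test_unannotated_feature_named_in_error(self):
        with pytest.raises(ValueError, match="f1"):
            om.drop_sex_chromosomes(_layer(np.ones((3, 2)), "F3", {"f0": "chr1"}))


class TestTopVariable:
    def test_keeps_all_when_k_exceeds_width(self):
        vals = np.random.default_rng(1).normal(size=(10, 5))
        out = om.top_variable(_layer(vals), k=2000)
        assert out.n_features == 5

    def test_tie_broken_by_original_order(self):
        vals = np.zeros((4, 3))
        vals[:, 0] = [0, 0, 1, 1]   # same SD as f1
        vals[:, 1] = [1, 1, 0, 0]
        vals[:, 2] = [0, 0, 0, 0.1]  # smaller SD
        out = om.top_variable(_layer(vals), k=1)
        assert out.feature_ids == ["f0"]

    @settings(max_examples=30, deadline=None)
    @given(
        vals=hnp.arrays(np.float64, shape=st.tuples(st.integers(3, 8), st.integers(2, 10)),
                        elements=st.floats(-50, 50)),
        k=st.integers(1, 5),
    )
    def test_matches_stable_sort_oracle(self, vals, k):
        layer = _layer(vals)
        out = om.top_variable(layer, k=k)
        sd = np.std(vals, axis=0, ddof=1)
        order = sorted(range(vals.shape[1]), key=lambda j: (-sd[j], j))[:k]
        expected = [layer.feature_ids[j] for j in sorted(order)]
        assert out.feature_ids == expected

    def test_sd_uses_observed_values_only(self):
        vals = np.array([[0.0, 0.0], [1.0, 0.1], [100.0, 0.2], [np.nan, 0.3]])
        out = om.top_variable(_layer(vals, "F3"), k=1)
        assert out.feature_ids == ["f0"]


class TestKnnImpute:
    def test_identity_on_complete_layer(self):
        vals = np.random.default_rng(2).normal(size=(8, 3))
        out = om.knn_impute(_layer(vals, "F4"))
        np.testing.assert_array_equal(out.values, vals)

    def test_single_missing_cell_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(6, 3))
        vals[0, 1] = np.nan
        out = om.knn_impute(_layer(vals, "F4"), k=2)
        # oracle: Euclidean distance over mutually observed features
        dists = [
            (np.sqrt((vals[0, 0] - vals[i, 0]) ** 2 + (vals[0, 2] - vals[i, 2]) ** 2), i)
            for i in range(1, 6)
        ]
        nearest = [i for _, i in sorted(dists)[:2]]
        expected = vals[nearest, 1].mean()
        assert out.values[0, 1] == pytest.approx(expected, abs=1e-10)
        untouched = ~np.isnan(vals)
        np.testing.assert_array_equal(out.values[untouched], vals[untouched])

    def test_too_few_donors_is_error(self):
        vals = np.ones((4, 2))
        vals[:, 0] = [np.nan, np.nan, 1.0, 2.0]
        with pytest.raises(ValueError, match="fewer than k"):
            om.knn_impute(_layer(vals, "F4"), k=3)

    def test_feature_missing_everywhere_is_error(self):
        vals = np.ones((6, 2))
        vals[:, 1] = np.nan
        with pytest.raises(ValueError, match="every sample"):
            om.knn_impute(_layer(vals, "F3"), k=2)


class TestStacking:
    def test_intersection_and_prefixing(self):
        a = OmicsLayer(["A", "B", "C"], ["g1"], np.array([[1.0], [2.0], [3.0]]), "F1")
        b = OmicsLayer(["B", "C", "D"], ["m1"], np.array([[4.0], [5.0], [6.0]]), "F2")
        stacked = om.stack_layers([a, b])
        assert stacked.sample_ids == ["B", "C"]
        assert stacked.feature_ids == ["F1:g1", "F2:m1"]
        np.testing.assert_array_equal(stacked.values, [[2.0, 4.0], [3.0, 5.0]])
        assert stacked.provenance == {"F1:g1": "F1", "F2:m1": "F2"}

    def test_width_is_sum_of_retained_widths(self, toy_study):
        processed, stacked = om.preprocess_study(toy_study.layers)
        assert stacked.p == sum(l.n_features for l in processed.values())
        assert stacked.n == 12

    def test_values_are_bit_exact(self):
        rng = np.random.default_rng(4)
        a = _layer(rng.normal(size=(5, 3)), "F1", prefix="g")
        b = _layer(rng.exponential(size=(5, 2)), "F4", prefix="p")
        stacked = om.stack_layers([a, b])
        np.testing.assert_array_equal(stacked.values[:, :3], a.values)
        np.testing.assert_array_equal(stacked.values[:, 3:], b.values)

    def test_disjoint_samples_is_error(self):
        a = OmicsLayer(["A"], ["g1"], np.array([[1.0]]), "F1")
        b = OmicsLayer(["B"], ["m1"], np.array([[2.0]]), "F2")
        with pytest.raises(ValueError, match="common"):
            om.stack_layers([a, b])

    def test_unimputed_layer_rejected(self):
        vals = np.ones((3, 2))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputed"):
            om.stack_layers([_layer(vals, "F3")])


@pytest.mark.parametrize(
    "filter_fn,datatype,annotation",
    [
        (om.drop_high_zero, "F1", None),
        (om.drop_high_missing, "F4", None),
        (om.drop_sex_chromosomes, "F3", "make"),
    ],
)
def test_filters_are_idempotent(filter_fn, datatype, annotation):
    rng = np.random.default_rng(5)
    vals = rng.uniform(0.1, 1.0, size=(10, 8))
    vals[:4, 0] = 0.0
    vals[:3, 1] = np.nan
    ann = None
    if annotation:
        chroms = ["chrX", "chr1", "chr2", "chrY", "chr3", "chr4", "chr5", "chr6"]
        ann = {f"f{j}": chroms[j] for j in range(8)}
    layer = _layer(np.nan_to_num(vals) if datatype == "F1" else vals, datatype, ann)
    once = filter_fn(layer)
    twice = filter_fn(once)
    assert once.feature_ids == twice.feature_ids
    np.testing.assert_array_equal(once.values, twice.values)


def test_pipeline_order_toy_counts(toy_study):
    """F1: zero filter (+SD cut); F2: zero filter; F3: NA filter -> sex filter
    -> SD cut -> impute; F4: NA filter -> impute."""
    processed, _ = om.preprocess_study(toy_study.layers)
    assert processed["F1"].n_features == 8   # 10 - 2 high-zero
    assert processed["F2"].n_features == 9   # 10 - 1 high-zero
    assert processed["F3"].n_features == 8   # 10 - 1 high-NA - 1 chrX
    assert processed["F4"].n_features == 9   # 10 - 1 high-NA
    for tag in ("F3", "F4"):
        assert not np.isnan(processed[tag].values).any()
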