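import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from trnareg.reference import aggregate_hierarchy
from trnareg.repertoire import (
    aggregate,
    buffering_summary,
    detection_filter,
    major_isodecoder_count,
    proportions,
    rle_size_factors,
)


def _table(values, features=None, samples=("iPSC_rep1",)):
    arr = np.atleast_2d(np.asarray(values))
    features = features or [f"t{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=features, columns=list(samples))


class TestProportions:
    def test_column_normalization(self):
        p = proportions(_table([[10], [30], [60]]))
        assert np.allclose(p.iloc[:, 0], [0.1, 0.3, 0.6])

    def test_single_feature_is_one(self):
        assert proportions(_table([[17]])).iloc[0, 0] == 1.0

    def test_all_zero_sample_named_in_error(self):
        t = _table([[0, 1], [0, 2]], samples=["iPSC_rep1", "iPSC_rep2"])
        with pytest.raises(ValueError, match="iPSC_rep1"):
            proportions(t)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.int64, (50, 4), elements=st.integers(0, 1000)))
    def test_columns_sum_to_one(self, mat):
        t = pd.DataFrame(mat, index=[f"t{i}" for i in range(50)],
                         columns=[f"c{j}_rep1" for j in range(4)])
        if (t.sum(axis=0) == 0).any():
            return
        assert np.allclose(proportions(t).sum(axis=0), 1.0, atol=1e-9)


class TestAggregate:
    def _hier(self, mapping):
        return pd.DataFrame(
            {"transcript": list(mapping), "family": list(mapping.values())}
        )

    def test_two_transcripts_sum(self):
        t = _table([[5], [7]], features=["a", "b"])
        out = aggregate(t, self._hier({"a": "F", "b": "F"}))
        assert out.loc["F"].iloc[0] == 12

    def test_identity_when_all_distinct(self):
        t = _table([[5], [7]], features=["a", "b"])
        out = aggregate(t, self._hier({"a": "F1", "b": "F2"}))
        assert sorted(out.iloc[:, 0]) == [5, 7]

    def test_totals_conserved_exactly(self, counts_small, sim_small):
        _, genes, _ = sim_small
        h = aggregate_hierarchy(genes)
        out = aggregate(counts_small, h, "family")
        assert out.sum(axis=0).equals(counts_small.sum(axis=0))
        # integer dtype preserved: conservation is exact, not approximate
        assert (out.dtypes == counts_small.dtypes).all()

    def test_unmapped_feature_rejected(self):
        t = _table([[5]], features=["orphan"])
        with pytest.raises(ValueError, match="orphan"):
            aggregate(t, self._hier({"a": "F"}))


class TestDetectionFilter:
    def _props(self, rows):
        cols = ["A_rep1", "A_rep2", "B_rep1", "B_rep2"]
        return pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))],
                            columns=cols)

    def test_below_threshold_everywhere_is_undetected(self):
        p = self._props([[4e-5] * 4, [1e-3] * 4])
        det, undet = detection_filter(p)
        assert list(undet) == ["t0"]

    def test_single_cell_type_above_threshold_detected(self):
        p = self._props([[1e-4, 1e-4, 0.0, 0.0]])
        det, undet = detection_filter(p)
        assert list(det) == ["t0"]

    def test_zero_threshold_keeps_any_nonzero(self):
        p = self._props([[0, 0, 0, 0], [1e-9, 0, 0, 0]])
        det, _ = detection_filter(p, threshold=0)
        assert list(det) == ["t1"]

    def test_replicate_mean_vs_per_replicate_flag(self):
        # one replicate above, the mean below: detected only per-replicate
        p = self._props([[9e-5, 0.0, 0.0, 0.0]])
        det_mean, _ = detection_filter(p, threshold=5e-5)
        det_rep, _ = detection_filter(p, threshold=5e-5, per_replicate=True)
        assert list(det_mean) == []
        assert list(det_rep) == ["t0"]


class TestMajorIsodecoderCount:
    @pytest.mark.parametrize(
        "props, expected",
        [
            ((0.50, 0.42, 0.08), 2),
            ((1.0,), 1),
            ((0.1,) * 10, 9),
            ((0.91, 0.09), 1),
        ],
    )
    def test_examples(self, props, expected):
        assert major_isodecoder_count(pd.Series(props)) == expected

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            major_isodecoder_count(pd.Series([], dtype=float))

    def test_bounded_by_nonzero_members(self):
        s = pd.Series([5.0, 0.0, 1.0, 0.0])
        k = major_isodecoder_count(s)
        assert 1 <= k <= int((s > 0).sum())


class TestRLESizeFactors:
    def test_doubling_closed_form(self):
        t = _table(
            [[10, 20], [30, 60], [7, 14]], samples=["a_rep1", "a_rep2"]
        )
        f = rle_size_factors(t)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])
        assert np.isclose(np.prod(f), 1.0)

    def test_identical_columns_unit_factors(self):
        t = _table([[10, 10], [3, 3]], samples=["a_rep1", "a_rep2"])
        assert np.allclose(rle_size_factors(t), 1.0)

    def test_fold_change_invariant_to_library_scaling(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 500, size=(40, 2))
        t = pd.DataFrame(base, columns=["x_rep1", "y_rep1"],
                         index=[f"t{i}" for i in range(40)])
        t2 = t.copy()
        t2["y_rep1"] = t2["y_rep1"] * 3
        n1 = t / rle_size_factors(t)
        n2 = t2 / rle_size_factors(t2)
        fc1 = n1["y_rep1"] / n1["x_rep1"]
        fc2 = n2["y_rep1"] / n2["x_rep1"]
        assert np.allclose(fc1, fc2)

    def test_requires_an_all_nonzero_feature(self):
        t = _table([[0, 5], [5, 0]], samples=["a_rep1", "b_rep1"])
        with pytest.raises(ValueError):
            rle_size_factors(t)


class TestBufferingSummary:
    def test_identical_columns_zero_log2fc(self):
        t = pd.DataFrame(
            {"iPSC_rep1": [10, 20], "iPSC_rep2": [10, 20],
             "NPC_rep1": [10, 20], "NPC_rep2": [10, 20]},
            index=["a", "b"],
        )
        h = pd.DataFrame({"transcript": ["a", "b"], "family": ["F", "G"]})
        rep = buffering_summary(t, h, "iPSC")
        for level in ("transcript", "anticodon"):
            assert rep["levels"][level]["max_abs_log2fc"] == pytest.approx(0.0)

    def test_singleton_families_match_transcript_level(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(
            rng.integers(5, 500, size=(6, 4)),
            index=[f"t{i}" for i in range(6)],
            columns=["iPSC_rep1", "iPSC_rep2", "NPC_rep1", "NPC_rep2"],
        )
        h = pd.DataFrame({"transcript": t.index, "family": [f"F{i}" for i in range(6)]})
        rep = buffering_summary(t, h, "iPSC")
        lv = rep["levels"]
        tr = lv["transcript"]["log2fc"].sort_index()
        an = lv["anticodon"]["log2fc"]
        an.index = [f"t{i}" for i in range(6)]
        assert np.allclose(tr.to_numpy(), an.sort_index().to_numpy())

    def test_anticodon_level_compresses_fold_changes(self, sim_small, counts_small):
        cfg, genes, truth = sim_small
        rep = buffering_summary(counts_small, truth.genes, cfg.reference)
        lv = rep["levels"]
        assert (
            lv["anticodon"]["max_abs_log2fc"] < lv["transcript"]["max_abs_log2fc"]
        )
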