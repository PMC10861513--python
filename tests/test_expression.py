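"""Expression containers, replicate collapse, thresholding, filters, overlaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_profile
from vernalign.expression import (
    ExpressionSeries,
    classify_expressed,
    collapse_replicates,
    expressed_set,
    read_expression_table,
    som_prefilter,
    variety_specific_sets,
)


def make_series(values, meta_rows):
    frame = pd.DataFrame(values)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return ExpressionSeries(values=frame, sample_meta=meta)


@pytest.fixture
def pooled_series():
    return make_series(
        {"s1": [1.0, 0.0], "s2": [3.0, 0.0], "s3": [5.0, 6.0]},
        [
            {"sample_id": "s1", "variety": "A", "tissue": "apex", "day": 22, "pool": 1},
            {"sample_id": "s2", "variety": "A", "tissue": "apex", "day": 22, "pool": 2},
            {"sample_id": "s3", "variety": "A", "tissue": "apex", "day": 43, "pool": 1},
        ],
    )


class TestSeriesValidation:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_series(
                {"s1": [-1.0]},
                [{"sample_id": "s1", "variety": "A", "tissue": "apex", "day": 1, "pool": 1}],
            )

    def test_sample_missing_from_metadata_rejected(self):
        with pytest.raises(ValueError, match="s2"):
            make_series(
                {"s1": [1.0], "s2": [2.0]},
                [{"sample_id": "s1", "variety": "A", "tissue": "apex", "day": 1, "pool": 1}],
            )

    def test_read_rejects_duplicate_gene_ids(self, tmp_path):
        (tmp_path / "expr.tsv").write_text("gene\ts1\ng1\t1.0\ng1\t2.0\n")
        (tmp_path / "samples.tsv").write_text(
            "sample_id\tvariety\ttissue\tday\tpool\ns1\tA\tapex\t1\t1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_table(tmp_path / "expr.tsv", tmp_path / "samples.tsv")


class TestCollapseReplicates:
    def test_pool_means_per_day(self, pooled_series):
        prof = collapse_replicates(pooled_series, "A", "apex")
        assert prof.days == [22, 43]
        assert prof.values.loc[0, 22] == pytest.approx(2.0)  # mean(1, 3)
        assert prof.values.loc[1, 22] == pytest.approx(0.0)
        assert prof.values.loc[0, 43] == pytest.approx(5.0)  # single pool identity

    def test_three_pool_mean(self):
        series = make_series(
            {"s1": [0.0], "s2": [0.0], "s3": [6.0], "s4": [1.0]},
            [
                {"sample_id": f"s{i}", "variety": "A", "tissue": "apex",
                 "day": 22 if i < 4 else 43, "pool": i}
                for i in range(1, 5)
            ],
        )
        prof = collapse_replicates(series, "A", "apex")
        assert prof.values.loc[0, 22] == pytest.approx(2.0)  # mean(0, 0, 6)

    def test_missing_combination_raises(self, pooled_series):
        with pytest.raises(ValueError, match="leaf"):
            collapse_replicates(pooled_series, "A", "leaf")

    def test_idempotent_on_single_pool_series(self, tiny_dataset):
        series = tiny_dataset.expression[("Tapidor", "apex")]
        prof = collapse_replicates(series, "Tapidor", "apex")
        # re-collapsing the collapsed profile (one pool per day) is identity
        meta = pd.DataFrame(
            [
                {"sample_id": str(d), "variety": "Tapidor", "tissue": "apex",
                 "day": d, "pool": 1}
                for d in prof.days
            ]
        ).set_index("sample_id")
        re_series = ExpressionSeries(
            values=prof.values.rename(columns=str), sample_meta=meta
        )
        re_prof = collapse_replicates(re_series, "Tapidor", "apex")
        np.testing.assert_allclose(re_prof.values.to_numpy(), prof.values.to_numpy())


class TestClassifyExpressed:
    @pytest.mark.parametrize(
        "profile_vals,expected",
        [([1.0, 2.0], True), ([1.0, 1.999], False), ([0.0, 0.0], False)],
    )
    def test_inclusive_threshold_boundary(self, profile_vals, expected):
        prof = make_profile({"g": profile_vals, "pad": [9, 9]}, [1, 2])
        assert bool(classify_expressed(prof)["g"]) is expected

    def test_negative_threshold_rejected(self):
        prof = make_profile({"g": [1.0, 1.0]}, [1, 2])
        with pytest.raises(ValueError):
            classify_expressed(prof, threshold=-1.0)

    @given(st.floats(min_value=0, max_value=20), st.floats(min_value=0, max_value=20))
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_enlarges_set(self, t1, t2):
        lo, hi = sorted((t1, t2))
        prof = make_profile(
            {f"g{i}": [float(i), float(2 * i % 7)] for i in range(10)}, [1, 2]
        )
        assert expressed_set(prof, hi) <= expressed_set(prof, lo)


class TestSomPrefilter:
    def _toy(self):
        return make_profile(
            {
                "g1": [5, 5, 5, 5],
                "g2": [5, 0, 0, 0],
                "g3": [1, 1, 1, 1],
                "g4": [5, 5, 5, 5],
                "g5": [0, 3, 3, 0],
                "g6": [0, 0, 0, 0],
            },
            [1, 2, 3, 4],
        )

    def test_worked_example_stage_counts_and_survivors(self):
        homology = {"g1", "g2", "g3", "g5", "g6"}  # g4 lacks a homologue
        survivors, counts = som_prefilter(self._toy(), homology)
        assert (counts["detected_half"], counts["expressed"], counts["homologous"]) == (4, 3, 2)
        assert set(survivors) == {"g1", "g5"}

    def test_all_pass_when_flat_high_with_homologues(self):
        prof = make_profile({f"g{i}": [10.0] * 4 for i in range(5)}, [1, 2, 3, 4])
        survivors, counts = som_prefilter(prof, {f"g{i}" for i in range(5)})
        assert len(survivors) == 5
        assert len(set(counts.values())) == 1

    def test_empty_homology_gives_zero_final_count(self):
        survivors, counts = som_prefilter(self._toy(), set())
        assert survivors == [] and counts["homologous"] == 0

    def test_stage_counts_monotone_on_synthetic(self, tiny_dataset):
        prof = collapse_replicates(
            tiny_dataset.expression[("Westar", "leaf")], "Westar", "leaf"
        )
        _, counts = som_prefilter(prof, set(tiny_dataset.homology["crop_gene"]))
        seq = [counts["input"], counts["detected_half"], counts["expressed"], counts["homologous"]]
        assert seq == sorted(seq, reverse=True)

    def test_odd_day_count_uses_half_rule(self):
        # 3 days: detected in >= 1.5 time points means >= 2
        prof = make_profile({"g1": [5, 5, 0], "g2": [5, 0, 0]}, [1, 2, 3])
        _, counts = som_prefilter(prof, {"g1", "g2"})
        assert counts["detected_half"] == 1


class TestVarietySpecificSets:
    def _pair(self):
        a = make_profile(
            {"a": [3, 0], "b": [3, 0], "c": [0, 3], "d": [1, 0]}, [1, 2]
        )
        b = make_profile(
            {"a": [1, 0], "b": [3, 0], "c": [0, 9], "d": [5, 0]}, [1, 2], variety="B"
        )
        return a, b

    def test_set_arithmetic_and_percentages(self):
        ov = variety_specific_sets(*self._pair())
        assert ov.only_a == {"a"}
        assert ov.only_b == {"d"}
        assert ov.shared == {"b", "c"}
        assert ov.percentages == pytest.approx((25.0, 25.0, 50.0))

    def test_identical_profiles_share_everything(self):
        a, _ = self._pair()
        ov = variety_specific_sets(a, a)
        assert ov.only_a == ov.only_b == frozenset()
        assert ov.shared == {"a", "b", "c"}

    def test_subset_restriction_contains_only_subset(self):
        ov = variety_specific_sets(*self._pair(), gene_subset=["a", "b"])
        assert (ov.only_a | ov.only_b | ov.shared) <= {"a", "b"}

    def test_disjoint_universes_raise(self):
        a = make_profile({"x": [3, 3]}, [1, 2])
        b = make_profile({"y": [3, 3]}, [1, 2])
        with pytest.raises(ValueError, match="disjoint"):
            variety_specific_sets(a, b)

    def test_partition_conserves_union(self, tiny_dataset):
        pa = collapse_replicates(tiny_dataset.expression[("Tapidor", "leaf")], "Tapidor", "leaf")
        pb = collapse_replicates(tiny_dataset.expression[("Westar", "leaf")], "Westar", "leaf")
        ov = variety_specific_sets(pa, pb)
        union = expressed_set(pa) | expressed_set(pb)
        assert ov.only_a | ov.only_b | ov.shared == union
        assert sum(ov.percentages) == pytest.approx(100.0)
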