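"""Across-group comparison stage: test selection, conventions, calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mlcnet.cohort import CohortTable, VariableMeta
from mlcnet.group_tests import GroupComparison, compare_groups


def cohort_from_arrays(columns: dict, labels, levels=None):
    data = pd.DataFrame(columns)
    data.index = pd.Index([f"S{i}" for i in range(len(data))],
                          name="subject_id")
    groups = pd.Series(list(labels), index=data.index, name="group")
    meta = [VariableMeta(c, (levels or {}).get(c, "blood"), "continuous")
            for c in data.columns]
    return CohortTable(data, groups, meta)


class TestConventions:
    def test_mann_whitney_complete_separation_is_zero(self):
        # U statistic of the first group in sorted-label order; here group
        # "a" holds the uniformly smaller values, so U = 0.
        c = cohort_from_arrays(
            {"x": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]},
            ["a"] * 5 + ["b"] * 5,
        )
        (res,) = GroupComparison(parametric="never").fit(c).results_
        assert res.test_name == "mann_whitney"
        assert res.statistic == 0.0

    def test_identical_groups_give_null_kruskal_wallis(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 3
        c = cohort_from_arrays({"x": vals}, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        (res,) = GroupComparison(parametric="never").fit(c).results_
        assert res.test_name == "kruskal_wallis"
        assert res.p_value > 0.9

    def test_kruskal_p_close_to_exact_permutation_oracle(self):
        # exhaustive label-assignment oracle at n=4 per group (34650 splits)
        rng = np.random.default_rng(42)
        vals = rng.standard_normal(12) ** 3  # skewed -> non-parametric path
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        c = cohort_from_arrays({"x": vals}, labels)
        (res,) = compare_groups(c)
        assert res.test_name == "kruskal_wallis"

        obs = stats.kruskal(vals[:4], vals[4:8], vals[8:]).statistic
        idx = set(range(12))
        count = total = 0
        for ga in itertools.combinations(range(12), 4):
            rest = sorted(idx - set(ga))
            for gb in itertools.combinations(rest, 4):
                gc = sorted(set(rest) - set(gb))
                h = stats.kruskal(vals[list(ga)], vals[list(gb)],
                                  vals[gc]).statistic
                count += h >= obs - 1e-12
                total += 1
        p_exact = count / total
        # engine uses the chi-square approximation; agreement within its
        # known small-sample error
        assert res.p_value == pytest.approx(p_exact, abs=0.05)

    def test_mixed_presentation_matches_test_family(self):
        rng = np.random.default_rng(0)
        normal = rng.normal(10, 2, size=30)
        skewed = rng.lognormal(0, 1.5, size=30)
        c = cohort_from_arrays({"norm": normal, "skew": skewed},
                               ["a"] * 15 + ["b"] * 15)
        by_var = {r.variable: r for r in compare_groups(c)}
        assert by_var["norm"].test_name == "t_test"
        assert "+/-" in by_var["norm"].per_group_summary[0][1]
        assert by_var["skew"].test_name == "mann_whitney"
        assert "[" in by_var["skew"].per_group_summary[0][1]


class TestEdgeCases:
    def test_single_group_errors(self):
        c = cohort_from_arrays({"x": [1.0, 2, 3, 4]}, ["a"] * 4)
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(c)

    def test_constant_variable_flagged_untestable(self):
        c = cohort_from_arrays({"x": [5.0] * 8}, ["a"] * 4 + ["b"] * 4)
        (res,) = compare_groups(c)
        assert res.test_name == "untestable"
        assert "constant" in res.reason
        assert not res.significant

    def test_sparse_variable_untestable_not_dropped(self):
        x = [1.0, 2.0, np.nan, np.nan, 3.0, 4.0, 5.0, 6.0]
        c = cohort_from_arrays({"x": x}, ["a"] * 4 + ["b"] * 4)
        (res,) = compare_groups(c)
        assert res.test_name == "untestable"
        assert "insufficient n" in res.reason
        assert dict(res.n_per_group) == {"a": 2, "b": 4}


class TestInvariances:
    def test_within_group_permutation_changes_nothing(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=20)
        labels = ["a"] * 10 + ["b"] * 10
        c1 = cohort_from_arrays({"x": vals}, labels)
        shuffled = np.concatenate([rng.permutation(vals[:10]),
                                   rng.permutation(vals[10:])])
        c2 = cohort_from_arrays({"x": shuffled}, labels)
        r1, r2 = compare_groups(c1)[0], compare_groups(c2)[0]
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_shift_invariance_of_rank_tests(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(size=24)
        labels = ["a"] * 12 + ["b"] * 12
        r1 = compare_groups(cohort_from_arrays({"x": vals}, labels))[0]
        r2 = compare_groups(cohort_from_arrays({"x": vals + 100}, labels))[0]
        assert r1.test_name == r2.test_name == "mann_whitney"
        assert r1.statistic == r2.statistic
        assert r1.p_value == r2.p_value


def test_type_i_rate_on_skewed_data_roughly_nominal():
    """Two identical lognormal groups: rejection rate near alpha (300 reps)."""
    rng = np.random.default_rng(9)
    hits = 0
    reps = 300
    for _ in range(reps):
        vals = rng.lognormal(size=30)
        c = cohort_from_arrays({"x": vals}, ["a"] * 15 + ["b"] * 15)
        hits += compare_groups(c)[0].significant
    assert 0.02 <= hits / reps <= 0.09


def test_report_frame_carries_levels_and_note(tiny_cohort=None):
    from mlcnet.group_tests import results_to_frame
    rng = np.random.default_rng(1)
    c = cohort_from_arrays(
        {"x": rng.normal(size=12), "y": rng.normal(size=12)},
        ["a"] * 6 + ["b"] * 6, levels={"x": "clinical"},
    )
    frame = results_to_frame(c)
    assert set(frame["variable"]) == {"x", "y"}
    assert "no multiple-testing correction" in frame.attrs["note"]
    assert frame.loc[frame["variable"] == "x", "level"].item() == "clinical"
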