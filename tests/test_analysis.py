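import numpy as np
import pytest

from rtsig import (
    EmptySelectionError,
    ModificationAnnotation,
    compare_conditions,
    compare_pools,
    mismatch_composition,
    prevalence,
    select_profiles,
    summarize,
)
from rtsig.analysis import feature_value
from rtsig.datasets import example_m1a_profile


def profile_row(template, **overrides):
    import dataclasses

    return dataclasses.replace(template, **overrides)


@pytest.fixture(scope="module")
def rows():
    return example_m1a_profile()


@pytest.fixture(scope="module")
def ann(rows):
    return [ModificationAnnotation(r.ref_seg, r.pos, "m1A") for r in rows]


class TestSummarize:
    def test_single_position_degenerates_to_point(self, rows, ann):
        s = summarize(rows[:1], ann, "m1A", "mismatch", n_boot=200)
        assert s.n_positions == 1
        assert s.median == s.mean == pytest.approx(0.94012)
        assert s.ci95_mean == (pytest.approx(0.94012), pytest.approx(0.94012))

    def test_mean_and_median_simple_values(self, rows, ann):
        picked = [profile_row(rows[0], mism_rate=v, pos=50 + i)
                  for i, v in enumerate((0.1, 0.2, 0.3))]
        ann3 = [ModificationAnnotation(p.ref_seg, p.pos, "m1A") for p in picked]
        s = summarize(picked, ann3, "m1A", "mismatch", n_boot=200)
        assert s.mean == pytest.approx(0.2)
        assert s.median == pytest.approx(0.2)

    def test_constant_vector_gives_zero_width_ci(self, rows, ann):
        constant = [profile_row(r, mism_rate=0.5) for r in rows]
        s = summarize(constant, ann, "m1A", "mismatch", n_boot=500)
        assert s.ci95_mean == (0.5, 0.5)
        assert s.ci95_median == (0.5, 0.5)

    def test_bootstrap_deterministic_for_fixed_seed(self, rows, ann):
        a = summarize(rows, ann, "m1A", "arrest", seed=42, n_boot=2000)
        b = summarize(rows, ann, "m1A", "arrest", seed=42, n_boot=2000)
        c = summarize(rows, ann, "m1A", "arrest", seed=43, n_boot=2000)
        assert a.ci95_mean == b.ci95_mean and a.ci95_median == b.ci95_median
        assert a.ci95_mean != c.ci95_mean

    def test_empty_selection_raises(self, rows, ann):
        with pytest.raises(EmptySelectionError):
            summarize(rows, ann, "m3C", "arrest")

    def test_jump_total_is_sum_of_classes(self, rows):
        r = rows[2]  # carries all three deletion classes
        assert feature_value(r, "jump_total") == pytest.approx(
            r.single_jump_rate_direct + r.single_jump_rate_delayed + r.double_jump_rate
        )


class TestSelect:
    def test_modified_and_unmodified_partition(self, rows, ann):
        half_ann = ann[:5]
        modified = select_profiles(rows, half_ann, "modified")
        unmodified = select_profiles(rows, half_ann, "unmodified")
        assert len(modified) == 5 and len(unmodified) == 5
        assert {id(r) for r in modified + unmodified} == {id(r) for r in rows}


class TestCompareConditions:
    def test_identity_comparison_not_significant(self, rows, ann):
        result = compare_conditions(rows, rows, ann, "m1A", "arrest", n_boot=200)
        assert all(d.delta == 0.0 for d in result.deltas)
        assert result.p_value == 1.0
        assert not result.significant

    def test_deltas_are_treated_minus_reference(self, rows, ann):
        treated = [profile_row(r, arrest_rate=min(1.0, r.arrest_rate + 0.1)) for r in rows]
        result = compare_conditions(rows, treated, ann, "m1A", "arrest", n_boot=200)
        assert result.mean_delta == pytest.approx(0.1)
        assert result.significant  # 10 matched positions, all shifted one way

    def test_symmetry_deltas_negate(self, rows, ann):
        rng = np.random.default_rng(0)
        treated = [profile_row(r, arrest_rate=float(rng.uniform(0, 1))) for r in rows]
        fwd = compare_conditions(rows, treated, ann, "m1A", "arrest", n_boot=200)
        rev = compare_conditions(treated, rows, ann, "m1A", "arrest", n_boot=200)
        assert [d.delta for d in fwd.deltas] == pytest.approx(
            [-d.delta for d in rev.deltas]
        )
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_positions_must_match_in_both_sets(self, rows, ann):
        result = compare_conditions(rows, rows[:4], ann, "m1A", "arrest", n_boot=200)
        assert len(result.deltas) == 4

    def test_single_matched_position_flagged_undefined(self, rows, ann):
        result = compare_conditions(rows[:1], rows[:1], ann, "m1A", "arrest", n_boot=200)
        assert result.p_value is None
        assert not result.significant

    def test_unmatched_pools_mannwhitney(self, rows, ann):
        p = compare_pools(rows, rows, ann, "m1A", "arrest")
        assert p == pytest.approx(1.0)


class TestPrevalence:
    def test_zero_feature_gives_zero_percent(self, rows, ann):
        flat = [profile_row(r, double_jump_rate=0.0, single_jump_rate_direct=0.0,
                            single_jump_rate_delayed=0.0) for r in rows]
        assert prevalence(flat, ann, "jump_total") == 0.0

    def test_fraction_of_positions_above_threshold(self, rows, ann):
        vals = [0.0] * 8 + [0.2, 0.3]
        mixed = [profile_row(r, arrest_rate=v) for r, v in zip(rows, vals)]
        assert prevalence(mixed, ann, "arrest") == pytest.approx(20.0)
        assert prevalence(mixed, ann, "arrest", threshold=0.25) == pytest.approx(10.0)


class TestMismatchComposition:
    def test_worked_row_composition(self, rows, ann):
        # first worked-example row: mismatching bases G=39+58, T=24+25, C=7+4
        comp = mismatch_composition(rows[:1], ann, "m1A")
        row = comp.loc["all"]
        assert row["n_mismatch_bases"] == 157
        assert row["G"] == pytest.approx(97 / 157)
        assert row["T"] == pytest.approx(49 / 157)
        assert row["C"] == pytest.approx(11 / 157)
        assert row["A"] == 0.0  # the reference base is excluded

    def test_fractions_normalized_per_stratum(self, rows, ann):
        comp = mismatch_composition(rows, ann, "m1A", group_by_prebase=True)
        assert set(comp.index) <= {"A", "C", "G", "T"}
        for _, row in comp.iterrows():
            assert row[["A", "C", "G", "T", "N"]].sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_mismatch_base_type(self, rows, ann):
        solo = profile_row(rows[0], cov=12, A=10, G=2, T=0, C=0, N=0,
                           a=0, g=0, t=0, c=0, n=0)
        comp = mismatch_composition([solo], ann, "m1A")
        assert comp.loc["all", "G"] == 1.0

    def test_no_mismatching_bases_raises(self, rows, ann):
        clean = profile_row(rows[0], cov=10, A=10, G=0, T=0, C=0, N=0,
                            a=0, g=0, t=0, c=0, n=0, mism_rate=0.0)
        with pytest.raises(EmptySelectionError):
            mismatch_composition([clean], ann, "m1A")
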