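"""Health-deficit instruments: rank normalization, FI, disease counts,
composites, quartile levels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sweetspot import (InstrumentMetadata, QuartileCutoffs, TestSpec,
                       assign_health_levels, composite_instrument,
                       compute_instruments, disease_instrument,
                       frailty_index, invert_risk_direction,
                       quartile_cutoffs, rank_normalize)
from sweetspot.instruments import (LEVEL_GOOD, LEVEL_HEALTHIEST,
                                   LEVEL_LEAST_HEALTHY)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False)


class TestRankNormalize:
    def test_three_distinct_values(self):
        assert rank_normalize([10, 20, 30]) == pytest.approx(
            [1 / 6, 1 / 2, 5 / 6])

    def test_ties_get_average_rank(self):
        assert rank_normalize([5, 5]) == pytest.approx([0.5, 0.5])

    def test_missing_stays_missing(self):
        out = rank_normalize([1.0, np.nan, 3.0])
        assert np.isnan(out[1])
        assert out[[0, 2]] == pytest.approx([0.25, 0.75])

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            rank_normalize([np.nan, np.nan])

    @given(st.lists(st.integers(-1000, 1000), min_size=2, max_size=30,
                    unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        # integer inputs keep exp() collision-free at double precision
        x = np.array(xs, dtype=float)
        np.testing.assert_allclose(rank_normalize(np.exp(x / 100.0)),
                                   rank_normalize(x))

    @given(st.lists(finite_floats, min_size=2, max_size=30, unique=True))
    def test_inversion_reflects_ranks(self, xs):
        x = np.array(xs)
        inv = invert_risk_direction(x, "risk_decreases")
        np.testing.assert_allclose(rank_normalize(inv),
                                   1 - rank_normalize(x))


class TestInvertRiskDirection:
    def test_risk_increases_is_identity(self):
        np.testing.assert_array_equal(
            invert_risk_direction([1, 2, 3], "risk_increases"), [1, 2, 3])

    def test_risk_decreases_is_negation(self):
        np.testing.assert_array_equal(
            invert_risk_direction([1, 2, 3], "risk_decreases"), [-1, -2, -3])

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            invert_risk_direction([1.0], "sideways")
        with pytest.raises(ValueError):
            TestSpec("t", "sideways")


class TestFrailtyIndex:
    def test_floor_ceiling_and_arithmetic(self):
        df = pd.DataFrame([[0.0] * 51, [1.0] * 51,
                           [1.0] * 17 + [0.0] * 34])
        fi = frailty_index(df)
        assert fi.tolist() == pytest.approx([0.0, 1.0, 17 / 51])

    def test_denominator_is_observed_deficits(self):
        row = [1.0] * 5 + [np.nan] * 5 + [0.0] * 40
        fi = frailty_index(pd.DataFrame([row]))
        assert fi.iloc[0] == pytest.approx(5 / 45)

    def test_below_completeness_floor_is_missing(self):
        row = [1.0] * 10 + [np.nan] * 41
        assert np.isnan(frailty_index(pd.DataFrame([row])).iloc[0])

    def test_out_of_range_value_named(self):
        df = pd.DataFrame({"a": [0.0, 1.5], "b": [0.0, 0.0]})
        with pytest.raises(ValueError, match="'a'"):
            frailty_index(df)

    @given(st.permutations(list(range(8))))
    def test_permutation_invariant_across_deficit_columns(self, perm):
        base = pd.DataFrame(
            np.random.default_rng(0).integers(0, 2, (6, 8)).astype(float))
        fi1 = frailty_index(base, min_fraction=0.5)
        fi2 = frailty_index(base.iloc[:, list(perm)], min_fraction=0.5)
        np.testing.assert_allclose(fi1, fi2)


class TestDiseaseInstrument:
    pairs = [("d1", "m1"), ("d2", None), ("d3", None), ("d4", None),
             ("d5", None)]

    def _cohort(self, flags, m1=0.0):
        return pd.DataFrame([dict(zip("d1 d2 d3 d4 d5".split(), flags),
                                  m1=m1)])

    def test_no_disease_is_healthiest(self):
        score, level = disease_instrument(self._cohort([0, 0, 0, 0, 0]),
                                          self.pairs)
        assert score.iloc[0] == 0.0
        assert level.iloc[0] == LEVEL_HEALTHIEST

    def test_two_diseases_least_healthy(self):
        score, level = disease_instrument(self._cohort([1, 1, 0, 0, 0]),
                                          self.pairs)
        assert score.iloc[0] == pytest.approx(0.4)
        assert level.iloc[0] == LEVEL_LEAST_HEALTHY

    def test_medication_confirms_disease(self):
        score, level = disease_instrument(
            self._cohort([0, 0, 0, 0, 0], m1=1.0), self.pairs)
        assert score.iloc[0] == pytest.approx(0.2)
        assert level.iloc[0] == LEVEL_GOOD  # intermediate single disease

    def test_unresolved_flag_gives_missing_score(self):
        score, _ = disease_instrument(
            self._cohort([np.nan, 0, 0, 0, 0]), self.pairs)
        assert np.isnan(score.iloc[0])


class TestCompositeInstrument:
    def test_single_test_equals_rank_normalized(self):
        df = pd.DataFrame({"t": [3.0, 1.0, 2.0]})
        out = composite_instrument(df, [TestSpec("t", "risk_increases")])
        np.testing.assert_allclose(out, rank_normalize(df["t"]))

    def test_identical_tests_average_to_common_score(self):
        df = pd.DataFrame({"t1": [1.0, 2.0, 3.0], "t2": [1.0, 2.0, 3.0]})
        tests = [TestSpec("t1", "risk_increases", "d1"),
                 TestSpec("t2", "risk_increases", "d2")]
        np.testing.assert_allclose(composite_instrument(df, tests),
                                   rank_normalize(df["t1"]))

    def test_domains_weighted_equally_not_tests(self):
        # hand-computed oracle on a 4-participant table: domain A has one
        # test, domain B three; the composite averages domain means
        df = pd.DataFrame({
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [4.0, 3.0, 2.0, 1.0],
            "c": [1.0, 3.0, 2.0, 4.0],
            "d": [2.0, 2.0, 2.0, 2.0],
        })
        tests = [TestSpec("a", "risk_increases", "A"),
                 TestSpec("b", "risk_increases", "B"),
                 TestSpec("c", "risk_increases", "B"),
                 TestSpec("d", "risk_increases", "B")]
        out = composite_instrument(df, tests)
        expected = [0.3125, 0.47916667, 0.52083333, 0.6875]
        np.testing.assert_allclose(out, expected, rtol=1e-7)
        flat = composite_instrument(
            df, [TestSpec(c, "risk_increases") for c in "abcd"])
        assert not np.allclose(out, flat)  # distinguishes the weighting

    def test_missing_domain_gives_missing_composite(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 5.0]})
        tests = [TestSpec("a", "risk_increases", "A"),
                 TestSpec("b", "risk_increases", "B")]
        out = composite_instrument(df, tests)
        assert np.isnan(out.iloc[1]) and not np.isnan(out.iloc[0])

    def test_absent_column_is_config_error(self):
        with pytest.raises(KeyError):
            composite_instrument(pd.DataFrame({"a": [1.0]}),
                                 [TestSpec("zz", "risk_increases")])


class TestHealthLevels:
    def test_reference_cutoffs(self):
        cut = QuartileCutoffs("I", 0.04, 0.07, 0.11)
        levels = assign_health_levels([0.03, 0.12], cut)
        assert levels.tolist() == [LEVEL_HEALTHIEST, LEVEL_LEAST_HEALTHY]

    def test_exact_quartiles_partition_evenly(self):
        scores = np.arange(1.0, 9.0)
        cut = quartile_cutoffs(scores, "x")
        levels = assign_health_levels(scores, cut)
        assert levels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_tie_at_q1_goes_less_healthy(self):
        cut = QuartileCutoffs("I", 0.04, 0.07, 0.11)
        assert assign_health_levels([0.04], cut).iloc[0] == LEVEL_GOOD

    def test_missing_score_gives_missing_level(self):
        cut = QuartileCutoffs("I", 0.04, 0.07, 0.11)
        assert np.isnan(assign_health_levels([np.nan], cut).iloc[0])

    def test_disordered_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            QuartileCutoffs("I", 0.2, 0.1, 0.3)


def test_all_scores_in_unit_interval(demo_scores):
    scores, cutoffs = demo_scores
    for inst in ("I", "II", "III", "IV", "V"):
        s = scores[f"score_{inst}"].dropna()
        assert ((s >= 0) & (s <= 1)).all()
    for inst, cut in cutoffs.items():
        assert cut.q1 <= cut.q2 <= cut.q3


def test_quartile_levels_partition_cohort(demo_scores):
    scores, _ = demo_scores
    counts = scores["level_IV"].value_counts()
    n = scores["level_IV"].notna().sum()
    # rank-normalised scores are nearly tie-free, so groups are near-equal
    assert counts.max() - counts.min() <= 0.02 * n


def test_metadata_yaml_roundtrip(tmp_path):
    meta = InstrumentMetadata.for_synthetic_cohort()
    meta.to_yaml(tmp_path / "meta.yaml")
    back = InstrumentMetadata.from_yaml(tmp_path / "meta.yaml")
    assert back == meta
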