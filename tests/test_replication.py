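"""Replicate agreement statistics against brute-force formula oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lacpi.errors import InputError, UndefinedStatisticError
from lacpi.replication import (
    ReplicateSet,
    agreement_by_group,
    cv_replicates,
    pearson_r,
    rmse_vs_replicate_mean,
    spearman_s,
    variability_decomposition,
)


# -- independent oracles ----------------------------------------------------
def pearson_oracle(x, y):
    """Direct covariance / (sd·sd) evaluation with explicit loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def average_ranks(values):
    """Average ranks with ties, by enumeration."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestPearson:
    def test_perfect_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 5.0]
        assert pearson_r(x, y) == pytest.approx(pearson_oracle(x, y), rel=1e-10)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-4000, max_value=4000), min_size=4, max_size=10
        )
    )
    def test_affine_invariance(self, x):
        if np.ptp(x) < 1e-3:  # avoid numerically degenerate spreads
            return
        y = [2.0 * v - 100.0 for v in x]
        r = pearson_r(x, y)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert pearson_r([3 * v + 7 for v in x], y) == pytest.approx(r, abs=1e-9)


class TestSpearman:
    def test_monotone_transform_gives_unit_rank_correlation(self):
        x = [1.0, 5.0, 2.0, 9.0, 4.0]
        y = [math.exp(v / 3) for v in x]  # strictly monotone transform
        assert spearman_s(x, y) == pytest.approx(1.0)
        assert spearman_s(x, list(reversed(sorted(x)))[:: 1]) != 1.0

    def test_reversed_order_is_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_s(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_hand_ranking_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [10.0, 8.0, 9.0, 5.0, 1.0]
        rx = average_ranks(x)  # [1, 2.5, 2.5, 4, 5]
        assert rx == [1.0, 2.5, 2.5, 4.0, 5.0]
        expected = pearson_oracle(rx, average_ranks(y))
        assert spearman_s(x, y) == pytest.approx(expected, rel=1e-10)


class TestCV:
    def test_identical_replicates_zero(self):
        assert cv_replicates(ReplicateSet("L", 0, [-100.0, -100.0, -100.0])) == 0.0

    def test_pair_hand_arithmetic(self):
        # sd of (-100, -300) = 141.42, mean -200 -> 70.7%
        cv = cv_replicates(ReplicateSet("L", 0, [-100.0, -300.0]))
        assert cv == pytest.approx(100.0 * math.sqrt(2) * 100 / 200, rel=1e-12)
        assert cv == pytest.approx(70.71, abs=0.01)

    def test_triplicate_hand_arithmetic(self):
        assert cv_replicates(
            ReplicateSet("L", 0, [-90.0, -100.0, -110.0])
        ) == pytest.approx(10.0)

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cv_replicates(ReplicateSet("L", 0, [-50.0, 50.0]))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=-4000, max_value=-1), min_size=2, max_size=5),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_scale_invariance(self, values, c):
        base = cv_replicates(ReplicateSet("L", 0, values))
        scaled = cv_replicates(ReplicateSet("L", 0, [c * v for v in values]))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestRmse:
    def test_internally_identical_sets_give_zero(self):
        sets = [ReplicateSet("L1", 0, [-400.0, -400.0]),
                ReplicateSet("L2", 0, [-90.0, -90.0, -90.0])]
        rmse, rel = rmse_vs_replicate_mean(sets)
        assert rmse == 0.0 and rel == 0.0

    def test_single_pair_is_half_absolute_difference(self):
        rmse, _ = rmse_vs_replicate_mean([ReplicateSet("L", 0, [-400.0, -480.0])])
        assert rmse == pytest.approx(40.0)

    def test_two_pairs_pooled(self):
        rmse, rel = rmse_vs_replicate_mean(
            [
                ReplicateSet("L1", 0, [-400.0, -480.0]),
                ReplicateSet("L2", 0, [-100.0, -100.0]),
            ]
        )
        assert rmse == pytest.approx(math.sqrt((40**2 + 40**2) / 4))
        assert rmse == pytest.approx(28.28, abs=0.01)
        grand_mean = (-400 - 480 - 100 - 100) / 4
        assert rel == pytest.approx(rmse / abs(grand_mean) * 100)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.tuples(
            st.floats(min_value=-4000, max_value=-10),
            st.floats(min_value=-4000, max_value=-10),
        )
    )
    def test_pair_closed_form_property(self, pair):
        a, b = pair
        rmse, _ = rmse_vs_replicate_mean([ReplicateSet("L", 0, [a, b])])
        assert rmse == pytest.approx(abs(a - b) / 2, rel=1e-9, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            rmse_vs_replicate_mean([])


def _pairs_frame(n_dates=5, n_locations=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_dates):
        for loc in range(n_locations):
            mean = -200.0 * (d + 1) * (loc + 1) / 2
            rows.append(
                {
                    "location_id": f"L{loc:02d}",
                    "date": float(33 * (d + 1)),
                    "delta_a": mean + rng.normal(0, 20),
                    "delta_b": mean + rng.normal(0, 20),
                }
            )
    return pd.DataFrame(rows)


class TestAgreementGroups:
    def test_identical_pairs_are_perfectly_correlated(self):
        pairs = _pairs_frame()
        pairs["delta_b"] = pairs["delta_a"]
        for grouping in ("all", "by_date", "by_quintile"):
            tables, skipped = agreement_by_group(pairs, grouping=grouping)
            assert not skipped
            for t in tables:
                assert t.pearson == pytest.approx(1.0)
                assert t.rmse == 0.0

    def test_by_date_matches_direct_recomputation(self):
        pairs = _pairs_frame()
        tables, _ = agreement_by_group(pairs, grouping="by_date")
        for t in tables:
            g = pairs[pairs["date"] == float(t.label)]
            a, b = g["delta_a"].to_numpy(), g["delta_b"].to_numpy()
            assert t.n_pairs == len(g)
            assert t.pearson == pytest.approx(pearson_oracle(list(a), list(b)), rel=1e-10)
            devs = np.concatenate([(a - (a + b) / 2), (b - (a + b) / 2)])
            assert t.rmse == pytest.approx(float(np.sqrt((devs**2).mean())), rel=1e-10)

    def test_140_pairs_split_into_five_groups_of_28(self):
        rng = np.random.default_rng(1)
        pairs = pd.DataFrame(
            {
                "location_id": [f"L{i % 20:02d}" for i in range(140)],
                "date": [float(33 * (i // 20 + 1)) for i in range(140)],
                "delta_a": rng.uniform(-3000, 50, 140),
                "delta_b": rng.uniform(-3000, 50, 140),
            }
        )
        tables, _ = agreement_by_group(pairs, grouping="by_quintile")
        assert [t.label for t in tables] == ["Q1", "Q2", "Q3", "Q4", "Q5"]
        assert [t.n_pairs for t in tables] == [28] * 5
        # Q1 is the least-darkened quintile
        assert tables[0].mean_delta > tables[-1].mean_delta

    def test_all_group_rmse_is_pooled_recombination_of_dates(self):
        pairs = _pairs_frame()
        all_tables, _ = agreement_by_group(pairs, grouping="all")
        date_tables, _ = agreement_by_group(pairs, grouping="by_date")
        pooled = np.sqrt(
            sum(t.rmse**2 * 2 * t.n_pairs for t in date_tables)
            / sum(2 * t.n_pairs for t in date_tables)
        )
        assert all_tables[0].rmse == pytest.approx(pooled, rel=1e-12)

    def test_small_groups_skipped_with_warning(self):
        pairs = _pairs_frame(n_dates=1, n_locations=2)
        tables, skipped = agreement_by_group(pairs, grouping="by_date")
        assert tables == [] and len(skipped) == 1


class TestVariabilityDecomposition:
    def test_identical_everywhere_gives_zero_cvs(self):
        records = pd.DataFrame(
            [
                {"location_id": loc, "time": t, "delta_pi": -500.0}
                for loc in ("L1", "L2")
                for t in (33.0, 55.0)
                for _ in range(2)
            ]
        )
        decomp = variability_decomposition(records)
        assert decomp.among_locations_cv == 0.0
        assert decomp.within_location_cv == 0.0
        assert decomp.replicate_cv == 0.0

    def test_controlled_components_order_correctly(self):
        rng = np.random.default_rng(7)
        rows = []
        loc_level = {f"L{i}": -300.0 * (i + 1) for i in range(6)}  # big spread
        for loc, level in loc_level.items():
            for t in (33.0, 55.0, 90.0, 118.0):
                drift = level * 0.1 * (t / 90.0)  # mild temporal spread
                for _ in range(2):
                    rows.append(
                        {
                            "location_id": loc,
                            "time": t,
                            "delta_pi": level + drift + rng.normal(0, 3.0),
                        }
                    )
        decomp = variability_decomposition(pd.DataFrame(rows))
        assert decomp.among_locations_cv > decomp.within_location_cv
        assert decomp.within_location_cv > decomp.replicate_cv

    def test_two_location_hand_arithmetic(self):
        # constant in time, exact replicates: among-location CV is the CV of
        # the two location means: sd(-100,-300)=141.42, mean -200 -> 70.7%
        records = pd.DataFrame(
            [
                {"location_id": loc, "time": t, "delta_pi": v}
                for loc, v in (("L1", -100.0), ("L2", -300.0))
                for t in (33.0, 55.0)
                for _ in range(2)
            ]
        )
        decomp = variability_decomposition(records)
        assert decomp.among_locations_cv == pytest.approx(70.71, abs=0.01)
        assert decomp.within_location_cv == 0.0
        assert decomp.replicate_cv == 0.0

    def test_insufficient_structure_rejected(self):
        records = pd.DataFrame(
            [{"location_id": "L1", "time": 33.0, "delta_pi": -10.0}] * 3
        )
        with pytest.raises(InputError):
            variability_decomposition(records)
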