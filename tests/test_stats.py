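import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from precue_erd.preprocess import DataError
from precue_erd.stats import (
    accuracy_association,
    add_fdr_flags,
    analyze_session,
    bh_fdr,
    localize,
    mann_whitney,
    median_split,
    participant_aggregate,
    shapiro_wilk,
    spearman,
)


def bh_oracle(p, q):
    """Literal step-up definition, independent of the implementation."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i / m * q:
            k = i
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags


def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mean_u = n_a * len(b) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.array([0.3, 1.2, 2.2, 5.0, 9.1, 12.0])
        r, p = spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_reversal_gives_minus_one(self):
        x = np.arange(6, dtype=float)
        r, _ = spearman(x, -(x**3))
        assert r == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        d2 = sum((rx - ry) ** 2 for rx, ry in zip(x, y))  # ranks = values here
        expected = 1 - 6 * d2 / (5 * (5**2 - 1))
        r, p = spearman(x, y)
        assert r == pytest.approx(expected, abs=1e-12)
        # exact permutation p at n=5: share of the 120 orderings at least as extreme
        perm_r = []
        for perm in itertools.permutations(y):
            d2p = sum((rx - ry) ** 2 for rx, ry in zip(x, perm))
            perm_r.append(1 - 6 * d2p / (5 * 24))
        p_oracle = np.mean(np.abs(perm_r) >= abs(r) - 1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_constant_input_flagged(self):
        r, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(r) and math.isnan(p)

    def test_short_input_rejected(self):
        with pytest.raises(DataError):
            spearman([1, 2, 3], [3, 2, 1])


class TestMannWhitney:
    def test_fully_separated_small_groups_exact_p(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [6.0, 7.0, 8.0, 9.0, 10.0]
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_identical_samples_symmetric(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(a, list(a))
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p > 0.99

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(mw_exact_oracle(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            mann_whitney([], [1.0])


class TestShapiroWilk:
    def test_type_one_error_rate_on_normal_data(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            shapiro_wilk(rng.standard_normal(500))[1] < 0.05 for _ in range(1000)
        )
        assert 30 <= rejections <= 80  # ~5% nominal

    def test_power_on_exponential_data(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            shapiro_wilk(rng.exponential(size=500))[1] < 0.05 for _ in range(100)
        )
        assert rejections >= 99

    def test_constant_input_rejected(self):
        with pytest.raises(DataError):
            shapiro_wilk(np.ones(10))


class TestBhFdr:
    def test_small_example_all_rejected(self):
        np.testing.assert_array_equal(
            bh_fdr([0.01, 0.02, 0.04], q=0.05), [True, True, True]
        )

    def test_all_ones_none_rejected(self):
        assert not bh_fdr(np.ones(7)).any()

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, pvals):
        np.testing.assert_array_equal(bh_fdr(pvals, 0.05), bh_oracle(pvals, 0.05))

    def test_superset_of_bonferroni(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=20)
            bh = bh_fdr(p, 0.05)
            bonf = p <= 0.05 / len(p)
            assert np.all(bh[bonf])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 1.2])


class TestMedianSplit:
    def test_even_split(self):
        upper, lower = median_split(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(upper, [False, False, True, True])

    def test_ties_go_to_lower_group(self):
        upper, lower = median_split(np.array([1.0, 2.0, 2.0, 3.0]))
        np.testing.assert_array_equal(upper, [False, False, False, True])
        assert lower.sum() == 3

    def test_constant_rejected(self):
        with pytest.raises(DataError):
            median_split(np.full(6, 2.0))


def _toy_features(n=24, coupled=True, seed=0):
    rng = np.random.default_rng(seed)
    alpha = rng.lognormal(size=n)
    erd = -alpha if coupled else rng.normal(size=n)
    return pd.DataFrame(
        {
            "participant": 0,
            "session": 0,
            "trial": np.arange(n),
            "class": np.tile(["left", "right"], n // 2),
            "retained": True,
            "alpha_power": alpha,
            "rel_alpha": alpha / (1 + alpha),
            "mean_erd": erd,
            "erd_channel": "C3",
        }
    )


class TestAnalyzeSession:
    def test_perfectly_coupled_toy_gives_minus_one(self):
        stats = analyze_session(_toy_features(coupled=True), by_class=False)
        assert stats["r"].iloc[0] == pytest.approx(-1.0)
        assert stats["u_p"].iloc[0] < 0.01

    def test_by_class_produces_one_row_per_condition(self):
        stats = analyze_session(_toy_features(), by_class=True)
        assert sorted(stats["condition"]) == ["left", "right"]
        assert (stats["n_upper"] + stats["n_lower"] == stats["n_trials"]).all()

    def test_small_conditions_skipped(self):
        feats = _toy_features(n=6)  # 3 trials per hand: below the minimum
        stats = analyze_session(feats, by_class=True)
        assert stats.empty
        pooled = analyze_session(feats, by_class=False)
        assert len(pooled) == 1  # 6 pooled trials are enough

    def test_fdr_flags_respect_families(self):
        frames = [
            analyze_session(_toy_features(coupled=(s % 2 == 0), seed=s), by_class=False).assign(session=s)
            for s in range(6)
        ]
        stats = add_fdr_flags(pd.concat(frames, ignore_index=True))
        assert stats.loc[stats["r"] < -0.99, "significant_fdr"].all()


class TestParticipantAggregate:
    def test_single_session_aggregation_is_identity(self):
        frames = []
        rng = np.random.default_rng(3)
        for p in range(8):
            f = _toy_features(seed=p)
            f["participant"] = p
            f["alpha_power"] += p  # participant-level gradient
            f["mean_erd"] -= p
            frames.append(f)
        feats = pd.concat(frames, ignore_index=True)
        res = participant_aggregate(feats, by_class=False)
        assert res["pooled"]["n_participants"] == 8
        assert res["pooled"]["r"] < -0.9

    def test_too_few_participants_rejected(self):
        with pytest.raises(DataError):
            participant_aggregate(_toy_features(), by_class=False)


class TestLocalize:
    def test_driving_channel_has_extreme_median_r(self):
        rng = np.random.default_rng(4)
        n, n_participants = 40, 6
        frames, erds, pids = [], [], []
        for p in range(n_participants):
            alpha = pd.DataFrame(
                {
                    "Pz": rng.lognormal(size=n),
                    "Cz": rng.lognormal(size=n),
                    "Oz": rng.lognormal(size=n),
                }
            )
            frames.append(alpha)
            erds.append(-alpha["Pz"].to_numpy() + 0.1 * rng.normal(size=n))
            pids.append(np.full(n, p))
        table = localize(
            pd.concat(frames, ignore_index=True),
            np.concatenate(erds),
            np.concatenate(pids),
        )
        best = table.loc[table["median_r"].idxmin()]
        assert best["channel"] == "Pz"
        assert best["fraction_significant"] == 1.0

    def test_single_channel_map(self):
        rng = np.random.default_rng(5)
        alpha = pd.DataFrame({"Pz": rng.lognormal(size=30)})
        table = localize(alpha, rng.normal(size=30), np.zeros(30))
        assert len(table) == 1


class TestAccuracyAssociation:
    def test_identity_gives_perfect_fit(self):
        x = np.linspace(0.1, 0.9, 12)
        res = accuracy_association(x, x)
        assert res["r"] == pytest.approx(1.0)
        assert res["r_squared"] == pytest.approx(1.0)
        assert not res["low_n"]

    def test_constant_accuracy_flagged(self):
        res = accuracy_association(np.linspace(0, 1, 10), np.full(10, 0.7))
        assert math.isnan(res["r"])
        assert math.isnan(res["r_squared"])

    def test_low_n_flag(self):
        res = accuracy_association([0.1, 0.2, 0.5, 0.6], [0.5, 0.6, 0.7, 0.8])
        assert res["low_n"]
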