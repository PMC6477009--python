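"""Exact nonparametric tests vs enumeration oracles; summary tables."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, mannwhitneyu, wilcoxon

from mapkit.stats import (SubjectRecord, TABLE2_COLUMNS, TABLE3_COLUMNS,
                          build_summary_tables, holm_adjust, mann_whitney_u,
                          spearman_rho, wilcoxon_signed_rank)


# --- independent brute-force oracles (coded here, kept separate from the
#     implementation's cached enumeration) --------------------------------

def oracle_mwu_p(x, y):
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = ranks[:len(x)].sum()
    sums = np.array([sum(ranks[i] for i in ix)
                     for ix in combinations(range(len(pooled)), len(x))])
    lo = (sums <= rx + 1e-9).mean()
    hi = (sums >= rx - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


def oracle_wsr_p(d):
    d = np.asarray(d, float)
    nz = d[d != 0]
    ranks = rankdata(np.abs(nz))
    w = ranks[nz > 0].sum()
    n = len(nz)
    ws = np.array([sum(r for r, bit in zip(ranks, range(n)) if (m >> bit) & 1)
                   for m in range(2 ** n)])
    lo = (ws <= w + 1e-9).mean()
    hi = (ws >= w - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_textbook_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_multisets_p_one(self):
        assert mann_whitney_u([5, 1, 3], [3, 1, 5]).p_two_sided == 1.0

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(25):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.integers(0, 5, nx).astype(float)
            y = rng.integers(0, 5, ny).astype(float)
            assert mann_whitney_u(x, y).p_two_sided == \
                pytest.approx(oracle_mwu_p(x, y), abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        ours = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)
        assert ours.statistic == pytest.approx(ref.statistic)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_large_samples_use_approximation(self, rng):
        res = mann_whitney_u(rng.normal(size=12), rng.normal(size=12))
        assert res.method == "approximation"

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=5),
           st.lists(st.integers(-50, 50), min_size=2, max_size=5))
    def test_rank_invariance_under_monotone_transform(self, x, y):
        # integer inputs keep the monotone transform injective in floats
        p1 = mann_whitney_u(x, y).p_two_sided
        f = lambda v: np.exp(np.asarray(v, dtype=float) / 25.0)
        p2 = mann_whitney_u(f(x), f(y)).p_two_sided
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestWilcoxon:
    def test_textbook_example(self):
        res = wilcoxon_signed_rank([1, 2, 3])
        assert res.statistic == 6.0
        assert res.p_two_sided == pytest.approx(0.25)

    def test_antisymmetric_pair_p_one(self):
        assert wilcoxon_signed_rank([-1, 1]).p_two_sided == 1.0

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.p_two_sided == 1.0 and "degenerate" in res.note

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(3, 11)
            d = rng.integers(-5, 6, n).astype(float)
            if (d == 0).all():
                continue
            assert wilcoxon_signed_rank(d).p_two_sided == \
                pytest.approx(oracle_wsr_p(d), abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self, rng):
        d = rng.normal(size=8)
        ours = wilcoxon_signed_rank(d)
        ref = wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)


class TestSpearman:
    def test_monotone_limits(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]).statistic == -1.0

    def test_exact_p_matches_sampled_permutations(self, rng):
        x = rng.normal(size=7)
        y = 0.8 * x + rng.normal(size=7) * 0.5
        res = spearman_rho(x, y)
        assert res.method == "exact"
        # sampled-permutation cross-check
        rx, ry = rankdata(x), rankdata(y)
        def corr(a, b):
            a = a - a.mean(); b = b - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))
        obs = abs(corr(rx, ry))
        hits = sum(abs(corr(rx, rng.permutation(ry))) >= obs - 1e-12
                   for _ in range(20000))
        assert res.p_two_sided == pytest.approx(hits / 20000, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [2, 1])


def test_type_one_error_controlled_at_n8(rng):
    """Empirical size of both exact tests stays at or below ~5% at the
    study's n=8 sample sizes (2,000 null simulations)."""
    rej_mwu = sum(mann_whitney_u(rng.standard_normal(8),
                                 rng.standard_normal(8)).p_two_sided <= 0.05
                  for _ in range(2000))
    rej_wsr = sum(wilcoxon_signed_rank(rng.standard_normal(8)).p_two_sided <= 0.05
                  for _ in range(2000))
    assert rej_mwu / 2000 <= 0.06
    assert rej_wsr / 2000 <= 0.06


def make_records(rng, n=4, effect=0.0):
    recs = []
    for g in ("AS", "control"):
        for i in range(n):
            rec = SubjectRecord(subject_id=f"{g}{i}", group=g)
            for h in ("L", "R"):
                bump = effect if (g == "AS" and h == "L") else 0.0
                rec.rmt[h] = rng.normal(56, 5)
                rec.sp[h] = rng.normal(110, 10)
                rec.rest_amp_mv[h] = rng.normal(0.6, 0.1)
                rec.rest_lat[h] = rng.normal(20, 1)
                rec.active_lat[h] = rng.normal(18, 1)
                rec.area_hand[h] = rng.normal(6, 1)
                rec.area_arm[h] = rng.normal(6, 1)
                rec.overlap[h] = rng.normal(50, 5) + bump
                rec.bbt[h] = rng.normal(60, 5)
                rec.hand_arm_ratio[h] = rng.normal(1, 0.1)
            rec.lr_ratio = {"hand": rng.normal(1, 0.1), "arm": rng.normal(1, 0.1)}
            rec.mean_motor_gm = rng.normal(0.5, 0.02)
            rec.mean_sensory_gm = rng.normal(0.5, 0.02)
            rec.activity = rng.normal(90, 20)
            recs.append(rec)
    return recs


class TestSummaryTables:
    def test_schema_matches_documented_columns(self, rng):
        tables = build_summary_tables(make_records(rng))
        assert list(tables["table2"].columns) == TABLE2_COLUMNS
        assert list(tables["table3"].columns) == TABLE3_COLUMNS
        assert set(tables["table2"]["hemisphere"]) == {"L", "R"}

    def test_identical_groups_between_p_one(self, rng):
        recs = make_records(rng)
        # clone AS values into control so the groups are identical
        for a, c in zip(recs[:4], recs[4:]):
            for attr in ("rmt", "sp", "rest_amp_mv", "rest_lat", "active_lat",
                         "area_hand", "area_arm", "overlap", "bbt"):
                setattr(c, attr, dict(getattr(a, attr)))
        t2 = build_summary_tables(recs)["table2"]
        assert (t2["between_p"] == 1.0).all()

    def test_planted_overlap_asymmetry_flagged(self, rng):
        recs = make_records(rng, n=8, effect=25.0)
        t2 = build_summary_tables(recs)["table2"]
        row = t2[(t2.measure == "overlap") & (t2.hemisphere == "L")].iloc[0]
        assert row["AS_within_p"] <= 0.05
        assert row["control_within_p"] > 0.05

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            build_summary_tables(make_records(rng, n=1))


def test_holm_adjustment_monotone():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert adj.max() <= 1.0
    order_raw = np.argsort(p)
    assert np.all(np.diff(adj[order_raw]) >= -1e-12)
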