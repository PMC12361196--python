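"""Delphi engine: item statistics, screening rules, concordance, authority."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pmssa.delphi import (
    DelphiScreener,
    ExpertProfile,
    authority_coefficient,
    chi_square_from_w,
    compute_item_stats,
    compute_thresholds,
    is_high_authority,
    kendalls_w,
    screen_items,
)
from pmssa.errors import DegenerateInputError, InvalidInputError

from .conftest import make_rating_matrix

# independent hand/brute-force oracles ---------------------------------


def brute_force_ranks(values):
    """Rank by explicit comparison counting (average ranks for ties)."""
    out = []
    for v in values:
        smaller = sum(1 for u in values if u < v)
        ties = sum(1 for u in values if u == v)
        out.append(smaller + (ties + 1) / 2.0)
    return out


def brute_force_w(arr):
    """Tie-corrected concordance computed with plain-Python loops."""
    m, n = arr.shape
    ranks = [brute_force_ranks(list(row)) for row in arr]
    sums = [sum(ranks[i][j] for i in range(m)) for j in range(n)]
    mean = sum(sums) / n
    s = sum((r - mean) ** 2 for r in sums)
    t_total = 0.0
    for row in arr:
        for v in set(row.tolist()):
            t = list(row).count(v)
            t_total += t ** 3 - t
    denom = m * m * (n ** 3 - n) - m * t_total
    return 12.0 * s / denom if denom > 0 else None


# item statistics ------------------------------------------------------


def test_item_stats_hand_computed_values():
    rm = make_rating_matrix(np.array([[5, 4], [5, 4], [5, 5], [5, 5], [5, 5]]))
    stats = compute_item_stats(rm)
    unanimous, mixed = stats
    assert unanimous.mean_score == 5.0
    assert unanimous.cv == 0.0
    assert unanimous.full_score_freq == 1.0
    # ratings [4,4,5,5,5]: sample SD sqrt(0.3), CV ~ 0.11907
    assert mixed.mean_score == pytest.approx(4.6)
    assert mixed.sd_score == pytest.approx(0.5477, abs=1e-4)
    assert mixed.cv == pytest.approx(0.11907, abs=1e-5)
    assert mixed.full_score_freq == pytest.approx(0.6)


def test_item_stats_population_mode_uses_n_denominator():
    rm = make_rating_matrix(np.array([[4, 4], [5, 4], [5, 5]]).T.reshape(2, 3).T)
    sample = compute_item_stats(rm, sd_mode="sample")
    population = compute_item_stats(rm, sd_mode="population")
    for s, p in zip(sample, population):
        assert p.sd_score == pytest.approx(s.sd_score * np.sqrt(2 / 3))


def test_round_summary_mean_matches_constructed_fixture():
    # a deterministic round whose item means average exactly 4.45,
    # mirroring a first-round applicability summary
    cols = [[5, 5, 5, 5, 5], [5, 5, 5, 4, 4], [5, 4, 4, 4, 5], [4, 4, 4, 4, 3]]
    rm = make_rating_matrix(np.array(cols).T)
    stats = compute_item_stats(rm)
    assert np.mean([s.mean_score for s in stats]) == pytest.approx(4.45)


# thresholds and screening ---------------------------------------------


def test_thresholds_hand_computed():
    rm = make_rating_matrix(np.array([[5, 4, 3], [5, 4, 3]]))
    stats = compute_item_stats(rm)
    th = compute_thresholds(stats)
    # item means {5,4,3}: mean 4, sample SD 1 -> threshold 3
    assert th.mean_score_threshold == pytest.approx(3.0)
    from pmssa.delphi import ItemStats
    stats = [ItemStats(f"i{k}", 4.0, 0.0, cv, 0.5) for k, cv in enumerate([0.10, 0.20, 0.30])]
    th = compute_thresholds(stats)
    assert th.cv_threshold == pytest.approx(0.30)


def test_thresholds_require_two_items():
    rm = make_rating_matrix(np.array([[5, 4], [4, 4]]))
    stats = compute_item_stats(rm)
    with pytest.raises(InvalidInputError):
        compute_thresholds(stats[:1])


def test_zero_variance_round_excludes_nothing():
    # every item identical -> thresholds equal the stats, strict
    # comparisons never fire
    rm = make_rating_matrix(np.tile([4, 5, 4], (3, 1)).T.reshape(3, 3))
    stats = compute_item_stats(make_rating_matrix(np.full((4, 6), 4)))
    results = screen_items(stats, compute_thresholds(stats))
    assert not any(r.excluded for r in results)


def test_single_outlier_item_is_the_only_exclusion(rng):
    arr = rng.integers(4, 6, size=(8, 10))
    arr[:, 3] = 3  # one weak item among strong ones
    rm = make_rating_matrix(arr)
    stats = compute_item_stats(rm)
    results = screen_items(stats, compute_thresholds(stats))
    assert [r.item_id for r in results if r.excluded] == ["i3"]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.integers(2, 8), st.integers(2, 10), st.integers(0, 10_000))
def test_screening_agrees_with_bruteforce_rules(m, n, seed):
    rng = np.random.default_rng(seed)
    rm = make_rating_matrix(rng.integers(1, 6, size=(m, n)))
    stats = compute_item_stats(rm)
    th = compute_thresholds(stats)
    results = screen_items(stats, th)
    for s, r in zip(stats, results):
        expected = set()
        if s.full_score_freq < th.full_score_threshold:
            expected.add("low_full_score")
        if s.mean_score < th.mean_score_threshold:
            expected.add("low_mean")
        if s.cv > th.cv_threshold:
            expected.add("high_cv")
        assert set(r.criteria_met) == expected
        assert r.excluded == bool(expected)


def test_permutation_invariance_of_stats_and_w(rng):
    arr = rng.integers(1, 6, size=(6, 9))
    rm = make_rating_matrix(arr)
    perm_items = rng.permutation(9)
    perm_experts = rng.permutation(6)
    rm_perm = make_rating_matrix(arr[np.ix_(perm_experts, perm_items)])
    stats = {s.item_id: s for s in compute_item_stats(rm)}
    stats_perm = compute_item_stats(rm_perm)
    for j, s in zip(perm_items, stats_perm):
        assert s.mean_score == stats[f"i{j}"].mean_score
        assert s.cv == stats[f"i{j}"].cv
    assert kendalls_w(rm).w == pytest.approx(kendalls_w(rm_perm).w)


# Kendall's W ----------------------------------------------------------


def test_identical_rankings_give_perfect_concordance():
    rm = make_rating_matrix(np.tile([1, 2, 4, 5], (3, 1)))
    res = kendalls_w(rm)
    assert res.w == pytest.approx(1.0)
    assert res.chi_square == pytest.approx(res.m * (res.n - 1))
    assert res.df == 3


def test_identical_tied_rankings_still_give_w_of_one():
    rm = make_rating_matrix(np.tile([2, 2, 5], (2, 1)))
    assert kendalls_w(rm).w == pytest.approx(1.0)


def test_w_matches_bruteforce_oracle_with_ties():
    rm = make_rating_matrix(np.array([[1, 1, 3], [2, 1, 3], [1, 2, 3]]))
    assert kendalls_w(rm).w == pytest.approx(brute_force_w(rm.ratings))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(2, 6), st.integers(3, 5), st.integers(0, 10_000))
def test_w_and_chi_square_match_independent_oracles(m, n, seed):
    rng = np.random.default_rng(seed)
    arr = rng.integers(1, 6, size=(m, n))
    expected = brute_force_w(arr)
    if expected is None:
        with pytest.raises(DegenerateInputError):
            kendalls_w(make_rating_matrix(arr))
        return
    res = kendalls_w(make_rating_matrix(arr))
    assert res.w == pytest.approx(expected, abs=1e-12)
    # Friedman's statistic is an algebraically independent route to chi2
    friedman = sps.friedmanchisquare(*[arr[:, j] for j in range(n)])
    assert res.chi_square == pytest.approx(friedman.statistic, rel=1e-9)
    assert res.p_value == pytest.approx(friedman.pvalue, rel=1e-9)
    assert 0.0 <= res.w <= 1.0


def test_degenerate_panel_raises():
    with pytest.raises(DegenerateInputError):
        kendalls_w(make_rating_matrix(np.full((3, 4), 3)))


def test_chi_square_identity_helper():
    assert chi_square_from_w(0.5, 10, 5) == pytest.approx(20.0)
    with pytest.raises(InvalidInputError):
        chi_square_from_w(1.2, 10, 5)


# authority coefficient ------------------------------------------------


@pytest.mark.parametrize(
    "ca, cs, expected, high",
    [(0.90, 0.82, 0.86, True), (0.7, 0.7, 0.7, True), (0.5, 0.5, 0.5, False)],
)
def test_authority_coefficient(ca, cs, expected, high):
    cr = authority_coefficient(ca, cs)
    assert cr == pytest.approx(expected)
    assert is_high_authority(cr) is high


def test_judgment_basis_components_sum_to_ca():
    from pmssa.delphi import judgment_basis_score

    ca = judgment_basis_score([0.3, 0.3, 0.2, 0.1])
    assert ca == pytest.approx(0.9)
    with pytest.raises(InvalidInputError):
        judgment_basis_score([0.5, 0.6, 0.2, 0.1])


def test_authority_rejects_out_of_range():
    with pytest.raises(InvalidInputError):
        authority_coefficient(1.2, 0.5)


def test_expert_profile_checks_cr_consistency():
    p = ExpertProfile("e1", ca=0.9, cs=0.82)
    assert p.cr == pytest.approx(0.86)
    assert p.high_authority
    with pytest.raises(InvalidInputError):
        ExpertProfile("e2", ca=0.9, cs=0.82, cr=0.5)


# estimator surface ----------------------------------------------------


def test_screener_transform_drops_excluded_columns(rng):
    arr = rng.integers(4, 6, size=(8, 10))
    arr[:, 3] = 3
    screener = DelphiScreener().fit(arr)
    assert screener.excluded_items_ == ["item4"]
    kept = screener.transform(arr)
    assert kept.shape == (8, 9)
    assert screener.get_support().sum() == 9


def test_screener_is_sklearn_clonable():
    from sklearn.base import clone

    screener = DelphiScreener(sd_mode="population")
    assert clone(screener).get_params() == {"sd_mode": "population"}
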