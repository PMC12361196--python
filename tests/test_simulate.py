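"""Synthetic-data generators: determinism, calibration, monotone links."""

import numpy as np
import pytest

from pmssa.ahp import AHPWeighter, principal_weights
from pmssa.delphi import (
    compute_item_stats,
    compute_thresholds,
    kendalls_w,
    screen_items,
)
from pmssa.scoring import LEVEL_POINTS
from pmssa.simulate import (
    CohortSpec,
    PanelSpec,
    expected_incidence,
    expected_score_pct,
    generate_cohort,
    generate_matrices,
    generate_panel,
)


# determinism ----------------------------------------------------------


def test_identical_seeds_reproduce_identical_outputs(hierarchy):
    a1, r1, q1 = generate_cohort(CohortSpec(seed=11), hierarchy)
    a2, r2, q2 = generate_cohort(CohortSpec(seed=11), hierarchy)
    assert np.array_equal(q1, q2)
    assert [a.responses for a in a1] == [a.responses for a in a2]
    assert r1 == r2
    p1, _ = generate_panel(PanelSpec(seed=5))
    p2, _ = generate_panel(PanelSpec(seed=5))
    assert np.array_equal(p1.ratings, p2.ratings)
    assert not np.array_equal(p1.ratings, generate_panel(PanelSpec(seed=6))[0].ratings)


# panels ---------------------------------------------------------------


def test_full_consensus_is_deterministic_rounding():
    spec = PanelSpec(m_experts=4, n_items=6, consensus=1.0, outlier_items=0, seed=0)
    rm, quality = generate_panel(spec)
    expected = np.clip(np.rint(quality), 1, 5).astype(int)
    assert np.array_equal(rm.ratings, np.tile(expected, (4, 1)))


def test_full_consensus_on_distinct_items_gives_w_of_one():
    spec = PanelSpec(m_experts=3, n_items=4, consensus=1.0, outlier_items=2,
                     item_quality=(3.8, 4.4), outlier_quality=(1.6, 2.4), seed=1)
    rm, quality = generate_panel(spec)
    assert kendalls_w(rm).w == pytest.approx(1.0)


def test_zero_consensus_w_concentrates_at_null_expectation():
    # under independent ratings E[W] is about 1/m
    ws = [kendalls_w(generate_panel(PanelSpec(consensus=0.0, outlier_items=0, seed=s))[0]).w
          for s in range(10)]
    assert abs(np.mean(ws) - 1 / 15) < 0.03


def test_higher_consensus_raises_w_stochastically():
    def mean_w(c):
        return np.mean([
            kendalls_w(generate_panel(PanelSpec(consensus=c, seed=s))[0]).w
            for s in range(8)
        ])

    assert mean_w(0.3) < mean_w(0.6) < mean_w(0.9)


def test_default_panel_screens_out_the_outlier_set():
    """Calibration contract: the 15x91 default round with 7 planted weak
    items excludes all 7 in every replicate and exactly 7 in the median
    replicate."""
    n_excluded, outliers_caught = [], []
    for seed in range(40):
        rm, _ = generate_panel(PanelSpec(seed=seed))
        stats = compute_item_stats(rm)
        results = screen_items(stats, compute_thresholds(stats))
        excluded = {r.item_id for r in results if r.excluded}
        n_excluded.append(len(excluded))
        outliers_caught.append(set(rm.item_ids[-7:]) <= excluded)
    assert all(outliers_caught)
    assert np.median(n_excluded) == 7


# matrices -------------------------------------------------------------


def test_zero_noise_reproduces_consistent_matrix():
    w_true = np.array([0.5, 0.3, 0.2])
    mats = generate_matrices(w_true, noise=0.0, n_experts=3, seed=0)
    for m in mats:
        weights, report = principal_weights(m)
        assert weights == pytest.approx(w_true, abs=1e-10)
        assert report.cr == pytest.approx(0.0, abs=1e-12)


def test_generated_matrices_are_exactly_reciprocal():
    mats = generate_matrices([0.4, 0.3, 0.2, 0.1], noise=0.4, n_experts=6, seed=2)
    for m in mats:
        assert np.allclose(m.entries * m.entries.T, 1.0)


def test_snap_to_saaty_restricts_entries():
    from pmssa.ahp import SAATY_VALUES

    mats = generate_matrices([0.6, 0.25, 0.15], noise=0.3, n_experts=4, seed=3,
                             snap_to_saaty=True)
    grid = np.array(SAATY_VALUES)
    for m in mats:
        iu = np.triu_indices(3, 1)
        assert all(np.min(np.abs(grid - v)) < 1e-9 for v in m.entries[iu])


def test_mean_cr_nondecreasing_in_noise():
    def mean_cr(noise):
        crs = []
        for seed in range(10):
            mats = generate_matrices([0.4, 0.25, 0.2, 0.15], noise=noise,
                                     n_experts=1, seed=seed)
            crs.append(principal_weights(mats[0])[1].cr)
        return np.mean(crs)

    assert mean_cr(0.0) <= mean_cr(0.2) <= mean_cr(0.6)


def test_aggregated_panel_recovers_weights_closely():
    w_true = np.array([0.35, 0.30, 0.20, 0.15])
    mats = generate_matrices(w_true, noise=0.1, n_experts=15, seed=4)
    est = AHPWeighter().fit(mats)
    assert np.abs(est.weights_ - w_true).sum() < 0.05


# cohorts --------------------------------------------------------------


def test_ceiling_quality_yields_all_e_and_minimal_errors(hierarchy):
    spec = CohortSpec(n_facilities=5, quality_alpha=1e6, quality_beta=1e-3,
                      response_noise=1e-6, frailty_sd=0.0, seed=0)
    assessments, records, q = generate_cohort(spec, hierarchy)
    assert np.all(q > 0.99)
    for a in assessments:
        assert set(a.responses.values()) == {"E"}
    # with every facility at the quality ceiling and no frailty, the
    # incidence sits at the model's baseline floor
    floor = sum(spec.error_baseline.values())
    inc = [(r.dispensing_errors + r.prescribing_errors + r.medication_errors)
           / r.total_prescriptions for r in records]
    assert np.mean(inc) == pytest.approx(floor, rel=0.25)


def test_counts_never_exceed_prescriptions():
    spec = CohortSpec(n_facilities=30, frailty_sd=3.0, seed=9)
    _, records, _ = generate_cohort(spec)
    for r in records:
        assert max(r.dispensing_errors, r.prescribing_errors,
                   r.medication_errors) <= r.total_prescriptions


def test_expected_score_strictly_increasing_in_quality():
    spec = CohortSpec()
    qs = np.linspace(0.3, 0.99, 40)
    pct = expected_score_pct(spec, qs)
    assert np.all(np.diff(pct) > 0)


def test_expected_error_probability_decreasing_in_quality():
    from pmssa.simulate import _error_prob

    spec = CohortSpec()
    qs = np.linspace(0.6, 0.99, 40)   # above the clip region
    p = _error_prob(spec, qs, np.zeros_like(qs), "prescribing")
    assert np.all(np.diff(p) < 0)


def test_empirical_monotone_links_on_large_sample(hierarchy):
    spec = CohortSpec(n_facilities=400, seed=21)
    assessments, records, q = generate_cohort(spec, hierarchy)
    pts = np.array([np.mean([LEVEL_POINTS[l] for l in a.responses.values()])
                    for a in assessments]) / 4 * 100
    inc = np.array([100.0 * (r.dispensing_errors + r.prescribing_errors +
                             r.medication_errors) / r.total_prescriptions
                    for r in records])
    order = np.argsort(q)
    lo, hi = order[:100], order[-100:]
    assert pts[hi].mean() > pts[lo].mean()
    assert inc[hi].mean() < inc[lo].mean()


def test_expected_incidence_matches_monte_carlo(hierarchy):
    spec = CohortSpec(n_facilities=800, seed=33)
    _, records, _ = generate_cohort(spec, hierarchy)
    mc = np.mean([100.0 * r.prescribing_errors / r.total_prescriptions for r in records])
    assert expected_incidence(spec, "prescribing") == pytest.approx(mc, rel=0.15)


def test_null_error_model_centres_rho_on_zero(hierarchy):
    from pmssa.validation import spearman

    rhos = []
    for seed in range(12):
        spec = CohortSpec(error_slope=0.0, seed=seed)
        assessments, records, _ = generate_cohort(spec, hierarchy)
        pts = [np.mean([LEVEL_POINTS[l] for l in a.responses.values()]) for a in assessments]
        inc = [100.0 * (r.dispensing_errors + r.prescribing_errors + r.medication_errors)
               / r.total_prescriptions for r in records]
        rhos.append(spearman(pts, inc).rho)
    assert abs(np.mean(rhos)) < 0.15
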