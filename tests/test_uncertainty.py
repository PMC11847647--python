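"""Clustered bootstrap and BCa intervals: determinism, clustering,
jackknife acceleration, and the adjusted-percentile formulas against an
independent brute-force implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from leaaf import (
    CohortPanel,
    bca_interval,
    bootstrap_leaaf,
    jackknife_leaaf,
    leaaf_with_bca,
)
from leaaf.uncertainty import resample_participants


def _clone_panel(n_clones: int = 12) -> CohortPanel:
    """Panel of identical participants (3 person-years each, one profile)."""
    blocks = []
    for pid in range(n_clones):
        blocks.append(pd.DataFrame({
            "person_id": pid, "t": [0, 1, 2],
            "c0": [0, 1, 1], "z0": [0, 1, 0],
            "outcome": [0, 0, 1],
        }))
    return CohortPanel(pd.concat(blocks, ignore_index=True), ("c0",), ("z0",))


def test_bootstrap_is_deterministic_and_prefix_stable(toy_panel):
    a, _ = bootstrap_leaaf(toy_panel, B=4, seed=123)
    b, _ = bootstrap_leaaf(toy_panel, B=4, seed=123)
    np.testing.assert_array_equal(a, b)
    # growing B keeps the earlier replicates identical
    c, _ = bootstrap_leaaf(toy_panel, B=8, seed=123)
    np.testing.assert_array_equal(a, c[:4])


def test_resampling_is_clustered_on_participants(toy_panel):
    rng = np.random.default_rng(0)
    rep = resample_participants(toy_panel, rng)
    sizes = toy_panel.df.groupby("person_id").size()
    rep_sizes = rep.df.groupby("person_id").size()
    # every resampled participant carries a whole person-year block
    assert set(rep_sizes.unique()) <= set(sizes.unique())
    assert rep.df["person_id"].nunique() <= toy_panel.n_persons
    assert len(rep.df) == rep_sizes.sum()


def test_replicate_additivity(toy_panel):
    boot, diag = bootstrap_leaaf(toy_panel, B=10, seed=7)
    assert diag["n_failed"] == 0
    np.testing.assert_allclose(boot[:, :-1].sum(axis=1), boot[:, -1], atol=1e-10)


def test_jackknife_count_one_vector_per_deleted_participant():
    # profiles chosen so every single-deletion refit still converges
    profiles = [
        (0, [0, 0, 1]), (1, [0, 1, 0]), (1, [0, 0, 1]),
        (0, [0, 0, 0]), (1, [0, 0, 0]), (0, [0, 1, 0]),
    ]
    blocks = []
    for pid, (c0, ys) in enumerate(profiles):
        blocks.append(pd.DataFrame({
            "person_id": pid, "t": [0, 1, 2], "c0": c0, "outcome": ys,
        }))
    panel = CohortPanel(pd.concat(blocks, ignore_index=True), ("c0",), ())
    jack = jackknife_leaaf(panel)
    assert jack.shape[0] == 6  # one estimate vector per deleted participant


def test_resampling_identical_participants_leaves_data_unchanged():
    """With every participant identical, any participant resample yields the
    same dataset, so the attribution under a fixed risk model is exactly the
    point estimate — no resampling variability."""
    from leaaf import RiskModelFit, compute_attribution

    panel = _clone_panel()
    fit = RiskModelFit(
        condition_names=("c0",), covariate_names=("z0",),
        beta0=-2.0, beta_time=0.3, beta_cond=np.array([0.5]),
        beta_cov=np.array([0.1]),
    )
    point = compute_attribution(fit, panel)
    for seed in range(5):
        rep = resample_participants(panel, np.random.default_rng(seed))
        pd.testing.assert_frame_equal(
            rep.df.drop(columns="person_id"),
            panel.df.drop(columns="person_id"),
        )
        res = compute_attribution(fit, rep)
        np.testing.assert_array_equal(res.leaaf, point.leaaf)


def test_equal_jackknife_estimates_give_zero_acceleration():
    iv = bca_interval(0.3, np.array([0.2, 0.3, 0.4]), np.full(7, 0.25))
    assert iv.a == 0.0


def test_degenerate_bootstrap_distribution_collapses_interval():
    boot = np.full(50, 0.3)
    with pytest.warns(UserWarning, match="degenerate"):
        iv = bca_interval(0.3, boot, np.array([0.29, 0.30, 0.31]))
    assert iv.lower == iv.upper == 0.3


def test_bca_reduces_to_percentile_when_unbiased_and_unaccelerated():
    boot = np.sort(np.random.default_rng(3).normal(size=500))
    point = np.median(boot)  # exactly half below -> z0 = 0
    jack = np.array([-1.0, -0.5, 0.5, 1.0])  # symmetric -> a = 0
    iv = bca_interval(point, boot, jack, alpha=0.10)
    assert iv.z0 == 0.0 and iv.a == 0.0
    assert iv.lower == pytest.approx(np.quantile(boot, 0.05), abs=1e-12)
    assert iv.upper == pytest.approx(np.quantile(boot, 0.95), abs=1e-12)


def test_bca_matches_independent_brute_force():
    rng = np.random.default_rng(11)
    boot = rng.gamma(2.0, 1.5, size=500)          # skewed distribution
    jack = rng.gamma(2.0, 0.1, size=40)
    point = 2.9
    alpha = 0.05
    iv = bca_interval(point, boot, jack, alpha=alpha)

    # brute-force re-implementation of the z0 / a / adjusted percentiles
    z0 = norm.ppf(np.mean(boot < point))
    tb = jack.mean()
    a = np.sum((tb - jack) ** 3) / (6.0 * (np.sum((tb - jack) ** 2)) ** 1.5)
    lo = norm.cdf(z0 + (z0 + norm.ppf(alpha / 2)) / (1 - a * (z0 + norm.ppf(alpha / 2))))
    hi = norm.cdf(z0 + (z0 + norm.ppf(1 - alpha / 2)) / (1 - a * (z0 + norm.ppf(1 - alpha / 2))))
    assert iv.z0 == pytest.approx(z0, abs=1e-12)
    assert iv.a == pytest.approx(a, abs=1e-12)
    assert iv.lower == pytest.approx(np.quantile(boot, lo), abs=1e-10)
    assert iv.upper == pytest.approx(np.quantile(boot, hi), abs=1e-10)


def test_one_sided_bootstrap_clamps_bias_with_warning():
    boot = np.linspace(1.0, 2.0, 50)
    with pytest.warns(UserWarning, match="one side"):
        iv = bca_interval(0.5, boot, np.array([0.4, 0.5, 0.6]))
    assert np.isfinite(iv.z0)
    assert 1.0 <= iv.lower <= iv.upper <= 2.0


def test_half_tie_mode_counts_ties_half():
    boot = np.array([1.0, 2.0, 2.0, 3.0])
    strict = bca_interval(2.0, boot, np.array([1.9, 2.0, 2.1]), tie_mode="strict")
    half = bca_interval(2.0, boot, np.array([1.9, 2.0, 2.1]), tie_mode="half")
    assert strict.z0 == pytest.approx(norm.ppf(0.25))
    assert half.z0 == pytest.approx(norm.ppf(0.5))


def test_resampling_refit_path_matches_reference_estimator(toy_panel):
    """The array-only refit engine used inside the bootstrap loop must
    reproduce the public statsmodels-fit + attribution path exactly."""
    from leaaf import compute_attribution, fit_pooled_logistic
    from leaaf.plr import newton_logistic
    from leaaf.uncertainty import (
        _ResamplingPipeline,
        _leaaf_vector,
        _replicate_seed_rng,
    )

    pipe = _ResamplingPipeline(toy_panel)
    pipe.warm = newton_logistic(pipe.X, pipe.y)
    # full sample
    fit = fit_pooled_logistic(toy_panel)
    res = compute_attribution(fit, toy_panel)
    full = pipe.leaaf_for_rows(np.arange(len(pipe.y)))
    np.testing.assert_allclose(full, np.r_[res.leaaf, res.total], atol=1e-8)
    # a resampled replicate, drawn identically along both paths
    for i in range(3):
        draw = _replicate_seed_rng(77, i).integers(0, pipe.n_persons, pipe.n_persons)
        fast = pipe.leaaf_for_rows(pipe.rows_for_participants(draw))
        slow = _leaaf_vector(
            resample_participants(toy_panel, _replicate_seed_rng(77, i)),
            "subset-weights")
        np.testing.assert_allclose(fast, slow, atol=1e-8)


def test_end_to_end_intervals_bracket_point(toy_panel):
    res = leaaf_with_bca(toy_panel, B=30, seed=2)
    for lab, iv in res["intervals"].items():
        assert iv.lower <= iv.point <= iv.upper, lab
        assert iv.B == 30
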