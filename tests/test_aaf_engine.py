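"""Attribution engine: excess-fraction arithmetic, telescoping of
sequential contributions, order-averaging (Shapley) identity against
explicit permutation enumeration, component-additivity, and the
person-year-weighted longitudinal aggregation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leaaf import (
    af_subset,
    average_af,
    compute_attribution,
    le_aaf,
    sequential_af,
    single_factor_af,
)
from leaaf.plr import RiskModelFit

from conftest import random_toy_panel


def _hand_af(fit, df, removed):
    """Independent excess-fraction oracle in plain Python arithmetic."""
    num = den = 0.0
    for _, row in df.iterrows():
        lp = fit.beta0 + fit.beta_time * row["t"]
        lp0 = lp
        for j, c in enumerate(fit.condition_names):
            lp += fit.beta_cond[j] * row[c]
            lp0 += fit.beta_cond[j] * (0 if j in removed else row[c])
        for k, z in enumerate(fit.covariate_names):
            lp += fit.beta_cov[k] * row[z]
            lp0 += fit.beta_cov[k] * row[z]
        den += 1 / (1 + math.exp(-lp))
        num += 1 / (1 + math.exp(-lp)) - 1 / (1 + math.exp(-lp0))
    return num / den


@pytest.fixture
def toy2():
    """4-row, 2-condition panel with hand-set coefficients."""
    df = pd.DataFrame({
        "person_id": [0, 1, 2, 3],
        "t": [1, 1, 1, 1],
        "c0": [1, 1, 0, 0],
        "c1": [1, 0, 1, 0],
        "z0": [1, 0, 1, 0],
        "z1": [0, 1, 0, 0],
        "outcome": [0, 0, 0, 1],
    })
    fit = RiskModelFit(
        condition_names=("c0", "c1"), covariate_names=("z0", "z1"),
        beta0=-1.5, beta_time=0.2,
        beta_cond=np.array([0.8, 0.4]), beta_cov=np.array([0.3, -0.2]),
    )
    return fit, df


def test_empty_removal_set_gives_zero(toy2):
    fit, df = toy2
    assert af_subset(fit, df, []) == 0.0


def test_null_coefficient_condition_gives_zero_af(toy2):
    fit, df = toy2
    fit.beta_cond[1] = 0.0
    assert af_subset(fit, df, [1]) == pytest.approx(0.0, abs=1e-15)


def test_af_matches_hand_computed_inverse_logit_sums(toy2):
    fit, df = toy2
    for removed in ([0], [1], [0, 1]):
        assert af_subset(fit, df, removed) == pytest.approx(
            _hand_af(fit, df, removed), abs=1e-10)


def test_af_accepts_condition_names(toy2):
    fit, df = toy2
    assert af_subset(fit, df, ["c0"]) == af_subset(fit, df, [0])


def test_sequential_contributions_telescope_to_joint_af(toy2):
    fit, df = toy2
    for order in itertools.permutations(range(2)):
        contribs = sequential_af(fit, df, order)
        assert contribs.sum() == pytest.approx(af_subset(fit, df, [0, 1]), abs=1e-12)


def test_removal_orders_disagree_per_condition_but_not_in_total(toy2):
    fit, df = toy2
    c01 = sequential_af(fit, df, (0, 1))   # ordered by removal sequence
    c10 = sequential_af(fit, df, (1, 0))
    assert c01[0] != pytest.approx(c10[1])  # c0 removed first vs last
    assert c01.sum() == pytest.approx(c10.sum(), abs=1e-12)
    # hand check: first contribution is AF of that condition alone
    assert c01[0] == pytest.approx(_hand_af(fit, df, [0]), abs=1e-10)
    assert c10[0] == pytest.approx(_hand_af(fit, df, [1]), abs=1e-10)


def test_single_condition_aaf_reduces_to_plain_af():
    rng = np.random.default_rng(5)
    fit, df = random_toy_panel(rng, d=1)
    assert average_af(fit, df)[0] == pytest.approx(af_subset(fit, df, [0]), abs=1e-12)


def test_exchangeable_conditions_get_equal_aaf():
    rng = np.random.default_rng(8)
    fit, df = random_toy_panel(rng, d=2)
    df["c1"] = df["c0"]
    fit.beta_cond[:] = 0.35
    a = average_af(fit, df)
    assert a[0] == pytest.approx(a[1], abs=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), d=st.integers(1, 4))
def test_subset_weight_aaf_equals_order_enumeration(seed, d):
    rng = np.random.default_rng(seed)
    fit, df = random_toy_panel(rng, d=d)
    np.testing.assert_allclose(
        average_af(fit, df, method="subset-weights"),
        average_af(fit, df, method="enumerate"),
        atol=1e-10,
    )


@settings(max_examples=50, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000), d=st.integers(2, 4))
def test_aaf_additivity_and_order_invariance(seed, d):
    rng = np.random.default_rng(seed)
    fit, df = random_toy_panel(rng, d=d)
    aaf = average_af(fit, df)
    # component-additivity: per-condition AAFs sum to the joint AF
    assert aaf.sum() == pytest.approx(af_subset(fit, df, list(range(d))), abs=1e-10)
    # relabeling invariance: permuting conditions permutes the output
    perm = rng.permutation(d)
    names = tuple(f"c{j}" for j in range(d))
    fit2 = RiskModelFit(
        condition_names=names, covariate_names=fit.covariate_names,
        beta0=fit.beta0, beta_time=fit.beta_time,
        beta_cond=fit.beta_cond[perm], beta_cov=fit.beta_cov,
    )
    df2 = df.copy()
    for j, p in enumerate(perm):
        df2[f"c{j}"] = df[f"c{p}"]
    np.testing.assert_allclose(average_af(fit2, df2), aaf[perm], atol=1e-10)


def test_single_factor_af_equals_subset_af(toy2):
    fit, df = toy2
    for j in range(2):
        assert single_factor_af(fit, df, j) == pytest.approx(
            af_subset(fit, df, [j]), abs=1e-10)


def test_single_factor_af_zero_prevalence_returns_zero(toy2):
    fit, df = toy2
    df = df.copy()
    df["c0"] = 0
    assert single_factor_af(fit, df, 0) == 0.0


def test_leaaf_weighted_mean_arithmetic():
    leaaf, total = le_aaf(np.array([[0.10, 0.30]]), np.array([1.0, 3.0]))
    assert leaaf[0] == pytest.approx(0.25, abs=1e-12)
    assert total == pytest.approx(0.25, abs=1e-12)


def test_leaaf_of_constant_trajectory_is_the_constant():
    aaf = np.full((3, 7), 0.042)
    leaaf, total = le_aaf(aaf, np.arange(1, 8, dtype=float))
    np.testing.assert_allclose(leaaf, 0.042, atol=1e-12)
    assert total == pytest.approx(3 * 0.042, abs=1e-12)


def test_leaaf_rejects_zero_or_negative_weights():
    with pytest.raises(ValueError, match="zero"):
        le_aaf(np.ones((1, 2)), np.zeros(2))
    with pytest.raises(ValueError, match="negative"):
        le_aaf(np.ones((1, 2)), np.array([1.0, -1.0]))


def test_full_attribution_additive_at_every_timepoint(toy_panel, toy_fit):
    res = compute_attribution(toy_fit, toy_panel)
    for k, t in enumerate(res.times):
        rows = toy_panel.df[toy_panel.df["t"] == t]
        joint = af_subset(toy_fit, rows, list(range(len(res.condition_names))))
        assert res.aaf_by_time[:, k].sum() == pytest.approx(joint, abs=1e-10)
    assert res.leaaf.sum() == pytest.approx(res.total, abs=1e-10)
    assert res.weights.sum() == toy_panel.n_person_years
    assert res.total < 1.0  # predicted risks stay positive with all removed


def test_attribution_methods_agree_on_real_panel(toy_panel, toy_fit):
    a = compute_attribution(toy_fit, toy_panel, method="subset-weights")
    b = compute_attribution(toy_fit, toy_panel, method="enumerate")
    np.testing.assert_allclose(a.aaf_by_time, b.aaf_by_time, atol=1e-10)


def test_tidy_export_shapes(toy_fit, toy_panel):
    res = compute_attribution(toy_fit, toy_panel)
    frame = res.to_frame()
    d, T = res.aaf_by_time.shape
    assert len(frame) == d * T
    assert set(frame.columns) == {"condition", "t", "aaf", "weight"}
    s = res.summary()
    assert s["total"] == pytest.approx(res.total)
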