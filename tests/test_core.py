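"""Unit and property tests for the Gibbs sampler building blocks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import subridge as sr
from subridge.core import VAR_FLOOR

from conftest import make_dataset


class RecordingRng:
    """Stub RNG: returns the conditional mean / a fixed chi-square value and
    records the arguments it was called with."""

    def __init__(self, chisq=None):
        self.normal_args = []
        self.chisq_args = []
        self._chisq = chisq

    def normal(self, loc, scale):
        self.normal_args.append((loc, scale))
        return loc

    def chisquare(self, dof):
        self.chisq_args.append(dof)
        return self._chisq


def make_state(x_cols, e, b, var_b, var_e, d=None):
    X = np.asarray(x_cols, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    e = np.asarray(e, dtype=np.float64)
    d = np.einsum("ij,ij->j", X, X) if d is None else np.asarray(d, dtype=np.float64)
    return sr.SamplerState(
        mu=0.0, b=b, e=e, var_b=var_b, var_e=var_e, lam=var_e / var_b, d=d, X=X
    )


def full_bag(n):
    return sr.SubsampleDraw(indices=np.arange(n), m=n, with_replacement=False)


# ---------------------------------------------------------------------------
# genotype container


def test_genotype_matrix_rejects_bad_entries_and_ids():
    with pytest.raises(sr.InvalidInputError):
        sr.GenotypeMatrix(np.array([[0, 3]]), ("a", "b"), ("i1",))
    with pytest.raises(sr.InvalidInputError):
        sr.GenotypeMatrix(np.array([[0, 1]]), ("a", "a"), ("i1",))
    with pytest.raises(sr.InvalidInputError):
        sr.GenotypeMatrix(np.array([[0], [1]]), ("a",), ("i1", "i1"))


# ---------------------------------------------------------------------------
# prior elicitation and initialization


def test_prior_shapes_follow_r2_rule():
    # shape_b = r2 * var_y * (nu_b + 2) / sum_j var(x_j)
    rng = np.random.default_rng(5)
    y = rng.normal(size=40)
    X = rng.integers(0, 3, size=(40, 6)).astype(float)
    var_y = np.var(y, ddof=1)
    sum_var_x = np.var(X, axis=0, ddof=1).sum()
    pri = sr.compute_prior_shapes(y, X, r_squared=0.5, nu_b=5, nu_e=5)
    assert pri.shape_b == pytest.approx(0.5 * var_y * 7.0 / sum_var_x, rel=1e-12)
    assert pri.shape_e == pytest.approx(0.5 * var_y * 7.0, rel=1e-12)
    # direct evaluation with the stated quantities
    assert 0.5 * 2.0 * (5 + 2) / 7.0 == pytest.approx(1.0)
    assert 0.5 * 1.0 * (5 + 2) == pytest.approx(3.5)
    # r2 = 1 zeroes the residual shape
    pri1 = sr.compute_prior_shapes(y, X, r_squared=1.0)
    assert pri1.shape_e == 0.0


def test_prior_shapes_reject_degenerate_inputs():
    X = np.ones((5, 3))
    with pytest.raises(sr.InvalidInputError):
        sr.compute_prior_shapes(np.ones(5), np.random.default_rng(0).integers(0, 3, (5, 3)))
    with pytest.raises(sr.InvalidInputError):
        sr.compute_prior_shapes(np.arange(5.0), X)  # all monomorphic


def test_initialize_state_contract():
    y = np.array([1.0, 1.0, 1.0])
    X = np.array([[0, 1], [1, 2], [2, 0]], dtype=float)
    pri = sr.PriorSpec()
    st_ = sr.initialize_state(y, X, pri)
    assert st_.mu == 1.0
    assert np.all(st_.e == 0.0)
    assert np.all(st_.b == 0.0)

    y2 = np.array([0.0, 2.0])
    st2 = sr.initialize_state(y2, np.array([[0, 1], [1, 0]], dtype=float),
                              sr.PriorSpec(r_squared=0.5))
    assert st2.var_e == pytest.approx(0.5 * np.var(y2, ddof=1))
    assert st2.d == pytest.approx([1.0, 1.0])

    with pytest.raises(sr.InvalidInputError):
        sr.initialize_state(np.ones(4), X, pri)


# ---------------------------------------------------------------------------
# subsample draws


def test_identity_bag_at_psi_one():
    cfg = sr.MCMCConfig(psi=1.0, with_replacement=False)
    sub = sr.draw_subsample(7, cfg, np.random.default_rng(0))
    assert np.array_equal(sub.indices, np.arange(7))


@settings(deadline=None, max_examples=40)
@given(n=st.integers(2, 200), seed=st.integers(0, 2**31 - 1),
       psi=st.floats(0.2, 1.0), wr=st.booleans())
def test_subsample_draw_properties(n, seed, psi, wr):
    cfg = sr.MCMCConfig(psi=psi, with_replacement=wr)
    m = int(round(psi * n))
    if m == 0:
        with pytest.raises(sr.InvalidConfigError):
            sr.draw_subsample(n, cfg, np.random.default_rng(seed))
        return
    sub = sr.draw_subsample(n, cfg, np.random.default_rng(seed))
    assert sub.m == m == sub.indices.size
    assert sub.indices.min() >= 0 and sub.indices.max() < n
    if not wr:
        assert np.unique(sub.indices).size == m


def test_with_replacement_produces_repeats_over_seeds():
    cfg = sr.MCMCConfig(psi=0.5, with_replacement=True)
    any_repeat = any(
        np.unique(sr.draw_subsample(10, cfg, np.random.default_rng(s)).indices).size < 5
        for s in range(50)
    )
    assert any_repeat


# ---------------------------------------------------------------------------
# single Gibbs updates against hand-evaluated conditionals


def test_coefficient_conditional_full_data():
    # x'e = 1, d = 4, b_j = 0.5, lambda = 2, var_e = 1 -> mean 0.5, var 1/6
    state = make_state(x_cols=[[2.0], [0.0]], e=[0.5, 9.9], b=[0.5],
                       var_b=0.5, var_e=1.0)
    rng = RecordingRng()
    val = sr.sample_coefficient(0, state, full_bag(2), psi=1.0, rng=rng)
    (loc, scale), = rng.normal_args
    assert loc == pytest.approx(0.5)
    assert scale == pytest.approx(math.sqrt(1.0 / 6.0))
    assert val == loc


def test_coefficient_conditional_subsampled():
    # psi=0.5, bagged x'e = 1, d = 4, b_j = 1, lambda = 2 -> mean 0.75, var 0.25
    state = make_state(x_cols=[[1.0], [5.0]], e=[1.0, 7.0], b=[1.0],
                       var_b=0.5, var_e=1.0, d=[4.0])
    sub = sr.SubsampleDraw(indices=np.array([0]), m=1, with_replacement=False)
    rng = RecordingRng()
    sr.sample_coefficient(0, state, sub, psi=0.5, rng=rng)
    (loc, scale), = rng.normal_args
    assert loc == pytest.approx(0.75)
    assert scale == pytest.approx(0.5)


def test_coefficient_null_case_and_degeneracy():
    state = make_state(x_cols=[[1.0], [-1.0]], e=[0.0, 0.0], b=[0.0],
                       var_b=1.0, var_e=1.0)
    rng = RecordingRng()
    sr.sample_coefficient(0, state, full_bag(2), psi=1.0, rng=rng)
    (loc, scale), = rng.normal_args
    assert loc == 0.0
    assert scale == pytest.approx(math.sqrt(1.0 / 3.0))

    degen = make_state(x_cols=[[0.0], [0.0]], e=[1.0, 1.0], b=[0.0],
                       var_b=1.0, var_e=0.0, d=[0.0])
    degen.lam = 0.0
    with pytest.raises(sr.NumericalDegeneracyError):
        sr.sample_coefficient(0, degen, full_bag(2), psi=1.0, rng=rng)


def test_residual_update_applies_to_all_rows():
    state = make_state(x_cols=[[1.0], [-1.0]], e=[1.0, 2.0], b=[0.0],
                       var_b=1.0, var_e=1.0)
    sr.update_residual(state, 0, b_old=0.0, b_new=0.5)
    assert state.e == pytest.approx([0.5, 2.5])
    assert state.b[0] == 0.5
    # zero delta and null marker leave e untouched
    before = state.e.copy()
    sr.update_residual(state, 0, b_old=0.5, b_new=0.5)
    assert np.array_equal(state.e, before)


def test_intercept_draw_and_identity():
    rng_data = np.random.default_rng(3)
    y = rng_data.normal(size=30)
    X = rng_data.integers(0, 3, (30, 4)).astype(float)
    pri = sr.compute_prior_shapes(y, X)
    state = sr.initialize_state(y, X, pri)
    state.var_e = 1.0
    sub = sr.SubsampleDraw(indices=np.arange(10), m=10, with_replacement=False)
    rng = RecordingRng()
    sr.sample_intercept(state, sub, rng)
    (loc, scale), = rng.normal_args
    expected_mean = y.mean() + (y[:10] - y.mean()).mean()
    assert loc == pytest.approx(expected_mean)
    assert scale == pytest.approx(math.sqrt(1.0 / 10.0))
    # identity holds after the shift
    resid = y - state.mu - X @ state.b
    assert np.abs(resid - state.e).max() < 1e-12


def test_genetic_variance_update():
    # b'b = 2, S_b = 1, nu_b = 5, p = 10, chi2 draw 15 -> 7/15
    state = make_state(
        x_cols=np.zeros((3, 10)), e=np.zeros(3),
        b=np.r_[np.sqrt(2.0), np.zeros(9)], var_b=1.0, var_e=1.0,
        d=np.ones(10),
    )
    pri = sr.PriorSpec(shape_b=1.0, nu_b=5.0)
    rng = RecordingRng(chisq=15.0)
    out = sr.sample_genetic_variance(state, pri, rng)
    assert out == pytest.approx(7.0 / 15.0)
    assert rng.chisq_args == [15.0]
    assert state.lam == pytest.approx(1.0 / out)

    # null numerator is guarded to the floor
    state.b[:] = 0.0
    out = sr.sample_genetic_variance(state, sr.PriorSpec(shape_b=0.0), rng)
    assert out == VAR_FLOOR


def test_genetic_variance_scaled_inverse_chisq_expectation():
    """Monte-Carlo mean of the update matches numerator / (dof - 2)."""
    p, nu_b = 10, 5.0
    state = make_state(
        x_cols=np.zeros((3, p)), e=np.zeros(3),
        b=np.r_[np.sqrt(2.0), np.zeros(p - 1)], var_b=1.0, var_e=1.0,
        d=np.ones(p),
    )
    pri = sr.PriorSpec(shape_b=1.0, nu_b=nu_b)
    rng = np.random.default_rng(12345)
    draws = np.array([sr.sample_genetic_variance(state, pri, rng)
                      for _ in range(100_000)])
    expected = (2.0 + 1.0 * nu_b) / (p + nu_b - 2.0)
    assert draws.mean() == pytest.approx(expected, rel=0.02)


def test_residual_variance_update():
    # bagged e'e = 10, S_e = 3.5, nu_e = 5, psi*n = 20, chi2 draw 25 -> 1.1
    e = np.zeros(40)
    e[:20] = np.sqrt(0.5)
    state = make_state(x_cols=np.zeros((40, 1)), e=e, b=[0.0],
                       var_b=1.0, var_e=1.0, d=[1.0])
    sub = sr.SubsampleDraw(indices=np.arange(20), m=20, with_replacement=False)
    rng = RecordingRng(chisq=25.0)
    out = sr.sample_residual_variance(state, sub, sr.PriorSpec(shape_e=3.5, nu_e=5.0),
                                      psi=0.5, rng=rng)
    assert out == pytest.approx(27.5 / 25.0)
    assert rng.chisq_args == [0.5 * 40 + 5.0]

    # psi=1 without replacement reduces to the full-data update
    rng = RecordingRng(chisq=25.0)
    out_full = sr.sample_residual_variance(state, full_bag(40),
                                           sr.PriorSpec(shape_e=3.5, nu_e=5.0),
                                           psi=1.0, rng=rng)
    assert out_full == pytest.approx((e @ e + 17.5) / 25.0)
    assert rng.chisq_args == [45.0]

    # null numerator guarded to floor
    state.e[:] = 0.0
    rng = RecordingRng(chisq=25.0)
    out0 = sr.sample_residual_variance(state, full_bag(40),
                                       sr.PriorSpec(shape_e=0.0), psi=1.0, rng=rng)
    assert out0 == VAR_FLOOR


# ---------------------------------------------------------------------------
# whole-chain behaviour


def test_run_chain_contracts(small_dataset):
    y, gm, _ = small_dataset
    cfg = sr.MCMCConfig(iterations=400, burn_in=100, seed=9)
    s = sr.run_chain(y, gm, config=cfg)
    assert s.samples["mu"].shape == (300,)
    assert s.samples["var_b"].shape == (300,)
    assert (s.samples["var_b"] > 0).all() and (s.samples["var_e"] > 0).all()
    assert s.diagnostics["op_count"] == 400 * gm.n_markers * gm.n_individuals

    # determinism: identical config + seed -> bit-identical summary
    s2 = sr.run_chain(y, gm, config=cfg)
    assert np.array_equal(s.b_mean, s2.b_mean)
    assert np.array_equal(s.samples["var_e"], s2.samples["var_e"])
    assert s.mu_mean == s2.mu_mean

    # a different seed gives a different chain
    s3 = sr.run_chain(y, gm, config=sr.MCMCConfig(iterations=400, burn_in=100, seed=10))
    assert not np.array_equal(s.b_mean, s3.b_mean)


def test_run_chain_residual_identity(small_dataset):
    y, gm, _ = small_dataset
    for wr in (False, True):
        cfg = sr.MCMCConfig(iterations=300, burn_in=0, psi=0.4,
                            with_replacement=wr, seed=4)
        s = sr.run_chain(y, gm, config=cfg)
        d = s.diagnostics
        resid = y - d["final_mu"] - gm.as_float() @ d["final_b"]
        dev = np.abs(resid - d["final_e"]).max() / (1.0 + np.abs(y).max())
        assert dev < 1e-8


def test_monomorphic_marker_effect_stays_zero():
    rng = np.random.default_rng(8)
    X = rng.integers(0, 3, (50, 5)).astype(float)
    X[:, 2] = 0.0  # null marker, d_j = 0
    y = rng.normal(size=50)
    s = sr.run_chain(y, X, config=sr.MCMCConfig(iterations=200, burn_in=50, seed=1))
    assert s.b_mean[2] == 0.0


def test_permuted_update_order_runs_and_differs(small_dataset):
    y, gm, _ = small_dataset
    fixed = sr.run_chain(y, gm, config=sr.MCMCConfig(iterations=300, burn_in=50,
                                                     seed=2, update_order="fixed"))
    perm = sr.run_chain(y, gm, config=sr.MCMCConfig(iterations=300, burn_in=50,
                                                    seed=2, update_order="permuted"))
    assert not np.array_equal(fixed.b_mean, perm.b_mean)
    # both posterior means should still broadly agree
    assert np.corrcoef(fixed.b_mean, perm.b_mean)[0, 1] > 0.9


def test_op_level_loop_matches_chain_structure():
    """A chain assembled from the single-update functions keeps the residual
    identity at every round (both replacement modes)."""
    y, gm, _ = make_dataset(n=40, p=8, seed=77)
    X = gm.as_float()
    for wr in (False, True):
        pri = sr.compute_prior_shapes(y, gm)
        state = sr.initialize_state(y, gm, pri)
        cfg = sr.MCMCConfig(psi=0.4, with_replacement=wr, seed=13)
        rng = np.random.default_rng(cfg.seed)
        for _ in range(50):
            sub = sr.draw_subsample(40, cfg, rng)
            sr.sample_intercept(state, sub, rng)
            for j in range(8):
                b_new = sr.sample_coefficient(j, state, sub, cfg.psi, rng)
                sr.update_residual(state, j, state.b[j], b_new)
            sr.sample_genetic_variance(state, pri, rng)
            sr.sample_residual_variance(state, sub, pri, cfg.psi, rng)
            resid = y - state.mu - X @ state.b
            assert np.abs(resid - state.e).max() / (1 + np.abs(y).max()) < 1e-8


# ---------------------------------------------------------------------------
# prediction and the closed-form oracle


def test_predict_linear_model():
    summary = sr.PosteriorSummary(
        mu_mean=1.0, b_mean=np.array([0.5]), var_b_mean=1.0, var_e_mean=1.0,
        samples={}, marker_ids=("m1",), b_samples=None, diagnostics={},
    )
    assert sr.predict(np.array([[2.0]]), summary) == pytest.approx([2.0])
    assert sr.predict(np.zeros((3, 1)), summary) == pytest.approx([1.0, 1.0, 1.0])
    # permuting rows permutes predictions identically
    X = np.array([[0.0], [1.0], [2.0]])
    out = sr.predict(X, summary)
    assert sr.predict(X[::-1], summary) == pytest.approx(out[::-1])
    # marker mismatch is rejected
    gm = sr.GenotypeMatrix(np.array([[1]]), ("other",), ("i1",))
    with pytest.raises(sr.InvalidInputError):
        sr.predict(gm, summary)


def test_ridge_oracle_closed_form():
    X = np.array([[1.0], [1.0]])
    y = np.array([1.0, 1.0])
    assert sr.ridge_closed_form_oracle(y, X, 0.0) == pytest.approx([1.0])
    assert sr.ridge_closed_form_oracle(y, X, 2.0) == pytest.approx([0.5])
    assert sr.ridge_closed_form_oracle(y, X, 1e12)[0] == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(sr.InvalidInputError):
        sr.ridge_closed_form_oracle(np.ones(2), np.ones((2, 5)), 0.0)


def test_reference_chain_rejects_subsampling(small_dataset):
    y, gm, _ = small_dataset
    with pytest.raises(sr.InvalidConfigError):
        sr.gsru_reference_chain(y, gm, config=sr.MCMCConfig(psi=0.5))


def test_config_validation():
    with pytest.raises(sr.InvalidConfigError):
        sr.MCMCConfig(iterations=100, burn_in=100)
    with pytest.raises(sr.InvalidConfigError):
        sr.MCMCConfig(psi=0.0)
    with pytest.raises(sr.InvalidConfigError):
        sr.MCMCConfig(psi=1.5)
    with pytest.raises(sr.InvalidConfigError):
        sr.MCMCConfig(update_order="random")
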