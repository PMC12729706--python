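"""Bernoulli naive Bayes: counting estimators, exact inference against a
brute-force Bayes oracle, and the integer LUT path."""

import numpy as np
import pytest

from hdseizure.bnbc import (
    LUT_CLAMP,
    LUT_LOG_OFFSET,
    BnbcModel,
    build_lut,
    fit,
    load_model,
    lut_costs,
    lut_entry,
    lut_table,
    predict_float,
    predict_float_batch,
    predict_lut,
    predict_lut_batch,
    quantize_bin,
    save_model,
)


def _model(p, priors=(0.5, 0.5)):
    p = np.asarray(p, dtype=np.float64)
    return BnbcModel(D=p.shape[0], priors=np.asarray(priors, dtype=np.float64),
                     p=p, n_train=np.array([10, 10]))


# ---------------------------------------------------------------- fitting

def test_fit_priors_by_counting():
    X = np.array([[0, 1], [1, 1], [0, 0], [1, 0]])
    m = fit(X, [0, 0, 1, 1])
    np.testing.assert_allclose(m.priors, [0.5, 0.5])
    np.testing.assert_array_equal(m.n_train, [2, 2])


def test_fit_bernoulli_frequency():
    X = np.array([[1], [1], [0], [0], [0], [0]])
    m = fit(X, [0, 0, 0, 1, 1, 1])
    assert m.p[0, 0] == pytest.approx(2 / 3)
    assert m.p[0, 1] == 0.0  # no smoothing


def test_fit_rejects_single_class_and_nonbinary():
    with pytest.raises(ValueError, match="both classes"):
        fit(np.array([[0], [1]]), [1, 1])
    with pytest.raises(ValueError, match="binary"):
        fit(np.array([[0.5], [1]]), [0, 1])


def test_fit_recovers_generating_probabilities(rng):
    n, d = 2000, 40
    p_true = rng.uniform(0.1, 0.9, size=(d, 2))
    X = np.vstack([
        (rng.random((n, d)) < p_true[:, 0]).astype(np.uint8),
        (rng.random((n, d)) < p_true[:, 1]).astype(np.uint8),
    ])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    m = fit(X, y)
    bound = 3 * np.sqrt(p_true * (1 - p_true) / n)
    assert np.all(np.abs(m.p - p_true) <= bound)


def test_estimation_error_shrinks_with_n(rng):
    p_true = np.full((30, 2), 0.3)
    errs = []
    for n in (100, 400, 1600):
        X = (rng.random((2 * n, 30)) < 0.3).astype(np.uint8)
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        errs.append(np.abs(fit(X, y).p - p_true).mean())
    assert errs[2] < errs[0]


# ------------------------------------------------------- float inference

def test_prior_dominates_when_likelihoods_cancel(rng):
    p = rng.uniform(0.2, 0.8, size=(10, 1)) * np.ones((1, 2))
    m = _model(p, priors=(0.9, 0.1))
    for _ in range(20):
        x = rng.integers(0, 2, size=10)
        assert predict_float(m, x)[0] == 0


def test_single_informative_dimension():
    m = _model(np.array([[0.995, 0.005]]))
    assert predict_float(m, [1])[0] == 0
    assert predict_float(m, [0])[0] == 1


def test_tie_resolves_to_interictal():
    m = _model(np.full((5, 2), 0.4))
    assert predict_float(m, [1, 0, 1, 0, 1])[0] == 0


def _oracle_posterior(model, x):
    """Brute-force Bayes rule in probability space: prior times the product
    of per-dimension Bernoulli masses (same zero guard, no logs)."""
    def guard(v):
        return v + LUT_LOG_OFFSET if v <= LUT_CLAMP else v

    post = []
    for c in (0, 1):
        prob = guard(model.priors[c])
        for k in range(model.D):
            pk = model.p[k, c]
            prob *= guard(pk) if x[k] else guard(1.0 - pk)
        post.append(prob)
    return 1 if post[1] > post[0] else 0


def test_float_path_matches_exhaustive_bayes_oracle(rng):
    d = 8
    X = rng.integers(0, 2, size=(60, d))
    y = rng.integers(0, 2, size=60)
    y[:2] = [0, 1]
    m = fit(X, y)
    for value in range(2 ** d):
        x = [(value >> k) & 1 for k in range(d)]
        assert predict_float(m, x)[0] == _oracle_posterior(m, x)


def test_dimension_mismatch_raises():
    m = _model(np.full((4, 2), 0.5))
    with pytest.raises(ValueError):
        predict_float(m, [0, 1])


# ------------------------------------------------------------- LUT table

@pytest.mark.parametrize("bin_index,cost", [(1, 884), (2, 577), (99, 2),
                                            (100, 1)])
def test_lut_entry_printed_values(bin_index, cost):
    assert lut_entry(bin_index) == cost


@pytest.mark.parametrize("bin_index,cost", [(3, 495), (4, 445)])
def test_lut_entry_remaining_rows_within_one(bin_index, cost):
    assert abs(lut_entry(bin_index) - cost) <= 1


def test_lut_entries_positive_and_nonincreasing():
    table = lut_table()
    assert (table >= 1).all()
    assert (np.diff(table) <= 0).all()


def test_lut_entry_index_bounds():
    with pytest.raises(ValueError):
        lut_entry(0)
    with pytest.raises(ValueError):
        lut_entry(101)


def test_quantize_bins():
    assert quantize_bin(0.015) == 2
    assert quantize_bin(0.0) == 1
    assert quantize_bin(1.0) == 100
    with pytest.raises(ValueError):
        quantize_bin(1.5)


def test_build_lut_degenerate_probabilities():
    lut = build_lut(_model(np.array([[1.0, 0.015]])))
    assert lut.cost_active[0, 0] == 1  # p = 1 -> top bin
    assert lut.cost_inactive[0, 0] == 884  # 1 - p = 0 -> bottom bin
    assert lut.cost_active[0, 1] == 577  # bin 2


def test_no_32bit_overflow_at_large_d():
    # every cost <= 884 < 2^10, so a D=10,000 total stays under 2^24
    assert lut_table().max() * 10_000 < 2 ** 24


# --------------------------------------------------------- LUT inference

def test_all_zero_input_cost_identity(rng):
    m = _model(rng.uniform(0.1, 0.9, size=(6, 2)))
    lut = build_lut(m)
    x = np.zeros(6, dtype=int)
    costs = lut_costs(lut, x)[0]
    expected = lut.prior_cost + lut.cost_inactive.sum(axis=0)
    np.testing.assert_array_equal(costs, expected)


def test_symmetric_model_ties_to_interictal(rng):
    p = rng.uniform(0.1, 0.9, size=(8, 1)) * np.ones((1, 2))
    lut = build_lut(_model(p))
    for _ in range(10):
        label, costs = predict_lut(lut, rng.integers(0, 2, size=8))
        assert costs[0] == costs[1]
        assert label == 0


def test_active_only_mode_drops_inactive_terms(rng):
    m = _model(rng.uniform(0.1, 0.9, size=(6, 2)))
    lut = build_lut(m, active_only=True)
    x = rng.integers(0, 2, size=6)
    costs = lut_costs(lut, x)[0]
    expected = lut.prior_cost + (x[:, None] * lut.cost_active).sum(axis=0)
    np.testing.assert_array_equal(costs, expected)
    # and the default full-Bernoulli sum differs when any bit is inactive
    full = lut_costs(lut, x, active_only=False)[0]
    assert (full >= costs).all()


def test_lut_decisions_track_float_decisions(rng):
    """>= 99% agreement over 1000 random draws with probabilities away
    from bin edges; the rare disagreements sit at near-tie float margins."""
    d = 16
    agree = 0
    disagree_margins = []
    for _ in range(1000):
        bins = rng.integers(5, 95, size=(d, 2))
        p = bins / 100 + 0.005 + rng.uniform(-0.003, 0.003, size=(d, 2))
        m = _model(p)
        lut = build_lut(m)
        x = rng.integers(0, 2, size=d)
        f_label, lp = predict_float(m, x)
        l_label, _ = predict_lut(lut, x)
        if f_label == l_label:
            agree += 1
        else:
            disagree_margins.append(abs(lp[1] - lp[0]))
    assert agree >= 990
    assert all(mg < 0.1 for mg in disagree_margins)


def test_batch_predictors_match_scalar(rng):
    m = _model(rng.uniform(0.05, 0.95, size=(12, 2)), priors=(0.3, 0.7))
    lut = build_lut(m)
    X = rng.integers(0, 2, size=(50, 12))
    np.testing.assert_array_equal(
        predict_float_batch(m, X), [predict_float(m, x)[0] for x in X])
    np.testing.assert_array_equal(
        predict_lut_batch(lut, X), [predict_lut(lut, x)[0] for x in X])


def test_model_round_trip(tmp_path, rng):
    X = rng.integers(0, 2, size=(40, 10))
    y = rng.integers(0, 2, size=40)
    y[:2] = [0, 1]
    m = fit(X, y)
    lut = build_lut(m)
    path = tmp_path / "model.json"
    save_model(m, path, lut=lut, metadata={"window_s": 0.25})
    m2, lut2, meta = load_model(path)
    np.testing.assert_array_equal(m.p, m2.p)
    np.testing.assert_array_equal(m.priors, m2.priors)
    np.testing.assert_array_equal(lut.cost_active, lut2.cost_active)
    np.testing.assert_array_equal(lut.cost_inactive, lut2.cost_inactive)
    assert meta["window_s"] == 0.25
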