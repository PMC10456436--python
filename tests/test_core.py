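import numpy as np
import pytest

from serdakit import (
    CorruptionSpec,
    HyperParams,
    NormalizationError,
    RoleSelection,
    autoscale_fit_apply,
    corrupt,
    estimate_noise_sigma,
    fit_dae,
    glog_transform,
    init_params,
    inverse_glog,
    oversample,
    serda_normalize,
    tune_hyperparameters,
)
from serdakit.core import _elu, injection_order_folds

from conftest import make_table


# ----------------------------------------------------------------------
# transforms
# ----------------------------------------------------------------------
def test_glog_reduces_to_log2_for_lambda_zero():
    assert glog_transform(np.array([8.0]))[0] == pytest.approx(3.0)


def test_glog_at_zero_with_lambda_two():
    assert glog_transform(np.array([0.0]), lam=2.0)[0] == pytest.approx(0.0)
    assert inverse_glog(np.array([0.0]), lam=2.0)[0] == pytest.approx(0.0)


def test_glog_round_trip():
    rng = np.random.default_rng(0)
    x = rng.uniform(0.1, 1e6, size=(5, 4))
    for lam in (0.0, 2.0, 100.0):
        back = inverse_glog(glog_transform(x, lam), lam)
        np.testing.assert_allclose(back, x, rtol=1e-9)


def test_glog_rejects_negative():
    with pytest.raises(NormalizationError):
        glog_transform(np.array([-1.0]))


def test_inverse_glog_example():
    assert inverse_glog(np.array([3.0]))[0] == pytest.approx(8.0)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    st.lists(
        st.floats(min_value=1e-3, max_value=1e9, allow_nan=False),
        min_size=1,
        max_size=30,
    ),
    st.sampled_from([0.0, 0.7, 25.0]),
)
@settings(deadline=None, derandomize=True, max_examples=60)
def test_glog_round_trip_property(values, lam):
    x = np.asarray(values)
    np.testing.assert_allclose(
        inverse_glog(glog_transform(x, lam), lam), x, rtol=1e-9
    )


def test_glog_monotone():
    x = np.linspace(0.0, 50.0, 200)
    for lam in (0.5, 4.0):
        g = glog_transform(x, lam)
        assert (np.diff(g) > 0).all()


# ----------------------------------------------------------------------
# noise model
# ----------------------------------------------------------------------
def test_sigma_direct_and_clamped():
    rng = np.random.default_rng(1)
    x1 = rng.normal(0, 1.0, size=(4000, 2))
    x2 = rng.normal(0, 1.0, size=(4000, 2))
    x2[:, 0] *= 3.0  # sd(x2)=3 vs sd(x1)=1 -> sigma ~ 2
    x2[:, 1] *= 0.2  # sd(x2) < sd(x1) -> clamped at 0
    sigma = estimate_noise_sigma(x1, x2)
    assert sigma[0] == pytest.approx(2.0, rel=0.05)
    assert sigma[1] == 0.0


def test_sigma_identical_distributions_is_zero():
    x = np.random.default_rng(2).normal(size=(50, 3))
    np.testing.assert_array_equal(estimate_noise_sigma(x, x), np.zeros(3))


def test_sigma_single_row_rejected():
    with pytest.raises(NormalizationError):
        estimate_noise_sigma(np.ones((1, 2)), np.ones((3, 2)))


def test_corrupt_identity_when_no_noise():
    x = np.arange(12.0).reshape(3, 4)
    spec = CorruptionSpec(sigma=np.zeros(4), nu=0.0)
    out = corrupt(x, spec, np.random.default_rng(0))
    np.testing.assert_array_equal(out, x)


def test_corruption_spec_rejects_full_dropout():
    with pytest.raises(NormalizationError):
        CorruptionSpec(sigma=np.zeros(3), nu=1.0)


def test_corrupt_moments_and_dropout_fraction():
    rng = np.random.default_rng(3)
    d = 20
    spec = CorruptionSpec(sigma=np.ones(d), nu=0.1)
    x = np.zeros((400, d))
    out = corrupt(x, spec, rng)
    # floor(0.1 * 20) = 2 entries zeroed per row, exactly
    zero_frac = (out == 0).mean()
    assert zero_frac == pytest.approx(0.1, abs=0.01)
    # residual variance of surviving noise ~ 1
    assert out[out != 0].std() == pytest.approx(1.0, rel=0.05)


def test_oversample_shapes_and_zero_noise():
    x = np.arange(10.0).reshape(5, 2)
    spec = CorruptionSpec(sigma=np.zeros(2))
    rng = np.random.default_rng(0)
    assert oversample(x, 0, spec, rng).shape == (5, 2)
    out = oversample(x, 2, spec, rng)
    assert out.shape == (15, 2)
    np.testing.assert_array_equal(out[5:10], x)  # sigma=0 -> exact copies


def test_autoscale_standardizes_and_inverts():
    rng = np.random.default_rng(4)
    train = rng.normal(5, 3, size=(30, 4))
    target = rng.normal(5, 3, size=(10, 4))
    tr, tg, scaler = autoscale_fit_apply(train, target, fit_on="train")
    np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(tr.std(axis=0, ddof=1), 1.0, rtol=1e-12)
    np.testing.assert_allclose(scaler.invert(tg), target, rtol=1e-12)


def test_autoscale_constant_column_floored():
    train = np.ones((6, 2))
    train[:, 1] = np.arange(6.0)
    tr, _, _ = autoscale_fit_apply(train, train)
    np.testing.assert_allclose(tr[:, 0], 0.0, atol=1e-12)


# ----------------------------------------------------------------------
# network
# ----------------------------------------------------------------------
def test_init_params_glorot_bounds_and_determinism():
    d, dp = 30, 7
    m1 = init_params(d, dp, np.random.default_rng(5))
    m2 = init_params(d, dp, np.random.default_rng(5))
    limit = np.sqrt(6.0 / (d + dp))
    assert np.abs(m1.W).max() <= limit and np.abs(m1.W_prime).max() <= limit
    np.testing.assert_array_equal(m1.b_enc, 0.0)
    np.testing.assert_array_equal(m1.b_dec, 0.0)
    np.testing.assert_array_equal(m1.W, m2.W)


def test_elu_activation_table():
    v = _elu(np.array([1.0, 0.0, -1.0]))
    assert v[0] == 1.0 and v[1] == 0.0
    assert v[2] == pytest.approx(np.exp(-1) - 1)


def test_forward_zero_weights_gives_zero():
    m = init_params(3, 2, np.random.default_rng(0))
    m.W[:] = 0.0
    m.W_prime[:] = 0.0
    np.testing.assert_array_equal(m.forward(np.ones((4, 3))), np.zeros((4, 3)))


def test_forward_matches_hand_algebra():
    m = init_params(3, 2, np.random.default_rng(0))
    m.W = np.array([[1.0, 0.0, -1.0], [0.5, 0.5, 0.5]])
    m.b_enc = np.array([0.1, -0.2])
    m.W_prime = np.array([[1.0, -1.0], [0.0, 2.0], [0.3, 0.3]])
    m.b_dec = np.array([0.0, 0.1, -0.1])
    x = np.array([[0.2, -0.4, 0.6], [1.0, 1.0, 1.0]])

    def elu(a):
        return np.where(a > 0, a, np.exp(a) - 1)

    y = elu(x @ m.W.T + m.b_enc)
    expect = elu(y @ m.W_prime.T + m.b_dec)
    np.testing.assert_allclose(m.forward(x), expect, rtol=1e-14)


def test_forward_shape_mismatch():
    m = init_params(3, 2, np.random.default_rng(0))
    with pytest.raises(NormalizationError):
        m.forward(np.ones((2, 5)))


def test_fit_dae_reconstructs_constant_data():
    clean = np.tile(np.array([0.5, -0.5, 0.2, 0.0]), (12, 1))
    hp = HyperParams(d_prime=4, nu=0.0, batch_size=4, seed=0, max_epochs=400)
    model = fit_dae(clean, clean, hp)
    mae = np.abs(model.forward(clean) - clean).mean()
    assert mae < 0.05


def test_fit_dae_bit_reproducible():
    rng = np.random.default_rng(6)
    clean = rng.normal(size=(20, 6))
    noisy = clean + 0.1 * rng.normal(size=clean.shape)
    hp = HyperParams(d_prime=3, batch_size=5, seed=11, max_epochs=150, patience=20)
    m1 = fit_dae(noisy, clean, hp)
    m2 = fit_dae(noisy, clean, hp)
    assert m1.n_epochs == m2.n_epochs
    np.testing.assert_array_equal(m1.W, m2.W)
    np.testing.assert_array_equal(m1.W_prime, m2.W_prime)


def test_fit_dae_low_rank_recovery():
    # all compounds scalar multiples of one drift factor -> d'=1 suffices;
    # positive regime, where the elu output map is effectively linear
    rng = np.random.default_rng(7)
    factor = rng.uniform(0.5, 1.5, size=40)
    loadings = rng.uniform(0.5, 1.5, size=6)
    clean = np.outer(factor, loadings)
    noisy = clean + 0.05 * rng.normal(size=clean.shape)
    hp = HyperParams(
        d_prime=1, nu=0.0, batch_size=8, seed=3, max_epochs=3000, patience=100
    )
    model = fit_dae(noisy, clean, hp)
    mae = np.abs(model.forward(clean) - clean).mean()
    assert mae < 0.1 * clean.std()


def test_fit_dae_validates_batch_size():
    clean = np.zeros((6, 2))
    with pytest.raises(NormalizationError, match="batch_size"):
        fit_dae(clean, clean, HyperParams(batch_size=50))


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------
def qc_table(n_qc=12, n_study=20, d=8, seed=0, drift=True):
    rng = np.random.default_rng(seed)
    n = n_qc + n_study
    order = np.arange(n)
    mu = rng.uniform(12, 16, size=d)
    log2x = np.tile(mu, (n, 1))
    if drift:
        path = np.sin(order / 6.0)
        loadings = rng.uniform(0.5, 1.5, size=d)
        log2x += np.outer(path, loadings)
    log2x += rng.normal(0, 0.05, size=(n, d))
    roles = (["pool_qc"] + ["study"] * (n_study // n_qc + 1)) * n_qc
    roles = roles[:n]
    return make_table(np.exp2(log2x), roles)


def test_mean_preservation_on_scaled_space():
    # step 12 subtracts a mean-centered quantity: per-compound target means
    # on the scaled space are preserved to machine precision
    t = qc_table()
    res = serda_normalize(t, hp=HyperParams(batch_size=4, seed=0, max_epochs=100))
    raw_target = glog_transform(t.sorted_by_injection().intensities)
    x2s = res.model.scaler.apply(raw_target)  # every sample is a target here
    np.testing.assert_allclose(
        res.x2_prime.mean(axis=0), x2s.mean(axis=0), atol=1e-10
    )


def test_degenerate_constant_model_leaves_target_unchanged():
    # a reconstruction that is constant across samples subtracts to zero
    m = init_params(4, 2, np.random.default_rng(0))
    m.W[:] = 0.0  # phi(x) = elu(b_dec) for every x
    m.b_dec = np.array([0.3, -0.3, 0.0, 1.0])
    x2 = np.random.default_rng(1).normal(size=(9, 4))
    phi = m.forward(x2)
    corrected = x2 - (phi - phi.mean(axis=0))
    np.testing.assert_allclose(corrected, x2, atol=1e-14)


def test_serda_determinism_end_to_end():
    t = qc_table()
    hp = HyperParams(batch_size=4, seed=5, max_epochs=100)
    r1 = serda_normalize(t, hp=hp)
    r2 = serda_normalize(t, hp=hp)
    np.testing.assert_array_equal(r1.normalized.intensities, r2.normalized.intensities)


def test_serda_reduces_qc_rsd_under_drift():
    from serdakit import rsd_report

    t = qc_table(n_qc=16, n_study=32, seed=2)
    raw = rsd_report(t, "pool_qc").median
    res = serda_normalize(t, hp=HyperParams(batch_size=4, seed=0))
    after = rsd_report(res.normalized, "pool_qc").median
    assert after < 0.5 * raw


def test_serda_harmless_on_drift_free_data():
    from serdakit import rsd_report

    t = qc_table(n_qc=16, n_study=32, seed=3, drift=False)
    raw = rsd_report(t, "pool_qc").median
    res = serda_normalize(t, hp=HyperParams(batch_size=4, seed=0))
    after = rsd_report(res.normalized, "pool_qc").median
    assert after <= 1.2 * raw  # no harmful correction


def test_serda_requires_enough_qcs():
    t = make_table([[1.0, 2.0]] * 4, ["pool_qc", "study", "pool_qc", "study"])
    with pytest.raises(NormalizationError, match=">= 5"):
        serda_normalize(t)


def test_injection_order_folds_interleave():
    order = np.array([10, 20, 30, 40, 50, 60])
    folds = injection_order_folds(order, 3)
    np.testing.assert_array_equal(folds, [0, 1, 2, 0, 1, 2])
    with pytest.raises(NormalizationError, match="smaller k"):
        injection_order_folds(np.array([1, 2]), 5)


def test_tune_hyperparameters_single_point_and_ordering():
    t = qc_table(n_qc=15, n_study=30, seed=4)
    hp = HyperParams(d_prime=4, batch_size=4, seed=0, max_epochs=120)
    best, scores = tune_hyperparameters(t, grid=[hp], k=3)
    assert best == hp
    assert len(scores) == 1 and scores[0]["cv_median_rsd"] > 0

    grid = [
        HyperParams(d_prime=4, batch_size=4, seed=0, max_epochs=120),
        HyperParams(d_prime=8, batch_size=4, seed=0, max_epochs=120),
    ]
    best2, scores2 = tune_hyperparameters(t, grid=grid, k=3)
    assert best2 == min(
        scores2, key=lambda s: (s["cv_median_rsd"], s["hyperparams"].d_prime)
    )["hyperparams"]


def test_hyperparams_validation():
    with pytest.raises(NormalizationError):
        HyperParams(d_prime=0)
    with pytest.raises(NormalizationError):
        HyperParams(nu=1.0)
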