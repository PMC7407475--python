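import numpy as np
import pytest

from scopesim import (
    GEBVTable,
    PredictionModel,
    TrainingPanel,
    fit_rrblup,
    maf_filter,
    predict_gebv,
    tails_select,
    tails_update,
)


def make_tp(Z, y, capacity=None, cycles=None):
    n = len(y)
    return TrainingPanel(
        genotypes=np.asarray(Z, dtype=float),
        phenotypes=np.asarray(y, dtype=float),
        cycle_added=np.zeros(n, dtype=int) if cycles is None else np.asarray(cycles),
        capacity=capacity or n,
    )


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------


def test_maf_counting_and_boundary():
    Z = np.array([[1], [1], [1], [-1]])
    assert list(maf_filter(Z, 0.03)) == [0]  # MAF 0.25 retained
    mono = np.ones((10, 1))
    assert maf_filter(mono, 0.03).size == 0  # MAF 0 removed
    # 100 inbreds, 3 minor homozygotes -> MAF exactly 0.03, retained
    Z = np.full((100, 1), 1.0)
    Z[:3] = -1.0
    assert list(maf_filter(Z, 0.03)) == [0]
    # just below the threshold is removed
    Z2 = np.full((100, 1), 1.0)
    Z2[:2] = -1.0
    assert maf_filter(Z2, 0.03).size == 0


def test_heterozygotes_contribute_one_allele_each():
    Z = np.array([[0], [1], [1], [1], [1]])  # p = 9/10, MAF 0.1
    assert list(maf_filter(Z, 0.1)) == [0]
    assert maf_filter(Z, 0.11).size == 0


# ---------------------------------------------------------------------------
# REML / RR-BLUP
# ---------------------------------------------------------------------------


def test_noiseless_single_marker_recovered(rng):
    z = rng.choice([-1.0, 1.0], size=40)[:, None]
    y = 2.5 * z[:, 0]
    model = fit_rrblup(make_tp(z, y), maf_threshold=0.0)
    pred = predict_gebv(z, model)
    assert np.allclose(pred.values, y, atol=1e-3)
    assert model.sigma_e2 < 1e-3 * model.sigma_u2 * (z[:, 0] ** 2).mean() * 40


def test_kernel_and_marker_routes_agree(rng):
    """GEBVs from u_hat = Z'(K + dI)^-1 r equal the kernel-route prediction."""
    n, k = 10, 15
    Z = rng.choice([-1.0, 0.0, 1.0], size=(n, k))
    y = rng.normal(size=n) + Z @ rng.normal(scale=0.3, size=k)
    model = fit_rrblup(make_tp(Z, y), maf_threshold=0.0)
    delta = model.sigma_e2 / model.sigma_u2

    Zr = Z[:, model.retained_markers]
    K = Zr @ Zr.T
    Znew = rng.choice([-1.0, 0.0, 1.0], size=(6, k))
    resid = y - model.beta
    kernel_pred = model.beta + Znew[:, model.retained_markers] @ Zr.T @ np.linalg.solve(
        K + delta * np.eye(n), resid
    )
    marker_pred = predict_gebv(Znew, model).values
    assert np.allclose(kernel_pred, marker_pred, atol=1e-8)


def test_reml_recovers_genomic_heritability(rng):
    """Mean REML heritability over replicate panels is unbiased within MC error."""
    n, k, h2 = 300, 200, 0.5
    estimates = []
    for _ in range(8):
        Z = rng.choice([-1.0, 1.0], size=(n, k))
        kbar = np.mean(np.sum(Z**2, axis=1))  # = k for inbred codes
        sigma_u2 = 1.0 / kbar
        sigma_e2 = (1 - h2) / h2  # gives genomic h2 = 0.5
        u = rng.normal(scale=np.sqrt(sigma_u2), size=k)
        y = 1.0 + Z @ u + rng.normal(scale=np.sqrt(sigma_e2), size=n)
        m = fit_rrblup(make_tp(Z, y), maf_threshold=0.0)
        estimates.append(m.sigma_u2 * kbar / (m.sigma_u2 * kbar + m.sigma_e2))
    est = np.asarray(estimates)
    se = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - h2) < max(3 * se, 0.05)


def test_gebv_invariant_to_marker_order(rng):
    n, k = 30, 12
    Z = rng.choice([-1.0, 1.0], size=(n, k))
    y = rng.normal(size=n)
    perm = rng.permutation(k)
    m1 = fit_rrblup(make_tp(Z, y), maf_threshold=0.0)
    m2 = fit_rrblup(make_tp(Z[:, perm], y), maf_threshold=0.0)
    Znew = rng.choice([-1.0, 1.0], size=(5, k))
    assert np.allclose(
        predict_gebv(Znew, m1).values, predict_gebv(Znew[:, perm], m2).values, atol=1e-6
    )


def test_degenerate_panels_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        fit_rrblup(make_tp(np.array([[1.0], [-1.0]]), [3.0, 3.0]))
    with pytest.raises(ValueError, match="retained"):
        fit_rrblup(make_tp(np.ones((5, 2)), np.arange(5.0)))


# ---------------------------------------------------------------------------
# GEBV computation
# ---------------------------------------------------------------------------


def test_predict_gebv_dot_product():
    model = PredictionModel(
        beta=0.0,
        u_hat=np.array([0.5, -0.2]),
        retained_markers=np.array([0, 1]),
        sigma_u2=1.0,
        sigma_e2=1.0,
        n_markers_total=2,
    )
    vals = predict_gebv(np.array([[1.0, -1.0], [0.0, 0.0], [1.0, -1.0]]), model).values
    assert vals[0] == pytest.approx(0.7)
    assert vals[1] == pytest.approx(0.0)  # all-heterozygous genotype
    assert vals[2] == vals[0]  # duplicated individual


# ---------------------------------------------------------------------------
# Tails update
# ---------------------------------------------------------------------------


def test_tails_select_order_statistics():
    gebvs = GEBVTable(list(range(1000)), np.arange(1.0, 1001.0))
    chosen = tails_select(gebvs, 150)
    values = np.sort(np.arange(1.0, 1001.0)[chosen])
    assert np.array_equal(values[:75], np.arange(1.0, 76.0))
    assert np.array_equal(values[75:], np.arange(926.0, 1001.0))

    small = GEBVTable(list(range(10)), np.arange(10.0))
    assert set(tails_select(small, 10)) == set(range(10))
    with pytest.raises(ValueError):
        tails_select(small, 12)


def test_tails_update_keeps_capacity_and_evicts_oldest(rng):
    cap, k, n_new = 764, 5, 150
    tp = make_tp(
        rng.choice([-1.0, 1.0], size=(cap, k)),
        rng.normal(size=cap),
        capacity=cap,
        cycles=np.zeros(cap, dtype=int),
    )
    marker0 = tp.genotypes[n_new, 0]
    pop_Z = rng.choice([-1.0, 1.0], size=(1000, k))
    gebvs = GEBVTable(list(range(1000)), rng.normal(size=1000))
    tp1 = tails_update(tp, pop_Z, gebvs, lambda idx: np.zeros(len(idx)), cycle=1, n_new=n_new)
    assert len(tp1) == cap
    assert (tp1.cycle_added == 1).sum() == n_new
    assert (tp1.cycle_added == 0).sum() == cap - n_new
    assert tp1.genotypes[0, 0] == marker0  # oldest 150 records gone

    tp2 = tails_update(tp1, pop_Z, gebvs, lambda idx: np.ones(len(idx)), cycle=2, n_new=n_new)
    assert len(tp2) == cap
    assert (tp2.cycle_added == 0).sum() == cap - 2 * n_new
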