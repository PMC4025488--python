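import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbsdiv import (
    GenotypeMatrix,
    bin_estimates,
    impute,
    impute_nipals,
    impute_ppca,
    impute_rf,
)
from gbsdiv.impute import ImputationNumericError
from gbsdiv.io import MISSING
from .conftest import random_matrix


def _matrix(codes):
    codes = np.asarray(codes, dtype=np.int8)
    n, p = codes.shape
    return GenotypeMatrix([f"l{i}" for i in range(n)], [f"m{j}" for j in range(p)], codes)


# ---------------------------------------------------------------------- binning

@pytest.mark.parametrize(
    "value,code",
    [(1.5, 1), (1.51, 2), (2.5, 2), (2.51, 3), (-0.4, 1), (3.7, 3), (2.0, 2)],
)
def test_bin_thresholds(value, code):
    """Thresholds are closed on the left genotype: ≤1.5 → 1, ≤2.5 → 2, else 3."""
    assert bin_estimates(value)[0] == code


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(allow_nan=False, allow_infinity=False, width=32))
def test_bin_total_and_idempotent(v):
    c = bin_estimates(float(v))
    assert c[0] in (1, 2, 3)
    assert bin_estimates(c.astype(float))[0] == c[0]


def test_bin_nonfinite_error():
    with pytest.raises(ImputationNumericError, match="position 1"):
        bin_estimates(np.array([1.0, np.nan]))


# ------------------------------------------------------------------- PCA-based

def _low_rank_codes(rng, n, p, k):
    """Codes whose rows come from k prototype rows (exact rank ≤ k + mean)."""
    protos = rng.integers(1, 4, size=(k, p)).astype(np.int8)
    assign = rng.integers(0, k, size=n)
    return protos[assign]


@pytest.mark.parametrize("method", ["pp", "ni"])
def test_complete_matrix_matches_truncated_svd(method):
    """With no missing cells both PCA imputers reproduce the rank-k SVD reconstruction."""
    rng = np.random.default_rng(0)
    k = 2
    Z = rng.standard_normal((30, k))
    W = rng.standard_normal((k, 20))
    X = Z @ W + 0.05 * rng.standard_normal((30, 20))
    codes = np.clip(np.rint(2 + X / np.abs(X).max()), 1, 3).astype(np.int8)
    g = _matrix(codes)
    if method == "pp":
        res = impute_ppca(g, n_pcs=k, tol=1e-13, max_iter=20000, rng=np.random.default_rng(1))
    else:
        res = impute_nipals(g, n_pcs=k, tol=1e-13, max_iter=20000)
    Xf = codes.astype(float)
    mu = Xf.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xf - mu, full_matrices=False)
    svd_recon = (U[:, :k] * s[:k]) @ Vt[:k] + mu
    assert np.abs(res.reconstruction - svd_recon).max() < 1e-6


@pytest.mark.parametrize("method", ["pp", "ni"])
def test_rank1_completion(method):
    """An exactly rank-1 numeric matrix with one masked cell is recovered to 1e-4."""
    rng = np.random.default_rng(2)
    proto = rng.integers(1, 4, size=8).astype(np.int8)
    codes = np.tile(proto, (10, 1))  # identical rows: uncentered rank 1
    true = codes[4, 3]
    codes[4, 3] = MISSING
    g = _matrix(codes)
    if method == "pp":
        res = impute_ppca(g, n_pcs=1, tol=1e-12, max_iter=10000, rng=np.random.default_rng(3))
    else:
        res = impute_nipals(g, n_pcs=1, tol=1e-12, max_iter=10000)
    cell = res.reconstruction[4, 3]
    assert abs(cell - true) < 1e-4
    assert res.imputed.codes[4, 3] == true


@pytest.mark.parametrize("method", ["pp", "ni"])
def test_constant_column_imputes_constant(method):
    codes = np.array([[2, 1], [2, 3], [2, 1], [0, 2]], dtype=np.int8)  # col 0 constant, 1 masked
    g = _matrix(codes)
    res = impute_ppca(g, n_pcs=1) if method == "pp" else impute_nipals(g, n_pcs=1)
    assert res.imputed.codes[3, 0] == 2


def test_nipals_zero_components_is_mean_imputation():
    codes = np.array([[1, 3], [3, 3], [0, 1]], dtype=np.int8)
    res = impute_nipals(_matrix(codes), n_pcs=0)
    assert res.reconstruction[2, 0] == pytest.approx(2.0)  # mean of (1, 3)
    assert res.imputed.codes[2, 0] == 2


@pytest.mark.parametrize("method", ["pp", "ni"])
def test_low_rank_recovery_rate(method):
    """Rank-2 structured data, 30% masked: ≥95% of masked genotypes recovered."""
    rng = np.random.default_rng(4)
    codes = _low_rank_codes(rng, 40, 30, 2)
    masked = codes.copy()
    mask = rng.random(codes.shape) < 0.3
    masked[mask] = MISSING
    g = _matrix(masked)
    res = (
        impute_ppca(g, n_pcs=2, tol=1e-10, max_iter=5000, rng=np.random.default_rng(5))
        if method == "pp"
        else impute_nipals(g, n_pcs=2, tol=1e-10, max_iter=5000)
    )
    rec = res.imputed.codes[mask] == codes[mask]
    assert rec.mean() >= 0.95


# --------------------------------------------------------------- random forest

def test_rf_perfect_predictor():
    """A marker that copies another is recovered exactly from the copy."""
    rng = np.random.default_rng(6)
    a = rng.integers(1, 4, size=40).astype(np.int8)
    codes = np.column_stack([a, a, rng.integers(1, 4, size=(40, 3)).astype(np.int8)])
    true = codes[7, 1]
    codes[7, 1] = MISSING
    res = impute_rf(_matrix(codes), n_trees=60, rng=np.random.default_rng(7))
    assert res.imputed.codes[7, 1] == true


def test_rf_independent_noise_predicts_near_column_mean():
    """With no signal the forest regresses to the column mean → modal genotype."""
    rng = np.random.default_rng(8)
    n = 60
    codes = rng.choice([1, 1, 1, 3], size=(n, 6)).astype(np.int8)  # 75% majority code 1
    target_col_mean = codes[:, 0].astype(float).mean()
    codes2 = codes.copy()
    codes2[0, 0] = MISSING
    res = impute_rf(_matrix(codes2), n_trees=60, rng=np.random.default_rng(9))
    assert abs(res.continuous[0] - target_col_mean) < 0.5
    assert res.imputed.codes[0, 0] == 1  # modal genotype after binning


def test_rf_no_missing_is_identity(tiny_matrix):
    complete = tiny_matrix.copy()
    complete.codes[complete.codes == MISSING] = 1
    res = impute_rf(complete, n_trees=10, rng=np.random.default_rng(10))
    assert res.imputed.equals(complete)
    assert len(res.continuous) == 0


# ------------------------------------------------------------------ invariants

@pytest.mark.parametrize("method", ["PP", "NI", "RF"])
def test_observed_cells_invariant_and_complete(method):
    g = random_matrix(np.random.default_rng(11), 25, 15, missing=0.25)
    params = {"n_trees": 20} if method == "RF" else {"n_pcs": 2}
    res = impute(g, method, rng=np.random.default_rng(12), **params)
    obs = ~g.missing_mask
    assert np.array_equal(res.imputed.codes[obs], g.codes[obs])
    assert not res.imputed.missing_mask.any()


@pytest.mark.parametrize("method", ["PP", "NI", "RF"])
def test_deterministic_given_seed(method):
    g = random_matrix(np.random.default_rng(13), 20, 12, missing=0.2)
    params = {"n_trees": 15} if method == "RF" else {"n_pcs": 2}
    r1 = impute(g, method, rng=np.random.default_rng(99), **params)
    r2 = impute(g, method, rng=np.random.default_rng(99), **params)
    assert r1.imputed.equals(r2.imputed)
    assert np.array_equal(r1.continuous, r2.continuous)


def test_fully_missing_marker_reported():
    codes = np.array([[1, 0], [2, 0], [3, 0]], dtype=np.int8)
    res = impute_nipals(_matrix(codes), n_pcs=1)
    assert any("no observed" in reason for _, _, reason in res.unimputed)
    assert (res.imputed.codes[:, 1] == MISSING).all()
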