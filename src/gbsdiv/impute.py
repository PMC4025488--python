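"""Map-independent genotype imputation: random forest, probabilistic PCA, NIPALS.

All three methods operate directly on the 1/2/3 numeric code scale and share
one binning rule for converting continuous estimates back to genotypes:
estimate ≤ 1.5 → homozygote 1, 1.5 < estimate ≤ 2.5 → heterozygote 2,
estimate > 2.5 → homozygote 3.  Continuous estimates may fall outside
[1, 3]; the open tails absorb them.  Observed cells are never altered.

The PCA-based imputers treat lines as observations and markers as variables,
centering each marker on its observed-cell mean.  PPCA fits the
Tipping–Bishop latent-variable model by EM, with missing cells refreshed
from the current low-rank reconstruction each sweep; the final readout
projects each (filled) line onto the converged principal subspace by least
squares, so on a complete matrix the reconstruction equals the truncated
singular-value reconstruction.  NIPALS extracts one component at a time by
alternating regressions whose sums run over observed cells only — missing
cells are excluded, never filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationResult",
    "bin_estimates",
    "impute_ppca",
    "impute_nipals",
    "impute_rf",
    "impute",
]


class ImputationNumericError(ValueError):
    """A continuous estimate was non-finite."""


@dataclass
class ImputationResult:
    """Outcome of imputing the missing cells of a genotype matrix.

    ``line_idx``/``marker_idx``/``continuous`` are parallel arrays covering
    the input's missing cells for which an estimate was produced;
    ``unimputed`` lists (line index, marker index, reason) for cells left
    missing in documented degenerate cases.
    """

    imputed: GenotypeMatrix
    line_idx: np.ndarray
    marker_idx: np.ndarray
    continuous: np.ndarray
    method: str
    params: dict[str, Any] = field(default_factory=dict)
    convergence: dict[str, Any] = field(default_factory=dict)
    unimputed: list[tuple[int, int, str]] = field(default_factory=list)
    #: full continuous model reconstruction (lines × markers); None for NONE
    reconstruction: np.ndarray | None = None


def bin_estimates(values: np.ndarray | float) -> np.ndarray:
    """Bin continuous estimates into genotype codes via thresholds 1.5 and 2.5.

    Total on finite reals and idempotent on {1, 2, 3}.  Raises
    :class:`ImputationNumericError` naming the offending position on a
    non-finite value.
    """
    v = np.atleast_1d(np.asarray(values, dtype=float))
    bad = ~np.isfinite(v)
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ImputationNumericError(f"non-finite estimate {v.flat[pos]} at position {pos}")
    codes = np.full(v.shape, 2, dtype=np.int8)
    codes[v <= 1.5] = 1
    codes[v > 2.5] = 3
    return codes


def _prepare(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int, str]]]:
    """Numeric matrix, missing mask, observed-column means, dead-column flags."""
    X = g.codes.astype(float)
    miss = g.missing_mask
    X[miss] = np.nan
    obs_count = (~miss).sum(axis=0)
    dead_cols = obs_count == 0
    unimputed: list[tuple[int, int, str]] = []
    for j in np.flatnonzero(dead_cols):
        for i in np.flatnonzero(miss[:, j]):
            unimputed.append((int(i), int(j), "marker has no observed genotypes"))
    sums = np.where(miss, 0.0, X).sum(axis=0)
    mu = np.where(dead_cols, 0.0, sums / np.maximum(obs_count, 1))
    return X, miss, mu, dead_cols, unimputed


def _finalize(
    g: GenotypeMatrix,
    recon: np.ndarray,
    miss: np.ndarray,
    method: str,
    params: dict[str, Any],
    convergence: dict[str, Any],
    unimputed: list[tuple[int, int, str]],
) -> ImputationResult:
    """Bin reconstruction at estimable missing cells; observed cells untouched."""
    skip = np.zeros_like(miss)
    for i, j, _ in unimputed:
        skip[i, j] = True
    target = miss & ~skip
    li, mj = np.nonzero(target)
    cont = recon[li, mj]
    bad = ~np.isfinite(cont)
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise ImputationNumericError(
            f"{method}: non-finite estimate at line {g.line_ids[li[k]]!r}, "
            f"marker {g.marker_ids[mj[k]]!r}"
        )
    out = g.copy()
    if len(cont):
        out.codes[li, mj] = bin_estimates(cont)
    return ImputationResult(out, li, mj, cont, method, params, convergence, unimputed,
                            reconstruction=recon)


# ---------------------------------------------------------------------------
# probabilistic PCA


def impute_ppca(
    g: GenotypeMatrix,
    n_pcs: int = 2,
    tol: float = 1e-5,
    max_iter: int = 1000,
    rng: np.random.Generator | None = None,
) -> ImputationResult:
    """EM for probabilistic PCA with missing cells treated as latent.

    Each iteration computes expected scores and their second moments from
    the current fill, updates loadings and the isotropic noise variance, and
    refreshes missing cells from the reconstruction; stops when the relative
    change of the observed-cell reconstruction error falls below ``tol``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n, p = g.codes.shape
    if not (0 < n_pcs < min(n, p)):
        raise ValueError(f"n_pcs must be in (0, min(lines, markers)); got {n_pcs}")
    X, miss, mu, dead, unimputed = _prepare(g)
    obs = ~miss
    Xc = X - mu
    Xc[miss] = 0.0  # initial fill: observed column means

    W = rng.standard_normal((p, n_pcs)) * 0.01
    sigma2 = 1.0
    prev_err = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step on the current filled matrix
        M = W.T @ W + sigma2 * np.eye(n_pcs)
        Minv = np.linalg.inv(M)
        Z = Xc @ W @ Minv.T                       # n × k expected scores
        ZZ = n * sigma2 * Minv + Z.T @ Z          # Σ ⟨z zᵀ⟩
        # M-step (pinv guards rank-deficient ZZ, e.g. a zero-variance matrix)
        W = (Xc.T @ Z) @ np.linalg.pinv(ZZ)
        recon = Z @ W.T
        resid2 = float(((Xc - recon) ** 2).sum())
        sigma2 = max(resid2 / (n * p), 1e-12)
        # refresh latent (missing) cells from the reconstruction
        Xc[miss] = recon[miss]
        err = float(((X - mu - recon)[obs] ** 2).sum())
        denom = max(prev_err, 1e-300)
        if it > 1 and abs(prev_err - err) / denom < tol:
            prev_err = err
            converged = True
            break
        prev_err = err
    if not converged:
        logger.warning("ppca: no convergence in %d iterations (Δerr ratio > %g)", max_iter, tol)

    # least-squares readout on the converged subspace: scores · loadingsᵀ + means
    Z_ls = (np.linalg.pinv(W.T @ W) @ (W.T @ Xc.T)).T
    recon_full = Z_ls @ W.T + mu

    conv = {"iterations": it, "converged": converged, "sigma2": sigma2, "final_obs_sse": prev_err}
    params = {"n_pcs": n_pcs, "tol": tol, "max_iter": max_iter}
    return _finalize(g, recon_full, miss, "PP", params, conv, unimputed)


# ---------------------------------------------------------------------------
# NIPALS


def impute_nipals(
    g: GenotypeMatrix,
    n_pcs: int = 2,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> ImputationResult:
    """Sequential principal components by NIPALS, sums over observed cells only."""
    n, p = g.codes.shape
    if not (0 <= n_pcs < min(n, p)):
        raise ValueError(f"n_pcs must be in [0, min(lines, markers)); got {n_pcs}")
    X, miss, mu, dead, unimputed = _prepare(g)
    obs = ~miss
    R = X - mu
    R[miss] = 0.0           # excluded from sums via the obs mask, 0 keeps algebra simple
    O = obs.astype(float)

    dead_lines = np.flatnonzero(obs.sum(axis=1) == 0)
    for i in dead_lines:
        for j in np.flatnonzero(miss[i]):
            if not dead[j]:
                unimputed.append((int(i), int(j), "line has no observed genotypes"))

    recon = np.broadcast_to(mu, (n, p)).copy()
    iters: list[int] = []
    for _ in range(n_pcs):
        # start from the column with the largest observed sum of squares
        j0 = int(np.argmax((R * R).sum(axis=0)))
        t = R[:, j0].copy()
        if not np.any(t):
            break  # residual exhausted
        for inner in range(1, max_iter + 1):
            denom_p = (t * t) @ O                      # Σ_obs t_i² per column
            pvec = (t @ R) / np.where(denom_p > 0, denom_p, 1.0)
            norm = np.linalg.norm(pvec)
            if norm == 0:
                break
            pvec /= norm
            denom_t = O @ (pvec * pvec)                # Σ_obs p_j² per line
            t_new = (R @ pvec) / np.where(denom_t > 0, denom_t, 1.0)
            t_new[denom_t == 0] = 0.0
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if delta < tol:
                break
        iters.append(inner)
        recon = recon + np.outer(t, pvec)
        R = R - np.outer(t, pvec)
        R[miss] = 0.0

    conv = {"iterations_per_component": iters, "converged": all(i < max_iter for i in iters)}
    params = {"n_pcs": n_pcs, "tol": tol, "max_iter": max_iter}
    return _finalize(g, recon, miss, "NI", params, conv, unimputed)


# ---------------------------------------------------------------------------
# random forest


def impute_rf(
    g: GenotypeMatrix,
    n_trees: int = 100,
    mtry: int | None = None,
    n_iter: int = 1,
    rng: np.random.Generator | None = None,
) -> ImputationResult:
    """Marker-by-marker random-forest regression on all other markers.

    Missing cells start at observed column means; each sweep refits a
    regressor per masked marker (that marker's observed codes as response,
    the current-filled remaining markers as predictors) and overwrites the
    masked cells with the predictions.
    """
    from sklearn.ensemble import RandomForestRegressor

    if rng is None:
        rng = np.random.default_rng(0)
    n, p = g.codes.shape
    if p < 2:
        raise ValueError("random-forest imputation needs at least 2 markers")
    X, miss, mu, dead, unimputed = _prepare(g)
    obs = ~miss
    live = np.flatnonzero(~dead)
    filled = np.where(miss, mu, X)
    filled[:, np.flatnonzero(dead)] = 0.0

    mtry_eff = mtry if mtry is not None else int(np.ceil((len(live) - 1) / 3))
    mtry_eff = max(1, min(mtry_eff, len(live) - 1))

    targets = [j for j in live if miss[:, j].any()]
    last = filled
    for _ in range(max(1, n_iter)):
        new_vals: dict[int, np.ndarray] = {}
        for j in targets:
            feat = live[live != j]
            train = obs[:, j]
            model = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=mtry_eff,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            model.fit(last[np.ix_(train, feat)], X[train, j])
            new_vals[j] = model.predict(last[np.ix_(miss[:, j], feat)])
        nxt = last.copy()
        for j, vals in new_vals.items():
            nxt[miss[:, j], j] = vals
        last = nxt

    conv = {"sweeps": max(1, n_iter), "targets": len(targets)}
    params = {"n_trees": n_trees, "mtry": mtry_eff, "n_iter": n_iter}
    return _finalize(g, last, miss, "RF", params, conv, unimputed)


def impute(
    g: GenotypeMatrix,
    method: str,
    rng: np.random.Generator | None = None,
    **params: Any,
) -> ImputationResult:
    """Dispatch by method name: "RF", "PP", "NI", or "NONE" (no-op)."""
    method = method.upper()
    if method == "NONE":
        empty = np.empty(0, dtype=int)
        return ImputationResult(g.copy(), empty, empty, np.empty(0), "NONE")
    if method in ("PP", "PPCA"):
        return impute_ppca(g, rng=rng, **params)
    if method in ("NI", "NIPALS"):
        return impute_nipals(g, **params)
    if method == "RF":
        return impute_rf(g, rng=rng, **params)
    raise ValueError(f"unknown imputation method {method!r}")
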