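"""Permutation tests for the RDA: global model, per-term, per-axis.

All three tests use the pseudo-F statistic and the add-one permutation
p-value p = (1 + #{F* >= F_obs}) / (n_perm + 1), which is never zero and
is bounded below by 1/(n_perm + 1).

Permutation schemes
-------------------
global  : whole rows of X permuted against Y.
terms   : marginal test per predictor — Y and the focal predictor are
          residualized on the remaining predictors, and the residualized
          predictor's rows are permuted (each term is tested given all
          others, so the result is order-invariant).
axes    : sequential — axis k is tested after partialling the leading
          k - 1 constrained axes out of both Y and X; reporting stops at
          the first axis whose p exceeds alpha, since later nested axes
          cannot be interpreted once an earlier one fails.

An optional ``strata`` vector restricts global permutations to within
groups (e.g. populations) when samples are only exchangeable locally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rda import _as_matrices, center, standardize


@dataclass
class PermutationResult:
    """One permutation test: target is 'global', 'term:<name>' or 'axis:<k>'."""

    target: str
    observed_F: float
    n_perm: int
    p_value: float
    seed: int
    df_model: int = 0
    df_resid: int = 0


def _prepare(Y, X) -> tuple[np.ndarray, np.ndarray, list[str]]:
    Ym, Xm, _, _, names = _as_matrices(Y, X)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("Y and X row counts differ")
    return center(Ym), standardize(Xm, names), names


def _pvalue(f_obs: float, f_perm: np.ndarray) -> float:
    return (1.0 + int(np.sum(f_perm >= f_obs - 1e-12))) / (len(f_perm) + 1.0)


def _check_nperm(n_perm: int) -> None:
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")


def _permutations(rng: np.random.Generator, n: int, n_perm: int,
                  strata: np.ndarray | None) -> np.ndarray:
    """n_perm row permutations, optionally restricted within strata."""
    perms = np.empty((n_perm, n), dtype=np.intp)
    if strata is None:
        for i in range(n_perm):
            perms[i] = rng.permutation(n)
    else:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == g) for g in np.unique(strata)]
        base = np.arange(n)
        for i in range(n_perm):
            perm = base.copy()
            for idx in groups:
                perm[idx] = idx[rng.permutation(len(idx))]
            perms[i] = perm
    return perms


def test_global(Y, X, n_perm: int = 999, seed: int = 0,
                strata=None) -> PermutationResult:
    """Permutation test of the whole constrained model.

    Rows of X are permuted as units; F is recomputed per permutation.
    Permuting the orthonormal basis Q of X row-wise is equivalent to
    permuting X itself (QR commutes with row permutation), which keeps
    the per-permutation cost at one small matrix product.
    """
    _check_nperm(n_perm)
    Yc, Xs, _ = _prepare(Y, X)
    n, p = Xs.shape
    if n <= p + 1:
        raise ValueError("no residual degrees of freedom")
    Q, _ = np.linalg.qr(Xs)
    total = float(np.sum(Yc**2))

    def f_of(Qrows: np.ndarray) -> float:
        fitted = float(np.sum((Qrows.T @ Yc) ** 2))
        return (fitted / p) / ((total - fitted) / (n - p - 1))

    f_obs = f_of(Q)
    rng = np.random.default_rng(seed)
    perms = _permutations(rng, n, n_perm, strata)
    f_perm = np.array([f_of(Q[perm]) for perm in perms])
    return PermutationResult("global", f_obs, n_perm,
                             _pvalue(f_obs, f_perm), seed, p, n - p - 1)


def test_terms(Y, X, n_perm: int = 999, seed: int = 0) -> list[PermutationResult]:
    """Marginal permutation test of each predictor given all others.

    For term j, both Y and predictor j are residualized on the other
    predictors; the unique constrained inertia of the residualized
    predictor is compared against permutations of its rows.
    """
    _check_nperm(n_perm)
    Yc, Xs, names = _prepare(Y, X)
    n, p = Xs.shape
    if n <= p + 1:
        raise ValueError("no residual degrees of freedom")
    rng = np.random.default_rng(seed)
    results = []
    for j, name in enumerate(names):
        others = np.delete(Xs, j, axis=1)
        if others.shape[1]:
            Qo, _ = np.linalg.qr(others)
            Ry = Yc - Qo @ (Qo.T @ Yc)
            rx = Xs[:, j] - Qo @ (Qo.T @ Xs[:, j])
        else:
            Ry, rx = Yc, Xs[:, j].copy()
        norm = np.linalg.norm(rx)
        if norm < 1e-12:
            # predictor fully explained by the others: no unique signal
            results.append(PermutationResult(f"term:{name}", 0.0, n_perm,
                                             1.0, seed, 1, n - p - 1))
            continue
        q = rx / norm
        total_r = float(np.sum(Ry**2))

        def f_of(qvec: np.ndarray) -> float:
            added = float(np.sum((qvec @ Ry) ** 2))
            return added / ((total_r - added) / (n - p - 1))

        f_obs = f_of(q)
        f_perm = np.array([f_of(q[rng.permutation(n)]) for _ in range(n_perm)])
        results.append(PermutationResult(f"term:{name}", f_obs, n_perm,
                                         _pvalue(f_obs, f_perm), seed,
                                         1, n - p - 1))
    return results


def test_axes(Y, X, n_perm: int = 999, seed: int = 0, alpha: float = 0.01,
              max_axes: int | None = None) -> list[PermutationResult]:
    """Sequential (forward) permutation test of the constrained axes.

    Axis k is tested with axes 1..k-1 partialled out of Y and X; its
    statistic is the leading partial eigenvalue over the full-model
    residual mean square.  Testing stops after the first axis with
    p > alpha (that axis is still reported).
    """
    _check_nperm(n_perm)
    Yc, Xs, _ = _prepare(Y, X)
    n, p = Xs.shape
    if n <= p + 1:
        raise ValueError("no residual degrees of freedom")
    Q, _ = np.linalg.qr(Xs)
    C = Q.T @ Yc
    U, s, _ = np.linalg.svd(C, full_matrices=False)
    k_max = int(np.sum(s**2 > 1e-12 * max(float(s[0]) ** 2, 1e-300)))
    if max_axes is not None:
        k_max = min(k_max, max_axes)
    sample_lc = (Q @ U) * s  # LC site scores of all axes

    rng = np.random.default_rng(seed)
    results: list[PermutationResult] = []
    for k in range(k_max):
        if k == 0:
            Yr, Xr = Yc, Xs
        else:
            Z = sample_lc[:, :k]
            Qz, _ = np.linalg.qr(Z)
            Yr = Yc - Qz @ (Qz.T @ Yc)
            Xr = Xs - Qz @ (Qz.T @ Xs)
        Qx, Rx = np.linalg.qr(Xr)
        keep = np.abs(np.diag(Rx)) > 1e-10
        Qx = Qx[:, keep]
        total_r = float(np.sum(Yr**2))

        def f_of(Qrows: np.ndarray) -> float:
            Cp = Qrows.T @ Yr
            sv = np.linalg.svd(Cp, compute_uv=False)
            lam1 = float(sv[0]) ** 2
            fitted = float(np.sum(sv**2))
            return lam1 / ((total_r - fitted) / (n - p - 1))

        f_obs = f_of(Qx)
        f_perm = np.array(
            [f_of(Qx[rng.permutation(n)]) for _ in range(n_perm)])
        pval = _pvalue(f_obs, f_perm)
        results.append(PermutationResult(f"axis:{k + 1}", f_obs, n_perm,
                                         pval, seed, 1, n - p - 1))
        if pval > alpha:
            break
    return results


def significant_axes(results: list[PermutationResult],
                     alpha: float = 0.01) -> list[int]:
    """1-based indices of axes significant under the forward-stop rule."""
    out = []
    for r in results:
        if not r.target.startswith("axis:"):
            continue
        if r.p_value <= alpha:
            out.append(int(r.target.split(":")[1]))
        else:
            break
    return out
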