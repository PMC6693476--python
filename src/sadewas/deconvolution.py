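"""Reference-based leukocyte deconvolution from methylation.

Estimates per-sample proportions of six whole-blood cell types
(neutrophils, monocytes, B, CD4+, CD8+, NK) by projecting a sample's
betas at discriminating reference probes onto cell-type reference
profiles:

    min_w || beta_s - R w ||^2   subject to   w >= 0,  sum(w) = 1.

The default solver is an exact equality-constrained non-negative
least-squares: because the optimum of this convex program lies on a face
of the simplex, it enumerates candidate supports (k cell types give at
most 2^k - 1 faces), solves the equality-constrained normal equations on
each face via its KKT system, and keeps the feasible candidate with the
smallest objective.  This is deterministic and exact to solver tolerance;
for k > 12 an SLSQP fallback is used.  A truncate-and-renormalize variant
(unconstrained solve, negative weights clipped, then rescaled) is exposed
for comparison.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .core import MethylationMatrix, ValidationError

__all__ = ["estimate_cell_proportions", "solve_simplex_lsq",
           "select_reference_probes"]

_RANK_RTOL = 1e-8


def _face_solution(R: np.ndarray, b: np.ndarray,
                   support: tuple[int, ...]) -> np.ndarray | None:
    """Solve min ||R_S w - b||^2 s.t. sum(w)=1 on one support via KKT."""
    Rs = R[:, support]
    k = len(support)
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = Rs.T @ Rs
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([Rs.T @ b, [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        return None
    return sol[:k]


def solve_simplex_lsq(R: np.ndarray, b: np.ndarray,
                      tol: float = 1e-9) -> np.ndarray:
    """Exact simplex-constrained least squares for small k (see module doc)."""
    k = R.shape[1]
    if k > 12:
        return _solve_slsqp(R, b)
    best_w, best_obj = None, np.inf
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            w = _face_solution(R, b, support)
            if w is None or (w < -tol).any():
                continue
            full = np.zeros(k)
            full[list(support)] = np.clip(w, 0.0, None)
            full /= full.sum()
            obj = float(np.sum((R @ full - b) ** 2))
            if obj < best_obj - 1e-15:
                best_obj, best_w = obj, full
    if best_w is None:  # unreachable for full-rank R, guard anyway
        best_w = np.full(k, 1.0 / k)
    return best_w


def _solve_slsqp(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.optimize import minimize

    k = R.shape[1]
    RtR, Rtb = R.T @ R, R.T @ b

    def fun(w):
        return 0.5 * w @ RtR @ w - Rtb @ w

    def jac(w):
        return RtR @ w - Rtb

    res = minimize(fun, np.full(k, 1.0 / k), jac=jac, method="SLSQP",
                   bounds=[(0.0, 1.0)] * k,
                   constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1,
                                 "jac": lambda w: np.ones(k)}],
                   options={"ftol": 1e-14, "maxiter": 500})
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def estimate_cell_proportions(m: MethylationMatrix | pd.DataFrame,
                              reference: pd.DataFrame,
                              method: str = "constrained",
                              ) -> pd.DataFrame:
    """Estimate cell-type proportions for every sample.

    Parameters
    ----------
    m
        Methylation matrix (or samples x probes DataFrame); must contain
        the reference probes as columns.
    reference
        Reference beta profiles, probes x cell types.
    method
        ``"constrained"`` (default; equality-constrained NNLS on the
        simplex) or ``"truncate"`` (Houseman-style unconstrained solve,
        truncated at zero and renormalized).

    Returns
    -------
    DataFrame of proportions (samples x cell types), each row summing to
    one within solver tolerance.
    """
    beta = m.beta if isinstance(m, MethylationMatrix) else m
    missing = [p for p in reference.index if p not in beta.columns]
    if missing:
        raise ValidationError(
            f"reference probes absent from matrix: {missing[:5]}")
    R = reference.to_numpy(dtype=float)
    sv = np.linalg.svd(R, compute_uv=False)
    if sv[-1] < _RANK_RTOL * sv[0]:
        raise ValidationError(
            "reference matrix is rank deficient; supply more "
            "discriminating probes or remove collinear cell profiles")
    X = beta[list(reference.index)].to_numpy(dtype=float)
    out = np.empty((X.shape[0], R.shape[1]))
    for i in range(X.shape[0]):
        b = X[i]
        if method == "constrained":
            out[i] = solve_simplex_lsq(R, b)
        elif method == "truncate":
            w, *_ = np.linalg.lstsq(R, b, rcond=None)
            w = np.clip(w, 0.0, None)
            s = w.sum()
            out[i] = w / s if s > 0 else np.full(R.shape[1], 1 / R.shape[1])
        else:
            raise ValidationError(f"unknown method {method!r}")
    return pd.DataFrame(out, index=beta.index, columns=list(reference.columns))


def select_reference_probes(profiles: pd.DataFrame, n_per_type: int = 100,
                            ) -> list[str]:
    """Top discriminating probes per cell type from a whole reference panel.

    Ranks probes for each cell type by the one-vs-rest contrast
    |mean(type) - mean(others)| (the F-statistic of a two-group comparison
    of noiseless profiles is monotone in this contrast) and pools the top
    ``n_per_type`` per type.
    """
    chosen: list[str] = []
    vals = profiles.to_numpy(dtype=float)
    for k, ct in enumerate(profiles.columns):
        others = np.delete(vals, k, axis=1).mean(axis=1)
        contrast = np.abs(vals[:, k] - others)
        order = np.argsort(-contrast)[:n_per_type]
        chosen.extend(profiles.index[order])
    seen, out = set(), []
    for p in chosen:
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out
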