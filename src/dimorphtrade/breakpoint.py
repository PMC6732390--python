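"""Breakpoint inference: Davies test and iterative segmented regression.

The Davies test asks whether the slope of y on x changes at some unknown
point: at each candidate breakpoint k the hinge model
``y ~ x + (x - k)_+`` is fitted and the Wald statistic of the hinge term
recorded; the p-value is the Davies (1987) upper bound for the supremum of
that statistic process, using its total variation across the ordered
candidates. Segmented regression then estimates the breakpoint psi by the
Muggeo iteration, refitting ``y ~ x + U + V`` with ``U = (x - psi)_+`` and
``V = -1{x > psi}`` and updating ``psi <- psi + gamma/beta_U``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class DaviesResult:
    p_value: float
    best_candidate: float
    n_candidates: int
    statistics: np.ndarray  # signed Wald statistics along the candidate grid


@dataclass
class SegmentedFit:
    psi: float
    slope_left: float
    slope_right: float
    intercept: float
    psi_se: float
    converged: bool
    n_iter: int
    rss: float
    used_grid_fallback: bool = False


def _hinge_wald(x, y, k):
    """Signed Wald (t) statistic of the hinge term in y ~ x + (x - k)_+."""
    n = x.size
    X = np.column_stack([np.ones(n), x, np.maximum(x - k, 0.0)])
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        return 0.0
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if rss <= 1e-12 * max(tss, 1.0):  # (near-)perfect fit: noiseless input
        return 0.0 if abs(beta[2]) < 1e-8 else np.sign(beta[2]) * np.inf
    sigma2 = rss / (n - 3)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return float(beta[2] / np.sqrt(cov[2, 2]))


def davies_test(x, y, n_candidates: int = 10) -> DaviesResult:
    """Test for a change in slope at an unknown breakpoint.

    Candidates are evenly spaced between the 10th and 90th percentiles of
    `x`. The two-sided p-value is the Davies bound
    ``2 * (Phi(-M) + V * exp(-M^2/2) / sqrt(8*pi))`` capped at 1, with M the
    largest |statistic| and V the total variation of the signed statistic
    over the ordered candidates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 6:
        raise ValueError("need at least 6 paired observations")
    lo, hi = np.quantile(x, [0.10, 0.90])
    if hi <= lo or np.unique(x).size < 3:
        raise ValueError("insufficient spread in x for candidate breakpoints")
    candidates = np.linspace(lo, hi, n_candidates)
    statistics = np.array([_hinge_wald(x, y, k) for k in candidates])
    finite = statistics[np.isfinite(statistics)]
    if finite.size < statistics.size:  # perfect separation somewhere
        return DaviesResult(p_value=np.finfo(float).tiny,
                            best_candidate=float(candidates[np.argmax(np.abs(statistics))]),
                            n_candidates=n_candidates, statistics=statistics)
    M = float(np.max(np.abs(statistics)))
    V = float(np.sum(np.abs(np.diff(statistics))))
    p = 2.0 * (stats.norm.sf(M) + V * np.exp(-0.5 * M * M) / np.sqrt(8.0 * np.pi))
    return DaviesResult(p_value=float(min(1.0, max(p, np.finfo(float).tiny))),
                        best_candidate=float(candidates[int(np.argmax(np.abs(statistics)))]),
                        n_candidates=n_candidates, statistics=statistics)


def _hinge_fit(x, y, psi):
    """OLS of y ~ x + (x - psi)_+; returns (beta, rss)."""
    X = np.column_stack([np.ones(x.size), x, np.maximum(x - psi, 0.0)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _grid_fallback(x, y, n_grid: int = 400):
    xs = np.sort(np.unique(x))
    lo, hi = xs[0], xs[-1]
    eps = 1e-9 * (hi - lo)
    grid = np.linspace(lo + eps, hi - eps, n_grid)
    rss = np.array([_hinge_fit(x, y, g)[1] for g in grid])
    return float(grid[int(np.argmin(rss))])


def segmented_fit(x, y, psi0: float | None = None, tol: float = 1e-8,
                  max_iter: int = 100) -> SegmentedFit:
    """Estimate a single breakpoint by the Muggeo iteration.

    `psi0` defaults to the median of `x`. Iteration stops when the psi
    update falls below ``tol * range(x)``; psi is clamped strictly inside
    the data range at each step. If the hinge slope collapses toward zero
    (breakpoint unidentifiable by the update rule) a profiled-RSS grid
    search takes over. The breakpoint standard error is the delta-method
    ``SE(gamma)/|beta_U|``. Non-convergence returns the last iterate with
    ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 6:
        raise ValueError("need at least 6 paired observations")
    xmin, xmax = float(np.min(x)), float(np.max(x))
    rng_x = xmax - xmin
    if rng_x == 0:
        raise ValueError("x is constant")
    psi = float(np.median(x)) if psi0 is None else float(psi0)
    if not xmin < psi < xmax:
        raise ValueError("psi0 must lie strictly inside the range of x")
    eps = 1e-6 * rng_x

    used_grid = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = np.maximum(x - psi, 0.0)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones(x.size), x, U, V])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        b_u, gamma = beta[2], beta[3]
        if rank < 4 or abs(b_u) < 1e-10:
            psi = _grid_fallback(x, y)
            used_grid = True
            converged = True
            break
        step = gamma / b_u
        new_psi = float(np.clip(psi + step, xmin + eps, xmax - eps))
        if abs(new_psi - psi) < tol * rng_x:
            psi = new_psi
            converged = True
            break
        psi = new_psi

    # final hinge fit at the estimated breakpoint
    beta, rss = _hinge_fit(x, y, psi)
    intercept, b_x, b_u = beta

    # delta-method SE from the full (U, V) design at psi
    U = np.maximum(x - psi, 0.0)
    Vv = -(x > psi).astype(float)
    Xf = np.column_stack([np.ones(x.size), x, U, Vv])
    dof = x.size - 4
    resid = y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]
    rss_full = float(resid @ resid)
    psi_se = np.nan
    if dof > 0 and abs(b_u) > 1e-12:
        sigma2 = rss_full / dof
        XtX = Xf.T @ Xf
        try:
            cov = sigma2 * np.linalg.inv(XtX)
            psi_se = float(np.sqrt(max(cov[3, 3], 0.0)) / abs(b_u))
        except np.linalg.LinAlgError:
            pass

    return SegmentedFit(psi=float(psi), slope_left=float(b_x),
                        slope_right=float(b_x + b_u), intercept=float(intercept),
                        psi_se=psi_se, converged=converged, n_iter=it, rss=rss,
                        used_grid_fallback=used_grid)


def assign_groups_by_breakpoint(scores, psi: float) -> dict:
    """Assign species to trophic groups by the estimated breakpoint.

    `scores` maps species -> PC1 score (dict or pandas Series). Scores
    strictly above `psi` go to "above"; ties at psi go to "below".
    """
    if not np.isfinite(psi):
        raise ValueError("psi must be finite")
    items = scores.items()
    return {sp: ("above" if val > psi else "below") for sp, val in items}
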