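"""Statistical analysis: rank correlation, broken-line regression, ridgelines.

The study design treats each female as the experimental unit, so image-level
measurements are first averaged within females.  Monotone association of a
response with storage time is summarised by Spearman's rank correlation
(average ranks for ties).  The temporal trend itself is modelled by a
one-breakpoint segmented (broken-line) linear regression

    y = β₀ + β₁·x + β₂·(x − ψ)₊ + ε,

continuous at the unknown breakpoint ψ, estimated by Muggeo-style iterative
linearization: at the current ψ the model is augmented with the working
covariate V = −1{x > ψ}, refitted by OLS, and ψ updated by γ̂/β̂₂ until the
update is below tolerance.  Initialization takes the best SSE over a coarse
interior ψ grid, which makes the iteration robust to the profile's local
minima.  Slope confidence intervals are Wald intervals from the converged
working model; the right-segment slope is β₁+β₂ with variance
var β₁ + var β₂ + 2 cov.  Adjusted R² counts four estimated parameters
(β₀, β₁, β₂, ψ), i.e. n−4 residual degrees of freedom.

Distribution evolution across storage times is summarised by per-group
Gaussian kernel densities (Silverman bandwidth) on a shared grid — the data
behind a ridgeline plot — with modal values reported per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "SpearmanResult",
    "SegmentedFit",
    "DensitySummary",
    "per_female_means",
    "spearman",
    "fit_segmented",
    "breakpoint_sse_profile",
    "ridgeline_summary",
    "simple_ols",
]


def per_female_means(metrics_by_female: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Arithmetic mean of a per-comet metric within each female."""
    means = {}
    for female, values in metrics_by_female.items():
        values = np.asarray(list(values), float)
        if values.size == 0:
            raise ValueError(f"female {female!r} has no accepted comets")
        means[female] = float(values.mean())
    return means


@dataclass(frozen=True)
class SpearmanResult:
    r: float
    n: int
    p_value: float  # two-sided, t-approximation with n-2 df


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Tie-corrected Spearman correlation: average ranks, then Pearson."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant vector")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return SpearmanResult(r=r, n=n, p_value=p)


@dataclass
class SegmentedFit:
    """A fitted one-breakpoint broken-line regression."""

    intercept: float
    slope1: float  # left-segment slope
    slope_change: float  # β₂ = slope2 − slope1
    breakpoint: float
    slope2: float
    ci_slope1: tuple[float, float]
    ci_slope2: tuple[float, float]
    r_squared: float
    adj_r_squared: float
    sse: float
    residuals: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0
    psi_constrained: bool = False

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return self.intercept + self.slope1 * x + self.slope_change * np.maximum(x - self.breakpoint, 0.0)


def _ols_at_psi(x: np.ndarray, y: np.ndarray, psi: float):
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), resid


def breakpoint_sse_profile(
    x: Sequence[float], y: np.ndarray, psis: Sequence[float]
) -> np.ndarray:
    """Profile SSE of the broken-line model over candidate breakpoints.

    ``y`` may be a vector or an ``(n, m)`` matrix of m response replicates
    sharing the design ``x``; the result is then ``(len(psis), m)``.  This
    exhaustive profile is the reference against which the iterative
    estimator is validated.
    """
    x = np.asarray(x, float)
    Y = np.asarray(y, float)
    vector = Y.ndim == 1
    if vector:
        Y = Y[:, None]
    out = np.empty((len(psis), Y.shape[1]))
    for k, psi in enumerate(psis):
        X = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        out[k] = (resid * resid).sum(axis=0)
    return out[:, 0] if vector else out


def _iterate_breakpoint(x: np.ndarray, y: np.ndarray, psi: float, tol: float, max_iter: int):
    """Muggeo working-covariate iteration from one start; SSE-guarded steps."""
    xmin, xmax = float(x.min()), float(x.max())
    eps = 1e-6 * (xmax - xmin)
    constrained = False
    sse_cur = _ols_at_psi(x, y, psi)[1]
    for it in range(1, max_iter + 1):
        U = np.maximum(x - psi, 0.0)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        b2, gamma = beta[2], beta[3]
        if abs(b2) < 1e-12:
            return psi, sse_cur, it, constrained
        step = gamma / b2
        # accept only SSE-improving breakpoint updates, halving otherwise
        psi_new, sse_new = psi, sse_cur
        for _ in range(40):
            cand = psi + step
            if not xmin + eps <= cand <= xmax - eps:
                cand = float(np.clip(cand, xmin + eps, xmax - eps))
                constrained = True
            sse_cand = _ols_at_psi(x, y, cand)[1]
            if sse_cand <= sse_cur + 1e-12:
                psi_new, sse_new = cand, sse_cand
                break
            step /= 2.0
            if abs(step) < tol:
                break
        if abs(psi_new - psi) < tol:
            return psi_new, sse_new, it, constrained
        psi, sse_cur = psi_new, sse_new
    raise RuntimeError(f"no convergence in {max_iter} iterations (psi {psi:.4f})")


def fit_segmented(
    x: Sequence[float],
    y: Sequence[float],
    n_grid: int = 50,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SegmentedFit:
    """Fit y = β₀ + β₁x + β₂(x−ψ)₊ with ψ estimated by iterative linearization.

    Initialization: best SSE on an ``n_grid``-point ψ grid spanning the
    interior 10–90% quantiles of x.  Updates that would push ψ outside the
    observed x range are clamped (flagged via ``psi_constrained``).
    Raises ``RuntimeError`` carrying the best grid solution on
    non-convergence.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 6:
        raise ValueError("need equal-length x, y with n >= 6")
    if np.unique(x).size < 4:
        raise ValueError("too few distinct x values for a breakpoint model")

    grid = np.linspace(np.quantile(x, 0.10), np.quantile(x, 0.90), n_grid)
    grid_sse = breakpoint_sse_profile(x, y, grid)
    # the SSE profile in psi can hold nearly tied local minima in adjacent
    # inter-observation intervals; iterate from the few best grid starts and
    # keep the best converged solution
    starts = grid[np.argsort(grid_sse)[:3]]

    best_psi: float | None = None
    best_sse = np.inf
    constrained = False
    total_iter = 0
    last_err: RuntimeError | None = None
    for start in starts:
        try:
            psi_k, sse_k, it_k, con_k = _iterate_breakpoint(x, y, float(start), tol, max_iter)
        except RuntimeError as err:
            last_err = err
            continue
        total_iter += it_k
        constrained |= con_k
        if sse_k < best_sse:
            best_psi, best_sse = psi_k, sse_k
    if best_psi is None:
        raise RuntimeError(
            f"breakpoint iteration did not converge in {max_iter} steps from any start"
        ) from last_err
    psi = best_psi
    converged = True
    it = total_iter

    # Wald slope intervals from the full working model (with the breakpoint
    # working covariate V), which propagates psi uncertainty into the slope
    # covariance; the fitted curve itself uses the plain 3-parameter model
    U = np.maximum(x - psi, 0.0)
    V = -(x > psi).astype(float)
    working = sm.OLS(y, sm.add_constant(np.column_stack([x, U, V]))).fit()
    wcov = working.cov_params()
    se1 = float(np.sqrt(wcov[1, 1]))
    se2 = float(np.sqrt(wcov[1, 1] + wcov[2, 2] + 2.0 * wcov[1, 2]))
    model = sm.OLS(y, sm.add_constant(np.column_stack([x, U]))).fit()
    b0, b1, b2 = model.params
    n = x.size
    tcrit = sps.t.ppf(0.975, n - 4)
    slope2 = b1 + b2
    resid = np.asarray(model.resid)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 4)
    return SegmentedFit(
        intercept=float(b0),
        slope1=float(b1),
        slope_change=float(b2),
        breakpoint=float(psi),
        slope2=float(slope2),
        ci_slope1=(float(b1 - tcrit * se1), float(b1 + tcrit * se1)),
        ci_slope2=(float(slope2 - tcrit * se2), float(slope2 + tcrit * se2)),
        r_squared=float(r2),
        adj_r_squared=float(adj),
        sse=sse,
        residuals=resid,
        converged=converged,
        n_iter=it,
        psi_constrained=constrained,
    )


@dataclass
class DensitySummary:
    """Per-group kernel density on a shared grid, with modal values."""

    group: float
    grid: np.ndarray
    density: np.ndarray
    modes: list[float]


def ridgeline_summary(
    groups: Mapping[float, Sequence[float]],
    grid_points: int = 512,
    mode_floor: float = 0.10,
) -> list[DensitySummary]:
    """Gaussian KDE per group (Silverman bandwidth) on one shared grid.

    Modes are local density maxima above ``mode_floor`` times the global
    maximum across groups.  This is the numerical content of a ridgeline
    plot: stacked per-group densities on a common horizontal scale.
    """
    cleaned = {k: np.asarray(list(v), float) for k, v in groups.items()}
    for k, v in cleaned.items():
        if v.size < 2 or np.ptp(v) == 0:
            raise ValueError(f"group {k!r}: need >= 2 distinct values for a density")
    allv = np.concatenate(list(cleaned.values()))
    span = np.ptp(allv)
    lo, hi = allv.min() - 0.1 * span, allv.max() + 0.1 * span
    grid = np.linspace(lo, hi, grid_points)

    kdes = {k: sps.gaussian_kde(v, bw_method="silverman")(grid) for k, v in cleaned.items()}
    global_max = max(d.max() for d in kdes.values())
    out = []
    for k in sorted(cleaned):
        d = kdes[k]
        interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:]) & (d[1:-1] >= mode_floor * global_max)
        modes = [float(grid[i + 1]) for i in np.nonzero(interior)[0]]
        out.append(DensitySummary(group=float(k), grid=grid, density=d, modes=modes))
    return out


def simple_ols(x: Sequence[float], y: Sequence[float]):
    """Convenience single-line OLS fit (statsmodels results object)."""
    x = np.asarray(x, float)
    return sm.OLS(np.asarray(y, float), sm.add_constant(x)).fit()
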