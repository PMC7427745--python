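"""Multiple imputation of the home-monitoring feature matrix.

Missingness patterns are first checked for monotonicity. Monotone patterns
are imputed by sequential regression in the monotone column order; random
patterns by data augmentation — a Markov chain alternating draws of the
missing values given (mu, Sigma) and posterior draws of (mu, Sigma) given
the completed data, under a multivariate-normal working model with a
noninformative prior. Per-parameter bounds constrain the imputed values
(rejection redraw, then truncation) so that, e.g., lung-function values
cannot go negative. Estimates computed on the m completed data sets are
combined with Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ImputationError(ValueError):
    pass


@dataclass
class ImputedSet:
    """m completed copies of a feature matrix."""

    datasets: list[pd.DataFrame]
    seeds: list[int]
    pattern: str  # "monotone" | "random"

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass
class PooledEstimate:
    estimate: np.ndarray
    within_variance: np.ndarray
    between_variance: np.ndarray
    total_variance: np.ndarray
    df: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray


# ---------------------------------------------------------------------------
# Pattern analysis
# ---------------------------------------------------------------------------

def monotonicity_check(mask: np.ndarray) -> tuple[bool, np.ndarray]:
    """Whether a missingness mask (True = missing) is monotone.

    A pattern is monotone if the columns can be ordered so that, in every
    row, a missing column implies that all later columns are missing too.
    Columns are tried in order of increasing missing count (ties broken by
    index), which is sufficient: if any monotone order exists, this one is
    monotone as well. Returns (is_monotone, column order).
    """
    mask = np.asarray(mask, dtype=bool)
    order = np.lexsort((np.arange(mask.shape[1]), mask.sum(axis=0)))
    reordered = mask[:, order]
    # monotone iff every row's missing set is a suffix
    for row in reordered:
        miss = np.flatnonzero(row)
        if miss.size and not np.all(row[miss[0]:]):
            return False, order
    return True, order


# ---------------------------------------------------------------------------
# Posterior draws under the multivariate-normal working model
# ---------------------------------------------------------------------------

def _draw_mvn_params(data: np.ndarray, rng, ridge: float = 1e-6):
    """Posterior draw of (mu, Sigma) given complete data, Jeffreys prior."""
    n, p = data.shape
    xbar = data.mean(axis=0)
    centred = data - xbar
    scatter = centred.T @ centred + ridge * np.eye(p)
    sigma = stats.invwishart.rvs(df=max(n - 1, p + 1), scale=scatter, random_state=rng)
    sigma = np.atleast_2d(sigma)
    mu = rng.multivariate_normal(xbar, sigma / n, method="cholesky")
    return mu, sigma


def _conditional_draw(row, miss, mu, sigma, rng):
    """Draw missing entries of one row from the conditional normal."""
    obs = ~miss
    if not obs.any():
        cond_mu = mu[miss]
        cond_cov = sigma[np.ix_(miss, miss)]
    else:
        s_oo = sigma[np.ix_(obs, obs)]
        s_mo = sigma[np.ix_(miss, obs)]
        solve = np.linalg.solve(s_oo, (row[obs] - mu[obs]))
        cond_mu = mu[miss] + s_mo @ solve
        cond_cov = sigma[np.ix_(miss, miss)] - s_mo @ np.linalg.solve(s_oo, s_mo.T)
    cond_cov = 0.5 * (cond_cov + cond_cov.T) + 1e-10 * np.eye(miss.sum())
    return rng.multivariate_normal(cond_mu, cond_cov, method="cholesky")


def _apply_bounds(draw_fn, lo, hi, rng, max_attempts: int = 100):
    """Redraw until within bounds, then truncate as a last resort."""
    for _ in range(max_attempts):
        x = draw_fn()
        if np.all(x >= lo) and np.all(x <= hi):
            return x
    return np.clip(x, lo, hi)


def _bounds_arrays(columns, bounds) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([bounds.get(c, (-np.inf, np.inf))[0] for c in columns])
    hi = np.array([bounds.get(c, (-np.inf, np.inf))[1] for c in columns])
    return lo, hi


def _impute_mcmc(values, mask, lo, hi, rng, burn_in, thinning, m):
    """Data-augmentation chain; returns m completed matrices."""
    n, p = values.shape
    filled = values.copy()
    col_means = np.nanmean(values, axis=0)
    for j in range(p):
        filled[mask[:, j], j] = col_means[j]
    completed = []
    total = burn_in + m * thinning
    rows_with_missing = np.flatnonzero(mask.any(axis=1))
    for it in range(total):
        mu, sigma = _draw_mvn_params(filled, rng)
        for i in rows_with_missing:
            miss = mask[i]
            draw = _apply_bounds(
                lambda: _conditional_draw(filled[i], miss, mu, sigma, rng),
                lo[miss], hi[miss], rng)
            filled[i, miss] = draw
        if it >= burn_in and (it - burn_in + 1) % thinning == 0:
            completed.append(filled.copy())
    return completed[:m]


def _impute_monotone(values, mask, order, lo, hi, rng, m):
    """Sequential-regression imputation along the monotone column order.

    Column j is regressed on all earlier (fully observed for its missing
    rows) columns over the rows where it is observed; regression
    coefficients and the residual variance are drawn from their posterior
    before predicting the missing rows.
    """
    completed = []
    for _ in range(m):
        filled = values.copy()
        for pos, j in enumerate(order):
            miss = mask[:, j]
            if not miss.any():
                continue
            preds = order[:pos]
            obs = ~miss
            if obs.sum() < len(preds) + 2:
                raise ImputationError(f"too few observed rows to impute column {j}")
            X_obs = np.column_stack([np.ones(obs.sum())] +
                                    [filled[obs, k] for k in preds])
            y_obs = filled[obs, j]
            beta, res, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
            dof = max(obs.sum() - X_obs.shape[1], 1)
            rss = float(res[0]) if res.size else float(np.sum((y_obs - X_obs @ beta) ** 2))
            sigma2 = rss / stats.chi2.rvs(dof, random_state=rng)
            xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
            beta_draw = rng.multivariate_normal(beta, sigma2 * xtx_inv)
            X_mis = np.column_stack([np.ones(miss.sum())] +
                                    [filled[miss, k] for k in preds])
            mean = X_mis @ beta_draw
            for r, i in enumerate(np.flatnonzero(miss)):
                filled[i, j] = _apply_bounds(
                    lambda: np.array([mean[r] + rng.normal(0.0, np.sqrt(sigma2))]),
                    np.array([lo[j]]), np.array([hi[j]]), rng)[0]
        completed.append(filled)
    return completed


def impute(features: pd.DataFrame, m: int = 5, seed: int = 0,
           bounds: dict[str, tuple[float, float]] | None = None,
           burn_in: int = 200, thinning: int = 10,
           log_columns: tuple[str, ...] = ()) -> ImputedSet:
    """m completed copies of ``features`` (NaN = missing).

    The imputation branch (monotone sequential regression vs MCMC data
    augmentation) is chosen from the missingness pattern. Heavily skewed
    columns can be listed in ``log_columns`` to run the normal working
    model on the log scale. Deterministic given ``seed``.
    """
    values = features.to_numpy(dtype=float).copy()
    mask = ~np.isfinite(values)
    if mask.all(axis=0).any():
        raise ImputationError("a column is entirely missing")
    if (mask.sum(axis=0) > values.shape[0] - 2).any():
        raise ImputationError("every column needs at least 2 observed values")
    bounds = dict(bounds or {})
    columns = list(features.columns)

    log_idx = [columns.index(c) for c in log_columns if c in columns]
    work = values.copy()
    for j in log_idx:
        if np.nanmin(work[:, j]) <= 0:
            raise ImputationError(f"log transform of non-positive column {columns[j]!r}")
        work[:, j] = np.log(work[:, j])
    lo, hi = _bounds_arrays(columns, bounds)
    for j in log_idx:
        lo[j] = np.log(lo[j]) if lo[j] > 0 else -np.inf
        hi[j] = np.log(hi[j]) if np.isfinite(hi[j]) else np.inf

    rng = np.random.default_rng(seed)
    if not mask.any():
        datasets = [features.copy() for _ in range(m)]
        return ImputedSet(datasets, [seed] * m, "none")

    is_monotone, order = monotonicity_check(mask)
    if is_monotone:
        completed = _impute_monotone(work, mask, order, lo, hi, rng, m)
        pattern = "monotone"
    else:
        completed = _impute_mcmc(work, mask, lo, hi, rng, burn_in, thinning, m)
        pattern = "random"

    datasets = []
    for filled in completed:
        back = filled.copy()
        for j in log_idx:
            back[:, j] = np.exp(back[:, j])
        back[~mask] = values[~mask]  # observed cells are never altered
        datasets.append(pd.DataFrame(back, index=features.index, columns=features.columns))
    return ImputedSet(datasets, [seed] * m, pattern)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def pool(estimates: np.ndarray, variances: np.ndarray,
         alpha: float = 0.05) -> PooledEstimate:
    """Combine per-imputation estimates and variances with Rubin's rules.

    ``estimates`` and ``variances`` have shape (m,) or (m, k). The total
    variance is T = U + (1 + 1/m) B with U the mean within-imputation
    variance and B the between-imputation variance; confidence intervals
    use the t distribution with Rubin's degrees of freedom.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim == 1:  # one scalar estimate per imputation
        q = q.reshape(-1, 1)
        u = u.reshape(-1, 1)
    m = q.shape[0]
    if m < 2:
        raise ImputationError("pooling requires at least 2 imputations")
    qbar = q.mean(axis=0)
    ubar = u.mean(axis=0)
    b = q.var(axis=0, ddof=1)
    t = ubar + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1.0 + 1.0 / m) * b / ubar
        df = np.where(b > 0, (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2,
                      np.inf)
    half = stats.t.ppf(1.0 - alpha / 2.0, df) * np.sqrt(t)
    squeeze = np.ndim(estimates) == 1
    out = PooledEstimate(qbar, ubar, b, t, df, qbar - half, qbar + half)
    if squeeze:
        out = PooledEstimate(*(np.asarray(a).reshape(-1) for a in
                               (out.estimate, out.within_variance, out.between_variance,
                                out.total_variance, out.df, out.ci_low, out.ci_high)))
    return out
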