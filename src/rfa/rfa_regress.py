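"""Joint L1-regularized estimation of reference-free effects and link.

For noisy or partially sampled landscapes the effects are estimated by
minimizing

    sum_g (y_g - link(score_g))^2 + lambda * sum |terms|

over the effect coefficients and the sigmoid bounds (L, U); the intercept
and the link parameters are unpenalized.  The L1 term is handled exactly
by proximal-gradient (FISTA) steps on the coefficients, alternating with
quasi-Newton steps on the link parameters (the joint problem is
non-convex because of the sigmoid, so standalone fits support random
restarts).  The regularization strength is chosen by cross-validation:
the strongest lambda whose out-of-sample R^2 does not significantly
differ from the maximum at p = 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_space import TermKey, encode_design
from .nonspecific_link import LinkParams, inverse_link, link_transform
from .rfa_exact import EffectSet, PhenotypeTable, decode_coefficients

__all__ = [
    "FitConfig",
    "FitResult",
    "fit",
    "cross_validate",
    "out_of_sample_r2",
    "fit_binary_fourier",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Settings for regression fits and cross-validation.

    ``lambda_grid`` defaults to ``n_lambda`` log-spaced values spanning
    six decades below the data-driven lasso-path ceiling (see
    :meth:`resolve_lambda_grid`), strongest first, with 0 appended.  The
    leave-one-replicate-out scheme replaces random k-fold CV when the
    table is small (< ``small_data_rows`` rows) but replicated.
    """

    max_order: int = 2
    use_link: bool = True
    lambda_grid: tuple[float, ...] | None = None
    n_lambda: int = 20
    cv_folds: int = 10
    cv_repeats: int = 3
    cv_scheme: str = "auto"  # "kfold" | "loro" | "auto"
    p_threshold: float = 0.1
    n_restarts: int = 3
    cv_restarts: int = 1
    max_iter: int = 5000
    grad_tol: float = 1e-8
    seed: int = 0
    small_data_rows: int = 50

    def resolve_lambda_grid(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Decreasing penalty grid, strongest first, with 0 appended.

        The ceiling is the smallest strength that zeroes every penalized
        coefficient in the linear problem, ``2 * max|X^T (y - ybar)|``
        (the lasso path convention); the grid spans six decades below it.
        """
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0 or np.any(grid < 0):
                raise ValueError("lambda grid must be non-empty, non-negative")
            return np.sort(grid)[::-1]
        lam_max = 2.0 * float(np.max(np.abs(X[:, 1:].T @ (y - y.mean()))))
        lam_max = max(lam_max, 1e-12)
        grid = np.geomspace(1.0, 1e-6, self.n_lambda) * lam_max
        return np.concatenate([grid, [0.0]])


@dataclass
class FitResult:
    """A fitted model plus the trace of how it was chosen."""

    effects: EffectSet
    config: FitConfig
    lam: float
    r2_in_sample: float
    objective: float
    n_iter: int
    converged: bool
    chosen_lambda: float | None = None
    cv_table: pd.DataFrame | None = None
    raw_coefficients: np.ndarray | None = None
    columns: list[TermKey] | None = None
    basis: str = "zero_sum"


# ---------------------------------------------------------------------------
# Optimizer core
# ---------------------------------------------------------------------------


def _soft_threshold(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _model_response(X, beta, link_vec):
    s = X @ beta
    if link_vec is None:
        return s, s, None
    L, theta = link_vec
    span = np.exp(theta)
    sig = 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))
    return s, L + span * sig, sig


def _objective(X, y, beta, link_vec, lam, pen_mask):
    _, yhat, _ = _model_response(X, beta, link_vec)
    return float(np.sum((yhat - y) ** 2) + lam * np.sum(np.abs(beta[pen_mask])))


def _fista(X, y, beta, link_vec, lam, pen_mask, max_iter, tol):
    """Proximal-gradient descent on the coefficients with link fixed."""
    t_pen = np.where(pen_mask, lam, 0.0)

    def smooth_loss_grad(b):
        s, yhat, sig = _model_response(X, b, link_vec)
        r = yhat - y
        if link_vec is None:
            w = r
        else:
            span = np.exp(link_vec[1])
            w = r * span * sig * (1.0 - sig)
        return float(np.sum(r**2)), 2.0 * (X.T @ w)

    # initial step size from a crude Lipschitz bound
    col_ms = np.mean(X**2, axis=0)
    lip = 2.0 * X.shape[0] * float(np.sum(col_ms))
    if link_vec is not None:
        lip *= 0.25 * np.exp(link_vec[1]) ** 2
    eta = 1.0 / max(lip, 1e-12)

    z = beta.copy()
    t_mom = 1.0
    f_prev, _ = smooth_loss_grad(beta)
    obj_prev = f_prev + float(np.sum(t_pen * np.abs(beta)))
    n_done = 0
    for it in range(max_iter):
        f_z, g_z = smooth_loss_grad(z)
        # backtracking line search on the proximal step
        for _ in range(60):
            cand = _soft_threshold(z - eta * g_z, eta * t_pen)
            d = cand - z
            f_cand, _ = smooth_loss_grad(cand)
            if f_cand <= f_z + g_z @ d + (d @ d) / (2 * eta) + 1e-12:
                break
            eta *= 0.5
        obj = f_cand + float(np.sum(t_pen * np.abs(cand)))
        if obj > obj_prev:  # restart momentum
            z = beta.copy()
            t_mom = 1.0
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        z = cand + ((t_mom - 1.0) / t_next) * (cand - beta)
        beta, t_mom = cand, t_next
        n_done = it + 1
        if abs(obj_prev - obj) <= tol * (1.0 + abs(obj)):
            obj_prev = obj
            break
        obj_prev = obj
        eta *= 2.0  # allow the step to grow back
    return beta, obj_prev, n_done


def _optimize_link(X, y, beta, link_vec):
    s = X @ beta

    def fun(v):
        L, theta = v
        span = np.exp(theta)
        sig = 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))
        r = L + span * sig - y
        f = float(np.sum(r**2))
        gL = 2.0 * float(np.sum(r))
        gtheta = 2.0 * float(np.sum(r * sig)) * span
        return f, np.array([gL, gtheta])

    res = optimize.minimize(
        fun, np.asarray(link_vec, float), jac=True, method="L-BFGS-B",
        options={"maxiter": 200},
    )
    return res.x


def _optimize_joint(X, y, lam, pen_mask, use_link, beta0, link_vec0, config):
    """Alternate FISTA on coefficients with L-BFGS-B on the link bounds."""
    beta = beta0.copy()
    link_vec = None if not use_link else np.asarray(link_vec0, float)
    if not use_link:
        if lam == 0.0:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            obj = float(np.sum((X @ beta - y) ** 2))
            return beta, None, obj, 1, True
        beta, obj, n = _fista(
            X, y, beta, None, lam, pen_mask, config.max_iter, config.grad_tol
        )
        return beta, None, obj, n, n < config.max_iter

    obj = _objective(X, y, beta, link_vec, lam, pen_mask)
    total_iter = 0
    converged = False
    for outer in range(60):
        beta, obj_b, n = _fista(
            X, y, beta, link_vec, lam, pen_mask,
            max(200, config.max_iter // 10), config.grad_tol,
        )
        total_iter += n
        link_vec = _optimize_link(X, y, beta, link_vec)
        obj_new = _objective(X, y, beta, link_vec, lam, pen_mask)
        if abs(obj - obj_new) <= config.grad_tol * (1.0 + abs(obj_new)):
            obj = obj_new
            converged = True
            break
        obj = obj_new
    return beta, link_vec, obj, total_iter, converged


def _initialize(X, y, lam, pen_mask, use_link, config, rng=None):
    """Start the link at the data range +/- 5% and the coefficients at a
    least-squares fit of the inverse-link-transformed phenotypes (the
    classical two-step estimator, used here only as an initializer)."""
    if not use_link:
        return np.zeros(X.shape[1]), None
    lo, hi = float(np.min(y)), float(np.max(y))
    span = max(hi - lo, 1e-6 * max(abs(hi), 1.0))
    L0, U0 = lo - 0.05 * span, hi + 0.05 * span
    if rng is not None:
        jitter = 0.2 * span
        L0 -= rng.uniform(0, jitter)
        U0 += rng.uniform(0, jitter)
    link = LinkParams(L0, U0)
    s_obs = np.asarray(inverse_link(y, link, 1e-3))
    beta, *_ = np.linalg.lstsq(X, s_obs, rcond=None)
    return beta, np.array([L0, np.log(U0 - L0)])


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


def _design_for(table, config, basis, reference):
    return encode_design(
        table.space, table.genotypes, config.max_order,
        basis=basis, reference=reference,
    )


def fit(
    table: PhenotypeTable,
    config: FitConfig | None = None,
    lam: float = 0.0,
    basis: str = "onehot",
    reference: np.ndarray | None = None,
    y: np.ndarray | None = None,
    n_restarts: int | None = None,
) -> FitResult:
    """Single-lambda joint fit of effects (and link) to a table.

    ``basis`` selects the parameterization being penalized.  The default
    overcomplete ``onehot`` encoding carries one coefficient per state
    and state combination, so the L1 penalty acts on the effects
    themselves and an unsampled genotype is predicted from only the
    terms for its own states; ``zero_sum``/``fourier``/``background``/
    ``dummy`` give the contrast and comparator-formalism encodings.  The decoded
    ``effects`` are always canonical zero-sum; the raw coefficients are
    kept on the result for formalism-specific analyses.
    """
    config = config or FitConfig()
    if table.n_rows < 2:
        raise ValueError("need at least 2 rows to fit")
    X, columns = _design_for(table, config, basis, reference)
    yv = table.mean_phenotypes if y is None else np.asarray(y, float)
    pen_mask = np.array([k.order > 0 for k in columns])

    restarts = config.n_restarts if n_restarts is None else n_restarts
    rng = np.random.default_rng(config.seed)
    best = None
    n_starts = max(1, restarts) if config.use_link else 1
    for start in range(n_starts):
        beta0, link_vec0 = _initialize(
            X, yv, lam, pen_mask, config.use_link, config,
            rng=None if start == 0 else rng,
        )
        beta, link_vec, obj, n_iter, converged = _optimize_joint(
            X, yv, lam, pen_mask, config.use_link, beta0, link_vec0, config
        )
        if best is None or obj < best[2]:
            best = (beta, link_vec, obj, n_iter, converged)
    beta, link_vec, obj, n_iter, converged = best

    link = None
    if link_vec is not None:
        link = LinkParams(float(link_vec[0]), float(link_vec[0] + np.exp(link_vec[1])))
    effects = decode_coefficients(
        table.space, beta, columns, basis=basis, reference=reference,
        max_order=config.max_order, link=link,
    )
    pred = np.asarray(effects.predict(table.genotypes))
    sst = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(np.sum((yv - pred) ** 2)) / sst if sst > 0 else np.nan
    if not converged:
        logger.warning("fit did not converge within iteration budget")
    return FitResult(
        effects=effects, config=config, lam=float(lam), r2_in_sample=r2,
        objective=obj, n_iter=n_iter, converged=converged,
        raw_coefficients=beta, columns=columns, basis=basis,
    )


def out_of_sample_r2(effects, test_table: PhenotypeTable) -> float:
    """1 - SSE/SST on held-out genotypes; may be negative."""
    y = test_table.mean_phenotypes
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("test set has zero phenotypic variance")
    pred = np.asarray(effects.predict(test_table.genotypes))
    return 1.0 - float(np.sum((y - pred) ** 2)) / sst


def _kfold_splits(n_rows, folds, repeats, seed):
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(repeats):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n_rows)
        for f in range(folds):
            test = perm[f::folds]
            train = np.setdiff1d(perm, test)
            out.append((train, test))
    return out


def _choose_scheme(table: PhenotypeTable, config: FitConfig) -> str:
    if config.cv_scheme != "auto":
        return config.cv_scheme
    if table.n_rows < config.small_data_rows and table.n_replicates >= 2:
        return "loro"
    return "kfold"


def cross_validate(
    table: PhenotypeTable,
    config: FitConfig | None = None,
    basis: str = "onehot",
    reference: np.ndarray | None = None,
) -> FitResult:
    """Fit with the regularization strength chosen by cross-validation.

    For each lambda on the grid the mean and standard error of the
    out-of-sample R^2 are recorded across folds (or held-out replicates
    for small replicated tables); the chosen lambda is the strongest one
    whose R^2 does not significantly differ from the maximum in a paired
    two-sided t-test at ``p_threshold``.  The returned model is refit on
    all data at that lambda.
    """
    config = config or FitConfig()
    yv = table.mean_phenotypes
    X_full, _ = _design_for(table, config, basis, reference)
    grid = config.resolve_lambda_grid(X_full, yv)
    scheme = _choose_scheme(table, config)

    if scheme == "kfold":
        if table.n_rows < config.cv_folds:
            raise ValueError(
                f"k-fold CV needs at least {config.cv_folds} rows"
            )
        splits = _kfold_splits(
            table.n_rows, config.cv_folds, config.cv_repeats, config.seed
        )
        tasks = [
            (table.subset(tr), table.subset(te), f // config.cv_folds)
            for f, (tr, te) in enumerate(splits)
        ]
    elif scheme == "loro":
        if table.n_replicates < 2:
            raise ValueError("leave-one-replicate-out needs >= 2 replicates")
        tasks = []
        for j in range(table.n_replicates):
            keep = [k for k in range(table.n_replicates) if k != j]
            train_y = table.phenotypes[:, keep]
            rows = ~np.all(np.isnan(train_y), axis=1)
            train = PhenotypeTable(
                table.space, table.genotypes[rows], train_y[rows]
            )
            test_rows = np.isfinite(table.phenotypes[:, j])
            test = PhenotypeTable(
                table.space,
                table.genotypes[test_rows],
                table.phenotypes[test_rows, j][:, None],
            )
            tasks.append((train, test, j))
    else:
        raise ValueError(f"unknown cv scheme {scheme!r}")

    n_repeats = len({rep for *_, rep in tasks})
    r2_matrix = np.full((len(grid), len(tasks)), np.nan)
    sse = np.zeros((len(grid), n_repeats))
    sst = np.zeros(n_repeats)
    skipped = np.zeros(len(tasks), dtype=bool)
    pooled_test: dict[int, list[np.ndarray]] = {}
    for t_idx, (train, test, rep) in enumerate(tasks):
        if np.var(test.mean_phenotypes) == 0:
            logger.warning("CV fold %d skipped: zero test variance", t_idx)
            skipped[t_idx] = True
            continue
        pooled_test.setdefault(rep, []).append(test.mean_phenotypes)
        warm_cfg = replace(config, seed=config.seed + 104729 + t_idx)
        for l_idx, lam in enumerate(grid):
            res = fit(
                train, warm_cfg, lam=lam, basis=basis, reference=reference,
                n_restarts=config.cv_restarts,
            )
            pred = np.asarray(res.effects.predict(test.genotypes))
            sse[l_idx, rep] += float(np.sum((test.mean_phenotypes - pred) ** 2))
            r2_matrix[l_idx, t_idx] = out_of_sample_r2(res.effects, test)
    for rep, chunks in pooled_test.items():
        yr = np.concatenate(chunks)
        sst[rep] = float(np.sum((yr - yr.mean()) ** 2))

    r2_matrix = r2_matrix[:, ~skipped]
    if r2_matrix.shape[1] == 0:
        raise ValueError("all CV folds were degenerate")
    ok_rep = sst > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled_r2 = np.mean(1.0 - sse[:, ok_rep] / sst[ok_rep], axis=1)
    mean_r2 = np.nanmean(r2_matrix, axis=1)
    se_r2 = np.nanstd(r2_matrix, axis=1, ddof=1) / np.sqrt(r2_matrix.shape[1])
    best_idx = int(np.nanargmax(mean_r2))

    chosen_idx = best_idx
    for l_idx in range(len(grid)):  # grid is decreasing: strongest first
        if l_idx == best_idx:
            chosen_idx = l_idx
            break
        a, b = r2_matrix[l_idx], r2_matrix[best_idx]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            continue
        diff = a[ok] - b[ok]
        if np.allclose(diff, 0.0):
            chosen_idx = l_idx
            break
        _, p = stats.ttest_rel(a[ok], b[ok])
        if np.isnan(p) or p > config.p_threshold:
            chosen_idx = l_idx
            break

    chosen_lambda = float(grid[chosen_idx])
    final = fit(
        table, config, lam=chosen_lambda, basis=basis, reference=reference
    )
    final.chosen_lambda = chosen_lambda
    final.cv_table = pd.DataFrame(
        {
            "lambda": grid,
            "mean_r2": mean_r2,
            "se_r2": se_r2,
            "pooled_r2": pooled_r2,
            "n_folds": r2_matrix.shape[1],
        }
    )
    return final


def fit_binary_fourier(
    table: PhenotypeTable,
    config: FitConfig | None = None,
    lam: float | None = None,
) -> FitResult:
    """Fit via Fourier coefficients for all-binary sites, then convert.

    In a binary space there are as many Fourier coefficients as free
    reference-free terms and the two parameterizations are related by a
    per-site sign basis, so the converted effects reproduce the direct
    fit exactly at lambda = 0 on complete data.
    """
    if not table.space.is_binary:
        raise ValueError("fit_binary_fourier requires all sites binary")
    if lam is None:
        return cross_validate(table, config, basis="fourier")
    return fit(table, config, lam=lam, basis="fourier")
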