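"""Post-fit diagnostics: sparsity, inferability, outliers, specificity.

These analyses characterize a fitted genetic architecture rather than
estimate it: how many model terms are needed to predict the phenotype
with 90% accuracy (T90), how many randomly sampled genotypes are needed
to infer the architecture to the same accuracy (N90), which genotypes
bear strong high-order epistasis (second-order-model outliers), how much
of the landscape sits at the phenotype bounds, and how state effects
differ between two phenotypes (specificity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_space import TermKey
from .nonspecific_link import LinkParams
from .rfa_exact import EffectSet, PhenotypeTable, variance_partition
from .rfa_regress import (
    FitConfig,
    FitResult,
    _kfold_splits,
    _optimize_joint,
    _initialize,
)

__all__ = [
    "SparsityCurve",
    "SamplingCurve",
    "rank_terms",
    "t90_curve",
    "n90_curve",
    "detect_outliers",
    "bound_fraction",
    "specificity_scores",
    "fit_power_law",
    "PowerLawFit",
]

logger = logging.getLogger(__name__)

NOT_ATTAINED = float("nan")


# ---------------------------------------------------------------------------
# Term ranking and the T90 sparsity curve
# ---------------------------------------------------------------------------


def rank_terms(fit: FitResult | EffectSet) -> list[tuple[TermKey, float]]:
    """Model terms in descending order of variance contribution.

    Ties break deterministically by (order, sites, states).  Returns
    ``(TermKey, variance contribution)`` pairs.
    """
    effects = fit.effects if isinstance(fit, FitResult) else fit
    part = variance_partition(effects)
    return sorted(
        part.per_term.items(),
        key=lambda kv: (-kv[1], kv[0].order, kv[0].sites, kv[0].states),
    )


@dataclass
class SparsityCurve:
    """Out-of-sample R^2 of prefix models of the ranked term list.

    ``t90_threshold`` is the smallest prefix reaching R^2 >= 0.9 (an
    overestimate under noise, since no model attains R^2 = 1);
    ``t90_relative`` the smallest prefix reaching 90% of the full model's
    R^2; ``t90`` their average.  NaN marks a target never attained.
    """

    prefix_sizes: np.ndarray
    r2: np.ndarray
    full_model_r2: float
    t90_threshold: float
    t90_relative: float

    @property
    def t90(self) -> float:
        return 0.5 * (self.t90_threshold + self.t90_relative)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_terms": self.prefix_sizes, "r2": self.r2})


def _prefix_design(table: PhenotypeTable, terms: list[TermKey]) -> np.ndarray:
    """Indicator features: column t is 1 when the genotype carries term t's
    state combination.  A prefix model predicts score = e0 + sum of the
    matching refit term values, mirroring how the full model predicts."""
    g = table.genotypes
    X = np.ones((g.shape[0], len(terms) + 1))
    for j, key in enumerate(terms, start=1):
        col = np.ones(g.shape[0])
        for i, s in zip(key.sites, key.states):
            col *= g[:, i] == s
        X[:, j] = col
    return X


def _fit_prefix(X, y, use_link, config):
    """Unpenalized least-squares (optionally through the link) on a small
    explicit feature set."""
    pen = np.zeros(X.shape[1], dtype=bool)
    beta0, link_vec0 = _initialize(X, y, 0.0, pen, use_link, config)
    beta, link_vec, obj, _, _ = _optimize_joint(
        X, y, 0.0, pen, use_link, beta0, link_vec0, config
    )
    return beta, link_vec


def _predict_prefix(X, beta, link_vec):
    s = X @ beta
    if link_vec is None:
        return s
    return link_vec[0] + np.exp(link_vec[1]) / (1.0 + np.exp(-np.clip(s, -500, 500)))


def t90_curve(
    table: PhenotypeTable,
    fit: FitResult,
    config: FitConfig | None = None,
    prefix_sizes: np.ndarray | None = None,
    r2_target: float = 0.9,
) -> SparsityCurve:
    """Accuracy of increasingly complex models built from the ranked terms.

    The ranking is frozen from the fitted model; each prefix refits its
    term values (plus intercept and link) and is scored by k-fold
    cross-validation.  ``fit`` should normally be a third-order model
    chosen by cross-validation.
    """
    config = config or replace(fit.config, cv_folds=5, cv_repeats=1)
    ranked = [k for k, _ in rank_terms(fit)]
    if not ranked:
        logger.warning("model has no nonzero terms; T90 not attained")
        return SparsityCurve(
            np.array([], dtype=int), np.array([]), 0.0, NOT_ATTAINED, NOT_ATTAINED
        )
    if prefix_sizes is None:
        sizes = np.arange(1, len(ranked) + 1)
    else:
        sizes = np.asarray(prefix_sizes, dtype=int)
    use_link = fit.effects.link is not None
    y = table.mean_phenotypes
    splits = _kfold_splits(
        table.n_rows, config.cv_folds, config.cv_repeats, config.seed
    )

    full_r2 = _cv_r2_of_model(fit, table, config)
    r2s = np.empty(len(sizes))
    for si, size in enumerate(sizes):
        X = _prefix_design(table, ranked[:size])
        fold_r2 = []
        for train, test in splits:
            yt = y[test]
            if np.var(yt) == 0:
                continue
            try:
                beta, link_vec = _fit_prefix(X[train], y[train], use_link, config)
            except np.linalg.LinAlgError:
                logger.warning("prefix %d: refit failed on one fold", size)
                continue
            pred = _predict_prefix(X[test], beta, link_vec)
            fold_r2.append(
                1.0 - np.sum((yt - pred) ** 2) / np.sum((yt - yt.mean()) ** 2)
            )
        r2s[si] = np.mean(fold_r2) if fold_r2 else np.nan

    t90_thr = _first_crossing(sizes, r2s, r2_target)
    t90_rel = _first_crossing(sizes, r2s, r2_target * full_r2)
    return SparsityCurve(sizes, r2s, full_r2, t90_thr, t90_rel)


def _cv_r2_of_model(fit: FitResult, table, config) -> float:
    if fit.cv_table is not None and fit.chosen_lambda is not None:
        row = fit.cv_table.loc[fit.cv_table["lambda"] == fit.chosen_lambda]
        if len(row):
            return float(row["mean_r2"].iloc[0])
    return float(fit.r2_in_sample)


def _first_crossing(sizes, r2s, target) -> float:
    ok = np.where(np.nan_to_num(r2s, nan=-np.inf) >= target)[0]
    return float(sizes[ok[0]]) if len(ok) else NOT_ATTAINED


# ---------------------------------------------------------------------------
# N90 sampling curve
# ---------------------------------------------------------------------------


@dataclass
class SamplingCurve:
    """Mean/SD of out-of-sample R^2 versus random sample size.

    ``n90`` interpolates (linearly on log sample size) the smallest size
    whose mean R^2 reaches 0.9; NaN when never attained.
    """

    sizes: np.ndarray
    mean_r2: np.ndarray
    sd_r2: np.ndarray
    n90: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_sampled": self.sizes, "mean_r2": self.mean_r2, "sd_r2": self.sd_r2}
        )


def n90_curve(
    table: PhenotypeTable,
    sizes: np.ndarray,
    trials: int = 10,
    config: FitConfig | None = None,
    r2_target: float = 0.9,
) -> SamplingCurve:
    """Inferability by random sampling.

    For each sample size, ``trials`` random without-replacement samples
    are drawn, a model is fit to each (with cross-validated lambda) and
    evaluated on all unsampled genotypes.
    """
    from .rfa_regress import cross_validate, out_of_sample_r2

    config = config or FitConfig(max_order=3)
    sizes = np.asarray(sorted(int(s) for s in sizes))
    if sizes[-1] >= table.n_rows:
        raise ValueError("sample sizes must be below the number of rows")
    ss = np.random.SeedSequence(config.seed)
    mean_r2 = np.full(len(sizes), np.nan)
    sd_r2 = np.full(len(sizes), np.nan)
    for si, (size, child) in enumerate(zip(sizes, ss.spawn(len(sizes)))):
        vals = []
        for trial, tchild in enumerate(child.spawn(trials)):
            rng = np.random.default_rng(tchild)
            rows = np.sort(rng.choice(table.n_rows, size=size, replace=False))
            mask = np.ones(table.n_rows, dtype=bool)
            mask[rows] = False
            try:
                res = cross_validate(
                    table.subset(rows),
                    replace(config, seed=int(tchild.generate_state(1)[0] % 2**31)),
                )
                vals.append(
                    out_of_sample_r2(res.effects, table.subset(np.where(mask)[0]))
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("size %d trial %d failed: %s", size, trial, exc)
        if vals:
            mean_r2[si] = float(np.mean(vals))
            sd_r2[si] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    n90 = _interpolate_crossing(sizes, mean_r2, r2_target)
    return SamplingCurve(sizes, mean_r2, sd_r2, n90)


def _interpolate_crossing(sizes, mean_r2, target) -> float:
    above = np.nan_to_num(mean_r2, nan=-np.inf) >= target
    if not above.any():
        return NOT_ATTAINED
    i = int(np.argmax(above))
    if i == 0:
        return float(sizes[0])
    x0, x1 = math.log(sizes[i - 1]), math.log(sizes[i])
    y0, y1 = mean_r2[i - 1], mean_r2[i]
    if not np.isfinite(y0) or y1 == y0:
        return float(sizes[i])
    frac = (target - y0) / (y1 - y0)
    return float(math.exp(x0 + frac * (x1 - x0)))


# ---------------------------------------------------------------------------
# Outliers, bounds, specificity, power law
# ---------------------------------------------------------------------------


def detect_outliers(
    table: PhenotypeTable,
    second_order_fit: FitResult | EffectSet,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Candidates for strong high-order epistasis.

    Residuals of the (second-order) model are compared against the
    observed phenotype range; a genotype is flagged iff its absolute
    residual strictly exceeds ``threshold`` (20%) of that range.  The
    returned frame carries one row per genotype with an ``outlier``
    column; the flagged fraction is in ``frame.attrs["fraction"]``.
    """
    effects = (
        second_order_fit.effects
        if isinstance(second_order_fit, FitResult)
        else second_order_fit
    )
    y = table.mean_phenotypes
    y_range = float(np.max(y) - np.min(y))
    if y_range == 0:
        raise ValueError("phenotype range is zero; outlier rule undefined")
    pred = np.asarray(effects.predict(table.genotypes))
    resid = y - pred
    flagged = np.abs(resid) > threshold * y_range
    frame = pd.DataFrame(
        {
            "genotype": [
                table.space.format_genotype(g) for g in table.genotypes
            ],
            "observed": y,
            "predicted": pred,
            "residual": resid,
            "outlier": flagged,
        }
    )
    frame.attrs["fraction"] = float(flagged.mean())
    frame.attrs["threshold"] = threshold * y_range
    return frame


def bound_fraction(
    table: PhenotypeTable, link: LinkParams, tol_fraction: float = 0.02
) -> float:
    """Fraction of genotypes whose mean phenotype lies within
    ``tol_fraction`` of the link range of either bound."""
    y = table.mean_phenotypes
    tol = tol_fraction * link.range
    at_bound = (y <= link.L + tol) | (y >= link.U - tol)
    return float(np.mean(at_bound))


def specificity_scores(fit_a: FitResult, fit_b: FitResult) -> pd.DataFrame:
    """Per-term genetic-score differences between two phenotypes.

    Both fits must share a genotype space.  A positive difference means
    the state (combination) favors phenotype A; exp of the difference is
    the fold preference in relative occupancy under the sigmoid reading.
    """
    ea, eb = fit_a.effects, fit_b.effects
    if ea.space != eb.space:
        raise ValueError("fits are on different genotype spaces")
    keys = sorted(
        {k for k, _ in ea.term_items()} | {k for k, _ in eb.term_items()},
        key=lambda k: (k.order, k.sites, k.states),
    )
    records = [
        {
            "sites": tuple(i + 1 for i in k.sites),
            "states": tuple(
                ea.space.site_alphabets[i][s] for i, s in zip(k.sites, k.states)
            ),
            "order": k.order,
            "effect_a": ea.get(k),
            "effect_b": eb.get(k),
            "delta_score": ea.get(k) - eb.get(k),
        }
        for k in keys
    ]
    frame = pd.DataFrame.from_records(records)
    frame.attrs["delta_intercept"] = ea.intercept - eb.intercept
    return frame


@dataclass(frozen=True)
class PowerLawFit:
    """T90 ~ prefactor * N^exponent, fit by least squares on log-log scale."""

    prefactor: float
    exponent: float

    def predict(self, n) -> np.ndarray | float:
        n = np.asarray(n, dtype=float)
        out = self.prefactor * n**self.exponent
        return float(out) if out.ndim == 0 else out


def fit_power_law(points) -> PowerLawFit:
    """Fit a power function to (N, T90)-style pairs (>= 3 positive points)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (N, T90) pairs")
    if np.any(pts <= 0):
        raise ValueError("power-law fit requires positive values")
    logn, logt = np.log(pts[:, 0]), np.log(pts[:, 1])
    A = np.stack([np.ones_like(logn), logn], axis=1)
    coef, *_ = np.linalg.lstsq(A, logt, rcond=None)
    return PowerLawFit(float(np.exp(coef[0])), float(coef[1]))
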