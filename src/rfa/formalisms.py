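"""Comparator decompositions: reference-based, Fourier, background-averaged.

All four formalisms (including the reference-free one in
:mod:`rfa.rfa_exact`) parameterize the same space of functions on a
combinatorial genotype space and differ only in the per-site basis, so a
full-order model in any of them reproduces a complete landscape exactly
and converts losslessly into any other.

- Reference-based analysis (RBA) designates a wild-type genotype; its
  order-k terms are defined by the requirement that the model reproduce
  the wild type and every mutant carrying up to k mutations exactly.
- Fourier analysis (FA) uses an orthonormal per-site contrast basis
  (the Walsh-Hadamard transform when all sites are binary).
- Background-averaged analysis (BA) averages the effect of a mutation
  combination (relative to a per-site reference state) over all genetic
  backgrounds at the remaining sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_space import (
    GenotypeSpace,
    TermKey,
    encode_design,
    enumerate_genotypes,
    site_subsets,
)
from .nonspecific_link import LinkParams, inverse_link, link_transform
from .rfa_exact import (
    EffectSet,
    PhenotypeTable,
    decompose_tensor,
    exact_effects,
)

__all__ = [
    "RBAModel",
    "FourierModel",
    "BAModel",
    "RBALinkFit",
    "rba_effects",
    "rba_fit_with_link",
    "fourier_effects",
    "ba_effects",
    "convert",
]


class MissingGenotypesError(ValueError):
    """Required genotypes are absent from the table."""

    def __init__(self, labels: list[str]):
        self.labels = labels
        preview = ", ".join(labels[:10])
        more = "" if len(labels) <= 10 else f" (+{len(labels) - 10} more)"
        super().__init__(f"missing required genotypes: {preview}{more}")


# ---------------------------------------------------------------------------
# Reference-based analysis
# ---------------------------------------------------------------------------


@dataclass
class RBAModel:
    """Truncated reference-based model around a wild-type genotype.

    ``terms`` maps ``TermKey(sites, states)`` — all states differing from
    the reference at those sites — to the effect of introducing that
    mutation combination on the reference background.  ``intercept`` is
    the (score-scale) phenotype of the reference itself.
    """

    space: GenotypeSpace
    reference: np.ndarray
    intercept: float
    terms: dict[TermKey, float] = field(default_factory=dict)
    max_order: int = 0
    link: LinkParams | None = None

    def __post_init__(self) -> None:
        self.reference = self.space.validate_genotypes(self.reference)[0]

    def scores(self, genotypes: np.ndarray) -> np.ndarray:
        g = self.space.validate_genotypes(genotypes)
        out = np.full(g.shape[0], self.intercept)
        for key, v in self.terms.items():
            mask = np.ones(g.shape[0], dtype=bool)
            for i, s in zip(key.sites, key.states):
                mask &= g[:, i] == s
            out[mask] += v
        return out

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        s = self.scores(genotypes)
        return link_transform(s, self.link) if self.link is not None else s


def _mutant_order(genotypes: np.ndarray, reference: np.ndarray) -> np.ndarray:
    return np.sum(np.atleast_2d(genotypes) != reference[None, :], axis=1)


def rba_effects(
    table: PhenotypeTable,
    reference: np.ndarray,
    max_order: int,
    values: np.ndarray | None = None,
) -> RBAModel:
    """Reference-based effects by inclusion-exclusion over low-order mutants.

    The term for mutation combination ``m`` at sites ``S`` is
    ``sum_{T subseteq S} (-1)^{|S \\ T|} y(reference with T mutated)``,
    which makes the order-k model exact for the reference and all mutants
    of order up to k.  ``values`` optionally overrides the table's mean
    phenotypes (used to work on the score scale under a link).
    """
    space = table.space
    ref = space.validate_genotypes(reference)[0]
    y = table.mean_phenotypes if values is None else np.asarray(values, float)
    lookup = dict(zip(space.ravel(table.genotypes).tolist(), y.tolist()))

    missing: list[str] = []

    def phenotype_of(g: np.ndarray) -> float:
        idx = int(space.ravel(g[None, :])[0])
        if idx not in lookup:
            missing.append(space.format_genotype(g))
            return np.nan
        return lookup[idx]

    intercept = phenotype_of(ref)
    terms: dict[TermKey, float] = {}
    for S in site_subsets(space, max_order):
        state_choices = [
            [s for s in range(space.shape[i]) if s != ref[i]] for i in S
        ]
        for states in itertools.product(*state_choices):
            val = 0.0
            for r in range(len(S) + 1):
                for T in itertools.combinations(range(len(S)), r):
                    g = ref.copy()
                    for j in T:
                        g[S[j]] = states[j]
                    val += (-1) ** (len(S) - r) * phenotype_of(g)
            terms[TermKey(tuple(S), tuple(states))] = val
    if missing:
        raise MissingGenotypesError(sorted(set(missing)))
    return RBAModel(space, ref, float(intercept), terms, max_order)


@dataclass
class RBALinkFit:
    model: RBAModel
    link: LinkParams
    r2_higher_order: float
    n_evaluated: int


def rba_fit_with_link(
    table: PhenotypeTable,
    reference: np.ndarray,
    max_order: int,
    link_grid: Sequence[LinkParams] | None = None,
    grid_size: int = 25,
    refine: bool = True,
    epsilon: float = 1e-6,
) -> RBALinkFit:
    """Reference-based analysis with a sigmoid link chosen by grid search.

    For each candidate ``(L, U)`` the observed phenotypes are pulled back
    through the inverse link, the low-order mutants define the RBA terms
    exactly, and the candidate is scored by out-of-sample R^2 on the
    mutants of order above ``max_order``.  The grid spans the observed
    range expanded by 50% and is refined once around the best cell.
    """
    space = table.space
    ref = space.validate_genotypes(reference)[0]
    ybar = table.mean_phenotypes
    order = _mutant_order(table.genotypes, ref)
    eval_mask = order > max_order
    if not np.any(eval_mask):
        raise ValueError("no mutants above the model order to evaluate on")
    y_eval = ybar[eval_mask]
    if np.var(y_eval) == 0:
        raise ValueError("higher-order mutants have zero phenotypic variance")

    def score_candidate(link: LinkParams) -> tuple[float, RBAModel]:
        s_obs = np.asarray(inverse_link(ybar, link, epsilon))
        model = rba_effects(table, ref, max_order, values=s_obs)
        model.link = link
        pred = np.asarray(model.predict(table.genotypes[eval_mask]))
        sse = float(np.sum((y_eval - pred) ** 2))
        sst = float(np.sum((y_eval - y_eval.mean()) ** 2))
        return 1.0 - sse / sst, model

    def grid_around(lo_c: float, lo_h: float, hi_c: float, hi_h: float):
        Ls = np.linspace(lo_c - lo_h, lo_c + lo_h, grid_size)
        Us = np.linspace(hi_c - hi_h, hi_c + hi_h, grid_size)
        sep = 1e-3 * (np.max(ybar) - np.min(ybar) + 1e-12)
        return [
            LinkParams(L, U) for L in Ls for U in Us if U - L > sep
        ]

    if link_grid is None:
        rng_obs = np.max(ybar) - np.min(ybar)
        half = 0.75 * rng_obs  # full span = observed range expanded by 50%
        candidates = grid_around(np.min(ybar), half, np.max(ybar), half)
        step = 2 * half / (grid_size - 1)
    else:
        candidates = list(link_grid)
        refine = False
        step = 0.0

    best_r2, best_model, best_link = -np.inf, None, None
    for link in candidates:
        r2, model = score_candidate(link)
        if r2 > best_r2:
            best_r2, best_model, best_link = r2, model, link
    if refine and best_link is not None:
        for link in grid_around(best_link.L, step, best_link.U, step):
            r2, model = score_candidate(link)
            if r2 > best_r2:
                best_r2, best_model, best_link = r2, model, link
    assert best_model is not None
    return RBALinkFit(best_model, best_link, float(best_r2), int(eval_mask.sum()))


# ---------------------------------------------------------------------------
# Fourier analysis
# ---------------------------------------------------------------------------


@dataclass
class FourierModel:
    """Coefficients in the orthonormal per-site contrast basis.

    Keys are ``TermKey(sites, basis ordinals)``; the ordinals index the
    ``q_i - 1`` Helmert contrast columns of each site, which reduce to the
    Walsh-Hadamard basis (up to scale) for binary sites.
    """

    space: GenotypeSpace
    intercept: float
    coeffs: dict[TermKey, float] = field(default_factory=dict)
    max_order: int = 0
    link: LinkParams | None = None

    def scores(self, genotypes: np.ndarray) -> np.ndarray:
        g = self.space.validate_genotypes(genotypes)
        X, columns = encode_design(self.space, g, self.max_order, basis="fourier")
        beta = np.zeros(len(columns))
        beta[0] = self.intercept
        index = {key: j for j, key in enumerate(columns)}
        for key, v in self.coeffs.items():
            beta[index[key]] = v
        return X @ beta

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        s = self.scores(genotypes)
        return link_transform(s, self.link) if self.link is not None else s


def fourier_effects(table: PhenotypeTable, max_order: int) -> FourierModel:
    """Exact (least-squares) Fourier coefficients of a complete landscape."""
    if not table.is_complete:
        raise _incomplete("fourier")
    g = table.genotypes
    X, columns = encode_design(table.space, g, max_order, basis="fourier")
    beta, *_ = np.linalg.lstsq(X, table.mean_phenotypes, rcond=None)
    coeffs = {
        key: float(b)
        for key, b in zip(columns[1:], beta[1:])
        if b != 0.0
    }
    return FourierModel(table.space, float(beta[0]), coeffs, max_order)


# ---------------------------------------------------------------------------
# Background-averaged analysis
# ---------------------------------------------------------------------------


@dataclass
class BAModel:
    """Background-averaged terms relative to per-site reference states.

    The term for mutation combination ``m`` at sites ``S`` is the finite
    difference of the phenotype over ``S`` (mutations versus reference
    states), averaged over all backgrounds at the other sites.  Keys are
    ``TermKey(sites, states)`` with states differing from the per-site
    reference.  The intercept is the global mean phenotype.
    """

    space: GenotypeSpace
    reference_states: np.ndarray
    intercept: float
    terms: dict[TermKey, float] = field(default_factory=dict)
    max_order: int = 0
    link: LinkParams | None = None

    def __post_init__(self) -> None:
        self.reference_states = self.space.validate_genotypes(
            self.reference_states
        )[0]

    def scores(self, genotypes: np.ndarray) -> np.ndarray:
        g = self.space.validate_genotypes(genotypes)
        X, columns = encode_design(
            self.space, g, self.max_order, basis="background",
            reference=self.reference_states,
        )
        beta = np.zeros(len(columns))
        beta[0] = self.intercept
        index = {key: j for j, key in enumerate(columns)}
        for key, v in self.terms.items():
            beta[index[key]] = v
        return X @ beta

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        s = self.scores(genotypes)
        return link_transform(s, self.link) if self.link is not None else s


def ba_effects(
    table: PhenotypeTable,
    max_order: int,
    reference_states: np.ndarray | None = None,
) -> BAModel:
    """Exact background-averaged terms of a complete landscape.

    Computed as the per-site finite difference of the reference-free
    effect tensors: averaging over backgrounds cancels every term not
    involving all of the focal sites, so the BA term of order k is a
    signed combination of the order-k reference-free effects only.
    """
    if not table.is_complete:
        raise _incomplete("background-averaged")
    space = table.space
    if reference_states is None:
        ref = np.zeros(space.n_sites, dtype=np.int64)
    else:
        ref = space.validate_genotypes(reference_states)[0]
    eff = exact_effects(table, max_order)
    terms: dict[TermKey, float] = {}
    for S, t in eff.tensors.items():
        # apply b[m] = e[m] - e[r] along each axis
        d = t
        for axis, i in enumerate(S):
            d = d - np.take(d, int(ref[i]), axis=axis)[
                tuple(slice(None) if a != axis else None for a in range(d.ndim))
            ]
        state_choices = [
            [s for s in range(space.shape[i]) if s != ref[i]] for i in S
        ]
        for states in itertools.product(*state_choices):
            v = float(d[tuple(states)])
            if v != 0.0:
                terms[TermKey(S, tuple(states))] = v
    return BAModel(space, ref, float(eff.intercept), terms, max_order)


# ---------------------------------------------------------------------------
# Conversion
# ---------------------------------------------------------------------------


def _incomplete(name: str):
    from .rfa_exact import IncompleteDataError

    return IncompleteDataError(
        f"exact {name} analysis needs a complete table; "
        "use rfa.rfa_regress.fit on the matching encoding instead"
    )


def convert(
    model,
    target: str,
    reference: np.ndarray | None = None,
    reference_states: np.ndarray | None = None,
):
    """Re-express a model in another formalism, preserving predictions.

    Works on the score scale (any link is carried over unchanged): the
    source model is evaluated on the complete genotype space and exactly
    re-decomposed at its own order in the target formalism.  A truncated
    model of order k spans only interactions up to order k in any of the
    parameterizations, so the conversion is prediction-identical.
    """
    space: GenotypeSpace = model.space
    max_order = model.max_order if model.max_order is not None else space.n_sites
    genotypes = enumerate_genotypes(space)
    scores = np.asarray(model.scores(genotypes), dtype=float)
    link = model.link

    if target in ("rfa", "reference_free"):
        e0, tensors = decompose_tensor(
            scores.reshape(space.shape), space.n_sites, max_order
        )
        tensors = {S: t for S, t in tensors.items() if np.any(np.abs(t) > 0)}
        return EffectSet(space, float(e0), tensors, max_order, link)

    score_table = PhenotypeTable(space, genotypes, scores[:, None])
    if target in ("rba", "reference_based"):
        if reference is None:
            reference = np.zeros(space.n_sites, dtype=np.int64)
        out = rba_effects(score_table, reference, max_order)
    elif target == "fourier":
        out = fourier_effects(score_table, max_order)
    elif target in ("ba", "background_averaged"):
        out = ba_effects(score_table, max_order, reference_states)
    else:
        raise ValueError(f"unsupported target formalism {target!r}")
    out.link = link
    return out
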