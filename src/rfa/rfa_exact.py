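"""Exact reference-free decomposition of completely sampled landscapes.

The reference-free effect of a state combination is defined by averaging:
the intercept ``e0`` is the mean phenotype over the whole genotype space;
the additive effect of state ``s`` at site ``i`` is the mean phenotype of
all genotypes carrying that state minus ``e0``; an order-k effect is the
mean phenotype of the genotypes carrying the k-state combination minus
the expectation from all lower-order effects.  Averaging over each
involved site therefore gives zero — the canonical zero-sum form.

These definitions require every genotype to be present; for noisy or
partially sampled data see :mod:`rfa.rfa_regress`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .genotype_space import (
    GenotypeSpace,
    TermKey,
    contrast_basis,
    site_subsets,
)
from .nonspecific_link import LinkParams, link_transform

__all__ = [
    "PhenotypeTable",
    "EffectSet",
    "VariancePartition",
    "IncompleteDataError",
    "exact_effects",
    "variance_partition",
    "noise_variance",
    "decode_coefficients",
]

ZERO_SUM_TOL = 1e-9


class IncompleteDataError(ValueError):
    """The exact averaging path needs every genotype; use regression."""


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Sampled genotypes with replicate phenotype measurements.

    ``genotypes`` is an ``(R, n)`` state-index array with unique rows;
    ``phenotypes`` an ``(R, n_rep)`` float array, NaN-padded when rows
    carry unequal replicate counts.
    """

    space: GenotypeSpace
    genotypes: np.ndarray
    phenotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = self.space.validate_genotypes(self.genotypes)
        y = np.asarray(self.phenotypes, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[0] != self.genotypes.shape[0]:
            raise ValueError("genotype and phenotype row counts differ")
        if np.any(np.all(np.isnan(y), axis=1)):
            raise ValueError("every row needs at least one phenotype value")
        idx = self.space.ravel(self.genotypes)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate genotypes; merge them as replicates")
        self.phenotypes = y

    # -- constructors ---------------------------------------------------------

    @classmethod
    def from_rows(
        cls,
        space: GenotypeSpace,
        genotypes: np.ndarray,
        values: Sequence[Sequence[float]] | np.ndarray,
    ) -> "PhenotypeTable":
        """Build a table from per-row replicate value lists, merging
        duplicate genotypes into additional replicates."""
        g = space.validate_genotypes(genotypes)
        idx = space.ravel(g)
        per_index: dict[int, list[float]] = {}
        for i, row in zip(idx, values):
            vals = np.atleast_1d(np.asarray(row, dtype=float))
            per_index.setdefault(int(i), []).extend(
                float(v) for v in vals if np.isfinite(v)
            )
        keys = sorted(per_index)
        width = max(len(per_index[k]) for k in keys)
        y = np.full((len(keys), width), np.nan)
        for r, k in enumerate(keys):
            y[r, : len(per_index[k])] = per_index[k]
        return cls(space, space.unravel(np.array(keys)), y)

    # -- derived quantities ---------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.phenotypes.shape[1]

    @property
    def mean_phenotypes(self) -> np.ndarray:
        return np.nanmean(self.phenotypes, axis=1)

    @property
    def is_complete(self) -> bool:
        return self.n_rows == self.space.n_genotypes

    def replicate_noise_variance(self) -> float | None:
        """Pooled within-genotype replicate variance (omega); None if no
        row has two or more replicates."""
        counts = np.sum(np.isfinite(self.phenotypes), axis=1)
        if counts.max(initial=0) < 2:
            return None
        dev = self.phenotypes - np.nanmean(self.phenotypes, axis=1, keepdims=True)
        ss = np.nansum(dev**2)
        dof = int(np.sum(np.maximum(counts - 1, 0)))
        return float(ss / dof)

    def mean_tensor(self) -> np.ndarray:
        """Mean phenotypes arranged on the full factorial grid."""
        if not self.is_complete:
            raise IncompleteDataError(
                f"table has {self.n_rows} of {self.space.n_genotypes} "
                "genotypes; fit incomplete data with rfa.rfa_regress.fit"
            )
        t = np.empty(self.space.n_genotypes)
        t[self.space.ravel(self.genotypes)] = self.mean_phenotypes
        return t.reshape(self.space.shape)

    def subset(self, rows: np.ndarray) -> "PhenotypeTable":
        return PhenotypeTable(
            self.space, self.genotypes[rows], self.phenotypes[rows]
        )


# ---------------------------------------------------------------------------
# Effect sets
# ---------------------------------------------------------------------------


@dataclass
class EffectSet:
    """A truncated reference-free model in canonical zero-sum form.

    Effects are stored densely as one tensor per site subset; the tensor
    for subset ``S`` has shape ``(q_i for i in S)`` and sums to zero along
    every axis.  ``intercept`` is ``e0``.  When ``link`` is present the
    linear part is a genetic score and predictions pass through the link.
    """

    space: GenotypeSpace
    intercept: float
    tensors: dict[tuple[int, ...], np.ndarray] = field(default_factory=dict)
    max_order: int | None = None
    link: LinkParams | None = None

    def __post_init__(self) -> None:
        if self.max_order is None:
            orders = [len(S) for S in self.tensors]
            self.max_order = max(orders, default=0)
        for S, t in self.tensors.items():
            expect = tuple(self.space.shape[i] for i in S)
            if t.shape != expect:
                raise ValueError(f"tensor for sites {S} has shape {t.shape}")
            if len(S) > self.max_order:
                raise ValueError(f"term of order {len(S)} exceeds max_order")

    @classmethod
    def from_terms(
        cls,
        space: GenotypeSpace,
        intercept: float,
        terms: Mapping[TermKey, float] | Mapping[tuple, float],
        max_order: int | None = None,
        link: LinkParams | None = None,
    ) -> "EffectSet":
        tensors: dict[tuple[int, ...], np.ndarray] = {}
        for key, value in terms.items():
            if not isinstance(key, TermKey):
                key = TermKey(tuple(key[0]), tuple(key[1]))
            if key.order == 0:
                intercept = intercept + float(value)
                continue
            S = key.sites
            if S not in tensors:
                tensors[S] = np.zeros(tuple(space.shape[i] for i in S))
            tensors[S][key.states] = float(value)
        return cls(space, float(intercept), tensors, max_order, link)

    # -- term access ----------------------------------------------------------

    def term_items(self, include_zero: bool = False) -> Iterator[tuple[TermKey, float]]:
        """Iterate ``(TermKey, value)`` in (order, sites, states) order."""
        for S in sorted(self.tensors, key=lambda s: (len(s), s)):
            t = self.tensors[S]
            for states in itertools.product(*(range(q) for q in t.shape)):
                v = float(t[states])
                if include_zero or v != 0.0:
                    yield TermKey(S, states), v

    def get(self, key: TermKey) -> float:
        if key.order == 0:
            return self.intercept
        t = self.tensors.get(key.sites)
        return 0.0 if t is None else float(t[key.states])

    @property
    def n_nonzero_terms(self) -> int:
        return sum(int(np.count_nonzero(t)) for t in self.tensors.values())

    def zero_sum_violation(self) -> float:
        """Largest absolute sum over any one site's states in any term group."""
        worst = 0.0
        for S, t in self.tensors.items():
            for axis in range(len(S)):
                worst = max(worst, float(np.max(np.abs(t.sum(axis=axis)))))
        return worst

    def is_canonical(self, tol: float = ZERO_SUM_TOL) -> bool:
        return self.zero_sum_violation() <= tol

    # -- prediction -----------------------------------------------------------

    def scores(self, genotypes: np.ndarray) -> np.ndarray:
        """Genetic score of each genotype: intercept plus matching terms."""
        g = self.space.validate_genotypes(genotypes)
        out = np.full(g.shape[0], self.intercept)
        for S, t in self.tensors.items():
            out += t[tuple(g[:, i] for i in S)]
        return out

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        """Predicted phenotype: the score, link-transformed if present."""
        g = np.asarray(genotypes, dtype=np.int64)
        squeeze = g.ndim == 1
        s = self.scores(g)
        y = link_transform(s, self.link) if self.link is not None else s
        y = np.asarray(y, dtype=float)
        return float(y[0]) if squeeze else y

    def predict_all(self) -> np.ndarray:
        from .genotype_space import enumerate_genotypes

        return np.asarray(self.predict(enumerate_genotypes(self.space)))

    def truncate(self, max_order: int) -> "EffectSet":
        tensors = {S: t.copy() for S, t in self.tensors.items() if len(S) <= max_order}
        return EffectSet(self.space, self.intercept, tensors, max_order, self.link)


# ---------------------------------------------------------------------------
# Exact decomposition
# ---------------------------------------------------------------------------


def decompose_tensor(
    y: np.ndarray, n_sites: int, max_order: int
) -> tuple[np.ndarray, dict[tuple[int, ...], np.ndarray]]:
    """Factorial (zero-sum) decomposition of a phenotype tensor.

    ``y`` has the per-site state axes as its *last* ``n_sites`` axes; any
    leading axes are treated as a batch, which lets Monte-Carlo noise
    studies decompose thousands of landscapes in one call.  Returns
    ``(e0, {sites: effect tensor})`` with matching batch axes.
    """
    nd = y.ndim
    site_axis = lambda i: nd - n_sites + i  # noqa: E731
    e0 = y.mean(axis=tuple(range(nd - n_sites, nd)))
    tensors: dict[tuple[int, ...], np.ndarray] = {}
    for k in range(1, max_order + 1):
        for S in itertools.combinations(range(n_sites), k):
            other = tuple(site_axis(i) for i in range(n_sites) if i not in S)
            m = y.mean(axis=other) if other else y.copy()
            # subtract the expectation from all lower-order effects
            m -= np.expand_dims(e0, tuple(range(-k, 0)))
            for r in range(1, k):
                for T in itertools.combinations(S, r):
                    keep = [S.index(i) for i in T]
                    drop = tuple(
                        -(k - j) for j in range(k) if j not in keep
                    )
                    m -= np.expand_dims(tensors[T], drop)
            tensors[S] = m
    return e0, tensors


def exact_effects(table: PhenotypeTable, max_order: int) -> EffectSet:
    """Reference-free effects of a completely sampled landscape.

    Every order-k effect is the subset-mean phenotype minus the
    expectation from lower orders; the order-n model reproduces each mean
    phenotype exactly.  Raises :class:`IncompleteDataError` on partial
    tables — fit those with :func:`rfa.rfa_regress.fit` instead.
    """
    if not 0 <= max_order <= table.space.n_sites:
        raise ValueError(
            f"max_order must be in [0, {table.space.n_sites}], got {max_order}"
        )
    y = table.mean_tensor()
    e0, tensors = decompose_tensor(y, table.space.n_sites, max_order)
    return EffectSet(table.space, float(e0), tensors, max_order)


# ---------------------------------------------------------------------------
# Variance partition
# ---------------------------------------------------------------------------


@dataclass
class VariancePartition:
    """Phenotypic variance attributed to each term, order, and site set.

    The contribution of a term with sites ``S`` is its squared magnitude
    times ``prod_{i in S} 1/q_i`` — the fraction of genotypes that carry
    the term.  On a complete full-order decomposition the contributions
    sum to the empirical variance of the mean phenotypes.
    """

    per_term: dict[TermKey, float]
    per_order: dict[int, float]
    per_site_set: dict[tuple[int, ...], float]
    total: float

    def fraction_by_order(self) -> dict[int, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.per_order}
        return {k: v / self.total for k, v in self.per_order.items()}


def variance_partition(effects: EffectSet) -> VariancePartition:
    if not effects.is_canonical():
        raise ValueError(
            "effects are not in canonical zero-sum form "
            f"(violation {effects.zero_sum_violation():.3g})"
        )
    shape = effects.space.shape
    per_term: dict[TermKey, float] = {}
    per_order: dict[int, float] = {}
    per_site_set: dict[tuple[int, ...], float] = {}
    for S, t in sorted(effects.tensors.items(), key=lambda kv: (len(kv[0]), kv[0])):
        w = math.prod(1.0 / shape[i] for i in S)
        contrib = t**2 * w
        per_site_set[S] = float(contrib.sum())
        per_order[len(S)] = per_order.get(len(S), 0.0) + per_site_set[S]
        for states in itertools.product(*(range(shape[i]) for i in S)):
            v = float(contrib[states])
            if v != 0.0:
                per_term[TermKey(S, states)] = v
    total = float(sum(per_order.values()))
    return VariancePartition(per_term, per_order, per_site_set, total)


# ---------------------------------------------------------------------------
# Noise propagation
# ---------------------------------------------------------------------------


def noise_variance(
    space: GenotypeSpace,
    order: int,
    omega: float,
    sites: tuple[int, ...] | None = None,
) -> float:
    """Sampling variance of an exactly computed effect under iid noise.

    With measurement noise of variance ``omega`` on each of the ``N``
    genotypes, an order-k effect has variance ``(q-1)^k omega / q^n`` for
    uniform alphabets; the mixed-alphabet generalization multiplies
    ``(q_i - 1)`` over the involved sites and divides by ``N``.
    """
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if not 0 <= order <= space.n_sites:
        raise ValueError(
            f"order must be in [0, {space.n_sites}], got {order}"
        )
    if sites is not None:
        if len(sites) != order:
            raise ValueError("sites must match the requested order")
        factor = math.prod(space.shape[i] - 1 for i in sites)
    elif space.is_uniform or order == 0:
        factor = (space.shape[0] - 1) ** order
    else:
        raise ValueError(
            "mixed-alphabet space: pass the involved sites explicitly"
        )
    return factor * omega / space.n_genotypes


# ---------------------------------------------------------------------------
# Coefficient decoding (regression support)
# ---------------------------------------------------------------------------


def decode_coefficients(
    space: GenotypeSpace,
    beta: np.ndarray,
    columns: Sequence[TermKey],
    basis: str = "zero_sum",
    reference: np.ndarray | None = None,
    max_order: int | None = None,
    link: LinkParams | None = None,
) -> EffectSet:
    """Decode design-matrix coefficients into canonical zero-sum effects.

    For each site subset the effect tensor is the fitted coefficients
    mapped through the per-site basis matrices, so any of the contrast /
    background / dummy parameterizations decodes to the same canonical
    form when it represents the same function.
    """
    beta = np.asarray(beta, dtype=float)
    if reference is None:
        ref = np.zeros(space.n_sites, dtype=np.int64)
    else:
        ref = space.validate_genotypes(reference)[0]

    by_subset: dict[tuple[int, ...], list[tuple[TermKey, float]]] = {}
    intercept = 0.0
    for key, b in zip(columns, beta):
        if key.order == 0:
            intercept += float(b)
        else:
            by_subset.setdefault(key.sites, []).append((key, float(b)))

    bases = [
        contrast_basis(q, basis, reference=int(ref[i]))
        for i, q in enumerate(space.shape)
    ]
    labels = [
        _decode_labels(q, basis, int(ref[i])) for i, q in enumerate(space.shape)
    ]

    tensors: dict[tuple[int, ...], np.ndarray] = {}
    for S, entries in by_subset.items():
        coef = np.zeros(tuple(len(labels[i]) for i in S))
        for key, b in entries:
            idx = tuple(labels[i].index(s) for i, s in zip(S, key.states))
            coef[idx] = b
        t = coef
        for axis, i in enumerate(S):
            t = np.moveaxis(
                np.tensordot(bases[i], np.moveaxis(t, axis, 0), axes=(1, 0)),
                0,
                axis,
            )
        tensors[S] = t

    if basis in ("background", "dummy", "onehot"):
        # these bases are not orthogonal to the constant: re-center so the
        # decoded effects obey the zero-sum constraints
        eff = EffectSet(space, 0.0, tensors, max_order=space.n_sites)
        # decompose the represented function restricted to the involved orders
        from .genotype_space import enumerate_genotypes

        y = intercept + eff.scores(enumerate_genotypes(space))
        k = max_order
        if k is None:
            k = max((len(S) for S in tensors), default=0)
        e0, tensors = decompose_tensor(
            y.reshape(space.shape), space.n_sites, k
        )
        intercept = float(e0)
        # drop numerical dust introduced by the re-centering
        for t in tensors.values():
            t[np.abs(t) < 1e-12] = 0.0
        tensors = {S: t for S, t in tensors.items() if np.any(t != 0.0)}
    return EffectSet(space, float(intercept), tensors, max_order, link)


def _decode_labels(q: int, basis: str, reference: int) -> list[int]:
    if basis in ("background", "dummy"):
        return [m for m in range(q) if m != reference]
    if basis == "onehot":
        return list(range(q))
    return list(range(q - 1))
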