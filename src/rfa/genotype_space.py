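"""Combinatorial genotype spaces with arbitrary per-site alphabets.

A genotype space is the Cartesian product of per-site state alphabets:
``n`` variable sites, site ``i`` carrying ``q_i >= 2`` states, for a total
of ``N = prod(q_i)`` genotypes.  Genotypes are represented internally as
integer state-index vectors of length ``n``; all user-facing I/O uses the
literal state tokens.

The module also builds the regression design matrices used throughout the
package.  Each model formalism corresponds to a choice of per-site basis
for the ``q_i``-dimensional space of functions of one site:

- ``"zero_sum"`` : scaled Helmert contrasts spanning the zero-sum subspace
  (the canonical reference-free parameterization),
- ``"fourier"``  : orthonormal Helmert contrasts (Walsh-Hadamard for
  binary sites up to scaling),
- ``"background"``: deviation-from-reference coordinates used by
  background-averaged analysis,
- ``"dummy"``    : one-hot indicators of non-reference states
  (reference-based analysis).

A model term of order ``k`` acts on a site subset and its design column is
the elementwise product of the chosen per-site basis columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.linalg import helmert

__all__ = [
    "GenotypeSpace",
    "TermKey",
    "enumerate_genotypes",
    "count_free_terms",
    "site_subsets",
    "contrast_basis",
    "encode_design",
    "DEFAULT_ENUMERATION_CAP",
]

DEFAULT_ENUMERATION_CAP = 2_000_000


class SpaceSizeError(ValueError):
    """Raised when a genotype space is too large to materialize."""


@dataclass(frozen=True)
class TermKey:
    """Identifier of one model term: a site subset plus a state assignment.

    ``sites`` is a strictly increasing tuple of 0-based site indices and
    ``states`` the matching tuple of 0-based state indices.  The order-0
    key ``TermKey((), ())`` denotes the intercept.
    """

    sites: tuple[int, ...]
    states: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.states):
            raise ValueError("sites and states must have equal length")
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("sites must be strictly increasing")

    @property
    def order(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class GenotypeSpace:
    """The combinatorial space defined by per-site state alphabets."""

    site_alphabets: tuple[tuple[str, ...], ...]
    token_delimiter: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        alphas = tuple(tuple(a) for a in self.site_alphabets)
        object.__setattr__(self, "site_alphabets", alphas)
        for i, alpha in enumerate(alphas):
            if len(alpha) < 2:
                raise ValueError(f"site {i + 1} has fewer than 2 states")
            if len(set(alpha)) != len(alpha):
                raise ValueError(f"site {i + 1} has duplicate state tokens")
        if self.token_delimiter == "" and any(
            len(tok) != 1 for alpha in alphas for tok in alpha
        ):
            object.__setattr__(self, "token_delimiter", ":")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_sizes(cls, sizes: Sequence[int]) -> "GenotypeSpace":
        """Space with numeric token alphabets of the given per-site sizes."""
        amino = "ACDEFGHIKLMNPQRSTVWY"
        alphas = []
        for q in sizes:
            if q <= 20:
                alphas.append(tuple(amino[:q]))
            else:
                alphas.append(tuple(str(s) for s in range(q)))
        return cls(tuple(alphas))

    @classmethod
    def uniform(cls, n_states: int, n_sites: int) -> "GenotypeSpace":
        return cls.from_sizes([n_states] * n_sites)

    # -- basic geometry -------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.site_alphabets)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.site_alphabets)

    @property
    def n_genotypes(self) -> int:
        return math.prod(self.shape)

    @property
    def is_uniform(self) -> bool:
        return len(set(self.shape)) == 1

    @property
    def is_binary(self) -> bool:
        return all(q == 2 for q in self.shape)

    # -- genotype representation ---------------------------------------------

    def validate_genotypes(self, genotypes: np.ndarray) -> np.ndarray:
        g = np.atleast_2d(np.asarray(genotypes, dtype=np.int64))
        if g.shape[1] != self.n_sites:
            raise ValueError(
                f"genotypes have {g.shape[1]} sites; space has {self.n_sites}"
            )
        for i, q in enumerate(self.shape):
            col = g[:, i]
            if col.min(initial=0) < 0 or col.max(initial=0) >= q:
                raise ValueError(f"state index out of range at site {i + 1}")
        return g

    def ravel(self, genotypes: np.ndarray) -> np.ndarray:
        """Map state vectors to flat indices (site 0 slowest-varying)."""
        g = self.validate_genotypes(genotypes)
        return np.ravel_multi_index(tuple(g.T), self.shape)

    def unravel(self, indices: np.ndarray) -> np.ndarray:
        return np.stack(np.unravel_index(np.asarray(indices), self.shape), axis=-1)

    def parse_genotype(self, text: str) -> np.ndarray:
        if self.token_delimiter:
            tokens = text.split(self.token_delimiter)
        else:
            tokens = list(text)
        if len(tokens) != self.n_sites:
            raise ValueError(
                f"genotype {text!r} has {len(tokens)} tokens; expected {self.n_sites}"
            )
        out = np.empty(self.n_sites, dtype=np.int64)
        for i, tok in enumerate(tokens):
            try:
                out[i] = self.site_alphabets[i].index(tok)
            except ValueError:
                raise ValueError(
                    f"unknown state {tok!r} at site {i + 1} (alphabet "
                    f"{''.join(self.site_alphabets[i])})"
                ) from None
        return out

    def format_genotype(self, genotype: np.ndarray) -> str:
        g = np.asarray(genotype, dtype=np.int64)
        return self.token_delimiter.join(
            self.site_alphabets[i][g[i]] for i in range(self.n_sites)
        )

    def describe(self) -> dict:
        """JSON-friendly description used by model serialization."""
        return {
            "site_alphabets": [list(a) for a in self.site_alphabets],
            "token_delimiter": self.token_delimiter,
        }

    @classmethod
    def from_description(cls, d: dict) -> "GenotypeSpace":
        return cls(
            tuple(tuple(a) for a in d["site_alphabets"]),
            token_delimiter=d.get("token_delimiter", ""),
        )


def enumerate_genotypes(
    space: GenotypeSpace, cap: int = DEFAULT_ENUMERATION_CAP
) -> np.ndarray:
    """All genotypes of ``space`` as an ``(N, n)`` state-index array.

    Deterministic lexicographic order with site 0 slowest-varying, so row
    ``r`` is ``space.unravel(r)``.
    """
    N = space.n_genotypes
    if N > cap:
        raise SpaceSizeError(
            f"space has {N} genotypes, above the enumeration cap of {cap}"
        )
    return space.unravel(np.arange(N))


def site_subsets(space: GenotypeSpace, max_order: int) -> Iterator[tuple[int, ...]]:
    """Site subsets of order 1..max_order in (order, lexicographic) order."""
    if not 0 <= max_order <= space.n_sites:
        raise ValueError(
            f"max_order must be in [0, {space.n_sites}], got {max_order}"
        )
    for k in range(1, max_order + 1):
        yield from itertools.combinations(range(space.n_sites), k)


def count_free_terms(space: GenotypeSpace, max_order: int) -> int:
    """Number of independent model terms up to the given order.

    Under the zero-sum constraints a site subset ``S`` contributes
    ``prod_{i in S} (q_i - 1)`` free terms; summed over all subsets of size
    up to ``n`` this telescopes to ``N`` itself.
    """
    total = 1  # intercept
    for S in site_subsets(space, max_order):
        total += math.prod(space.shape[i] - 1 for i in S)
    return total


def contrast_basis(q: int, kind: str, reference: int = 0) -> np.ndarray:
    """Per-site basis matrix of shape ``(q, q - 1)``.

    Rows index states, columns index the q-1 free coordinates of the
    chosen formalism.  For ``zero_sum`` and ``fourier`` the columns are
    orthogonal to the constant vector, so on a complete factorial design
    the blocks of different site subsets are mutually orthogonal.
    """
    if kind == "fourier":
        return helmert(q, full=False).T  # orthonormal columns
    if kind == "zero_sum":
        # scaled so each column has unit mean square (+/-1 when q == 2),
        # which equalizes the L1 penalty across sites of different size
        return helmert(q, full=False).T * math.sqrt(q)
    if kind == "background":
        # column m (non-reference state m): delta_{s,m} - 1/q
        cols = [m for m in range(q) if m != reference]
        B = -np.ones((q, q - 1)) / q
        for j, m in enumerate(cols):
            B[m, j] += 1.0
        return B
    if kind == "dummy":
        cols = [m for m in range(q) if m != reference]
        B = np.zeros((q, q - 1))
        for j, m in enumerate(cols):
            B[m, j] = 1.0
        return B
    if kind == "onehot":
        # overcomplete: one indicator per state; L1 regularization (or the
        # minimum-norm solution) resolves the non-identifiability, and
        # decoding re-centers into canonical zero-sum form.  This is the
        # parameterization whose terms ARE per-state effects, so an
        # unsampled genotype's prediction involves only its own states.
        return np.eye(q)
    raise ValueError(f"unknown basis kind {kind!r}")


def _basis_state_labels(q: int, kind: str, reference: int = 0) -> list[int]:
    """State index each basis column refers to (basis ordinal for contrasts)."""
    if kind in ("background", "dummy"):
        return [m for m in range(q) if m != reference]
    if kind == "onehot":
        return list(range(q))
    return list(range(q - 1))


def encode_design(
    space: GenotypeSpace,
    genotypes: np.ndarray,
    max_order: int,
    basis: str = "zero_sum",
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, list[TermKey]]:
    """Design matrix for a truncated model in the requested formalism.

    Returns ``(X, columns)`` where ``X`` has one all-ones intercept column
    followed by one column per free term, and ``columns`` maps each column
    to a :class:`TermKey`.  For contrast bases (``zero_sum``/``fourier``)
    the key's ``states`` are basis-column ordinals, not literal states;
    decoding into canonical per-state effects is done by
    :func:`rfa.rfa_exact.decode_coefficients`.
    """
    g = space.validate_genotypes(genotypes)
    if reference is None:
        ref = np.zeros(space.n_sites, dtype=np.int64)
    else:
        ref = space.validate_genotypes(reference)[0]

    site_cols: list[np.ndarray] = []  # per site: (R, q_i - 1) basis values
    for i, q in enumerate(space.shape):
        B = contrast_basis(q, basis, reference=int(ref[i]))
        site_cols.append(B[g[:, i], :])

    R = g.shape[0]
    blocks: list[np.ndarray] = [np.ones((R, 1))]
    columns: list[TermKey] = [TermKey((), ())]
    for S in site_subsets(space, max_order):
        labels = [
            _basis_state_labels(space.shape[i], basis, reference=int(ref[i]))
            for i in S
        ]
        sizes = [len(lab) for lab in labels]
        # product of per-site basis columns, all combinations
        block = np.ones((R, math.prod(sizes)))
        for axis, i in enumerate(S):
            reps_after = math.prod(sizes[axis + 1 :])
            reps_before = math.prod(sizes[:axis])
            idx = np.tile(
                np.repeat(np.arange(sizes[axis]), reps_after), reps_before
            )
            block *= site_cols[i][:, idx]
        blocks.append(block)
        for combo in itertools.product(*labels):
            columns.append(TermKey(tuple(S), tuple(combo)))
    X = np.concatenate(blocks, axis=1)
    return X, columns
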