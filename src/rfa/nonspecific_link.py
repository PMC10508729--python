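"""Sigmoid link between genetic score and observed phenotype.

Nonspecific (global) epistasis is modeled as a monotone transformation of
the genetic score ``s`` — the sum of an intercept and the reference-free
effects of the states carried by a genotype — into the measured phenotype:

    y = L + (U - L) / (1 + exp(-s))

with ``L`` and ``U`` the lower and upper bounds of the measurable
phenotype.  The sigmoid admits a two-state thermodynamic reading: the
functional state has phenotype ``U``, the nonfunctional state ``L``, and
``s`` plays the role of -dG/kT, so ``exp(s)`` is the relative occupancy of
the functional state and ``exp(s)/(1+exp(s))`` its absolute occupancy.
Score differences thereby convert to fold changes in occupancy and to
free-energy differences in physical units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinkParams",
    "link_transform",
    "inverse_link",
    "occupancy",
    "fold_change",
    "score_to_ddG",
    "BOLTZMANN_KCAL_PER_MOL_K",
    "BODY_TEMPERATURE_K",
]

logger = logging.getLogger(__name__)

#: Boltzmann constant times Avogadro's number, kcal / (mol K).
BOLTZMANN_KCAL_PER_MOL_K = 1.987204259e-3

#: 37 degrees Celsius, the default temperature for dG conversions.
BODY_TEMPERATURE_K = 310.15

DEFAULT_CLIP_EPSILON = 1e-6


@dataclass(frozen=True)
class LinkParams:
    """Bounds of the sigmoid link; ``U`` must exceed ``L``."""

    L: float
    U: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L) and np.isfinite(self.U)):
            raise ValueError("link bounds must be finite")
        if self.U <= self.L:
            raise ValueError(f"require U > L, got L={self.L}, U={self.U}")

    @property
    def range(self) -> float:
        return self.U - self.L

    @property
    def n_parameters(self) -> int:
        return 2


def link_transform(s, link: LinkParams):
    """Map genetic score(s) to phenotype: ``L + (U - L)/(1 + e^{-s})``."""
    s = np.asarray(s, dtype=float)
    out = link.L + link.range * _expit(s)
    return float(out) if out.ndim == 0 else out


def _expit(s: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(s, dtype=float)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    es = np.exp(s[~pos])
    out[~pos] = es / (1.0 + es)
    return out


def inverse_link(y, link: LinkParams, epsilon: float = DEFAULT_CLIP_EPSILON):
    """Score whose link transform equals ``y``, with clipping at the bounds.

    Phenotypes at or beyond the bounds have no finite preimage and are
    clipped into ``[L + eps*(U-L), U - eps*(U-L)]`` first; near-bound
    values amplify measurement noise dramatically, which is why the
    package fits the link jointly rather than by inverse transformation.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype values must be finite")
    lo = link.L + epsilon * link.range
    hi = link.U - epsilon * link.range
    n_clipped = int(np.sum((y < lo) | (y > hi)))
    if n_clipped:
        logger.warning(
            "inverse_link: clipped %d value(s) outside the open link range",
            n_clipped,
        )
    yc = np.clip(y, lo, hi)
    p = (yc - link.L) / link.range
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def occupancy(s):
    """Absolute equilibrium occupancy of the functional state: e^s/(1+e^s)."""
    s = np.asarray(s, dtype=float)
    out = _expit(s)
    return float(out) if out.ndim == 0 else out


def fold_change(delta_s):
    """Multiplicative change in relative occupancy for a score change."""
    out = np.exp(np.asarray(delta_s, dtype=float))
    return float(out) if out.ndim == 0 else out


def score_to_ddG(delta_s, temperature_kelvin: float = BODY_TEMPERATURE_K):
    """Free-energy equivalent of a score change, in kcal/mol.

    The score is dG in units of -kT, so ddG = -delta_s * kB * T; a
    favorable (positive) score change maps to a negative ddG.
    """
    if temperature_kelvin <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    out = -np.asarray(delta_s, dtype=float) * (
        BOLTZMANN_KCAL_PER_MOL_K * temperature_kelvin
    )
    return float(out) if out.ndim == 0 else out


def _sigfig(x: float, digits: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)
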