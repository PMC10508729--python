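"""Synthetic genetic architectures, noisy phenotypes, and experiment runners.

The generators double as the test-fixture factory for the package.  An
architecture is drawn in a chosen formalism (reference-based by default
for the missing-genotype experiment, mirroring how such benchmarks are
usually set up; reference-free when exact control over which orders are
populated is needed), converted to canonical reference-free form, and
pushed through an optional sigmoid link plus iid Gaussian measurement
noise to produce phenotype tables.

Three experiment runners quantify the method's robustness claims:

- ``run_noise_experiment``: per-order error SD of exactly computed
  reference-free vs reference-based effects under measurement noise;
  both estimators are linear in the data, so the error distribution is
  computed directly from noise draws.
- ``run_missing_experiment``: out-of-sample R^2 of regression-fitted
  reference-free / Fourier / background-averaged models versus the
  fraction of genotypes sampled.
- ``run_truncation_experiment``: truncated fits to a third-order-only
  architecture under a sigmoid link — lower-order models should explain
  approximately zero variance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formalisms import RBAModel, convert
from .genotype_space import GenotypeSpace, TermKey, enumerate_genotypes, site_subsets
from .nonspecific_link import LinkParams, link_transform
from .rfa_exact import (
    EffectSet,
    PhenotypeTable,
    decompose_tensor,
    noise_variance,
)
from .rfa_regress import FitConfig, cross_validate, fit, out_of_sample_r2

__all__ = [
    "SimulationSpec",
    "simulate_architecture",
    "simulate_phenotypes",
    "sample_table",
    "run_noise_experiment",
    "run_missing_experiment",
    "run_truncation_experiment",
]


@dataclass(frozen=True)
class SimulationSpec:
    """A stated world for one synthetic landscape.

    ``orders`` lists the epistatic orders carrying nonzero effects;
    ``formalism`` is the parameterization the effects are drawn in
    (standard-normal draws by default).  Drawing in the reference-free
    formalism gives exact control over the populated orders; drawing
    reference-based effects and converting induces nonzero lower-order
    reference-free terms, as it should.
    """

    space: GenotypeSpace
    orders: tuple[int, ...] = (1, 2, 3)
    effect_sd: float = 1.0
    formalism: str = "reference_free"
    link: LinkParams | None = None
    omega: float = 0.0
    sampling_fraction: float = 1.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 or k > self.space.n_sites for k in self.orders):
            raise ValueError("orders must lie in [1, n_sites]")
        if not 0.0 < self.sampling_fraction <= 1.0:
            raise ValueError("sampling fraction must be in (0, 1]")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")


def simulate_architecture(spec: SimulationSpec) -> EffectSet:
    """Draw a ground-truth architecture, canonicalized to zero-sum form."""
    rng = np.random.default_rng(spec.seed)
    space = spec.space
    max_order = max(spec.orders)
    if spec.formalism in ("reference_free", "rfa"):
        tensors: dict[tuple[int, ...], np.ndarray] = {}
        for S in site_subsets(space, max_order):
            if len(S) not in spec.orders:
                continue
            shape = tuple(space.shape[i] for i in S)
            t = rng.normal(0.0, spec.effect_sd, size=shape)
            scale = 1.0
            for axis, i in enumerate(S):
                t = t - t.mean(axis=axis, keepdims=True)
                q = space.shape[i]
                scale *= math.sqrt(q / (q - 1))
            tensors[S] = t * scale  # restore unit marginal SD after centering
        return EffectSet(space, 0.0, tensors, max_order, spec.link)
    if spec.formalism in ("reference_based", "rba"):
        ref = np.zeros(space.n_sites, dtype=np.int64)
        terms: dict[TermKey, float] = {}
        for S in site_subsets(space, max_order):
            if len(S) not in spec.orders:
                continue
            choices = [range(1, space.shape[i]) for i in S]
            for states in itertools.product(*choices):
                terms[TermKey(tuple(S), tuple(states))] = float(
                    rng.normal(0.0, spec.effect_sd)
                )
        rba = RBAModel(space, ref, 0.0, terms, max_order)
        eff = convert(rba, "rfa")
        eff.link = spec.link
        return eff
    raise ValueError(f"unknown formalism {spec.formalism!r}")


def simulate_phenotypes(
    truth: EffectSet,
    omega: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> PhenotypeTable:
    """Complete phenotype table: link(score) plus N(0, omega) per replicate."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    genotypes = enumerate_genotypes(truth.space)
    clean = np.asarray(truth.predict(genotypes), dtype=float)
    rng = np.random.default_rng(seed)
    y = clean[:, None] + rng.normal(
        0.0, math.sqrt(omega), size=(len(clean), n_replicates)
    )
    return PhenotypeTable(truth.space, genotypes, y)


def simulate_table(spec: SimulationSpec) -> tuple[EffectSet, PhenotypeTable]:
    """Architecture plus (possibly subsampled) phenotype table for a spec."""
    ss = np.random.SeedSequence(spec.seed)
    arch_seed, noise_seed, samp_seed = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    ]
    truth = simulate_architecture(replace(spec, seed=arch_seed))
    table = simulate_phenotypes(
        truth, spec.omega, spec.n_replicates, seed=noise_seed
    )
    if spec.sampling_fraction < 1.0:
        table = sample_table(table, spec.sampling_fraction, seed=samp_seed)
    return truth, table


def sample_table(
    table: PhenotypeTable, fraction: float, seed: int = 0
) -> PhenotypeTable:
    """Random without-replacement subsample of a table's rows."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = max(2, int(round(fraction * table.n_rows)))
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(table.n_rows, size=n, replace=False))
    return table.subset(rows)


# ---------------------------------------------------------------------------
# Experiment runners
# ---------------------------------------------------------------------------


def _rba_noise_operator(space: GenotypeSpace):
    """Sparse (signs, indices) representation of full-order RBA terms as
    linear functionals of the phenotype vector."""
    ref = np.zeros(space.n_sites, dtype=np.int64)
    rows: list[tuple[int, list[int], list[float]]] = []
    for S in site_subsets(space, space.n_sites):
        choices = [range(1, space.shape[i]) for i in S]
        for states in itertools.product(*choices):
            idxs, signs = [], []
            for r in range(len(S) + 1):
                for T in itertools.combinations(range(len(S)), r):
                    g = ref.copy()
                    for j in T:
                        g[S[j]] = states[j]
                    idxs.append(int(space.ravel(g[None, :])[0]))
                    signs.append((-1.0) ** (len(S) - r))
            rows.append((len(S), idxs, signs))
    return rows


def run_noise_experiment(
    n_states: int = 3,
    n_sites: int = 5,
    omega: float = 1.0,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-order error SD of exact reference-free vs reference-based effects.

    Both exact estimators are linear maps of the phenotype vector, so the
    estimation error (estimate minus truth) equals the same map applied
    to the noise alone; the underlying architecture drops out.  The
    reference-free error SD should match the analytic law
    ``sqrt((q-1)^k omega / q^n)`` while the reference-based error grows
    with epistatic order.
    """
    space = GenotypeSpace.uniform(n_states, n_sites)
    rng = np.random.default_rng(seed)
    noise = rng.normal(
        0.0, math.sqrt(omega), size=(n_reps,) + space.shape
    )

    records = []
    _, tensors = decompose_tensor(noise, n_sites, n_sites)
    by_order: dict[int, list[np.ndarray]] = {}
    for S, t in tensors.items():
        by_order.setdefault(len(S), []).append(t.reshape(n_reps, -1))
    for k in sorted(by_order):
        errs = np.concatenate(by_order[k], axis=1)
        records.append(
            {
                "formalism": "rfa",
                "order": k,
                "sd_error": float(errs.std()),
                "n_terms": errs.shape[1],
                "analytic_sd": math.sqrt(noise_variance(space, k, omega)),
            }
        )

    flat = noise.reshape(n_reps, -1)
    rba_by_order: dict[int, list[np.ndarray]] = {}
    for k, idxs, signs in _rba_noise_operator(space):
        rba_by_order.setdefault(k, []).append(
            flat[:, idxs] @ np.asarray(signs)
        )
    for k in sorted(rba_by_order):
        errs = np.stack(rba_by_order[k], axis=1)
        records.append(
            {
                "formalism": "rba",
                "order": k,
                "sd_error": float(errs.std()),
                "n_terms": errs.shape[1],
                "analytic_sd": math.sqrt((2.0**k) * omega),
            }
        )
    return pd.DataFrame.from_records(records)


_METHOD_BASIS = {"rfa": "onehot", "fourier": "fourier", "ba": "background"}


def run_missing_experiment(
    spaces: list[tuple[int, int]] | None = None,
    fractions: tuple[float, ...] = (0.02, 0.05, 0.1, 0.25),
    methods: tuple[str, ...] = ("rfa", "fourier", "ba"),
    n_trials: int = 20,
    max_order: int = 3,
    lam: float | str = "auto",
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-sample R^2 versus sampling fraction for the three averaging
    formalisms, on architectures drawn from standard-normal
    reference-based effects up to third order.

    ``lam="auto"`` uses a single weak L1 strength of ``1e-3 * var(y)``
    for every method; the comparison is between encodings, not between
    regularization schedules.
    """
    spaces = spaces if spaces is not None else [(4, 6), (16, 3)]
    ss = np.random.SeedSequence(seed)
    records = []
    for (q, n), child in zip(spaces, ss.spawn(len(spaces))):
        space = GenotypeSpace.uniform(q, n)
        for trial, tchild in enumerate(child.spawn(n_trials)):
            s1, s2 = [int(c.generate_state(1)[0] % 2**31) for c in tchild.spawn(2)]
            truth = simulate_architecture(
                SimulationSpec(
                    space,
                    orders=tuple(range(1, max_order + 1)),
                    formalism="reference_based",
                    seed=s1,
                )
            )
            table = simulate_phenotypes(truth, omega=0.0, seed=s2)
            lam_val = (
                1e-3 * float(np.var(table.mean_phenotypes))
                if lam == "auto"
                else float(lam)
            )
            config = FitConfig(max_order=max_order, use_link=False)
            rng = np.random.default_rng(s2)
            for fraction in fractions:
                n_train = max(2, int(round(fraction * table.n_rows)))
                if n_train >= table.n_rows:
                    # complete sampling: refit on all rows, evaluate in-sample
                    train = test = table
                else:
                    rows = rng.choice(table.n_rows, size=n_train, replace=False)
                    train = table.subset(np.sort(rows))
                    mask = np.ones(table.n_rows, dtype=bool)
                    mask[rows] = False
                    test = table.subset(np.where(mask)[0])
                for method in methods:
                    res = fit(
                        train, config, lam=lam_val,
                        basis=_METHOD_BASIS[method],
                    )
                    r2 = out_of_sample_r2(res.effects, test)
                    records.append(
                        {
                            "space": f"{q}^{n}",
                            "fraction": fraction,
                            "method": method,
                            "trial": trial,
                            "r2": r2,
                        }
                    )
    return pd.DataFrame.from_records(records)


def run_truncation_experiment(
    n_states: int = 3,
    n_sites: int = 5,
    link: LinkParams = LinkParams(0.0, 1.0),
    fit_orders: tuple[int, ...] = (1, 2, 3),
    fractions: tuple[float, ...] = (1.0, 0.5),
    config: FitConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit truncated models to a third-order-only architecture.

    The truth carries only third-order reference-free effects, passed
    through a sigmoid; first- and second-order fits should explain
    approximately zero phenotypic variance (no leakage of high-order
    variation into low-order terms), while the third-order fit should
    capture essentially all of it.
    """
    space = GenotypeSpace.uniform(n_states, n_sites)
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
    truth = simulate_architecture(
        SimulationSpec(space, orders=(3,), link=link, seed=s1)
    )
    table = simulate_phenotypes(truth, omega=0.0, seed=s2)
    if config is None:
        config = FitConfig(
            use_link=True, n_lambda=10, cv_folds=5, cv_repeats=1,
            grad_tol=1e-7,
        )
    records = []
    rng = np.random.default_rng(s3)
    for fraction in fractions:
        if fraction < 1.0:
            rows = np.sort(
                rng.choice(
                    table.n_rows,
                    size=max(2, int(round(fraction * table.n_rows))),
                    replace=False,
                )
            )
            sub = table.subset(rows)
        else:
            sub = table
        for k in fit_orders:
            res = cross_validate(sub, replace(config, max_order=k))
            row = res.cv_table.loc[
                res.cv_table["lambda"] == res.chosen_lambda
            ].iloc[0]
            records.append(
                {
                    "order": k,
                    "fraction": fraction,
                    # pooled predict-the-rest R2 (small-sample bias of the
                    # per-fold average would mask a true zero)
                    "r2_cv": float(row["pooled_r2"]),
                    "r2_in_sample": res.r2_in_sample,
                    "chosen_lambda": res.chosen_lambda,
                }
            )
    return pd.DataFrame.from_records(records)
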