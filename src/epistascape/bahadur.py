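"""Bahadur (Walsh-type) orthonormal expansion of binary-genotype landscapes.

Any function f on the n-cube decomposes exactly over the 2**n interaction
terms phi_S(x) = prod_{i in S} z_i(x), where z_i is the +/-1 encoding of
locus i (wild type -1, mutant +1) and S ranges over subsets of loci:

    f(x) = sum_S w_S * phi_S(x),        w_S = 2**-n * sum_x f(x) * phi_S(x)

phi_{} is the constant 1, so w_{} is the landscape mean; |S| = 1 terms are
additive locus effects, |S| = 2 pairwise epistasis, and so on.  The columns
of the psi matrix (genotypes x terms) are mutually orthogonal with squared
norm 2**n, which makes the coefficient fit an exact projection: including
all terms reconstructs the data with R^2 = 1, and truncating at a maximum
interaction order measures how much of the landscape low-order effects
explain.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_space import Genotype, Subnetwork, enumerate_genotypes, z_encode
from .landscape import ParameterLandscape

__all__ = [
    "InteractionBasis",
    "BahadurModel",
    "build_basis",
    "fit_coefficients",
    "reconstruct",
    "r2_profile",
    "subnetwork_r2",
    "coefficient_of_determination",
]

_MAX_N = 12


@dataclass(frozen=True)
class InteractionBasis:
    """Ordered interaction-term basis for the n-cube.

    ``terms[i]`` is the tuple of locus indices of term i (cardinality-major,
    lexicographic within cardinality: (), (0,), (1,), ..., (0,1), ...).
    ``psi[x, i]`` is phi_i evaluated at the x-th genotype in binary-ascending
    order.
    """

    n: int
    terms: tuple[tuple[int, ...], ...]
    psi: np.ndarray

    @property
    def genotypes(self) -> list[Genotype]:
        return enumerate_genotypes(self.n)

    def term_order(self) -> np.ndarray:
        """Cardinality of each term."""
        return np.array([len(t) for t in self.terms])


def build_basis(n: int) -> InteractionBasis:
    """Construct the full 2**n x 2**n psi matrix of +/-1 interaction values."""
    if not 1 <= n <= _MAX_N:
        raise ValueError(f"locus count must be in [1, {_MAX_N}], got {n}")
    terms = tuple(
        subset
        for order in range(n + 1)
        for subset in itertools.combinations(range(n), order)
    )
    genotypes = enumerate_genotypes(n)
    z = np.array([z_encode(g) for g in genotypes], dtype=float)  # (2^n, n)
    psi = np.empty((2**n, 2**n))
    for i, subset in enumerate(terms):
        psi[:, i] = z[:, subset].prod(axis=1) if subset else 1.0
    return InteractionBasis(n=n, terms=terms, psi=psi)


@dataclass
class BahadurModel:
    """Fitted coefficients over an interaction basis."""

    basis: InteractionBasis
    w: np.ndarray  # one coefficient per basis term
    fitness_source: str = ""

    def coefficient(self, subset: tuple[int, ...]) -> float:
        return float(self.w[self.basis.terms.index(tuple(sorted(subset)))])


def _fitness_vector(fitness: dict[Genotype, float], basis: InteractionBasis) -> np.ndarray:
    genotypes = basis.genotypes
    missing = [g.label for g in genotypes if g not in fitness]
    if missing:
        raise ValueError(f"fitness map incomplete; missing genotypes: {missing}")
    return np.array([fitness[g] for g in genotypes], dtype=float)


def fit_coefficients(
    fitness: dict[Genotype, float],
    basis: InteractionBasis,
    fitness_source: str = "",
) -> BahadurModel:
    """Exact orthonormal projection: w_i = 2**-n * sum_x f(x) phi_i(x)."""
    f = _fitness_vector(fitness, basis)
    w = basis.psi.T @ f / 2**basis.n
    return BahadurModel(basis=basis, w=w, fitness_source=fitness_source)


def reconstruct(model: BahadurModel, max_order: int) -> dict[Genotype, float]:
    """Evaluate the expansion keeping terms of cardinality <= max_order."""
    n = model.basis.n
    if not 0 <= max_order <= n:
        raise ValueError(f"max_order must be in [0, {n}], got {max_order}")
    keep = model.basis.term_order() <= max_order
    values = model.basis.psi[:, keep] @ model.w[keep]
    return dict(zip(model.basis.genotypes, values.tolist()))


def coefficient_of_determination(observed: np.ndarray, predicted: np.ndarray) -> float:
    """R^2 = 1 - SS_res / SS_tot.  Returns nan (with a warning) when the
    observed values have zero variance."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    ss_res = float(np.sum((observed - predicted) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined: observed values have zero variance", stacklevel=2)
        return math.nan
    return 1.0 - ss_res / ss_tot


def pearson_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation; coincides with the coefficient of
    determination for full-rank orthonormal projections with an intercept."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if np.std(observed) == 0 or np.std(predicted) == 0:
        return math.nan
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


def r2_profile(model: BahadurModel, data: dict[Genotype, float]) -> dict[int, float]:
    """R^2 of the truncated reconstruction against ``data`` for each maximum
    order 1..n; reaches exactly 1.0 at full order."""
    f = _fitness_vector(data, model.basis)
    orders = model.basis.term_order()
    out: dict[int, float] = {}
    for max_order in range(1, model.basis.n + 1):
        keep = orders <= max_order
        pred = model.basis.psi[:, keep] @ model.w[keep]
        out[max_order] = coefficient_of_determination(f, pred)
    # projection onto the complete basis is exact up to float roundoff
    if math.isfinite(out[model.basis.n]) and abs(out[model.basis.n] - 1.0) < 1e-9:
        out[model.basis.n] = 1.0
    return out


_BASIS_2 = None


def _two_locus_basis() -> InteractionBasis:
    global _BASIS_2
    if _BASIS_2 is None:
        _BASIS_2 = build_basis(2)
    return _BASIS_2


def subnetwork_fitness(landscape: ParameterLandscape, sub: Subnetwork) -> dict[Genotype, float]:
    """Log-scale fitness of the four square members relative to the
    subnetwork's own background, keyed by the reduced 2-locus genotype."""
    bg, single_a, single_b, double = sub.members
    v_bg = landscape.value(bg)
    if v_bg <= 0:
        raise ValueError(f"background {bg.label} has non-positive value")
    out = {}
    for reduced, member in zip(enumerate_genotypes(2), (bg, single_a, single_b, double)):
        v = landscape.value(member)
        if v <= 0:
            raise ValueError(f"member {member.label} has non-positive value")
        out[reduced] = math.log10(v / v_bg)
    out[Genotype((0, 0))] = 0.0
    return out


def subnetwork_r2(landscape: ParameterLandscape, sub: Subnetwork) -> float:
    """First-order R^2 of the 2-locus expansion on one square.

    1.0 means the two mutations act additively on the log scale; the
    shortfall from 1 is carried entirely by the single pairwise term.
    """
    basis = _two_locus_basis()
    fitness = subnetwork_fitness(landscape, sub)
    model = fit_coefficients(fitness, basis)
    return r2_profile(model, fitness)[1]
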