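"""Ground-truth landscape and dose-response simulators.

The generator works backwards through the analysis chain: a true fitness
landscape is specified by interaction coefficients (the expansion used
generatively), each genotype's fitness is realized as a Hill dose-response
parameter set anchored at a wild-type-like reference curve, and replicate
fluorescence measurements are drawn with multiplicative Gaussian noise on
the ligand concentration series of the real assay.  Every stage of the
pipeline can therefore be tested against known truth.

The default assay conditions mirror the combinatorial biosensor experiment:
16 variants over 4 loci, naringenin assayed at 0-2000 uM and resveratrol at
0-250 uM on fixed 12-point series, 3 biological replicates (optionally
topped up to 6 for noisy variants), and a 6-replicate constitutive sfGFP
positive control measured alongside for normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .bahadur import build_basis
from .genotype_space import Genotype, enumerate_genotypes
from .landscape import PARAMETER_NAMES, ParameterLandscape

__all__ = [
    "TrueLandscapeSpec",
    "AssaySpec",
    "HillParams",
    "DEFAULT_ANCHOR",
    "NARINGENIN_SERIES",
    "RESVERATROL_SERIES",
    "landscape_from_coefficients",
    "hill_params_from_fitness",
    "simulate_assay",
    "simulate_dataset",
    "random_coefficients",
]

NARINGENIN_SERIES = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0, 250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0)
RESVERATROL_SERIES = (0.0, 2.5, 5.0, 7.5, 10.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 250.0)

CONTROL_VARIANT = "sfGFP_control"
CONTROL_REPLICATES = 6


class HillParams(NamedTuple):
    """True dose-response parameters of one variant."""

    f_baseline: float
    f_max: float
    ec50: float
    n_hill: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(x > 0, x**self.n_hill / (self.ec50**self.n_hill + x**self.n_hill), 0.0)
        return self.f_baseline + (self.f_max - self.f_baseline) * frac


# Wild-type-like reference curve: moderate basal expression, ~29-fold
# induction at the top of the resveratrol series, mid-series EC50.
DEFAULT_ANCHOR = HillParams(f_baseline=100.0, f_max=3000.0, ec50=50.0, n_hill=2.0)


@dataclass(frozen=True)
class TrueLandscapeSpec:
    """Interaction-coefficient parameterization of a true fitness landscape.

    ``coefficients`` maps locus-index subsets (tuples) to coefficient
    values; unlisted subsets are zero.
    """

    n: int
    coefficients: dict[tuple[int, ...], float]
    seed: int = 0

    def __post_init__(self) -> None:
        for subset in self.coefficients:
            if any(not 0 <= i < self.n for i in subset):
                raise ValueError(f"subset {subset} out of range for n={self.n}")
            if len(set(subset)) != len(subset):
                raise ValueError(f"subset {subset} has repeated loci")


@dataclass(frozen=True)
class AssaySpec:
    """Measurement design: concentration series, replication and noise."""

    ligand: str = "resveratrol"
    concentrations: tuple[float, ...] = RESVERATROL_SERIES
    replicates: int = 3
    cv: float = 0.05  # multiplicative Gaussian noise, sd/mean
    control_drift: float = 0.0  # fractional control fold-change at top conc
    control_level: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        concs = tuple(float(c) for c in self.concentrations)
        if concs[0] != 0.0 or any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentration series must start at 0 and strictly increase")
        if self.cv < 0:
            raise ValueError("noise CV must be non-negative")
        if self.replicates < 1:
            raise ValueError("at least one replicate required")
        object.__setattr__(self, "concentrations", concs)

    @property
    def top(self) -> float:
        return self.concentrations[-1]

    def control_factor(self, x: float) -> float:
        """Multiplicative control fold change at concentration x (linear ramp
        from 1 at zero ligand to 1 + control_drift at the top)."""
        return 1.0 + self.control_drift * (x / self.top)


def landscape_from_coefficients(spec: TrueLandscapeSpec) -> dict[Genotype, float]:
    """Evaluate the interaction expansion at every genotype of the n-cube."""
    basis = build_basis(spec.n)
    w = np.zeros(2**spec.n)
    for subset, value in spec.coefficients.items():
        if not math.isfinite(value):
            raise ValueError(f"non-finite coefficient for subset {subset}")
        w[basis.terms.index(tuple(sorted(subset)))] = value
    values = basis.psi @ w
    return dict(zip(basis.genotypes, values.tolist()))


def random_coefficients(
    n: int, rng: np.random.Generator, scale_by_order: float = 0.5, magnitude: float = 0.4
) -> dict[tuple[int, ...], float]:
    """Random coefficient set with geometrically decaying interaction orders
    (realistic landscapes are dominated by low-order effects); the constant
    term is omitted so wild-type-relative fitness is well scaled."""
    basis = build_basis(n)
    out = {}
    for subset in basis.terms:
        if not subset:
            continue
        out[subset] = rng.normal(0.0, magnitude * scale_by_order ** (len(subset) - 1))
    return out


def hill_params_from_fitness(
    fitness: dict[Genotype, float],
    anchor: HillParams = DEFAULT_ANCHOR,
    mode: str = "fold_induction",
    top_concentration: float = RESVERATROL_SERIES[-1],
) -> dict[Genotype, HillParams]:
    """Realize a fitness landscape as per-variant Hill parameter sets.

    The landscape is carried by a single functional parameter (``mode``); the
    wild type (all zeros) reproduces the anchor curve exactly and every other
    genotype's parameter is anchor * 10**(fitness - wild-type fitness), so
    the log-relative fitness of the generated parameters equals the input
    landscape exactly.

    * ``fold_induction`` — F_max is adjusted so the predicted fluorescence
      at ``top_concentration`` over basal hits the target ratio;
    * ``basal`` — the whole curve is scaled (basal carries the signal;
      fold induction stays constant);
    * ``maximum`` — the predicted top-concentration fluorescence is scaled
      by adjusting F_max;
    * ``ec50`` — EC50 is scaled directly.
    """
    if mode not in PARAMETER_NAMES:
        raise ValueError(f"mode must be one of {PARAMETER_NAMES}, got {mode!r}")
    if any(not math.isfinite(v) for v in fitness.values()):
        raise ValueError("fitness values must be finite")
    n = next(iter(fitness)).n
    wt = Genotype((0,) * n)
    f_wt = fitness[wt]
    h = float(top_concentration**anchor.n_hill / (anchor.ec50**anchor.n_hill + top_concentration**anchor.n_hill))
    anchor_max = float(anchor.predict(top_concentration))
    anchor_fi = anchor_max / anchor.f_baseline

    out: dict[Genotype, HillParams] = {}
    for g, f in fitness.items():
        rel = 10.0 ** (f - f_wt)
        if mode == "fold_induction":
            fi = anchor_fi * rel
            fmax = anchor.f_baseline + anchor.f_baseline * (fi - 1.0) / h
            out[g] = HillParams(anchor.f_baseline, fmax, anchor.ec50, anchor.n_hill)
        elif mode == "basal":
            out[g] = HillParams(anchor.f_baseline * rel, anchor.f_max * rel, anchor.ec50, anchor.n_hill)
        elif mode == "maximum":
            target_max = anchor_max * rel
            fmax = anchor.f_baseline + (target_max - anchor.f_baseline) / h
            out[g] = HillParams(anchor.f_baseline, fmax, anchor.ec50, anchor.n_hill)
        else:  # ec50
            out[g] = HillParams(anchor.f_baseline, anchor.f_max, anchor.ec50 * rel, anchor.n_hill)
    return out


def simulate_assay(
    variant_params: dict[Genotype, HillParams],
    assay: AssaySpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw replicate fluorescence measurements for every variant plus the
    sfGFP positive control, in the standard long CSV layout.

    Each measurement is hill(x) * (1 + eps) with eps ~ Normal(0, CV); the
    control is a flat constitutive signal times the assay's drift ramp, with
    6 replicates.  Deterministic for a given Generator state.
    """
    if rng is None:
        rng = np.random.default_rng(assay.seed)
    rows = []
    for g in sorted(variant_params):
        hp = variant_params[g]
        for x in assay.concentrations:
            mean = float(hp.predict(x))
            noise = rng.normal(0.0, assay.cv, size=assay.replicates) if assay.cv > 0 else np.zeros(assay.replicates)
            for r, eps in enumerate(noise, start=1):
                rows.append((g.label, assay.ligand, x, r, mean * (1.0 + eps), False))
    for x in assay.concentrations:
        mean = assay.control_level * assay.control_factor(x)
        noise = rng.normal(0.0, assay.cv, size=CONTROL_REPLICATES) if assay.cv > 0 else np.zeros(CONTROL_REPLICATES)
        for r, eps in enumerate(noise, start=1):
            rows.append((CONTROL_VARIANT, assay.ligand, x, r, mean * (1.0 + eps), True))
    return pd.DataFrame(
        rows,
        columns=["variant", "ligand", "concentration_uM", "replicate", "fluorescence", "is_control"],
    )


def top_up_replicates(
    df: pd.DataFrame,
    variant_params: dict[Genotype, HillParams],
    assay: AssaySpec,
    rng: np.random.Generator,
    threshold: float = 0.10,
    target_replicates: int = 6,
) -> pd.DataFrame:
    """Re-measure noisy variants with more replicates.

    Variants whose replicate sd exceeds ``threshold`` times the mean at any
    concentration are redrawn with ``target_replicates`` replicates,
    mimicking the three-then-six replication rule of the real assay.
    """
    data = df[~df["is_control"]]
    noisy = []
    for (variant, _), grp in data.groupby(["variant", "ligand"]):
        stats = grp.groupby("concentration_uM")["fluorescence"].agg(["mean", "std"])
        if (stats["std"].fillna(0.0) > threshold * stats["mean"]).any():
            noisy.append(variant)
    if not noisy:
        return df
    rows = []
    for label in noisy:
        hp = variant_params[Genotype.from_label(label)]
        for x in assay.concentrations:
            mean = float(hp.predict(x))
            eps = rng.normal(0.0, assay.cv, size=target_replicates)
            for r, e in enumerate(eps, start=1):
                rows.append((label, assay.ligand, x, r, mean * (1.0 + e), False))
    redone = pd.DataFrame(rows, columns=df.columns.tolist())
    kept = df[~df["variant"].isin(noisy) | df["is_control"]]
    return pd.concat([kept, redone], ignore_index=True)


def simulate_dataset(
    n: int = 4,
    coefficients: dict[tuple[int, ...], float] | None = None,
    mode: str = "fold_induction",
    assay: AssaySpec | None = None,
    anchor: HillParams = DEFAULT_ANCHOR,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """End-to-end generator: coefficients -> fitness -> Hill parameters ->
    noisy measurements.  Returns the long-format measurement frame and a
    ground-truth record (coefficients, fitness, Hill parameters, and the
    noise-free parameter landscape).
    """
    rng = np.random.default_rng(seed)
    if coefficients is None:
        coefficients = random_coefficients(n, rng)
    if assay is None:
        assay = AssaySpec(seed=seed)
    spec = TrueLandscapeSpec(n=n, coefficients=coefficients, seed=seed)
    fitness = landscape_from_coefficients(spec)
    params = hill_params_from_fitness(fitness, anchor=anchor, mode=mode, top_concentration=assay.top)
    df = simulate_assay(params, assay, rng=rng)

    wt = Genotype((0,) * n)
    true_values = {}
    for g, hp in params.items():
        if mode == "fold_induction":
            true_values[g] = float(hp.predict(assay.top)) / hp.f_baseline
        elif mode == "basal":
            true_values[g] = hp.f_baseline
        elif mode == "maximum":
            true_values[g] = float(hp.predict(assay.top))
        else:
            true_values[g] = hp.ec50
    true_landscape = ParameterLandscape(
        mode, assay.ligand, {g: (v, 0.0) for g, v in true_values.items()}
    )
    truth = {
        "n": n,
        "mode": mode,
        "seed": seed,
        "coefficients": {",".join(map(str, k)): v for k, v in coefficients.items()},
        "fitness": {g.label: f for g, f in fitness.items()},
        "hill_params": {g.label: list(hp) for g, hp in params.items()},
        "true_values": {g.label: v for g, v in true_values.items()},
    }
    return df, {"record": truth, "landscape": true_landscape}
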