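"""Per-parameter fitness landscapes over the full genotype hypercube.

A :class:`ParameterLandscape` maps every genotype of the n-cube to the value
(and sd) of one functional parameter for one ligand.  Fitness for the
interaction-expansion analysis is defined on the log scale relative to wild
type: ``fitness(g) = log10(value(g) / value(wildtype))``, so the wild type
sits at 0 by construction and equal tenfold changes are symmetric around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .dose_response import FunctionalParameters
from .genotype_space import Genotype, LocusMap, enumerate_genotypes

__all__ = [
    "PARAMETER_NAMES",
    "ParameterLandscape",
    "build_landscape",
    "normalize_log10",
    "bahadur_fitness",
    "landscape_to_frame",
    "landscape_from_frame",
]

PARAMETER_NAMES = ("fold_induction", "basal", "maximum", "ec50")

_LN10 = math.log(10.0)


@dataclass
class ParameterLandscape:
    """Complete map genotype -> (value, sd) for one parameter and ligand."""

    parameter_name: str
    ligand: str
    values: dict[Genotype, tuple[float, float]]
    locus_map: LocusMap | None = None
    wildtype: Genotype = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("landscape has no entries")
        n = next(iter(self.values)).n
        if self.wildtype is None:
            self.wildtype = Genotype((0,) * n)
        if any(g.n != n for g in self.values):
            raise ValueError("landscape genotypes have inconsistent locus counts")
        expected = set(enumerate_genotypes(n))
        present = set(self.values)
        if present != expected:
            missing = sorted(g.label for g in expected - present)
            raise ValueError(f"landscape incomplete; missing genotypes: {missing}")
        for g, (v, sd) in self.values.items():
            if not (v > 0) or not math.isfinite(v):
                raise ValueError(f"non-positive or non-finite value for {g.label}: {v}")
            if sd < 0 or not math.isfinite(sd):
                raise ValueError(f"invalid sd for {g.label}: {sd}")

    @property
    def n(self) -> int:
        return self.wildtype.n

    @property
    def genotypes(self) -> list[Genotype]:
        return enumerate_genotypes(self.n)

    def value(self, g: Genotype) -> float:
        return self.values[g][0]

    def sd(self, g: Genotype) -> float:
        return self.values[g][1]


def build_landscape(
    params: dict[Genotype, FunctionalParameters] | dict[str, FunctionalParameters],
    parameter_name: str,
    ligand: str,
    locus_map: LocusMap | None = None,
) -> ParameterLandscape:
    """Assemble a landscape for one parameter from per-variant records.

    Keys may be Genotype objects or binary labels; the hypercube must be
    complete, and missing genotypes are reported by label.
    """
    if parameter_name not in PARAMETER_NAMES:
        raise ValueError(f"unknown parameter {parameter_name!r}; expected one of {PARAMETER_NAMES}")
    values: dict[Genotype, tuple[float, float]] = {}
    for key, rec in params.items():
        g = key if isinstance(key, Genotype) else Genotype.from_label(str(key))
        values[g] = rec.value(parameter_name)
    return ParameterLandscape(parameter_name, ligand, values, locus_map=locus_map)


def normalize_log10(landscape: ParameterLandscape) -> dict[Genotype, float]:
    """log10 of each value relative to wild type; wild type maps to 0."""
    wt = landscape.value(landscape.wildtype)
    if wt <= 0:
        raise ValueError("wild-type value must be positive")
    return {g: math.log10(v / wt) for g, (v, _) in landscape.values.items()}


def bahadur_fitness(landscape: ParameterLandscape) -> dict[Genotype, float]:
    """Fitness used by the orthonormal interaction expansion:
    log10(value / wild-type value), identically to :func:`normalize_log10`
    but with wild-type fitness pinned to exactly 0."""
    out = normalize_log10(landscape)
    out[landscape.wildtype] = 0.0
    return out


def log10_sd(landscape: ParameterLandscape) -> dict[Genotype, float]:
    """Delta-method sd of log10(value): sd / (value * ln 10)."""
    return {g: sd / (v * _LN10) for g, (v, sd) in landscape.values.items()}


def landscape_to_frame(landscape: ParameterLandscape) -> pd.DataFrame:
    """Serialize to the TSV layout: genotype, value, sd, log10_norm."""
    logs = normalize_log10(landscape)
    rows = [
        {"genotype": g.label, "value": v, "sd": sd, "log10_norm": logs[g]}
        for g, (v, sd) in sorted(landscape.values.items())
    ]
    return pd.DataFrame(rows)


def landscape_from_frame(df: pd.DataFrame, parameter_name: str, ligand: str) -> ParameterLandscape:
    values = {
        Genotype.from_label(str(r.genotype)): (float(r.value), float(r.sd))
        for r in df.itertuples()
    }
    return ParameterLandscape(parameter_name, ligand, values)
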