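"""Viable mutational pathway enumeration on parameter landscapes.

A pathway from wild type to an endpoint accumulates one mutation per step.
A step is viable when the parameter moves in the direction of the endpoint
(up if the endpoint outperforms the start, down otherwise), optionally
tolerating a bounded fractional move the wrong way — e.g. a 25% loss per
step — to emulate weak selection.  With d mutations separating start and
endpoint there are d! candidate orderings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

from .genotype_space import Genotype, hamming_distance
from .landscape import ParameterLandscape

__all__ = [
    "PathwaySpec",
    "PathwayResult",
    "count_total_paths",
    "constrained_max_paths",
    "enumerate_viable_paths",
    "result_to_dict",
]


@dataclass(frozen=True)
class PathwaySpec:
    """Start/end genotypes plus the viability rule parameters.

    ``direction`` is "increase" when the endpoint's value exceeds the
    start's, else "decrease"; ``tolerance`` is the allowed fractional move
    against that direction per step (0 = strictly monotone)."""

    start: Genotype
    end: Genotype
    direction: str
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.start == self.end:
            raise ValueError("start and end genotypes must differ")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"direction must be 'increase' or 'decrease', got {self.direction!r}")
        if not 0.0 <= self.tolerance < 1.0:
            raise ValueError(f"tolerance must be in [0, 1), got {self.tolerance}")

    @classmethod
    def from_landscape(
        cls,
        landscape: ParameterLandscape,
        end: Genotype | str = "auto",
        start: Genotype | None = None,
        tolerance: float = 0.0,
    ) -> "PathwaySpec":
        """Derive the direction from raw landscape values; ``end='auto'``
        targets the landscape's global optimum (the value farthest from the
        start's, i.e. the max if any genotype beats the start else the min)."""
        start = start if start is not None else landscape.wildtype
        if isinstance(end, str):
            if end == "auto":
                ranked = sorted(landscape.values, key=landscape.value)
                lo, hi = ranked[0], ranked[-1]
                v0 = landscape.value(start)
                end_g = hi if landscape.value(hi) - v0 >= v0 - landscape.value(lo) else lo
            else:
                end_g = Genotype.from_label(end)
        else:
            end_g = end
        direction = "increase" if landscape.value(end_g) > landscape.value(start) else "decrease"
        return cls(start, end_g, direction, tolerance)


@dataclass
class PathwayResult:
    viable_paths: list[tuple[Genotype, ...]]
    viable_edges: set[tuple[Genotype, Genotype]]
    total_paths: int

    @property
    def count(self) -> int:
        return len(self.viable_paths)


def count_total_paths(start: Genotype, end: Genotype) -> int:
    """d! orderings of the d mutations separating start from end, where the
    end genotype must carry every mutation of the start."""
    if not start.is_subset_of(end):
        raise ValueError(
            f"end {end.label} does not contain all mutations of start {start.label}"
        )
    return math.factorial(hamming_distance(start, end))


def constrained_max_paths(through: Genotype, start: Genotype, end: Genotype) -> int:
    """Maximum path count when a fixed intermediate is forced: the product of
    factorials of the two segment distances.  Forcing one particular first
    single mutant on a 4-cube gives 1! * 3! = 6."""
    if not (start.is_subset_of(through) and through.is_subset_of(end)):
        raise ValueError(
            f"{start.label} -> {through.label} -> {end.label} is not a bitwise-subset chain"
        )
    d1 = hamming_distance(start, through)
    d2 = hamming_distance(through, end)
    return math.factorial(d1) * math.factorial(d2)


def _step_viable(v_from: float, v_to: float, direction: str, tolerance: float) -> bool:
    # Multiplicative tolerance on the raw parameter scale, per step.
    if direction == "increase":
        return v_to >= (1.0 - tolerance) * v_from
    return v_to <= (1.0 + tolerance) * v_from


def _flip_order_paths(start: Genotype, end: Genotype):
    """Yield each ordering of the loci that must flip as a full genotype path."""
    flip_loci = [i for i, (a, b) in enumerate(zip(start.bits, end.bits)) if a != b]
    for order in permutations(flip_loci):
        path = [start]
        for locus in order:
            path.append(path[-1].flip(locus))
        yield tuple(path)


def enumerate_viable_paths(landscape: ParameterLandscape, spec: PathwaySpec) -> PathwayResult:
    """All monotone-under-tolerance pathways from start to end.

    Paths add exactly one mutation per step; a path is viable iff every step
    is viable under the spec's direction and tolerance.  Equal adjacent
    values are viable at tolerance 0 (weak inequality).
    """
    if not spec.start.is_subset_of(spec.end):
        raise ValueError("end genotype must contain all mutations of the start")
    viable: list[tuple[Genotype, ...]] = []
    edges: set[tuple[Genotype, Genotype]] = set()
    for path in _flip_order_paths(spec.start, spec.end):
        ok = all(
            _step_viable(landscape.value(u), landscape.value(v), spec.direction, spec.tolerance)
            for u, v in zip(path, path[1:])
        )
        if ok:
            viable.append(path)
            edges.update(zip(path, path[1:]))
    total = count_total_paths(spec.start, spec.end)
    return PathwayResult(viable, edges, total)


def result_to_dict(landscape: ParameterLandscape, spec: PathwaySpec, result: PathwayResult) -> dict:
    """JSON-ready summary of a pathway enumeration."""
    return {
        "parameter": landscape.parameter_name,
        "ligand": landscape.ligand,
        "start": spec.start.label,
        "end": spec.end.label,
        "direction": spec.direction,
        "tolerance": spec.tolerance,
        "tolerance_scale": "raw_multiplicative_per_step",
        "total_paths": result.total_paths,
        "count": result.count,
        "paths": [[g.label for g in p] for p in result.viable_paths],
        "viable_edges": sorted([u.label, v.label] for u, v in result.viable_edges),
    }
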