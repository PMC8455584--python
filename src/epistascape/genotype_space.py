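"""Binary genotype encodings, the mutational hypercube, and 2-locus subnetworks.

A combinatorial variant over ``n`` mutable loci is written as a binary string
("0110"), where 0 marks the wild-type residue and 1 the mutant residue at a
position.  The leftmost character corresponds to the first locus in the
governing :class:`LocusMap`.  Genotypes also carry a +/-1 "z-string" encoding
(wild type -> -1, mutant -> +1) used by the orthonormal interaction expansion.

The full set of ``2**n`` genotypes forms a hypercube graph whose edges connect
genotypes at Hamming distance 1; every 2-locus "subnetwork" (a background, two
single mutants off that background, and their double mutant) is a square face
of this hypercube and is the unit on which pairwise epistasis is scored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx

__all__ = [
    "Genotype",
    "LocusMap",
    "Subnetwork",
    "enumerate_genotypes",
    "hamming_distance",
    "hamming_neighbors",
    "enumerate_subnetworks",
    "z_encode",
    "z_decode",
    "hypercube_graph",
    "to_dot",
]

_MAX_LOCI = 20  # 2**20 genotypes; combinatorial guard


@dataclass(frozen=True, order=True)
class Genotype:
    """An ordered tuple of 0/1 locus states with a canonical string label."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bits:
            raise ValueError("genotype must have at least one locus")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"genotype bits must be 0 or 1, got {self.bits}")

    @classmethod
    def from_label(cls, label: str) -> "Genotype":
        if not label or set(label) - {"0", "1"}:
            raise ValueError(f"invalid genotype label {label!r}")
        return cls(tuple(int(c) for c in label))

    @property
    def label(self) -> str:
        return "".join(str(b) for b in self.bits)

    @property
    def n(self) -> int:
        return len(self.bits)

    @property
    def weight(self) -> int:
        """Number of mutant loci (Hamming weight)."""
        return sum(self.bits)

    def flip(self, i: int) -> "Genotype":
        """Return the genotype with locus ``i`` toggled."""
        bits = list(self.bits)
        bits[i] ^= 1
        return Genotype(tuple(bits))

    def is_subset_of(self, other: "Genotype") -> bool:
        """True if every mutation present here is also present in ``other``."""
        return all(a <= b for a, b in zip(self.bits, other.bits, strict=True))

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class LocusMap:
    """Ordered list of mutable locus names; leftmost bit = first locus.

    For the 4-site TtgR specificity switch the conventional order is
    ``("C137I", "I141W", "M167L", "F168Y")`` (positions 137, 141, 167, 168
    left to right).
    """

    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        if not self.loci:
            raise ValueError("locus map must name at least one locus")

    @property
    def n(self) -> int:
        return len(self.loci)

    def mutations(self, g: Genotype) -> tuple[str, ...]:
        """Names of the loci mutated in ``g``."""
        if g.n != self.n:
            raise ValueError(f"genotype length {g.n} != locus count {self.n}")
        return tuple(name for name, b in zip(self.loci, g.bits) if b)


TTGR_LOCI = LocusMap(("C137I", "I141W", "M167L", "F168Y"))


@dataclass(frozen=True)
class Subnetwork:
    """A square of four genotypes: background, two singles, and the double.

    ``locus_pair`` holds the two (0-based) locus indices that vary; the
    background is fixed at every other locus.
    """

    background: Genotype
    locus_pair: tuple[int, int]

    def __post_init__(self) -> None:
        i, j = self.locus_pair
        if i == j:
            raise ValueError("locus pair must name two distinct loci")
        if not (0 <= i < self.background.n and 0 <= j < self.background.n):
            raise ValueError(f"locus pair {self.locus_pair} out of range")
        if i > j:
            object.__setattr__(self, "locus_pair", (j, i))
        if self.background.bits[self.locus_pair[0]] or self.background.bits[self.locus_pair[1]]:
            raise ValueError("background must be wild type at the varied loci")

    @property
    def members(self) -> tuple[Genotype, Genotype, Genotype, Genotype]:
        """(background, single at first locus, single at second, double)."""
        i, j = self.locus_pair
        bg = self.background
        return (bg, bg.flip(i), bg.flip(j), bg.flip(i).flip(j))


def enumerate_genotypes(n: int) -> list[Genotype]:
    """All ``2**n`` genotypes in binary-ascending order (leftmost bit most
    significant), from all-zeros to all-ones."""
    if not 1 <= n <= _MAX_LOCI:
        raise ValueError(f"locus count must be in [1, {_MAX_LOCI}], got {n}")
    return [Genotype(bits) for bits in itertools.product((0, 1), repeat=n)]


def hamming_distance(a: Genotype, b: Genotype) -> int:
    return sum(x != y for x, y in zip(a.bits, b.bits, strict=True))


def hamming_neighbors(g: Genotype) -> list[Genotype]:
    """The ``n`` genotypes one mutation away from ``g``."""
    return [g.flip(i) for i in range(g.n)]


def enumerate_subnetworks(n: int) -> list[Subnetwork]:
    """All C(n,2) * 2**(n-2) two-locus subnetworks of the n-cube.

    Each choice of a locus pair and a background state at the remaining
    ``n - 2`` loci yields one subnetwork; for n=4 this gives 24.
    """
    if n < 2:
        raise ValueError(f"subnetworks require at least 2 loci, got {n}")
    if n > _MAX_LOCI:
        raise ValueError(f"locus count must be <= {_MAX_LOCI}, got {n}")
    out: list[Subnetwork] = []
    for i, j in itertools.combinations(range(n), 2):
        rest = [k for k in range(n) if k not in (i, j)]
        for bg_bits in itertools.product((0, 1), repeat=n - 2):
            bits = [0] * n
            for k, b in zip(rest, bg_bits):
                bits[k] = b
            out.append(Subnetwork(Genotype(tuple(bits)), (i, j)))
    return out


def z_encode(g: Genotype) -> tuple[int, ...]:
    """Map each locus state to the +/-1 convention: wild type 0 -> -1,
    mutant 1 -> +1."""
    return tuple(2 * b - 1 for b in g.bits)


def z_decode(z: Sequence[int]) -> Genotype:
    """Inverse of :func:`z_encode`."""
    if any(v not in (-1, 1) for v in z):
        raise ValueError(f"z-string values must be -1 or +1, got {tuple(z)}")
    return Genotype(tuple((v + 1) // 2 for v in z))


def hypercube_graph(n: int) -> nx.Graph:
    """The n-dimensional mutational hypercube: nodes are genotype labels,
    edges join genotypes that differ by a single mutation."""
    g = nx.Graph()
    genotypes = enumerate_genotypes(n)
    g.add_nodes_from(gt.label for gt in genotypes)
    for gt in genotypes:
        for nb in hamming_neighbors(gt):
            if nb.label > gt.label:
                g.add_edge(gt.label, nb.label)
    return g


def to_dot(
    graph: nx.Graph,
    highlighted_edges: set[tuple[str, str]] | frozenset[tuple[str, str]] = frozenset(),
) -> str:
    """Render the hypercube as DOT, with ``highlighted_edges`` (directed pairs
    of labels, order-insensitive here) drawn bold for viable-path display."""
    hi = {frozenset(e) for e in highlighted_edges}
    lines = ["graph landscape {"]
    for node in sorted(graph.nodes):
        lines.append(f'  "{node}" [label="{node}"];')
    for u, v in sorted(graph.edges):
        style = ' [style=bold, color=red]' if frozenset((u, v)) in hi else ' [color=gray]'
        lines.append(f'  "{u}" -- "{v}"{style};')
    lines.append("}")
    return "\n".join(lines)
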