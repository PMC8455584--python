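"""Pairwise epistasis classification on 2-locus subnetworks.

Each square (background, two single mutants, double mutant) is scored on the
log-fitness scale relative to its own background.  The interaction term

    eps = f11 - f10 - f01 + f00

is the deviation of the double mutant from the additive expectation.  When
eps is significantly nonzero the square is classified by sign behaviour:

* magnitude — both mutations keep the sign of their effect in either
  background; the combination is simply more (or less) than additive;
* sign — exactly one mutation's effect switches between beneficial and
  deleterious depending on the background;
* reciprocal sign — both mutations switch sign when paired, the hallmark of
  a fitness-landscape "valley" between two peaks.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

from .bahadur import subnetwork_r2
from .genotype_space import Subnetwork, enumerate_subnetworks
from .landscape import ParameterLandscape

__all__ = [
    "SubnetworkEffects",
    "EpistasisCall",
    "compute_effects",
    "classify",
    "classify_all",
    "summary_counts",
]

CATEGORIES = ("none", "magnitude", "sign", "reciprocal_sign")

_LN10 = math.log(10.0)
_ZERO_TOL = 1e-9  # noise-free data: |eps| below this is additive


@dataclass
class SubnetworkEffects:
    """Log-scale corner fitnesses and derived mutation effects of a square."""

    subnetwork: Subnetwork
    f00: float
    f10: float
    f01: float
    f11: float
    sd00: float
    sd10: float
    sd01: float
    sd11: float

    @property
    def effect_a_bg(self) -> float:
        """Effect of mutation A in the background."""
        return self.f10 - self.f00

    @property
    def effect_a_alt(self) -> float:
        """Effect of mutation A on top of mutation B."""
        return self.f11 - self.f01

    @property
    def effect_b_bg(self) -> float:
        return self.f01 - self.f00

    @property
    def effect_b_alt(self) -> float:
        return self.f11 - self.f10

    @property
    def interaction(self) -> float:
        return self.f11 - self.f10 - self.f01 + self.f00

    @property
    def interaction_sd(self) -> float:
        return math.sqrt(self.sd00**2 + self.sd10**2 + self.sd01**2 + self.sd11**2)


@dataclass
class EpistasisCall:
    subnetwork: Subnetwork
    category: str
    significant: bool
    interaction: float
    interaction_sd: float
    r2_first_order: float


def compute_effects(landscape: ParameterLandscape, sub: Subnetwork) -> SubnetworkEffects:
    """Corner fitnesses log10(value / background value), with delta-method
    sds, for one square."""
    members = sub.members
    v_bg = landscape.value(members[0])
    f, s = [], []
    for m in members:
        v = landscape.value(m)
        if v <= 0:
            raise ValueError(f"member {m.label} has non-positive value")
        f.append(math.log10(v / v_bg))
        s.append(landscape.sd(m) / (v * _LN10))
    f[0] = 0.0
    return SubnetworkEffects(sub, f[0], f[1], f[2], f[3], s[0], s[1], s[2], s[3])


def _flips(before: float, after: float) -> bool:
    # strict sign change; zero effects are treated as no flip
    return (before > 0 > after) or (before < 0 < after)


def classify(effects: SubnetworkEffects, alpha: float = 0.05) -> EpistasisCall:
    """Category call with a two-sided z-test on the interaction term.

    With all sds zero (noise-free input) significance reduces to
    |eps| > float tolerance.
    """
    eps = effects.interaction
    sd = effects.interaction_sd
    if sd > 0:
        z = norm.ppf(1 - alpha / 2)
        significant = abs(eps) > z * sd
    else:
        significant = abs(eps) > _ZERO_TOL
    if not significant:
        category = "none"
    else:
        a_flip = _flips(effects.effect_a_bg, effects.effect_a_alt)
        b_flip = _flips(effects.effect_b_bg, effects.effect_b_alt)
        if a_flip and b_flip:
            category = "reciprocal_sign"
        elif a_flip or b_flip:
            category = "sign"
        else:
            category = "magnitude"
    return EpistasisCall(
        subnetwork=effects.subnetwork,
        category=category,
        significant=significant,
        interaction=eps,
        interaction_sd=sd,
        r2_first_order=math.nan,
    )


def classify_all(landscape: ParameterLandscape, alpha: float = 0.05) -> list[EpistasisCall]:
    """One call per subnetwork of the landscape's hypercube (24 for n=4),
    each annotated with its first-order subnetwork R^2."""
    calls = []
    for sub in enumerate_subnetworks(landscape.n):
        call = classify(compute_effects(landscape, sub), alpha=alpha)
        call.r2_first_order = subnetwork_r2(landscape, sub)
        calls.append(call)
    return calls


def summary_counts(calls: list[EpistasisCall]) -> dict[str, int]:
    counts = Counter(call.category for call in calls)
    return {cat: counts.get(cat, 0) for cat in CATEGORIES}


def calls_to_frame(calls: list[EpistasisCall]) -> pd.DataFrame:
    rows = [
        {
            "background": c.subnetwork.background.label,
            "locus_pair": f"{c.subnetwork.locus_pair[0]},{c.subnetwork.locus_pair[1]}",
            "eps": c.interaction,
            "eps_sd": c.interaction_sd,
            "significant": c.significant,
            "category": c.category,
            "r2_first_order": c.r2_first_order,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
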