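"""Monte-Carlo propagation of measurement error into R^2, with bootstrap CIs.

Measurement uncertainty enters the expansion through the per-variant
parameter sds: each Monte-Carlo draw resamples every variant's parameter
value from Normal(mean, sd) on the raw measurement scale, recomputes the
log-fitness landscape, refits the interaction coefficients on the sampled
landscape, and records the R^2 of the truncated reconstruction against that
same sampled landscape.  The spread of the resulting R^2 distribution is
summarized with a bias-corrected (and optionally accelerated, BCa) bootstrap
confidence interval of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .bahadur import build_basis, coefficient_of_determination
from .genotype_space import Subnetwork, enumerate_genotypes
from .landscape import ParameterLandscape

__all__ = ["MonteCarloResult", "monte_carlo_r2", "bca_interval"]

DEFAULT_DRAWS = 500
DEFAULT_BOOTSTRAP_ITERS = 10_000

# Sampled values <= 0 (log undefined) are floored at this fraction of the
# landscape's smallest mean value; floored draws are counted, not discarded.
_FLOOR_FRACTION = 1e-6


@dataclass
class MonteCarloResult:
    r2_samples: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    draws: int
    bootstrap_iters: int
    seed: int
    floored_values: int
    max_order: int

    def to_dict(self) -> dict:
        return {
            "max_order": self.max_order,
            "draws": self.draws,
            "bootstrap_iters": self.bootstrap_iters,
            "mean_r2": self.mean,
            "ci": [self.ci_low, self.ci_high],
            "floored_values": self.floored_values,
            "seed": self.seed,
        }


def _sample_landscape_values(
    landscape: ParameterLandscape, rng: np.random.Generator
) -> tuple[dict, int]:
    """One Gaussian draw of every genotype's raw value; returns the sampled
    map and the number of values floored to stay positive."""
    floor = _FLOOR_FRACTION * min(v for v, _ in landscape.values.values())
    sampled = {}
    floored = 0
    for g in landscape.genotypes:  # fixed genotype order for reproducibility
        v, sd = landscape.values[g]
        draw = rng.normal(v, sd) if sd > 0 else v
        if draw <= 0:
            draw = floor
            floored += 1
        sampled[g] = draw
    return sampled, floored


def monte_carlo_r2(
    landscape: ParameterLandscape,
    target: Subnetwork | None = None,
    max_order: int = 1,
    draws: int = DEFAULT_DRAWS,
    bootstrap_iters: int = DEFAULT_BOOTSTRAP_ITERS,
    seed: int = 0,
    method: str = "bca",
) -> MonteCarloResult:
    """Monte-Carlo R^2 distribution for the full landscape or one subnetwork.

    ``target=None`` scores the truncated expansion of the whole n-locus
    landscape (fitness relative to wild type); a :class:`Subnetwork` target
    scores the 2-locus expansion of that square (fitness relative to the
    square's sampled background).  Deterministic for a fixed seed: each draw
    consumes an independent child stream spawned from the seed.
    """
    if draws < 2:
        raise ValueError("at least 2 Monte-Carlo draws are required")
    if target is None:
        basis = build_basis(landscape.n)
        members = landscape.genotypes
        ref = landscape.wildtype
        if not 0 <= max_order <= landscape.n:
            raise ValueError(f"max_order must be in [0, {landscape.n}]")
    else:
        basis = build_basis(2)
        members = list(target.members)
        ref = target.members[0]
        max_order = min(max_order, 2)

    reduced = enumerate_genotypes(basis.n)
    orders = basis.term_order()
    keep = orders <= max_order

    streams = np.random.SeedSequence(seed).spawn(draws)
    r2 = np.empty(draws)
    floored = 0
    for d in range(draws):
        rng = np.random.default_rng(streams[d])
        sampled, n_floor = _sample_landscape_values(landscape, rng)
        floored += n_floor
        f = np.array([math.log10(sampled[m] / sampled[ref]) for m in members])
        w = basis.psi.T @ f / 2**basis.n
        pred = basis.psi[:, keep] @ w[keep]
        r2[d] = coefficient_of_determination(f, pred)

    finite = r2[np.isfinite(r2)]
    if finite.size and np.ptp(finite) == 0.0:
        mean = float(finite[0])  # degenerate distribution at the point estimate
    else:
        mean = float(np.nanmean(r2))
    if finite.size >= 10:
        lo, hi = bca_interval(finite, iters=bootstrap_iters, seed=seed, method=method)
    else:
        lo = hi = mean
    return MonteCarloResult(
        r2_samples=r2, mean=mean, ci_low=lo, ci_high=hi, draws=draws,
        bootstrap_iters=bootstrap_iters, seed=seed, floored_values=floored,
        max_order=max_order,
    )


def bca_interval(
    samples,
    iters: int = DEFAULT_BOOTSTRAP_ITERS,
    seed: int = 0,
    confidence: float = 0.95,
    method: str = "bca",
) -> tuple[float, float]:
    """Bias-corrected bootstrap CI of the mean of ``samples``.

    ``method='bca'`` adds jackknife-based acceleration (the standard BCa
    interval); ``method='bc'`` uses bias correction only.  Constant samples
    give a degenerate (c, c) interval.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise ValueError("bootstrap interval requires at least 10 samples")
    if method not in ("bca", "bc"):
        raise ValueError(f"method must be 'bca' or 'bc', got {method!r}")
    theta = float(x.mean())
    if np.ptp(x) == 0.0:
        return float(x[0]), float(x[0])

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    idx = rng.integers(0, x.size, size=(iters, x.size))
    boot = x[idx].mean(axis=1)

    # bias correction from the fraction of bootstrap means below the estimate
    prop = np.mean(boot < theta)
    prop = min(max(prop, 1.0 / (iters + 1)), iters / (iters + 1.0))
    z0 = norm.ppf(prop)

    if method == "bca":
        # jackknife acceleration; leave-one-out means via the sum identity
        jack = (x.sum() - x) / (x.size - 1)
        diff = jack.mean() - jack
        denom = (diff**2).sum() ** 1.5
        a = float((diff**3).sum() / (6.0 * denom)) if denom > 0 else 0.0
    else:
        a = 0.0

    z_alpha = norm.ppf([(1 - confidence) / 2, (1 + confidence) / 2])
    adj = norm.cdf(z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi)
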