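import numpy as np
import pytest

from epistascape.genotype_space import Genotype, enumerate_genotypes
from epistascape.landscape import ParameterLandscape


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_landscape(values, sds=None, parameter="fold_induction", ligand="resveratrol"):
    """Build a ParameterLandscape from a {label: value} map (sds default 0)."""
    sds = sds or {}
    vals = {
        Genotype.from_label(lbl): (float(v), float(sds.get(lbl, 0.0)))
        for lbl, v in values.items()
    }
    return ParameterLandscape(parameter, ligand, vals)


def random_positive_landscape(rng, n=4, spread=0.6, sd_cv=0.0):
    """Log-normal random landscape over the n-cube, wild type near 1."""
    values = {}
    for g in enumerate_genotypes(n):
        v = float(np.exp(rng.normal(0.0, spread)))
        values[g] = (v, sd_cv * v)
    return ParameterLandscape("fold_induction", "resveratrol", values)


@pytest.fixture
def landscape_factory(rng):
    def factory(seed=None, **kw):
        local = np.random.default_rng(seed) if seed is not None else rng
        return random_positive_landscape(local, **kw)

    return factory
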