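"""End-to-end convenience wrappers: raw long-format data -> landscapes.

These functions chain the per-module steps (control normalization, Hill
fitting, parameter extraction, landscape assembly) in the standard order so
the CLI, tests, and batch analyses share one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dose_response import (
    DoseResponseCurve,
    FunctionalParameters,
    curves_from_frame,
    extract_parameters,
    fit_hill,
    normalize_by_control,
)
from .landscape import PARAMETER_NAMES, ParameterLandscape, build_landscape

__all__ = ["fit_dataset", "landscapes_from_parameters", "analyze"]


def fit_dataset(
    df: pd.DataFrame,
    normalize: bool = True,
    fit_seed: int = 0,
) -> dict[tuple[str, str], FunctionalParameters]:
    """Fit every (variant, ligand) curve in a long-format frame.

    When ``normalize`` is set and control rows are present (``is_control``
    true), each variant curve is first normalized by the matching-ligand
    control's fold change.
    """
    curves = curves_from_frame(df, include_controls=False)
    controls: dict[str, DoseResponseCurve] = {}
    if normalize and "is_control" in df.columns and df["is_control"].any():
        for (variant, ligand), curve in curves_from_frame(
            df[df["is_control"]], include_controls=True
        ).items():
            controls[ligand] = curve
    out: dict[tuple[str, str], FunctionalParameters] = {}
    rng = np.random.default_rng(fit_seed)
    for (variant, ligand), curve in curves.items():
        if ligand in controls:
            curve = normalize_by_control(curve, controls[ligand])
        fit = fit_hill(curve, rng=rng)
        out[(variant, ligand)] = extract_parameters(curve, fit)
    return out


def landscapes_from_parameters(
    params: dict[tuple[str, str], FunctionalParameters],
    ligand: str,
    parameters: tuple[str, ...] = PARAMETER_NAMES,
) -> dict[str, ParameterLandscape]:
    """One complete landscape per functional parameter for one ligand."""
    per_variant = {v: rec for (v, lig), rec in params.items() if lig == ligand}
    return {
        name: build_landscape(per_variant, name, ligand) for name in parameters
    }


def analyze(df: pd.DataFrame, ligand: str, normalize: bool = True) -> dict[str, ParameterLandscape]:
    """Raw measurements to the four per-parameter landscapes in one call."""
    return landscapes_from_parameters(fit_dataset(df, normalize=normalize), ligand)
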