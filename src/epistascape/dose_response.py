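"""Dose-response handling: control normalization, fold induction, Hill fits.

Induction of the GFP reporter by a ligand is summarized per variant by four
functional parameters:

* fold induction  -- reporter output at the top assayed concentration divided
  by the output at 0 uM;
* basal expression -- output at 0 uM (leakiness of repression);
* maximum expression -- output at the top assayed concentration;
* EC50 -- half-maximal ligand concentration from a Hill fit.

The Hill model is ``f(x) = F_baseline + (F_max - F_baseline) * x**n /
(EC50**n + x**n)``.  Fits are weighted nonlinear least squares on
per-concentration replicate means, weighted by replicate standard deviations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "FunctionalParameters",
    "read_long_csv",
    "curves_from_frame",
    "normalize_by_control",
    "fold_induction",
    "hill_predict",
    "fit_hill",
    "extract_parameters",
    "parameters_table",
]

CSV_COLUMNS = ["variant", "ligand", "concentration_uM", "replicate", "fluorescence"]

HILL_BOUNDS = ((1e-12, 1e-12, 1e-12, 0.1), (np.inf, np.inf, np.inf, 10.0))
_N_RESTARTS = 5


@dataclass
class DoseResponseCurve:
    """Per-variant, per-ligand series of replicate fluorescence values.

    ``points`` maps concentration (uM) -> 1-D array of replicate values;
    concentrations are sorted ascending and must include 0.
    """

    variant: str
    ligand: str
    points: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        pts = {float(c): np.asarray(v, dtype=float).ravel() for c, v in self.points.items()}
        if not pts:
            raise ValueError("curve has no concentrations")
        if any(c < 0 for c in pts):
            raise ValueError("concentrations must be non-negative")
        if 0.0 not in pts:
            raise ValueError(f"curve {self.variant}/{self.ligand} lacks a 0 uM point")
        if any(v.size == 0 for v in pts.values()):
            raise ValueError("every concentration needs at least one replicate")
        self.points = dict(sorted(pts.items()))

    @property
    def concentrations(self) -> np.ndarray:
        return np.array(list(self.points), dtype=float)

    @property
    def top_concentration(self) -> float:
        return max(self.points)

    def means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.points.values()])

    def sds(self) -> np.ndarray:
        return np.array([v.std(ddof=1) if v.size > 1 else 0.0 for v in self.points.values()])

    def mean_at(self, conc: float) -> float:
        return float(self.points[float(conc)].mean())

    def sd_at(self, conc: float) -> float:
        v = self.points[float(conc)]
        return float(v.std(ddof=1)) if v.size > 1 else 0.0


@dataclass
class HillFit:
    """Hill-equation fit result with standard errors from the covariance."""

    f_baseline: float
    f_max: float
    ec50: float
    n_hill: float
    param_sd: dict[str, float]
    covariance: np.ndarray
    converged: bool
    saturated: bool = True  # top concentration >= 2 * EC50
    ec50_identifiable: bool = True  # False when the curve is flat

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.f_baseline, self.f_max, self.ec50, self.n_hill)


@dataclass
class FunctionalParameters:
    """The four functional readouts for one (variant, ligand), each with sd.

    ``basal`` and ``maximum`` are observed replicate means at 0 uM and the top
    concentration; ``ec50`` comes from the Hill fit; ``fold_induction`` is
    maximum / basal.
    """

    variant: str
    ligand: str
    fold_induction: float
    fold_induction_sd: float
    basal: float
    basal_sd: float
    maximum: float
    maximum_sd: float
    ec50: float
    ec50_sd: float

    def value(self, parameter: str) -> tuple[float, float]:
        v = getattr(self, parameter)
        sd = getattr(self, parameter + "_sd")
        return float(v), float(sd)


def read_long_csv(path) -> pd.DataFrame:
    """Read the long-format input CSV (variant, ligand, concentration_uM,
    replicate, fluorescence[, is_control])."""
    df = pd.read_csv(path, dtype={"variant": str})  # keep leading zeros
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input CSV missing required columns: {missing}")
    if "is_control" not in df.columns:
        df["is_control"] = False
    df["is_control"] = df["is_control"].astype(bool)
    return df


def curves_from_frame(df: pd.DataFrame, include_controls: bool = False) -> dict[tuple[str, str], DoseResponseCurve]:
    """Group a long-format frame into DoseResponseCurve objects keyed by
    (variant, ligand)."""
    sub = df if include_controls else df[~df.get("is_control", False)]
    out: dict[tuple[str, str], DoseResponseCurve] = {}
    for (variant, ligand), grp in sub.groupby(["variant", "ligand"], sort=True):
        points = {
            float(c): g["fluorescence"].to_numpy(dtype=float)
            for c, g in grp.groupby("concentration_uM")
        }
        out[(str(variant), str(ligand))] = DoseResponseCurve(str(variant), str(ligand), points)
    return out


def normalize_by_control(raw: DoseResponseCurve, control: DoseResponseCurve) -> DoseResponseCurve:
    """Divide each fluorescence value by the positive control's fold change at
    that concentration relative to the control's own 0 uM mean.

    This removes ligand-dependent fluorescence changes that are independent of
    the regulator (e.g. growth or autofluorescence effects captured by a
    constitutive sfGFP control).
    """
    c0 = control.mean_at(0.0)
    if c0 <= 0:
        raise ValueError("control 0 uM mean fluorescence must be positive")
    points: dict[float, np.ndarray] = {}
    for conc, values in raw.points.items():
        if conc not in control.points:
            raise ValueError(
                f"control curve lacks concentration {conc} uM required to "
                f"normalize {raw.variant}/{raw.ligand}"
            )
        cmean = control.mean_at(conc)
        if cmean <= 0:
            raise ValueError(f"control mean at {conc} uM is non-positive")
        points[conc] = values / (cmean / c0)
    return DoseResponseCurve(raw.variant, raw.ligand, points)


def fold_induction(f_max: float, f_baseline: float) -> float:
    """Ratio of induced to baseline fluorescence."""
    if f_max <= 0 or f_baseline <= 0:
        raise ValueError("fluorescence values must be positive")
    return f_max / f_baseline


def fold_induction_replicatewise(induced: np.ndarray, baseline: np.ndarray) -> float:
    """Mean of per-replicate induced/baseline ratios (replicates paired by
    index), the per-replicate-then-average convention."""
    induced = np.asarray(induced, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if induced.shape != baseline.shape:
        raise ValueError("replicate-wise mode needs paired replicate arrays")
    if np.any(induced <= 0) or np.any(baseline <= 0):
        raise ValueError("fluorescence values must be positive")
    return float(np.mean(induced / baseline))


def hill_predict(x, f_baseline: float, f_max: float, ec50: float, n_hill: float):
    """Hill dose-response: f(0) = F_baseline, f(inf) = F_max, half-saturation
    at x = EC50 with steepness n."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(x > 0, x**n_hill / (ec50**n_hill + x**n_hill), 0.0)
    result = f_baseline + (f_max - f_baseline) * frac
    return float(result) if result.ndim == 0 else result


def _fit_sigma(sds: np.ndarray) -> np.ndarray:
    """Per-concentration weights; zero sds (single replicate or identical
    replicates) are replaced by the curve's median positive sd, or by 1 when
    every sd is zero (unweighted fit)."""
    sds = np.asarray(sds, dtype=float).copy()
    positive = sds[sds > 0]
    fill = float(np.median(positive)) if positive.size else 1.0
    sds[sds <= 0] = fill
    return sds


def fit_hill(curve: DoseResponseCurve, rng: np.random.Generator | None = None) -> HillFit:
    """Weighted least-squares Hill fit to per-concentration replicate means.

    Initialization anchors F_baseline and F_max at the observed ends of the
    curve and EC50 at the geometric mean of the nonzero concentrations; on
    optimizer failure up to five jittered restarts are attempted before the
    result is flagged non-converged.  A fit whose EC50 exceeds half the top
    assayed concentration is flagged unsaturated (``saturated=False``) because
    the plateau is poorly constrained.
    """
    concs = curve.concentrations
    if len(concs) < 5:
        raise ValueError("Hill fit requires at least 5 distinct concentrations")
    means = curve.means()
    sigma = _fit_sigma(curve.sds())
    nz = concs[concs > 0]

    fb0 = max(means[0], 1e-9)
    fm0 = max(means[-1], 1e-9)
    ec0 = float(np.exp(np.mean(np.log(nz))))
    p0 = np.array([fb0, fm0, ec0, 1.0])

    if rng is None:
        rng = np.random.default_rng(0)

    popt = None
    pcov = None
    for attempt in range(_N_RESTARTS + 1):
        start = p0 if attempt == 0 else p0 * np.exp(rng.normal(0, 0.3, size=4))
        start = np.clip(start, HILL_BOUNDS[0], HILL_BOUNDS[1])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    hill_predict, concs, means, p0=start, sigma=sigma,
                    absolute_sigma=True, bounds=HILL_BOUNDS, maxfev=20000,
                )
            break
        except (RuntimeError, ValueError):
            continue

    if popt is None:
        sd = {k: math.nan for k in ("f_baseline", "f_max", "ec50", "n_hill")}
        return HillFit(fb0, fm0, ec0, 1.0, sd, np.full((4, 4), np.nan), converged=False)

    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    sd = dict(zip(("f_baseline", "f_max", "ec50", "n_hill"), perr.tolist()))
    fit = HillFit(
        float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]),
        sd, pcov, converged=True, saturated=bool(curve.top_concentration >= 2 * popt[2]),
    )
    amplitude = abs(fit.f_max - fit.f_baseline)
    if amplitude < 1e-8 * max(abs(fit.f_baseline), 1.0):
        fit.ec50_identifiable = False
        warnings.warn(
            f"curve {curve.variant}/{curve.ligand} is flat (F_max ~= F_baseline); "
            "EC50 is unidentifiable",
            stacklevel=2,
        )
    if not fit.saturated:
        warnings.warn(
            f"curve {curve.variant}/{curve.ligand} does not saturate "
            f"(top concentration {curve.top_concentration} < 2 x EC50 {fit.ec50:.3g}); "
            "EC50 estimate is imprecise",
            stacklevel=2,
        )
    return fit


def extract_parameters(curve: DoseResponseCurve, fit: HillFit) -> FunctionalParameters:
    """Derive the four functional parameters from observed data plus the fit.

    Basal and maximum expression are the observed means at 0 uM and the top
    assayed concentration (not the fitted asymptote); fold induction is their
    ratio with error propagated from the two replicate sds; EC50 and its sd
    come from the Hill fit covariance.
    """
    top = curve.top_concentration
    if top <= 0:
        raise ValueError("curve has no nonzero concentration")
    basal = curve.mean_at(0.0)
    maximum = curve.mean_at(top)
    if basal <= 0 or maximum <= 0:
        raise ValueError("basal and maximum fluorescence must be positive")
    basal_sd = curve.sd_at(0.0)
    maximum_sd = curve.sd_at(top)
    fi = maximum / basal
    fi_sd = fi * math.sqrt((maximum_sd / maximum) ** 2 + (basal_sd / basal) ** 2)
    return FunctionalParameters(
        variant=curve.variant,
        ligand=curve.ligand,
        fold_induction=fi,
        fold_induction_sd=fi_sd,
        basal=basal,
        basal_sd=basal_sd,
        maximum=maximum,
        maximum_sd=maximum_sd,
        ec50=fit.ec50,
        ec50_sd=fit.param_sd["ec50"],
    )


def parameters_table(params: list[FunctionalParameters]) -> pd.DataFrame:
    """Flatten FunctionalParameters records into the output TSV layout."""
    rows = []
    for p in params:
        rows.append({
            "variant": p.variant, "ligand": p.ligand,
            "fold_induction": p.fold_induction, "fold_induction_sd": p.fold_induction_sd,
            "basal": p.basal, "basal_sd": p.basal_sd,
            "maximum": p.maximum, "maximum_sd": p.maximum_sd,
            "ec50": p.ec50, "ec50_sd": p.ec50_sd,
        })
    return pd.DataFrame(rows)


def fit_to_json(fit: HillFit) -> str:
    return json.dumps({
        "f_baseline": fit.f_baseline, "f_max": fit.f_max,
        "ec50": fit.ec50, "n_hill": fit.n_hill,
        "param_sd": fit.param_sd,
        "covariance": np.asarray(fit.covariance).tolist(),
        "converged": fit.converged, "saturated": fit.saturated,
        "ec50_sd_source": "covariance_diagonal",
    })
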