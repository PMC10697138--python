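"""Variable-slope logistic (Hill) fitting and derived dose-response metrics.

The readout model is the four-parameter logistic in dose x (molar):

    y(x) = bottom + (top - bottom) / (1 + (ec50 / x)**slope)

By default the bottom is fixed at 0, reflecting background subtraction of
the unstimulated signal before fitting; pass ``fix_bottom_to_zero=False``
to free it. Derived metrics: EC50 ratios (fold potency), Kd ratios (fold
affinity), area under the curve in log10-dose, the concentration reaching a
given fraction of a reference maximum ([C]10% and friends), and activity
retention ratios between an untreated and a treated preparation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DoseResponseDataset",
    "HillFit",
    "UnreachableLevelError",
    "normalize_responses",
    "fit_hill",
    "fold_potency",
    "fold_affinity",
    "auc_log_dose",
    "conc_at_fraction",
    "activity_retention",
]

_SLOPE_BOUNDS = (0.1, 10.0)  # physical Hill cooperativity range


class UnreachableLevelError(ValueError):
    """The requested response level lies outside the fitted curve's range."""


@dataclass(frozen=True)
class HillFit:
    """Result of a variable-slope logistic fit.

    ``ec50`` is NaN when the fit is degenerate (flat data); ``converged``
    is False on optimizer failure or when the EC50 lands more than 100x
    outside the fitted dose range.
    """

    bottom: float
    top: float
    ec50: float
    slope: float
    converged: bool
    residual_sse: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (self.ec50 / x) ** self.slope
        )


@dataclass
class DoseResponseDataset:
    """Long-format dose-response records plus normalization metadata.

    ``data`` columns: cell_type, ligand, treatment, dose_molar, replicate,
    response. Normalization references a (ligand, dose) condition per cell
    type (e.g. the natural cytokine at a saturating dose) and a background
    value (unstimulated signal).
    """

    data: pd.DataFrame
    reference_ligand: Optional[str] = None
    reference_dose: Optional[float] = None
    background: float = 0.0
    normalized: bool = False

    REQUIRED = ("cell_type", "ligand", "dose_molar", "replicate", "response")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"dose-response table missing columns {missing}")
        if "treatment" not in self.data.columns:
            self.data = self.data.assign(treatment="none")


def normalize_responses(dataset: DoseResponseDataset) -> DoseResponseDataset:
    """Background-subtract and scale responses to the reference condition.

    response' = (response - background) / (mean reference response - background),
    computed per cell type, so the reference condition maps to mean 1.0.
    """
    if dataset.reference_ligand is None or dataset.reference_dose is None:
        raise ValueError("normalization requires a reference (ligand, dose)")
    df = dataset.data.copy()
    bg = dataset.background
    out = []
    for cell_type, sub in df.groupby("cell_type", sort=False):
        ref = sub[
            (sub["ligand"] == dataset.reference_ligand)
            & np.isclose(sub["dose_molar"], dataset.reference_dose)
        ]
        if ref.empty:
            raise ValueError(
                f"cell type {cell_type!r} lacks the reference condition "
                f"({dataset.reference_ligand!r} at {dataset.reference_dose:.3g} M)"
            )
        scale = ref["response"].mean() - bg
        if scale <= 0:
            raise ValueError(
                f"reference response does not exceed background for {cell_type!r}"
            )
        sub = sub.assign(response=(sub["response"] - bg) / scale)
        out.append(sub)
    return replace(
        dataset, data=pd.concat(out, ignore_index=True), background=0.0, normalized=True
    )


def fit_hill(
    doses: Sequence[float],
    responses: Sequence[float],
    fix_bottom_to_zero: bool = True,
) -> HillFit:
    """Least-squares fit of the variable-slope logistic to (dose, response).

    Requires >= 4 distinct positive doses. EC50 is fitted in log10 space
    with bounds [min dose / 100, max dose * 100]; the slope is constrained
    to (0.1, 10). Flat data (zero spread) returns an unconverged fit with
    ``ec50 = nan`` rather than raising.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses must have the same length")
    if np.any(x <= 0):
        raise ValueError("fitted doses must be positive")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct doses for a Hill fit")

    spread = float(np.ptp(y))
    if spread == 0.0 or not np.isfinite(spread):
        return HillFit(
            bottom=float(y[0]) if not fix_bottom_to_zero else 0.0,
            top=float(np.mean(y)),
            ec50=float("nan"),
            slope=1.0,
            converged=False,
            residual_sse=float(np.sum((y - np.mean(y)) ** 2)),
        )

    log_lo, log_hi = math.log10(x.min() / 100.0), math.log10(x.max() * 100.0)
    top0 = float(np.max(y))
    bot0 = float(np.min(y))
    # crude EC50 initializer: dose nearest the half-maximal response
    half = bot0 + 0.5 * (top0 - bot0)
    ec0 = float(x[np.argmin(np.abs(y - half))])

    if fix_bottom_to_zero:
        p0 = [math.log10(ec0), 1.0, top0]
        lo = [log_lo, _SLOPE_BOUNDS[0], 0.0]
        hi = [log_hi, _SLOPE_BOUNDS[1], 10.0 * max(top0, 1e-12)]

        def resid(p):
            le, s, t = p
            return t / (1.0 + (10.0 ** le / x) ** s) - y

    else:
        p0 = [math.log10(ec0), 1.0, top0, bot0]
        lo = [log_lo, _SLOPE_BOUNDS[0], -np.inf, -np.inf]
        hi = [log_hi, _SLOPE_BOUNDS[1], np.inf, np.inf]

        def resid(p):
            le, s, t, b = p
            return b + (t - b) / (1.0 + (10.0 ** le / x) ** s) - y

    try:
        sol = optimize.least_squares(
            resid, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
    except Exception:
        return HillFit(0.0, top0, float("nan"), 1.0, False, float("inf"))

    ec50 = 10.0 ** sol.x[0]
    slope = float(sol.x[1])
    top = float(sol.x[2])
    bottom = 0.0 if fix_bottom_to_zero else float(sol.x[3])
    in_range = x.min() / 100.0 <= ec50 <= x.max() * 100.0
    converged = bool(sol.success) and in_range
    return HillFit(
        bottom=bottom,
        top=top,
        ec50=float(ec50),
        slope=slope,
        converged=converged,
        residual_sse=float(np.sum(sol.fun**2)),
    )


def fit_hill_curve(curve: pd.DataFrame, fix_bottom_to_zero: bool = True) -> HillFit:
    """Convenience wrapper fitting one long-format (dose_molar, response) group."""
    return fit_hill(
        curve["dose_molar"].to_numpy(),
        curve["response"].to_numpy(),
        fix_bottom_to_zero=fix_bottom_to_zero,
    )


def _require_converged(fit: HillFit, name: str) -> None:
    if not fit.converged or not np.isfinite(fit.ec50):
        raise ValueError(f"{name} Hill fit did not converge; metric undefined")


def fold_potency(fit_a: HillFit, fit_b: HillFit) -> float:
    """EC50(b) / EC50(a): how many-fold less potent b is than a."""
    _require_converged(fit_a, "first")
    _require_converged(fit_b, "second")
    return fit_b.ec50 / fit_a.ec50


def fold_affinity(kd_a: float, kd_b: float) -> float:
    """Kd(b) / Kd(a): how many-fold weaker b binds than a."""
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_b / kd_a


def auc_log_dose(fit: HillFit, dose_min: float, dose_max: float, n_nodes: int = 64) -> float:
    """Integral of the fitted curve over log10 dose between the bounds.

    Gauss-Legendre quadrature with ``n_nodes`` nodes; the integrand is a
    smooth logistic in log-dose, so 64 nodes reach ~1e-12 absolute error.
    """
    _require_converged(fit, "input")
    if not (0 < dose_min < dose_max):
        raise ValueError("need 0 < dose_min < dose_max")
    a, b = math.log10(dose_min), math.log10(dose_max)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (b - a) * nodes + 0.5 * (a + b)
    return float(0.5 * (b - a) * np.sum(weights * fit.predict(10.0**u)))


def conc_at_fraction(fit: HillFit, fraction: float, reference_top: float) -> float:
    """Concentration at which the fitted curve reaches fraction * reference_top.

    Closed-form inversion of the logistic. Raises
    :class:`UnreachableLevelError` when the target level is not strictly
    between the curve's bottom and top (e.g. a treated cytokine that never
    reaches 10% of the reference maximum).
    """
    _require_converged(fit, "input")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    target = fraction * reference_top
    if not (fit.bottom < target < fit.top):
        raise UnreachableLevelError(
            f"target level {target:.4g} is outside the fitted range "
            f"({fit.bottom:.4g}, {fit.top:.4g})"
        )
    ratio = (target - fit.bottom) / (fit.top - target)
    return fit.ec50 * ratio ** (1.0 / fit.slope)


def activity_retention(
    fit_untreated: HillFit,
    fit_treated: HillFit,
    fraction: float = 0.1,
    reference_top: float = 1.0,
) -> float:
    """[C]fraction(untreated) / [C]fraction(treated).

    Values < 1 indicate the treated preparation needs a higher concentration
    to reach the same activation level (activity loss).
    """
    try:
        c_untreated = conc_at_fraction(fit_untreated, fraction, reference_top)
    except UnreachableLevelError as err:
        raise UnreachableLevelError(f"untreated curve: {err}") from err
    try:
        c_treated = conc_at_fraction(fit_treated, fraction, reference_top)
    except UnreachableLevelError as err:
        raise UnreachableLevelError(f"treated curve: {err}") from err
    return c_untreated / c_treated
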