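"""1:1 Langmuir biolayer-interferometry kinetics: simulation and fitting.

A sensogram records association of a soluble analyte at concentration C to
an immobilized partner followed by dissociation in buffer:

    association:  y(t) = Req * (1 - exp(-(kon*C + koff) * t)),
                  Req = rmax * C / (C + Kd),  Kd = koff / kon
    dissociation: y(t) = y(t_assoc) * exp(-koff * (t - t_assoc))

Kinetic fitting is global: a single (kon, koff, rmax) is shared across all
dilutions of a titration series, with a per-trace baseline offset as a
nuisance parameter, matching instrument-software convention. Equilibrium
titrations are fitted with the one-site saturation isotherm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "Sensogram",
    "KineticFit",
    "EquilibriumFit",
    "simulate_sensogram",
    "fit_langmuir_global",
    "fit_equilibrium_titration",
]


@dataclass(frozen=True)
class Sensogram:
    """One BLI trace: time (s), signal (nm), association end time, baseline."""

    analyte_conc: float
    time: np.ndarray
    signal: np.ndarray
    t_assoc_end: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be a strictly increasing 1-D array")
        if not (t[0] <= self.t_assoc_end <= t[-1]):
            raise ValueError("t_assoc_end must lie within the time range")
        if len(self.signal) != t.size:
            raise ValueError("signal and time must have equal length")


@dataclass(frozen=True)
class KineticFit:
    """Globally fitted 1:1 Langmuir parameters; kd == koff / kon."""

    k_on: float
    k_off: float
    r_max: float
    kd: float
    residual_sse: float


@dataclass(frozen=True)
class EquilibriumFit:
    """One-site saturation fit of an equilibrium titration."""

    kd: float
    r_max: float
    extrapolated: bool
    residual_sse: float


def _langmuir_trace(t, t_assoc_end, conc, k_on, k_off, r_max, baseline=0.0):
    kd = k_off / k_on
    req = r_max * conc / (conc + kd)
    kobs = k_on * conc + k_off
    t = np.asarray(t, dtype=float)
    y = np.empty_like(t)
    assoc = t <= t_assoc_end
    y[assoc] = req * (1.0 - np.exp(-kobs * t[assoc]))
    y_end = req * (1.0 - np.exp(-kobs * t_assoc_end))
    y[~assoc] = y_end * np.exp(-k_off * (t[~assoc] - t_assoc_end))
    return y + baseline


def simulate_sensogram(
    k_on: float,
    k_off: float,
    r_max: float,
    analyte_conc: float,
    t_assoc: float = 900.0,
    t_dissoc: float = 1200.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float = 1.0,
) -> Sensogram:
    """Generate a noiseless or Gaussian-noisy 1:1 Langmuir trace.

    Defaults mirror a standard instrument protocol: 900 s association,
    1,200 s dissociation, 1 Hz sampling.
    """
    if min(k_on, k_off, r_max, t_assoc, t_dissoc, dt) <= 0:
        raise ValueError("kinetic parameters and durations must be positive")
    if analyte_conc < 0:
        raise ValueError("analyte concentration must be >= 0")
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    y = _langmuir_trace(t, t_assoc, analyte_conc, k_on, k_off, r_max)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return Sensogram(analyte_conc=analyte_conc, time=t, signal=y, t_assoc_end=t_assoc)


def fit_langmuir_global(traces: Sequence[Sensogram]) -> KineticFit:
    """Fit shared (kon, koff, rmax) to one or more sensograms.

    Minimizes the summed squared residual across traces; each trace gets its
    own baseline offset. kon/koff are fitted in log10 space, initialized at
    1e5 /M/s and 1e-3 /s, with 5 log-spaced multistarts on failure.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one sensogram")
    top = max(float(np.max(tr.signal)) for tr in traces)
    rmax0 = max(top, 1e-6)

    def resid(p):
        lkon, lkoff, rmax = p[0], p[1], p[2]
        baselines = p[3:]
        k_on, k_off = 10.0**lkon, 10.0**lkoff
        parts = [
            _langmuir_trace(tr.time, tr.t_assoc_end, tr.analyte_conc, k_on, k_off, rmax, b)
            - tr.signal
            for tr, b in zip(traces, baselines)
        ]
        return np.concatenate(parts)

    nb = len(traces)
    lo = [0.0, -7.0, 0.0] + [-np.inf] * nb
    hi = [9.0, 2.0, np.inf] + [np.inf] * nb
    starts = [(5.0, -3.0)] + [(lk, lk - 9.0) for lk in (3.0, 4.0, 6.0, 7.0, 8.0)]
    best = None
    for lkon0, lkoff0 in starts:
        try:
            sol = optimize.least_squares(
                resid,
                [lkon0, lkoff0, rmax0] + [0.0] * nb,
                bounds=(lo, hi),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and best.cost < 1e-18:
            break
    if best is None:
        raise RuntimeError("global Langmuir fit failed to converge from all starts")
    k_on = 10.0 ** best.x[0]
    k_off = 10.0 ** best.x[1]
    return KineticFit(
        k_on=float(k_on),
        k_off=float(k_off),
        r_max=float(best.x[2]),
        kd=float(k_off / k_on),
        residual_sse=float(2.0 * best.cost),
    )


def fit_equilibrium_titration(
    concs: Sequence[float], eq_signals: Sequence[float]
) -> EquilibriumFit:
    """Fit y = rmax * C / (C + kd) to equilibrium plateau signals.

    Requires >= 4 concentrations spanning >= 2 decades. When the estimated
    kd exceeds the highest measured concentration (a non-saturating
    titration) the result is flagged ``extrapolated`` rather than rejected.
    """
    c = np.asarray(concs, dtype=float)
    y = np.asarray(eq_signals, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concs and eq_signals must have equal length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if math.log10(c.max() / c.min()) < 2.0:
        raise ValueError("titration must span at least 2 decades")

    def resid(p):
        lkd, rmax = p
        return rmax * c / (c + 10.0**lkd) - y

    p0 = [math.log10(np.median(c)), float(np.max(y)) or 1.0]
    sol = optimize.least_squares(
        resid,
        p0,
        bounds=([math.log10(c.min()) - 6, 0.0], [math.log10(c.max()) + 6, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
    )
    if not sol.success:
        raise RuntimeError(f"equilibrium titration fit failed: {sol.message}")
    kd = 10.0 ** sol.x[0]
    return EquilibriumFit(
        kd=float(kd),
        r_max=float(sol.x[1]),
        extrapolated=bool(kd > c.max()),
        residual_sse=float(2.0 * sol.cost),
    )
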