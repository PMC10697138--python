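"""Equilibrium models of IL-4 receptor complex assembly.

IL-4-class ligands signal by heterodimerizing the private IL-4R-alpha chain
with one of two co-receptors: the common gamma chain (type I complex) or
IL-13R-alpha-1 (type II complex). IL-13-class ligands use IL-13R-alpha-1 as
their private chain and recruit IL-4R-alpha.

Two model variants are implemented:

* **multivalent** -- the ligand may capture either of its receptors from
  solution first; the second (surface) binding step proceeds with an
  effective association constant ``Kx* * Ka * r_free``, where ``Kx*`` is a
  lumped crosslinking constant (molar * cell / receptor) converting the
  solution affinity ``Ka`` (1/M) into a dimensionless gain proportional to
  the free co-receptor abundance ``r_free`` (receptors/cell).
* **sequential** -- the ligand must bind its private receptor first; the
  non-private chains cannot capture ligand from solution and are consumed
  only by ternary complexes.

Free ligand is identified with the nominal dose (no depletion): even at
assay cell densities, picomolar--micromolar doses vastly exceed the molar
equivalent of per-cell receptor numbers.

Units: doses and Kd/Ka in molar (Ka = 1/Kd); receptor abundances in
receptors per cell; complexes in complexes per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Literal, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "IL4RA",
    "IL13RA1",
    "ReceptorPanel",
    "AffinityTable",
    "CrosslinkConstant",
    "EquilibriumState",
    "PredictedCurve",
    "SolverError",
    "solve_equilibrium_multivalent",
    "solve_equilibrium_sequential",
    "predict_curves",
]

IL4RA = "IL4Ra"
IL13RA1 = "IL13Ra1"

#: relative convergence tolerance of the fixed-point iteration
_FP_TOL = 1e-12
_FP_MAX_ITER = 100_000
_FP_DAMPING = 0.5


class SolverError(RuntimeError):
    """Raised when the equilibrium solver fails to converge."""


@dataclass(frozen=True)
class ReceptorPanel:
    """Total surface abundances of the three receptor chains on one cell type.

    A total of exactly 0 encodes "receptor not expressed / not detectable".
    """

    cell_type: str
    r_alpha_total: float
    r_gamma_total: float
    r_13_total: float

    def __post_init__(self) -> None:
        totals = (self.r_alpha_total, self.r_gamma_total, self.r_13_total)
        if any(t < 0 for t in totals):
            raise ValueError(f"receptor totals must be >= 0, got {totals}")
        if not any(t > 0 for t in totals):
            raise ValueError("at least one receptor total must be positive")


@dataclass(frozen=True)
class AffinityTable:
    """Solution association constants (1/M) of one ligand for each chain.

    ``ka_* == 0`` encodes "no binding" exactly; it is never approximated by
    a small constant. ``private_receptor`` names the chain the ligand binds
    first under the sequential model (IL-13-class ligands use IL13Ra1,
    everything else IL4Ra).
    """

    ligand: str
    ka_alpha: float
    ka_gamma: float
    ka_13: float
    private_receptor: str = IL4RA

    def __post_init__(self) -> None:
        if min(self.ka_alpha, self.ka_gamma, self.ka_13) < 0:
            raise ValueError("association constants must be >= 0")
        if self.private_receptor not in (IL4RA, IL13RA1):
            raise ValueError(f"unknown private receptor {self.private_receptor!r}")


@dataclass(frozen=True)
class CrosslinkConstant:
    """Lumped crosslinking constant Kx* (molar * cell / receptor).

    ``kx_star * ka * r_free`` is the dimensionless gain of the second
    (surface) binding step.
    """

    kx_star: float

    def __post_init__(self) -> None:
        if not self.kx_star > 0:
            raise ValueError("Kx* must be positive")


@dataclass(frozen=True)
class EquilibriumState:
    """Species abundances (per cell) at a single ligand dose."""

    dose: float
    free_alpha: float
    free_gamma: float
    free_13: float
    binary_alpha: float
    binary_gamma: float
    binary_13: float
    type_i: float
    type_ii: float

    @property
    def signal(self) -> float:
        """Predicted pSTAT6-generating complexes: type I + type II."""
        return self.type_i + self.type_ii


@dataclass(frozen=True)
class PredictedCurve:
    """Forward-predicted signal of one ligand on one cell type."""

    cell_type: str
    ligand: str
    doses: tuple
    signal: tuple
    normalized_signal: tuple


def _validate_dose(dose: float) -> None:
    if dose < 0 or not math.isfinite(dose):
        raise ValueError(f"dose must be finite and >= 0, got {dose}")


def _solve_free(
    dose,
    panel: ReceptorPanel,
    aff: AffinityTable,
    kx: float,
    solution_mask: tuple,
):
    """Solve the three conservation equations for free receptor abundances.

    ``solution_mask`` = (m_a, m_g, m_13) with entries in {0, 1} switching the
    solution-capture (binary-complex) term of each chain on or off; the
    multivalent model uses (1, 1, 1), the sequential variants zero out the
    non-private chains. Vectorized over ``dose``.

    Returns arrays (r_a, r_g, r_13).
    """
    L = np.asarray(dose, dtype=float)
    ra_t, rg_t, r13_t = panel.r_alpha_total, panel.r_gamma_total, panel.r_13_total
    ka, kg, k13 = aff.ka_alpha, aff.ka_gamma, aff.ka_13
    m_a, m_g, m_13 = solution_mask

    r_a = np.full_like(L, float(ra_t))
    r_g = np.full_like(L, float(rg_t))
    r_13 = np.full_like(L, float(r13_t))

    def step(r_a, r_g, r_13):
        new_a = ra_t / (1.0 + ka * L * (m_a + kx * (kg * r_g + k13 * r_13)))
        new_g = rg_t / (1.0 + m_g * kg * L + kx * ka * kg * L * r_a) if rg_t > 0 else r_g
        new_13 = r13_t / (1.0 + m_13 * k13 * L + kx * ka * k13 * L * r_a) if r13_t > 0 else r_13
        return new_a, new_g, new_13

    # note the alpha equation keeps its solution term only when alpha is
    # solution-accessible (m_a); for the IL-13-class sequential model the
    # private chain is IL13Ra1 and the ternary gain enters via the k13 term.
    if aff.private_receptor == IL13RA1 and m_a == 0:
        # private = IL13Ra1: ligand binds IL-13Ra1 from solution, recruits
        # IL-4Ra on the surface; gamma-c is not reachable.
        def step(r_a, r_g, r_13):  # noqa: F811 - deliberate redefinition
            new_13 = r13_t / (1.0 + k13 * L * (1.0 + kx * ka * r_a)) if r13_t > 0 else r_13
            new_a = ra_t / (1.0 + kx * k13 * ka * L * r_13)
            return new_a, r_g, new_13

    for _ in range(_FP_MAX_ITER):
        new_a, new_g, new_13 = step(r_a, r_g, r_13)
        new_a = _FP_DAMPING * r_a + (1 - _FP_DAMPING) * new_a
        new_g = _FP_DAMPING * r_g + (1 - _FP_DAMPING) * new_g
        new_13 = _FP_DAMPING * r_13 + (1 - _FP_DAMPING) * new_13
        delta = max(
            _rel_delta(new_a, r_a), _rel_delta(new_g, r_g), _rel_delta(new_13, r_13)
        )
        r_a, r_g, r_13 = new_a, new_g, new_13
        if delta < _FP_TOL:
            return r_a, r_g, r_13

    return _solve_free_newton(L, panel, aff, kx, solution_mask)


def _rel_delta(new, old):
    scale = np.maximum(np.abs(new), 1e-300)
    return float(np.max(np.abs(new - old) / scale))


def _solve_free_newton(L, panel, aff, kx, solution_mask):
    """Log-space Newton fallback; positivity is guaranteed by construction."""
    ra_t, rg_t, r13_t = panel.r_alpha_total, panel.r_gamma_total, panel.r_13_total
    out_a = np.empty_like(L)
    out_g = np.empty_like(L)
    out_13 = np.empty_like(L)
    for i, ell in np.ndenumerate(L):
        x0 = np.log(np.maximum([ra_t, rg_t, r13_t], 1e-6))

        def resid(x):
            r = np.exp(x)
            st = _species(ell, r[0], r[1], r[2], aff, kx, solution_mask)
            return [
                (r[0] + st["binary_alpha"] + st["type_i"] + st["type_ii"]) - ra_t,
                (r[1] + st["binary_gamma"] + st["type_i"]) - rg_t if rg_t > 0 else x[1] - x0[1],
                (r[2] + st["binary_13"] + st["type_ii"]) - r13_t if r13_t > 0 else x[2] - x0[2],
            ]

        sol = optimize.root(resid, x0, method="hybr", tol=1e-14)
        if not sol.success:
            raise SolverError(
                f"equilibrium solver failed to converge for {aff.ligand!r} on "
                f"{panel.cell_type!r} at dose {ell:.3g} M: {sol.message}"
            )
        r = np.exp(sol.x)
        out_a[i], out_g[i], out_13[i] = r
    if rg_t == 0:
        out_g[...] = 0.0
    if r13_t == 0:
        out_13[...] = 0.0
    return out_a, out_g, out_13


def _species(L, r_a, r_g, r_13, aff: AffinityTable, kx: float, solution_mask):
    """Complex abundances given free receptors (vectorized)."""
    ka, kg, k13 = aff.ka_alpha, aff.ka_gamma, aff.ka_13
    m_a, m_g, m_13 = solution_mask
    if aff.private_receptor == IL13RA1 and m_a == 0:
        return {
            "binary_alpha": 0.0 * np.asarray(r_a),
            "binary_gamma": 0.0 * np.asarray(r_g),
            "binary_13": k13 * L * r_13,
            "type_i": 0.0 * np.asarray(r_a),
            "type_ii": kx * ka * k13 * L * r_a * r_13,
        }
    return {
        "binary_alpha": m_a * ka * L * r_a,
        "binary_gamma": m_g * kg * L * r_g,
        "binary_13": m_13 * k13 * L * r_13,
        "type_i": kx * ka * kg * L * r_a * r_g,
        "type_ii": kx * ka * k13 * L * r_a * r_13,
    }


def _solve(dose, panel, aff, kx_const: CrosslinkConstant, solution_mask):
    _validate_dose(float(np.min(dose)) if np.ndim(dose) else dose)
    kx = kx_const.kx_star
    L = np.asarray(dose, dtype=float)
    scalar = L.ndim == 0
    L = np.atleast_1d(L)
    r_a, r_g, r_13 = _solve_free(L, panel, aff, kx, solution_mask)
    # zero-abundance chains stay identically zero
    if panel.r_gamma_total == 0:
        r_g = np.zeros_like(r_a)
    if panel.r_13_total == 0:
        r_13 = np.zeros_like(r_a)
    sp = _species(L, r_a, r_g, r_13, aff, kx, solution_mask)
    states = [
        EquilibriumState(
            dose=float(L[i]),
            free_alpha=float(r_a[i]),
            free_gamma=float(r_g[i]),
            free_13=float(r_13[i]),
            binary_alpha=float(np.atleast_1d(sp["binary_alpha"])[i] if np.ndim(sp["binary_alpha"]) else sp["binary_alpha"]),
            binary_gamma=float(np.atleast_1d(sp["binary_gamma"])[i] if np.ndim(sp["binary_gamma"]) else sp["binary_gamma"]),
            binary_13=float(np.atleast_1d(sp["binary_13"])[i] if np.ndim(sp["binary_13"]) else sp["binary_13"]),
            type_i=float(np.atleast_1d(sp["type_i"])[i] if np.ndim(sp["type_i"]) else sp["type_i"]),
            type_ii=float(np.atleast_1d(sp["type_ii"])[i] if np.ndim(sp["type_ii"]) else sp["type_ii"]),
        )
        for i in range(L.size)
    ]
    return states[0] if scalar else states


def solve_equilibrium_multivalent(
    dose, panel: ReceptorPanel, affinity: AffinityTable, kx: CrosslinkConstant
):
    """Equilibrium species under the multivalent (either-order) model.

    Solves the conservation system::

        Ra_T  = r_a  * [1 + Ka_a*L*(1 + Kx*(Ka_g*r_g + Ka_13*r_13))]
        Rg_T  = r_g  * [1 + Ka_g*L + Kx*Ka_a*Ka_g*L*r_a]
        R13_T = r_13 * [1 + Ka_13*L + Kx*Ka_a*Ka_13*L*r_a]

    with binary_x = Ka_x*L*r_x, type I = Kx*Ka_a*Ka_g*L*r_a*r_g and
    type II = Kx*Ka_a*Ka_13*L*r_a*r_13. No gamma-c/IL-13Ra1 co-complex
    exists: the ligand has a single co-receptor site.

    Accepts a scalar dose (returns one :class:`EquilibriumState`) or a
    sequence of doses (returns a list).
    """
    return _solve(dose, panel, affinity, kx, (1, 1, 1))


def solve_equilibrium_sequential(
    dose, panel: ReceptorPanel, affinity: AffinityTable, kx: CrosslinkConstant
):
    """Equilibrium species under the sequential (private-chain-first) model.

    Identical to the multivalent system except that non-private chains are
    not solution-accessible: their binary complexes are forbidden and they
    are consumed only through ternary complexes formed via the
    private-receptor intermediate. For IL-13-class ligands (private chain
    IL13Ra1) only the type II complex can form.
    """
    if affinity.private_receptor == IL4RA:
        mask = (1, 0, 0)
    else:
        mask = (0, 0, 1)
    return _solve(dose, panel, affinity, kx, mask)


_SOLVERS = {
    "multivalent": solve_equilibrium_multivalent,
    "sequential": solve_equilibrium_sequential,
}


def predict_curves(
    doses: Sequence[float],
    panel: ReceptorPanel,
    affinities: Iterable[AffinityTable],
    kx: CrosslinkConstant,
    model: Literal["multivalent", "sequential"] = "multivalent",
) -> List[PredictedCurve]:
    """Forward-predict normalized signal for each ligand on one cell type.

    signal = type I + type II complexes; the normalization is joint across
    all ligands of the cell type (each curve is divided by the maximum
    signal over all ligands and doses), matching a per-cell-type
    max-normalized pSTAT6 readout. If every signal is zero the normalized
    curves are returned as zeros.
    """
    affinities = list(affinities)
    doses = list(doses)
    if len(doses) < 1 or len(affinities) < 1:
        raise ValueError("need at least one dose and one ligand")
    try:
        solver = _SOLVERS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None

    signals = {}
    for aff in affinities:
        try:
            states = solver(np.asarray(doses, dtype=float), panel, aff, kx)
        except SolverError as err:
            raise SolverError(
                f"prediction failed for ligand {aff.ligand!r} on "
                f"{panel.cell_type!r}: {err}"
            ) from err
        signals[aff.ligand] = np.array([s.signal for s in states])

    top = max(float(np.max(sig)) for sig in signals.values())
    curves = []
    for aff in affinities:
        sig = signals[aff.ligand]
        norm = sig / top if top > 0 else np.zeros_like(sig)
        curves.append(
            PredictedCurve(
                cell_type=panel.cell_type,
                ligand=aff.ligand,
                doses=tuple(doses),
                signal=tuple(float(x) for x in sig),
                normalized_signal=tuple(float(x) for x in norm),
            )
        )
    return curves
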