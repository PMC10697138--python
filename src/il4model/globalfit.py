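"""Global least-squares estimation of ligand-receptor affinities and Kx*.

All dose-response panels (every cell type x ligand curve) are fitted
jointly: free parameters are log10 association constants for the
ligand-receptor pairs that bind, plus a single shared log10 Kx* used for
every experiment and cell type. Pairs declared "no binding" are held at
exactly zero and never enter the optimizer. Prediction inside the objective
runs the forward equilibrium model and recomputes the per-cell-type max
normalization at every evaluation.

Also provides prediction-accuracy scoring (coefficient of determination),
leave-one-curve-out cross-validation, and receptor-density sensitivity
scans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .binding import AffinityTable, CrosslinkConstant, ReceptorPanel, predict_curves

__all__ = [
    "FitConfig",
    "GlobalFitResult",
    "SensitivityResult",
    "fit_global",
    "accuracy",
    "cross_validate",
    "sensitivity_scan",
]

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]  # (ligand, receptor) with receptor in {alpha, gamma, il13ra1}
_RECEPTOR_FIELDS = {"alpha": "ka_alpha", "gamma": "ka_gamma", "il13ra1": "ka_13"}

#: sentinel recorded when a sensitivity-scan refit fails at some factor
FAILED_REFIT = float("nan")


@dataclass(frozen=True)
class FitConfig:
    """Optimizer configuration for the global fit.

    ``free_pairs`` lists the (ligand, receptor) association constants to
    optimize; any pair absent from it keeps the value in the seed affinity
    table (no-binding pairs stay at exactly zero). Bounds are in log10
    units: Ka in 1/M (default Kd window 100 uM .. 1 pM) and Kx* in
    molar*cell/receptor.
    """

    free_pairs: Tuple[Pair, ...]
    model: Literal["multivalent", "sequential"] = "multivalent"
    bounds_log10_ka: Tuple[float, float] = (4.0, 12.0)
    bounds_log10_kx: Tuple[float, float] = (-15.0, -5.0)
    fit_kx: bool = True
    multistart: int = 5
    seed: int = 0
    max_nfev: Optional[int] = None
    xtol: float = 1e-10

    def __post_init__(self) -> None:
        for pair in self.free_pairs:
            if pair[1] not in _RECEPTOR_FIELDS:
                raise ValueError(f"unknown receptor {pair[1]!r} in free pair {pair}")
        if self.bounds_log10_ka[0] >= self.bounds_log10_ka[1]:
            raise ValueError("Ka bounds must be increasing")
        if self.bounds_log10_kx[0] >= self.bounds_log10_kx[1]:
            raise ValueError("Kx* bounds must be increasing")


@dataclass
class GlobalFitResult:
    """Fitted parameters, residuals, and per-cell-type accuracy."""

    log10_ka: Dict[Pair, float]
    log10_kx: float
    residuals: Dict[Tuple[str, str], np.ndarray]  # (cell_type, ligand) -> residual vector
    sse: float
    accuracy_by_cell: Dict[str, float]
    config: FitConfig
    n_starts_converged: int = 0

    @property
    def kd_table(self) -> Dict[Pair, float]:
        """Fitted equilibrium dissociation constants (molar)."""
        return {pair: 10.0 ** (-v) for pair, v in self.log10_ka.items()}

    @property
    def kx_star(self) -> float:
        return 10.0**self.log10_kx


@dataclass
class SensitivityResult:
    """Refit MSE as one receptor's abundance on one cell type is scaled."""

    receptor: str
    cell_type: str
    factors: np.ndarray
    mse: np.ndarray
    baseline_mse: float
    evaluable: bool = True


def _panel_receptor_field(receptor: str) -> str:
    return {"alpha": "r_alpha_total", "gamma": "r_gamma_total", "il13ra1": "r_13_total"}[
        receptor
    ]


def _build_affinities(
    seed_affinities: Mapping[str, AffinityTable],
    free_pairs: Sequence[Pair],
    values: Sequence[float],
) -> Dict[str, AffinityTable]:
    tables = {lig: aff for lig, aff in seed_affinities.items()}
    for (ligand, receptor), log_ka in zip(free_pairs, values):
        aff = tables[ligand]
        tables[ligand] = replace(aff, **{_RECEPTOR_FIELDS[receptor]: 10.0**log_ka})
    return tables


def _grouped_observations(data: pd.DataFrame):
    """Pre-index observations: {cell_type: {ligand: (doses, obs, row_idx)}}."""
    groups: Dict[str, Dict[str, tuple]] = {}
    for (ct, lig), sub in data.groupby(["cell_type", "ligand"], sort=False):
        groups.setdefault(ct, {})[lig] = (
            sub["dose_molar"].to_numpy(dtype=float),
            sub["response"].to_numpy(dtype=float),
        )
    return groups


def predict_normalized(
    groups: Mapping[str, Mapping[str, tuple]],
    panels: Mapping[str, ReceptorPanel],
    affinities: Mapping[str, AffinityTable],
    kx: CrosslinkConstant,
    model: str,
) -> Dict[Tuple[str, str], np.ndarray]:
    """Forward-model normalized signal at every observed dose.

    Normalization is joint per cell type across all of its ligands, taken
    over the union of observed doses, and recomputed from scratch here (so
    it tracks the current parameter values during optimization).
    """
    out: Dict[Tuple[str, str], np.ndarray] = {}
    for ct, ligands in groups.items():
        panel = panels[ct]
        dose_union: Dict[str, np.ndarray] = {
            lig: np.unique(doses) for lig, (doses, _obs) in ligands.items()
        }
        curves = {}
        for lig in ligands:
            curves[lig] = predict_curves(
                dose_union[lig], panel, [affinities[lig]], kx, model=model
            )[0]
        top = max(max(c.signal) for c in curves.values())
        for lig, (doses, _obs) in ligands.items():
            signal = np.asarray(curves[lig].signal)
            raw = signal[np.searchsorted(dose_union[lig], doses)]
            out[(ct, lig)] = raw / top if top > 0 else np.zeros_like(raw)
    return out


def _objective_factory(groups, panels, seed_affinities, config: FitConfig, kx_fixed):
    def residual_vector(theta):
        if config.fit_kx:
            kx = CrosslinkConstant(10.0 ** theta[-1])
            ka_vals = theta[:-1]
        else:
            kx = kx_fixed
            ka_vals = theta
        affinities = _build_affinities(seed_affinities, config.free_pairs, ka_vals)
        pred = predict_normalized(groups, panels, affinities, kx, config.model)
        parts = [arr - groups[ct][lig][1] for (ct, lig), arr in pred.items()]
        return np.concatenate(parts)

    return residual_vector


def fit_global(
    data: pd.DataFrame,
    panels: Mapping[str, ReceptorPanel],
    seed_affinities: Mapping[str, AffinityTable],
    config: FitConfig,
    kx_fixed: Optional[CrosslinkConstant] = None,
) -> GlobalFitResult:
    """Fit free affinities and the shared Kx* to all curves jointly.

    ``data`` is a long-format normalized table with columns cell_type,
    ligand, dose_molar, response. ``seed_affinities`` provides the binding
    topology (private receptors and fixed/no-binding entries); values of
    free pairs are only used as a fallback and are replaced by the fit.
    """
    required = {"cell_type", "ligand", "dose_molar", "response"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns {sorted(missing)}")
    groups = _grouped_observations(data)
    for ct in groups:
        if ct not in panels:
            raise ValueError(f"no receptor panel for cell type {ct!r}")
        for lig in groups[ct]:
            if lig not in seed_affinities:
                raise ValueError(f"no affinity-topology row for ligand {lig!r}")

    observed_ligands = {lig for ligands in groups.values() for lig in ligands}
    for ligand, receptor in config.free_pairs:
        if ligand not in observed_ligands:
            warnings.warn(
                f"free parameter ({ligand}, {receptor}) is unconstrained: "
                f"no data point involves this ligand",
                stacklevel=2,
            )
    if not config.fit_kx and kx_fixed is None:
        raise ValueError("kx_fixed is required when fit_kx is False")

    n_ka = len(config.free_pairs)
    lo = [config.bounds_log10_ka[0]] * n_ka
    hi = [config.bounds_log10_ka[1]] * n_ka
    if config.fit_kx:
        lo.append(config.bounds_log10_kx[0])
        hi.append(config.bounds_log10_kx[1])
    lo, hi = np.array(lo), np.array(hi)

    residual_vector = _objective_factory(groups, panels, seed_affinities, config, kx_fixed)

    # First start: the seed affinity table (e.g. BLI-informed priors), the
    # natural initialization for a model whose fitted constants are expected
    # to converge toward measured binding data. Remaining starts are
    # Latin-hypercube draws over the bounding box, seeded.
    n_params = lo.size
    warm = []
    for ligand, receptor in config.free_pairs:
        ka = getattr(seed_affinities[ligand], _RECEPTOR_FIELDS[receptor])
        warm.append(np.log10(ka) if ka > 0 else 0.5 * (lo[0] + hi[0]))
    if config.fit_kx:
        warm.append(
            np.log10(kx_fixed.kx_star)
            if kx_fixed is not None
            else 0.5 * (config.bounds_log10_kx[0] + config.bounds_log10_kx[1])
        )
    warm = np.clip(np.array(warm), lo, hi)
    starts = [warm]
    n_lhs = max(config.multistart, 1) - 1
    if n_lhs > 0:
        sampler = qmc.LatinHypercube(d=n_params, seed=config.seed)
        starts.extend(lo + sampler.random(n_lhs) * (hi - lo))

    from scipy import optimize

    best = None
    n_ok = 0
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residual_vector,
                x0,
                bounds=(lo, hi),
                xtol=config.xtol,
                ftol=config.xtol,
                gtol=config.xtol,
                max_nfev=config.max_nfev,
            )
        except Exception as err:  # solver failures inside the forward model
            logger.warning("multistart failed: %s", err)
            continue
        if sol.success:
            n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("global fit failed: no multistart converged")

    theta = best.x
    if config.fit_kx:
        log10_kx = float(theta[-1])
        ka_vals = theta[:-1]
    else:
        log10_kx = float(np.log10(kx_fixed.kx_star))
        ka_vals = theta
    log10_ka = {pair: float(v) for pair, v in zip(config.free_pairs, ka_vals)}

    affinities = _build_affinities(seed_affinities, config.free_pairs, ka_vals)
    pred = predict_normalized(
        groups, panels, affinities, CrosslinkConstant(10.0**log10_kx), config.model
    )
    residuals = {key: pred[key] - groups[key[0]][key[1]][1] for key in pred}
    sse = float(sum(np.sum(r**2) for r in residuals.values()))

    result = GlobalFitResult(
        log10_ka=log10_ka,
        log10_kx=log10_kx,
        residuals=residuals,
        sse=sse,
        accuracy_by_cell={},
        config=config,
        n_starts_converged=n_ok,
    )
    result.accuracy_by_cell = {
        ct: accuracy(result, data, ct) for ct in groups
    }
    return result


def accuracy(result: GlobalFitResult, data: pd.DataFrame, cell_type: str) -> float:
    """Coefficient of determination R^2 = 1 - SSE/SStot for one cell type.

    Returns NaN (undefined sentinel) when the observations have zero
    variance.
    """
    keys = [k for k in result.residuals if k[0] == cell_type]
    if not keys:
        raise ValueError(f"no residuals available for cell type {cell_type!r}")
    obs = np.concatenate(
        [
            data[(data["cell_type"] == ct) & (data["ligand"] == lig)]
            ["response"].to_numpy(dtype=float)
            for ct, lig in keys
        ]
    )
    res = np.concatenate([result.residuals[k] for k in keys])
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum(res**2)) / ss_tot


def cross_validate(
    data: pd.DataFrame,
    panels: Mapping[str, ReceptorPanel],
    seed_affinities: Mapping[str, AffinityTable],
    config: FitConfig,
    scheme: str = "leave_one_curve_out",
) -> Dict:
    """Leave-one-dose-response-curve-out cross-validation.

    Each (cell_type, ligand) curve is held out in turn; the model is refit
    on the remainder and scored (R^2) on the held-out curve. Folds in which
    a free parameter becomes unconstrained are flagged and excluded from the
    summary mean with a logged warning.
    """
    if scheme != "leave_one_curve_out":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    curves = list(data.groupby(["cell_type", "ligand"], sort=False).groups)
    if len(curves) < 3:
        raise ValueError("cross-validation needs at least 3 curves")

    fold_results = []
    for ct, lig in curves:
        train = data[~((data["cell_type"] == ct) & (data["ligand"] == lig))]
        test = data[(data["cell_type"] == ct) & (data["ligand"] == lig)]
        train_ligands = set(train["ligand"])
        unconstrained = [p for p in config.free_pairs if p[0] not in train_ligands]
        if unconstrained:
            logger.warning(
                "fold (%s, %s) leaves parameters %s unconstrained; excluded",
                ct, lig, unconstrained,
            )
            fold_results.append(
                {"cell_type": ct, "ligand": lig, "accuracy": float("nan"),
                 "flagged": True}
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_global(train, panels, seed_affinities, config)
        groups = _grouped_observations(data)  # full data: normalization context
        affinities = _build_affinities(
            seed_affinities, config.free_pairs,
            [fit.log10_ka[p] for p in config.free_pairs],
        )
        pred = predict_normalized(
            groups, panels, affinities, CrosslinkConstant(fit.kx_star), config.model
        )
        obs = test["response"].to_numpy(dtype=float)
        res = pred[(ct, lig)] - groups[ct][lig][1]
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        acc = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(res**2)) / ss_tot
        fold_results.append(
            {"cell_type": ct, "ligand": lig, "accuracy": acc, "flagged": False}
        )

    valid = [f["accuracy"] for f in fold_results
             if not f["flagged"] and np.isfinite(f["accuracy"])]
    return {
        "folds": fold_results,
        "mean_accuracy": float(np.mean(valid)) if valid else float("nan"),
        "scheme": scheme,
    }


def sensitivity_scan(
    data: pd.DataFrame,
    panels: Mapping[str, ReceptorPanel],
    seed_affinities: Mapping[str, AffinityTable],
    config: FitConfig,
    receptor: str,
    cell_type: str,
    factors: Optional[Sequence[float]] = None,
) -> SensitivityResult:
    """Refit MSE while scaling one receptor's abundance on one cell type.

    Default factors: 13 log-spaced points over 1e-2 .. 1e2. Receptors with
    zero abundance on the cell type are not evaluable (the panel recorded
    them as undetectable) and are returned flagged, without refitting. A
    refit failure at one factor records a NaN sentinel and the scan
    continues.
    """
    if factors is None:
        factors = np.logspace(-2, 2, 13)
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("scale factors must be positive")
    fieldname = _panel_receptor_field(receptor)
    base_panel = panels[cell_type]
    base_value = getattr(base_panel, fieldname)
    if base_value == 0:
        return SensitivityResult(
            receptor=receptor,
            cell_type=cell_type,
            factors=factors,
            mse=np.full(factors.shape, FAILED_REFIT),
            baseline_mse=float("nan"),
            evaluable=False,
        )

    n_points = len(data)
    mse = np.empty(factors.shape)
    for i, factor in enumerate(factors):
        scaled = dict(panels)
        scaled[cell_type] = replace(base_panel, **{fieldname: base_value * factor})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_global(data, scaled, seed_affinities, config)
            mse[i] = fit.sse / n_points
        except Exception as err:
            logger.warning("sensitivity refit failed at factor %.3g: %s", factor, err)
            mse[i] = FAILED_REFIT

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        baseline = fit_global(data, panels, seed_affinities, config)
    return SensitivityResult(
        receptor=receptor,
        cell_type=cell_type,
        factors=factors,
        mse=mse,
        baseline_mse=baseline.sse / n_points,
    )
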