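"""End-to-end analysis pipeline: simulate -> Hill fits -> global fit ->
evaluation -> PCA, driven by a YAML config.

The pipeline is deterministic for a given (config, seed) and writes
long-format CSV/JSON outputs plus a provenance record (package version,
seed, config hash). Every file write is atomic. Run from a shell with::

    python -m il4model.pipeline demo.yaml

or from Python via :func:`run_pipeline`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import CrosslinkConstant
from .doseresponse import DoseResponseDataset, auc_log_dose, fit_hill
from .globalfit import FitConfig, cross_validate, fit_global, sensitivity_scan
from .io import (
    read_affinity_table,
    read_dose_response,
    read_receptor_panels,
    write_affinity_table,
    write_csv,
    write_json,
    write_receptor_panels,
)
from .quantify import pca_responses
from .synthesize import build_human_panel, build_mouse_panel, simulate_signaling_dataset

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "model",
    "panel",
    "data_csv",
    "panels_csv",
    "topology_csv",
    "replicates",
    "noise_sd",
    "multistart",
    "run_cross_validation",
    "run_sensitivity",
    "sensitivity_cell_type",
    "log_level",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``panel`` names a packaged synthetic configuration ("human" or
    "mouse"), or ``data_csv`` + ``panels_csv`` + ``topology_csv`` point at
    user tables. A seed is mandatory whenever any stage is stochastic
    (synthetic noise > 0 or multistart optimization).
    """

    out_dir: Path
    seed: Optional[int] = None
    model: str = "multivalent"
    panel: Optional[str] = None
    data_csv: Optional[Path] = None
    panels_csv: Optional[Path] = None
    topology_csv: Optional[Path] = None
    replicates: int = 3
    noise_sd: float = 0.05
    multistart: int = 3
    run_cross_validation: bool = False
    run_sensitivity: bool = False
    sensitivity_cell_type: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.model not in ("multivalent", "sequential", "both"):
            raise ValueError(f"unknown model variant {self.model!r}")
        if self.panel is None and self.data_csv is None:
            raise ValueError("config must set either 'panel' or 'data_csv'")
        if self.panel is not None and self.panel not in ("human", "mouse"):
            raise ValueError("panel must be 'human' or 'mouse'")
        stochastic = (self.panel is not None and self.noise_sd > 0) or self.multistart > 1
        if stochastic and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic stages")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    for key in ("data_csv", "panels_csv", "topology_csv"):
        if raw.get(key) is not None:
            raw[key] = Path(raw[key])
    raw["out_dir"] = Path(raw.get("out_dir", "il4model_out"))
    return RunConfig(**raw)


def _free_pairs(affinities) -> tuple:
    pairs = []
    for lig, aff in affinities.items():
        for receptor, ka in (
            ("alpha", aff.ka_alpha),
            ("gamma", aff.ka_gamma),
            ("il13ra1", aff.ka_13),
        ):
            if ka > 0:  # no-binding entries never enter the optimizer
                pairs.append((lig, receptor))
    return tuple(pairs)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full analysis and return a report dict.

    Stages: (optional) simulate -> Hill fits per curve -> global binding
    fit(s) -> per-cell accuracy (+ optional cross-validation and
    sensitivity scan) -> AUC-matrix PCA. Outputs land in ``config.out_dir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs ---------------------------------------------------------
    if config.panel is not None:
        panel_cfg = build_human_panel() if config.panel == "human" else build_mouse_panel()
        dataset = simulate_signaling_dataset(
            panel_cfg,
            model="multivalent" if config.model == "both" else config.model,
            replicates=config.replicates,
            seed=config.seed or 0,
            noise_sd=config.noise_sd,
        )
        data = dataset.data
        panels = panel_cfg.panels
        affinities = panel_cfg.affinities
        write_receptor_panels(panels, out / "receptor_panels.csv")
        write_affinity_table(affinities, out / "affinity_topology.csv")
        write_csv(data, out / "dose_response.csv")
    else:
        for key in ("panels_csv", "topology_csv"):
            if getattr(config, key) is None:
                raise ValueError(f"data_csv mode requires {key}")
        data = read_dose_response(config.data_csv)
        panels = read_receptor_panels(config.panels_csv)
        affinities = read_affinity_table(config.topology_csv)

    # --- Hill fits and AUC matrix --------------------------------------
    hill_rows: List[dict] = []
    auc_records: List[dict] = []
    dose_min = float(data["dose_molar"].min())
    dose_max = float(data["dose_molar"].max())
    for (ct, lig), sub in data.groupby(["cell_type", "ligand"], sort=False):
        fit = fit_hill(sub["dose_molar"].to_numpy(), sub["response"].to_numpy())
        hill_rows.append(
            {
                "cell_type": ct,
                "ligand": lig,
                "treatment": sub.get("treatment", pd.Series(["none"])).iloc[0],
                "bottom": fit.bottom,
                "top": fit.top,
                "ec50_molar": fit.ec50,
                "slope": fit.slope,
                "converged": fit.converged,
                "sse": fit.residual_sse,
            }
        )
        if fit.converged:
            for rep, rep_sub in sub.groupby("replicate"):
                rep_fit = fit_hill(
                    rep_sub["dose_molar"].to_numpy(), rep_sub["response"].to_numpy()
                )
                if rep_fit.converged:
                    auc_records.append(
                        {
                            "row": f"{ct}::rep{rep}",
                            "ligand": lig,
                            "auc": auc_log_dose(rep_fit, dose_min, dose_max),
                        }
                    )
    hill_df = pd.DataFrame(hill_rows)
    write_csv(hill_df, out / "hill_fits.csv")

    # --- global binding fit --------------------------------------------
    pairs = _free_pairs(affinities)
    variants = ["multivalent", "sequential"] if config.model == "both" else [config.model]
    fit_report = {}
    for variant in variants:
        fc = FitConfig(
            free_pairs=pairs,
            model=variant,
            multistart=config.multistart,
            seed=config.seed or 0,
        )
        result = fit_global(data, panels, affinities, fc)
        fit_report[variant] = {
            "log10_kx_star": result.log10_kx,
            "kx_star": result.kx_star,
            "fitted_kd_molar": {
                f"{lig}:{receptor}": kd for (lig, receptor), kd in result.kd_table.items()
            },
            "fitted_log10_ka": {
                f"{lig}:{receptor}": v for (lig, receptor), v in result.log10_ka.items()
            },
            "sse": result.sse,
            "accuracy_by_cell": result.accuracy_by_cell,
            "n_starts_converged": result.n_starts_converged,
        }
        if config.run_cross_validation:
            cv = cross_validate(data, panels, affinities, fc)
            fit_report[variant]["cross_validation"] = {
                "mean_accuracy": cv["mean_accuracy"],
                "folds": cv["folds"],
            }
        if config.run_sensitivity:
            ct = config.sensitivity_cell_type or next(iter(panels))
            scans = {}
            for receptor in ("alpha", "gamma", "il13ra1"):
                scan = sensitivity_scan(
                    data, panels, affinities, fc, receptor, ct,
                    factors=np.logspace(-2, 2, 5),
                )
                scans[receptor] = {
                    "evaluable": scan.evaluable,
                    "factors": list(scan.factors),
                    "mse": [None if not np.isfinite(v) else v for v in scan.mse],
                    "baseline_mse": None
                    if not np.isfinite(scan.baseline_mse)
                    else scan.baseline_mse,
                }
            fit_report[variant]["sensitivity"] = {"cell_type": ct, "scans": scans}

    # --- PCA of per-replicate AUC profiles ------------------------------
    pca_report = None
    if auc_records:
        auc_matrix = (
            pd.DataFrame(auc_records)
            .pivot_table(index="row", columns="ligand", values="auc")
        )
        if len(auc_matrix.dropna()) >= 3:
            scores, loadings, evr = pca_responses(auc_matrix)
            write_csv(scores.reset_index(), out / "pca_scores.csv")
            write_csv(loadings.reset_index(), out / "pca_loadings.csv")
            pca_report = {"explained_variance_ratio": [float(v) for v in evr]}

    # --- provenance ------------------------------------------------------
    config_echo = {
        k: (str(v) if isinstance(v, Path) else v) for k, v in vars(config).items()
    }
    config_hash = hashlib.sha256(
        json.dumps(config_echo, sort_keys=True).encode()
    ).hexdigest()
    report = {
        "version": __version__,
        "seed": config.seed,
        "config": config_echo,
        "config_sha256": config_hash,
        "global_fit": fit_report,
        "pca": pca_report,
        "n_observations": int(len(data)),
    }
    write_json(report, out / "report.json")
    return report


def main(argv=None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 1:
        print("usage: python -m il4model.pipeline CONFIG.yaml", file=sys.stderr)
        return 2
    report = run_pipeline(load_config(argv[0]))
    print(json.dumps({"out_dir": report["config"]["out_dir"],
                      "sse": {k: v["sse"] for k, v in report["global_fit"].items()}}))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
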