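"""CSV/JSON readers and writers for the pipeline's external interfaces.

Long-format CSV with explicit molar units in column names (``dose_molar``,
``Kd_molar``) throughout, to prevent pM/nM/uM confusion. All writes are
atomic (write to a temporary file in the same directory, then rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Union

import pandas as pd

from .binding import IL4RA, IL13RA1, AffinityTable, ReceptorPanel

__all__ = [
    "atomic_write_text",
    "write_csv",
    "write_json",
    "read_receptor_panels",
    "write_receptor_panels",
    "read_affinity_table",
    "write_affinity_table",
    "read_dose_response",
    "read_gene_sets",
    "write_sensograms",
    "read_sensograms",
]

_RECEPTOR_NAMES = ("IL4Ra", "gamma_c", "IL13Ra1")


def atomic_write_text(path: Union[str, Path], text: str) -> None:
    """Write text atomically: temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    atomic_write_text(path, df.to_csv(index=False))


def write_json(obj, path: Union[str, Path]) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_receptor_panels(path: Union[str, Path]) -> Dict[str, ReceptorPanel]:
    """Read a panel CSV: cell_type, receptor in {IL4Ra, gamma_c, IL13Ra1},
    receptors_per_cell."""
    df = pd.read_csv(path)
    _require(df, path, ["cell_type", "receptor", "receptors_per_cell"])
    bad = set(df["receptor"]) - set(_RECEPTOR_NAMES)
    if bad:
        raise ValueError(f"{path}: unknown receptor name(s) {sorted(bad)}")
    panels = {}
    for ct, sub in df.groupby("cell_type", sort=False):
        counts = dict(zip(sub["receptor"], sub["receptors_per_cell"]))
        panels[ct] = ReceptorPanel(
            cell_type=ct,
            r_alpha_total=float(counts.get("IL4Ra", 0.0)),
            r_gamma_total=float(counts.get("gamma_c", 0.0)),
            r_13_total=float(counts.get("IL13Ra1", 0.0)),
        )
    return panels


def write_receptor_panels(panels: Mapping[str, ReceptorPanel], path) -> None:
    rows = []
    for ct, p in panels.items():
        for receptor, value in zip(
            _RECEPTOR_NAMES, (p.r_alpha_total, p.r_gamma_total, p.r_13_total)
        ):
            rows.append(
                {"cell_type": ct, "receptor": receptor, "receptors_per_cell": value}
            )
    write_csv(pd.DataFrame(rows), path)


def read_affinity_table(path: Union[str, Path]) -> Dict[str, AffinityTable]:
    """Read an affinity CSV: ligand, receptor, Kd_molar (empty = no binding),
    private_receptor."""
    df = pd.read_csv(path)
    _require(df, path, ["ligand", "receptor", "Kd_molar", "private_receptor"])
    out = {}
    for lig, sub in df.groupby("ligand", sort=False):
        kd = dict(zip(sub["receptor"], sub["Kd_molar"]))
        private = sub["private_receptor"].iloc[0]
        if private not in (IL4RA, IL13RA1):
            raise ValueError(f"{path}: unknown private receptor {private!r}")

        def ka(name):
            value = kd.get(name)
            if value is None or pd.isna(value):
                return 0.0
            if value <= 0:
                raise ValueError(f"{path}: nonpositive Kd for ({lig}, {name})")
            return 1.0 / float(value)

        out[lig] = AffinityTable(
            ligand=lig,
            ka_alpha=ka("IL4Ra"),
            ka_gamma=ka("gamma_c"),
            ka_13=ka("IL13Ra1"),
            private_receptor=private,
        )
    return out


def write_affinity_table(affinities: Mapping[str, AffinityTable], path) -> None:
    rows = []
    for lig, aff in affinities.items():
        for receptor, ka in zip(
            _RECEPTOR_NAMES, (aff.ka_alpha, aff.ka_gamma, aff.ka_13)
        ):
            rows.append(
                {
                    "ligand": lig,
                    "receptor": receptor,
                    "Kd_molar": (1.0 / ka) if ka > 0 else None,
                    "private_receptor": aff.private_receptor,
                }
            )
    write_csv(pd.DataFrame(rows), path)


def read_dose_response(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, path, ["cell_type", "ligand", "dose_molar", "replicate", "response"])
    return df


def read_gene_sets(path: Union[str, Path]) -> Dict[str, List[str]]:
    """Two-column CSV (set, gene) -> {set name: gene list}."""
    df = pd.read_csv(path)
    _require(df, path, ["set", "gene"])
    return {name: list(sub["gene"]) for name, sub in df.groupby("set", sort=False)}


def write_sensograms(traces, path) -> None:
    rows = []
    for i, tr in enumerate(traces):
        for t, y in zip(tr.time, tr.signal):
            rows.append(
                {
                    "trace_id": i,
                    "analyte_conc_molar": tr.analyte_conc,
                    "time_s": float(t),
                    "signal_nm": float(y),
                    "phase": "association" if t <= tr.t_assoc_end else "dissociation",
                }
            )
    write_csv(pd.DataFrame(rows), path)


def read_sensograms(path: Union[str, Path]):
    from .bli import Sensogram

    df = pd.read_csv(path)
    _require(df, path, ["trace_id", "analyte_conc_molar", "time_s", "signal_nm", "phase"])
    traces = []
    for _tid, sub in df.groupby("trace_id", sort=True):
        sub = sub.sort_values("time_s")
        assoc = sub[sub["phase"] == "association"]
        t_assoc_end = float(assoc["time_s"].max()) if not assoc.empty else 0.0
        traces.append(
            Sensogram(
                analyte_conc=float(sub["analyte_conc_molar"].iloc[0]),
                time=sub["time_s"].to_numpy(dtype=float),
                signal=sub["signal_nm"].to_numpy(dtype=float),
                t_assoc_end=t_assoc_end,
            )
        )
    return traces


def _require(df: pd.DataFrame, path, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
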