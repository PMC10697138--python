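"""Downstream quantitation: AUC-matrix PCA, bead-calibrated receptor counts,
Livak fold changes, and gene-set overlap summaries.

These are the bespoke bookkeeping steps surrounding the binding model:
summarizing dose-response panels into an AUC matrix and projecting it onto
two principal components; converting antibody-staining MFIs into receptors
per cell via calibrated-bead standard curves; relative qPCR quantification
by the 2^-ddCt method; and exact set arithmetic on differentially-expressed
gene lists.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "BeadCalibration",
    "ReceptorCount",
    "pca_responses",
    "fit_bead_calibration",
    "quantify_receptors",
    "livak_fold_change",
    "overlap_summary",
]


# ---------------------------------------------------------------------------
# AUC-matrix PCA


def pca_responses(matrix: pd.DataFrame, n_components: int = 2):
    """Column-centered PCA of an AUC matrix (rows = replicate response
    profiles, columns = ligands).

    Rows with any missing entry (a cell line not stimulated with every
    ligand) are excluded before the decomposition; at least 3 complete rows
    are required. Columns are centered but not scaled to unit variance: the
    AUCs of normalized responses already share a scale.

    Returns (scores, loadings, explained_variance_ratio); loadings has one
    row per component.
    """
    complete = matrix.dropna(axis=0, how="any")
    if len(complete) < 3:
        raise ValueError(
            f"PCA needs >= 3 complete rows; {len(complete)} remain after "
            "excluding rows with missing ligand responses"
        )
    n_components = min(n_components, complete.shape[1], len(complete) - 1)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(complete.to_numpy(dtype=float))
    scores = pd.DataFrame(
        scores, index=complete.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    loadings = pd.DataFrame(
        pca.components_, index=scores.columns, columns=complete.columns
    )
    return scores, loadings, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# Bead calibration and receptor quantification


@dataclass(frozen=True)
class BeadCalibration:
    """log10(net MFI) = slope * log10(ABC) + intercept standard curve."""

    slope: float
    intercept: float
    r_squared: float
    background: float
    mfi_range: Tuple[float, float]  # net-MFI span of the bead populations


@dataclass(frozen=True)
class ReceptorCount:
    """Quantified receptors/cell; NaN count with below_detection=True when
    the net MFI is not positive."""

    count: float
    extrapolated: bool
    below_detection: bool


def fit_bead_calibration(
    abc: Sequence[float], mfi: Sequence[float], background: float = 0.0
) -> BeadCalibration:
    """Ordinary least squares on log10 scales after background subtraction.

    Calibration-bead kits span decades of antibody binding capacity (ABC);
    fitting on log-log scale avoids leverage domination by the brightest
    bead. Beads with nonpositive net MFI are dropped with a warning; a
    non-monotone bead series triggers a warning but is still fitted.
    """
    abc = np.asarray(abc, dtype=float)
    mfi = np.asarray(mfi, dtype=float)
    if abc.shape != mfi.shape:
        raise ValueError("abc and mfi must have equal length")
    if np.unique(abc).size < 3:
        raise ValueError("need >= 3 bead populations with distinct ABC")
    net = mfi - background
    keep = net > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} bead(s) with nonpositive net MFI",
            stacklevel=2,
        )
    abc, net = abc[keep], net[keep]
    if np.unique(abc).size < 3:
        raise ValueError("fewer than 3 usable beads after background subtraction")
    order = np.argsort(abc)
    if np.any(np.diff(net[order]) <= 0):
        warnings.warn("bead MFIs are not monotone in ABC", stacklevel=2)
    x, y = np.log10(abc), np.log10(net)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    if slope <= 0:
        raise ValueError("bead calibration slope must be positive")
    return BeadCalibration(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        background=background,
        mfi_range=(float(net.min()), float(net.max())),
    )


def quantify_receptors(
    cal: BeadCalibration, cell_mfi: float, background: Optional[float] = None
) -> ReceptorCount:
    """Invert the bead standard curve: MFI -> receptors per cell.

    A net MFI <= 0 yields the below-detection sentinel (NaN count), which
    feeds the zero-abundance convention of receptor panels. Queries outside
    the calibrated MFI span are answered but flagged ``extrapolated``.
    """
    bg = cal.background if background is None else background
    net = cell_mfi - bg
    if net <= 0:
        return ReceptorCount(count=float("nan"), extrapolated=False, below_detection=True)
    count = 10.0 ** ((math.log10(net) - cal.intercept) / cal.slope)
    extrapolated = not (cal.mfi_range[0] <= net <= cal.mfi_range[1])
    return ReceptorCount(count=float(count), extrapolated=extrapolated, below_detection=False)


# ---------------------------------------------------------------------------
# Livak relative quantification


def livak_fold_change(
    table: pd.DataFrame,
    control_gene: str,
    control_condition: str,
    summary: str = "arithmetic",
) -> pd.DataFrame:
    """2^-ddCt fold changes relative to a control condition.

    ``table`` columns: sample, condition, gene, ct. Per sample,
    dCt = Ct(gene) - Ct(control gene); ddCt subtracts the mean dCt of the
    control-condition samples for that gene; FC = 2^-ddCt and
    log2 FC = -ddCt. ``summary`` selects arithmetic or geometric
    mean/SD of FC per (condition, gene) in the returned per-group frame
    attached as ``.attrs['summary']`` (geometric summaries are conventional
    for tissue-level panels).
    """
    required = {"sample", "condition", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if summary not in ("arithmetic", "geometric"):
        raise ValueError("summary must be 'arithmetic' or 'geometric'")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("all Ct values must be finite")

    ctrl_ct = (
        table[table["gene"] == control_gene]
        .set_index("sample")["ct"]
    )
    work = table[table["gene"] != control_gene].copy()
    missing_ctrl = set(work["sample"]) - set(ctrl_ct.index)
    if missing_ctrl:
        raise ValueError(
            f"samples missing the endogenous-control gene {control_gene!r}: "
            f"{sorted(missing_ctrl)}"
        )
    work["delta_ct"] = work["ct"].to_numpy() - ctrl_ct.loc[work["sample"]].to_numpy()

    ref = work[work["condition"] == control_condition]
    if ref.empty:
        raise ValueError(f"no samples in control condition {control_condition!r}")
    ref_mean = ref.groupby("gene")["delta_ct"].mean()
    genes_wo_ref = set(work["gene"]) - set(ref_mean.index)
    if genes_wo_ref:
        raise ValueError(
            f"genes missing from the control condition: {sorted(genes_wo_ref)}"
        )
    work["ddct"] = work["delta_ct"].to_numpy() - ref_mean.loc[work["gene"]].to_numpy()
    work["log2_fc"] = -work["ddct"]
    work["fold_change"] = 2.0 ** work["log2_fc"]

    if summary == "arithmetic":
        summ = (
            work.groupby(["condition", "gene"])["fold_change"]
            .agg(["mean", "std"])
            .rename(columns={"mean": "fc_mean", "std": "fc_sd"})
        )
    else:
        grouped = work.groupby(["condition", "gene"])["log2_fc"]
        summ = pd.DataFrame(
            {
                "fc_geomean": 2.0 ** grouped.mean(),
                "fc_geosd": 2.0 ** grouped.std(),
            }
        )
    work.attrs["summary"] = summ
    return work


# ---------------------------------------------------------------------------
# Gene-set overlap arithmetic


def overlap_summary(sets: Mapping[str, Iterable[str]]) -> Dict:
    """Exact pairwise and k-way intersection counts and shared fractions.

    Shared fraction of A with B = |A n B| / |A| (asymmetric: the fraction
    of A's genes that B also regulates); the k-way shared fraction is
    |intersection of all| / |union of all|. Duplicate IDs within a set are
    deduplicated with a warning.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 gene sets")
    clean: Dict[str, frozenset] = {}
    for name, genes in sets.items():
        genes = list(genes)
        unique = frozenset(genes)
        if len(unique) < len(genes):
            warnings.warn(
                f"set {name!r} contains {len(genes) - len(unique)} duplicate "
                "gene ID(s); deduplicated",
                stacklevel=2,
            )
        clean[name] = unique

    names = list(clean)
    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        inter = len(clean[a] & clean[b])
        pairwise[(a, b)] = {
            "intersection": inter,
            "fraction_of_first": inter / len(clean[a]) if clean[a] else float("nan"),
            "fraction_of_second": inter / len(clean[b]) if clean[b] else float("nan"),
        }
    all_inter = len(frozenset.intersection(*clean.values()))
    all_union = len(frozenset.union(*clean.values()))
    return {
        "sizes": {name: len(s) for name, s in clean.items()},
        "pairwise": pairwise,
        "k_way_intersection": all_inter,
        "union": all_union,
        "k_way_shared_fraction": all_inter / all_union if all_union else float("nan"),
    }
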