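"""Anchoring gene expression to DNA-lesion burden.

A candidate probeset is "anchored" when the Spearman rank correlation
between its normalized expression and the O6-mG lesion burden across
MAM-treated animals exceeds 0.70 at one or more timepoints.  Correlations
are computed separately per timepoint, pooling both genotypes, and pair
brain expression with brain lesions.  Censored lesion values enter at the
MDQ midpoint, which is rank-safe because all censored values tie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import ExpressionMatrix

__all__ = ["spearman_rho", "anchor_genes", "LesionAnchor"]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  A constant vector has undefined rank
    correlation; NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _rho_matrix(E: np.ndarray, lesions: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of expression rows with one lesion vector."""
    R = np.apply_along_axis(stats.rankdata, 1, E)
    r = stats.rankdata(lesions)
    R = R - R.mean(axis=1, keepdims=True)
    r = r - r.mean()
    denom = np.sqrt((R * R).sum(axis=1) * (r @ r))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (R @ r) / denom, np.nan)


def anchor_genes(norm: ExpressionMatrix, lesions: pd.DataFrame,
                 sheet: pd.DataFrame, candidates, threshold: float = 0.70,
                 absolute: bool = False, tissue: str = "brain",
                 min_animals: int = 3) -> pd.DataFrame:
    """Per-candidate anchoring results.

    Returns a table with one row per candidate probeset: per-timepoint rho,
    max rho, the anchored flag (rho > threshold at >= 1 timepoint; the flag
    compares signed rho unless ``absolute``), and the number of animals
    used.  Timepoints with fewer than ``min_animals`` matched MAM animals
    are skipped with a warning.
    """
    if norm.scale != "log2":
        raise ValueError("expected log2-scale expression")
    candidates = [c for c in candidates]
    if not candidates:
        return pd.DataFrame(columns=["probeset_id", "max_rho", "anchored", "n_animals"])
    missing = set(candidates) - set(norm.values.index)
    if missing:
        raise ValueError(f"candidates absent from matrix: {sorted(missing)[:3]}")
    les = lesions[lesions["tissue"] == tissue].set_index("animal_id")
    sheet = (sheet.set_index("sample_id").loc[norm.values.columns]
             .rename_axis("sample_id").reset_index())
    mam = sheet[sheet["treatment"] == "MAM"]
    timepoints = sorted(sheet["timepoint_h"].unique())
    rho_cols = {}
    n_used = {}
    for tp in timepoints:
        sub = mam[mam["timepoint_h"] == tp]
        sub = sub[sub["animal_id"].isin(les.index)]
        if len(sub) < min_animals:
            warnings.warn(f"timepoint {tp} h skipped: only {len(sub)} matched MAM animals")
            continue
        E = norm.values.loc[candidates, sub["sample_id"]].to_numpy(dtype=float)
        lvals = les.loc[sub["animal_id"], "lesions_per_1e8"].to_numpy(dtype=float)
        rho_cols[tp] = _rho_matrix(E, lvals)
        n_used[tp] = len(sub)
    out = pd.DataFrame({"probeset_id": candidates})
    for tp, rho in rho_cols.items():
        out[f"rho_{tp}h"] = rho
    rho_mat = out[[c for c in out.columns if c.startswith("rho_")]].to_numpy()
    if rho_mat.size == 0:
        out["max_rho"] = np.nan
        out["anchored"] = False
        out["n_animals"] = 0
        return out
    comp = np.abs(rho_mat) if absolute else rho_mat
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out["max_rho"] = np.nanmax(comp, axis=1)
    out["anchored"] = np.nan_to_num(out["max_rho"], nan=-2.0) > threshold
    out["n_animals"] = max(n_used.values())
    return out


@dataclass
class LesionAnchor:
    """Estimator flagging candidates whose expression tracks lesion burden.

    Parameters
    ----------
    threshold : float
        Spearman rho above which a probeset is anchored (default 0.70).
    absolute : bool
        Apply the threshold to |rho| instead of signed rho.
    """

    threshold: float = 0.70
    absolute: bool = False
    tissue: str = "brain"

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold, "absolute": self.absolute,
                "tissue": self.tissue}

    def set_params(self, **params) -> "LesionAnchor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, norm: ExpressionMatrix, lesions: pd.DataFrame,
            sheet: pd.DataFrame, candidates) -> "LesionAnchor":
        self.results_ = anchor_genes(norm, lesions, sheet, candidates,
                                     threshold=self.threshold,
                                     absolute=self.absolute, tissue=self.tissue)
        self.anchored_ = frozenset(
            self.results_.loc[self.results_["anchored"], "probeset_id"])
        return self
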