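"""Per-probeset factorial linear models with a laboratory-consistency filter.

Each timepoint is analyzed separately.  The full model for a probeset's
log2 expression over the 2x2x2 (treatment x genotype x laboratory) layout is

    y ~ trt + geno + trt:geno + lab + lab:trt + lab:geno + lab:trt:geno

with sum-to-zero (+-1/2) factor coding, so each coefficient is directly the
corresponding group contrast on the log2 scale.  If any interaction
involving the laboratory is significant at p < 0.15 the probeset is
excluded (its effects are not laboratory-consistent); otherwise the model
is reduced to

    y ~ trt + geno + trt:geno + lab

and refitted, and the effects of interest are taken from the reduced fit.
Within each (timepoint, effect) family, p-values of non-excluded probesets
are Benjamini-Hochberg adjusted; a probeset is declared differentially
expressed when q < fdr and the absolute (signed) fold change 2^|estimate|
exceeds the fold-change gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import ExpressionMatrix

__all__ = [
    "FactorialDE",
    "DEGeneSet",
    "FullModelFit",
    "fit_full_model",
    "consistency_filter",
    "benjamini_hochberg",
    "call_de",
    "combine_analyses",
    "fold_change",
]

EFFECTS = ("treatment", "genotype", "interaction", "treatment_in_ko")

_FULL_TERMS = ("intercept", "treatment", "genotype", "interaction",
               "lab", "lab_treatment", "lab_genotype", "lab_interaction")
_REDUCED_TERMS = ("intercept", "treatment", "genotype", "interaction", "lab")
_LAB_INTERACTIONS = ("lab_treatment", "lab_genotype", "lab_interaction")


def _codes(sheet: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """+-1/2 sum-to-zero codes for treatment (MAM+), genotype (ko+), lab."""
    t = np.where(sheet["treatment"].to_numpy() == "MAM", 0.5, -0.5)
    g = np.where(sheet["genotype"].to_numpy() == "ko", 0.5, -0.5)
    sites = sorted(sheet["site"].unique())
    if len(sites) != 2:
        raise ValueError(f"expected 2 sites, found {sites}")
    lab = np.where(sheet["site"].to_numpy() == sites[1], 0.5, -0.5)
    return t, g, lab


def design_matrices(sheet: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(full, reduced) design matrices for one timepoint's arrays."""
    t, g, lab = _codes(sheet)
    one = np.ones_like(t)
    full = np.column_stack([one, t, g, t * g, lab, lab * t, lab * g, lab * t * g])
    reduced = full[:, :5]
    return full, reduced


def _ols(Y: np.ndarray, X: np.ndarray):
    """Vectorized OLS of many responses on one design matrix.

    Y is (n_probesets, n_arrays).  Returns (beta, cov_unit, sigma2, df, rss)
    where cov(beta_i) = sigma2_i * cov_unit.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("rank-deficient design (missing cell)")
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv          # (P, p)
    resid = Y - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    return beta, XtX_inv, sigma2, df, rss


def _term_pvalues(beta, XtX_inv, sigma2, df) -> np.ndarray:
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    return 2.0 * stats.t.sf(np.abs(tval), df)


@dataclass
class FullModelFit:
    """Fit of the 8-term full model for a single probeset at one timepoint."""

    coef: pd.Series
    pvalues: pd.Series
    y: np.ndarray
    sheet: pd.DataFrame
    df: int
    rss: float

    @property
    def lab_interaction_pvalues(self) -> pd.Series:
        return self.pvalues[list(_LAB_INTERACTIONS)]


def fit_full_model(y, sheet: pd.DataFrame) -> FullModelFit:
    """OLS fit of the full two-laboratory factorial model for one probeset."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(sheet):
        raise ValueError("response length does not match sample sheet")
    X, _ = design_matrices(sheet)
    beta, XtX_inv, sigma2, df, rss = _ols(y[None, :], X)
    pvals = _term_pvalues(beta, XtX_inv, sigma2, df)[0]
    return FullModelFit(coef=pd.Series(beta[0], index=_FULL_TERMS),
                        pvalues=pd.Series(pvals, index=_FULL_TERMS),
                        y=y, sheet=sheet, df=df, rss=float(rss[0]))


def _joint_lab_p(rss_full, rss_red, df_full) -> np.ndarray:
    """Joint F test of the three laboratory-interaction terms."""
    num = np.maximum(rss_red - rss_full, 0.0) / 3.0
    den = rss_full / df_full
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(den > 0, num / den, 0.0)
    return stats.f.sf(F, 3, df_full)


def consistency_filter(fit: FullModelFit, alpha_lab: float = 0.15,
                       joint: bool = False):
    """Laboratory-consistency rule for a single probeset.

    If the laboratory-interaction terms are all non-significant
    (p > alpha_lab; or the joint F-test p > alpha_lab when ``joint``), the
    model is reduced by dropping them (the lab main effect stays) and
    refitted; effects of interest come from the reduced fit.  Otherwise the
    probeset is excluded.  Returns (status, reduced_fit_or_None).
    """
    X_full, X_red = design_matrices(fit.sheet)
    if joint:
        _, _, _, _, rss_red = _ols(fit.y[None, :], X_red)
        p_joint = _joint_lab_p(np.array([fit.rss]), rss_red, fit.df)[0]
        consistent = p_joint > alpha_lab
    else:
        consistent = bool((fit.lab_interaction_pvalues > alpha_lab).all())
    if not consistent:
        return "excluded", None
    beta, XtX_inv, sigma2, df, _ = _ols(fit.y[None, :], X_red)
    pvals = _term_pvalues(beta, XtX_inv, sigma2, df)[0]
    reduced = FullModelFit(coef=pd.Series(beta[0], index=_REDUCED_TERMS),
                           pvalues=pd.Series(pvals, index=_REDUCED_TERMS),
                           y=fit.y, sheet=fit.sheet, df=df, rss=float("nan"))
    return "reduced", reduced


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fold_change(log2_estimate) -> np.ndarray:
    """Signed linear-scale fold change: sign(est) * 2^|est|."""
    est = np.asarray(log2_estimate, dtype=float)
    return np.sign(est) * np.exp2(np.abs(est))


@dataclass
class DEGeneSet:
    """Per-timepoint significant probesets plus their union and gene ids."""

    label: str
    per_timepoint: dict              # timepoint_h -> frozenset of probeset ids
    probeset_to_gene: dict = field(default_factory=dict)

    @property
    def union(self) -> frozenset:
        out = frozenset()
        for s in self.per_timepoint.values():
            out |= s
        return out

    @property
    def genes(self) -> frozenset:
        if not self.probeset_to_gene:
            return self.union
        return frozenset(self.probeset_to_gene[p] for p in self.union
                         if p in self.probeset_to_gene)

    def __len__(self) -> int:
        return len(self.union)


def call_de(results: pd.DataFrame, effect: str, fdr: float = 0.05,
            min_fc: float = 1.3, probeset_to_gene: dict | None = None,
            label: str | None = None) -> DEGeneSet:
    """Significance calls from a FactorialDE results table.

    BH is applied within each (timepoint, effect) family over non-excluded
    probesets; significant means q < fdr and |fold change| > min_fc.
    Excluded probesets are never significant.
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    per_tp = {}
    res = results.copy()
    res[f"q_{effect}"] = np.nan
    for tp, grp in results.groupby("timepoint_h"):
        ok = grp[grp["status"] == "reduced"]
        if ok.empty:
            warnings.warn(f"no laboratory-consistent probesets at {tp} h")
            per_tp[tp] = frozenset()
            continue
        q = benjamini_hochberg(ok[f"p_{effect}"].to_numpy())
        res.loc[ok.index, f"q_{effect}"] = q
        fc = fold_change(ok[f"estimate_{effect}"].to_numpy())
        sig = (q < fdr) & (np.abs(fc) > min_fc)
        per_tp[tp] = frozenset(ok.loc[sig, "probeset_id"])
    de = DEGeneSet(label=label or effect, per_timepoint=per_tp,
                   probeset_to_gene=probeset_to_gene or {})
    de.table = res
    return de


def combine_analyses(set_a: DEGeneSet, set_b: DEGeneSet) -> list:
    """De-duplicated union gene list of two analyses."""
    return sorted(set_a.genes | set_b.genes)


@dataclass
class FactorialDE:
    """Sklearn-style estimator for the per-timepoint factorial analysis.

    Parameters
    ----------
    fdr : float
        Benjamini-Hochberg q-value cutoff (default 0.05).
    min_fc : float
        Absolute linear fold-change gate (default 1.3).
    alpha_lab : float
        Laboratory-consistency threshold: any lab-interaction p-value at or
        below this excludes the probeset (default 0.15).
    joint_lab_test : bool
        Use a joint 3-df F test of the laboratory interactions instead of
        the three per-term tests.
    """

    fdr: float = 0.05
    min_fc: float = 1.3
    alpha_lab: float = 0.15
    joint_lab_test: bool = False

    def get_params(self, deep: bool = True) -> dict:
        return {"fdr": self.fdr, "min_fc": self.min_fc,
                "alpha_lab": self.alpha_lab, "joint_lab_test": self.joint_lab_test}

    def set_params(self, **params) -> "FactorialDE":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, norm: ExpressionMatrix, sheet: pd.DataFrame) -> "FactorialDE":
        """Fit all probesets at every timepoint.

        Produces ``results_``: one row per probeset x timepoint with status,
        laboratory-interaction p-values, and estimate/p for each effect of
        interest (treatment, genotype, interaction, and the MAM-vs-vehicle
        contrast within the knockout genotype).
        """
        if norm.scale != "log2":
            raise ValueError("expected log2-scale expression")
        values = norm.values
        missing = set(values.columns) - set(sheet["sample_id"])
        if missing:
            raise ValueError(f"arrays absent from sample sheet: {sorted(missing)[:3]}")
        sheet = (sheet.set_index("sample_id").loc[values.columns]
                 .rename_axis("sample_id").reset_index())
        rows = []
        contrast_in_ko = np.zeros(5)
        contrast_in_ko[[1, 3]] = [1.0, 0.5]   # trt + 0.5 * trt:geno
        for tp, sub in sheet.groupby("timepoint_h"):
            cols = sub["sample_id"].tolist()
            Y = values[cols].to_numpy(dtype=float)
            try:
                X_full, X_red = design_matrices(sub)
                beta_f, C_f, s2_f, df_f, rss_f = _ols(Y, X_full)
            except (np.linalg.LinAlgError, ValueError) as err:
                warnings.warn(f"timepoint {tp} h unestimable: {err}")
                for ps in values.index:
                    rows.append({"probeset_id": ps, "timepoint_h": tp,
                                 "status": "excluded", "reason": "unestimable"})
                continue
            p_f = _term_pvalues(beta_f, C_f, s2_f, df_f)
            lab_p = p_f[:, [_FULL_TERMS.index(t) for t in _LAB_INTERACTIONS]]
            beta_r, C_r, s2_r, df_r, rss_r = _ols(Y, X_red)
            if self.joint_lab_test:
                consistent = _joint_lab_p(rss_f, rss_r, df_f) > self.alpha_lab
            else:
                consistent = (lab_p > self.alpha_lab).all(axis=1)
            p_r = _term_pvalues(beta_r, C_r, s2_r, df_r)
            est_ko = beta_r @ contrast_in_ko
            var_unit = float(contrast_in_ko @ C_r @ contrast_in_ko)
            se_ko = np.sqrt(s2_r * var_unit)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_ko = np.where(se_ko > 0, est_ko / se_ko, np.inf * np.sign(est_ko))
            p_ko = 2.0 * stats.t.sf(np.abs(t_ko), df_r)
            for i, ps in enumerate(values.index):
                rec = {"probeset_id": ps, "timepoint_h": tp,
                       "status": "reduced" if consistent[i] else "excluded",
                       "reason": "",
                       "p_lab_treatment": lab_p[i, 0],
                       "p_lab_genotype": lab_p[i, 1],
                       "p_lab_3way": lab_p[i, 2]}
                if consistent[i]:
                    for eff, col in (("treatment", 1), ("genotype", 2), ("interaction", 3)):
                        rec[f"estimate_{eff}"] = beta_r[i, col]
                        rec[f"p_{eff}"] = p_r[i, col]
                    rec["estimate_treatment_in_ko"] = est_ko[i]
                    rec["p_treatment_in_ko"] = p_ko[i]
                rows.append(rec)
        self.results_ = pd.DataFrame(rows)
        self.sheet_ = sheet
        return self

    def de_set(self, effect: str, probeset_to_gene: dict | None = None,
               label: str | None = None) -> DEGeneSet:
        if not hasattr(self, "results_"):
            raise ValueError("FactorialDE is not fitted")
        return call_de(self.results_, effect, fdr=self.fdr, min_fc=self.min_fc,
                       probeset_to_gene=probeset_to_gene, label=label)
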