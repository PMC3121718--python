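"""RMA-style preprocessing of probe-level intensity matrices.

Three canonical steps: background correction under the normal+exponential
convolution model, quantile normalization across arrays, and Tukey
median-polish summarization of probes into probeset expression values.
Input is a plain probes x samples matrix; binary CEL/CDF parsing is out of
scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

__all__ = [
    "ExpressionMatrix",
    "background_correct",
    "quantile_normalize",
    "median_polish",
    "median_polish_summarize",
    "rma",
    "RMANormalizer",
]


@dataclass
class ExpressionMatrix:
    """Expression values with explicit scale bookkeeping.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are probes or probesets, columns are samples.
    scale : {"raw", "log2"}
        Raw intensities must be strictly positive.
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if not self.values.index.is_unique:
            raise ValueError("row ids are not unique")
        if not self.values.columns.is_unique:
            raise ValueError("column ids are not unique")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "raw" and (self.values.to_numpy() <= 0).any():
            raise ValueError("raw intensities must be strictly positive")

    @property
    def row_ids(self):
        return self.values.index

    @property
    def column_ids(self):
        return self.values.columns

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="row_id")

    @classmethod
    def from_tsv(cls, path, scale: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(values=df, scale=scale)


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def _density_mode(x: np.ndarray, nbins: int = 512) -> float:
    """Argmax of a Gaussian-smoothed histogram (Silverman bandwidth)."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return float(lo)
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    spread = min(x.std(), stats.iqr(x) / 1.34)
    if spread <= 0:
        spread = x.std() or (hi - lo)
    bw = 0.9 * spread * x.size ** (-0.2)
    binwidth = (hi - lo) / nbins
    # zero padding: like a boundary-truncated KDE, mass falls off at the
    # range edges instead of piling up there
    density = ndimage.gaussian_filter1d(counts.astype(float),
                                        sigma=max(bw / binwidth, 1e-6),
                                        mode="constant", cval=0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[np.argmax(density)])


def _estimate_bg_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """Estimate (mu, sigma, alpha) of the normal+exponential convolution.

    mu is the mode of a kernel density estimate of the intensities (the bulk
    of probes is background), sigma comes from the spread of points left of
    the mode, and the exponential rate alpha from the mean excess of points
    right of the mode.  This is the classic mode-based RMA heuristic.
    """
    # two-pass mode of a smoothed histogram: the second pass re-estimates
    # the density on the data left of the first mode, where the Silverman
    # bandwidth is no longer inflated by the long signal tail
    mu = _density_mode(x)
    left = x[x < mu]
    if left.size >= 2:
        mu = _density_mode(left)
    left = x[x < mu]
    right = x[x > mu]
    if left.size < 2 or right.size < 2:
        raise ValueError("degenerate intensity distribution")
    # left-tail sd, doubled because only half the normal is seen
    sigma = float(np.sqrt(np.sum((left - mu) ** 2) / (left.size - 1)) * np.sqrt(2.0) / 0.85)
    alpha = float(1.0 / np.mean(right - mu))
    return mu, sigma, alpha


def _mills_ratio(z: np.ndarray) -> np.ndarray:
    """phi(z)/Phi(z), computed stably for very negative z via erfcx."""
    # Phi(z) = 0.5*erfc(-z/sqrt 2); phi/Phi = sqrt(2/pi) / erfcx(-z/sqrt 2)
    return np.sqrt(2.0 / np.pi) / special.erfcx(-z / np.sqrt(2.0))


def background_correct(column: np.ndarray, return_params: bool = False):
    """Background-correct one array's raw intensities.

    Models observed intensity as signal ~ Exponential(alpha) plus noise
    ~ Normal(mu, sigma) and returns the posterior mean of the signal,
    E[s | x] = a + sigma * phi(a/sigma)/Phi(a/sigma) with
    a = x - mu - sigma^2 * alpha.  The transform is strictly positive and
    monotone in x.

    Parameters are estimated from the column itself.  A (near-)constant
    column is returned unchanged: there is no identifiable noise component.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1:
        raise ValueError("background_correct expects a single column")
    if (x <= 0).any():
        raise ValueError("raw intensities must be strictly positive")
    if np.ptp(x) == 0:
        out = x.copy()
        return (out, None) if return_params else out
    try:
        mu, sigma, alpha = _estimate_bg_parameters(x)
    except ValueError:
        out = x.copy()
        return (out, None) if return_params else out
    a = x - mu - sigma * sigma * alpha
    corrected = a + sigma * _mills_ratio(a / sigma)
    # posterior mean of a positive quantity; clip defends against rounding
    corrected = np.maximum(corrected, np.finfo(float).tiny)
    if return_params:
        return corrected, (mu, sigma, alpha)
    return corrected


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix | pd.DataFrame) -> ExpressionMatrix | pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns.  Tied values
    within a column receive the mean of the reference values at their tied
    ranks, which makes the operation idempotent.
    """
    if isinstance(matrix, ExpressionMatrix):
        out = quantile_normalize(matrix.values)
        return ExpressionMatrix(values=out, scale=matrix.scale)
    X = matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    order = np.argsort(X, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(X, order, axis=0), axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        target = reference.copy()
        # average reference values over runs of tied input values
        start = 0
        n = len(sorted_col)
        while start < n:
            stop = start + 1
            while stop < n and sorted_col[stop] == sorted_col[start]:
                stop += 1
            if stop - start > 1:
                target[start:stop] = target[start:stop].mean()
            start = stop
        out[idx, j] = target
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

def median_polish(block: np.ndarray, tol: float = 0.01, max_sweeps: int = 10):
    """Tukey median polish of a probes x samples block.

    Returns (overall, row_effects, col_effects, residuals).  Sweeping stops
    when the largest absolute change in any fitted effect drops below `tol`
    or after `max_sweeps` full sweeps.
    """
    z = np.asarray(block, dtype=float)
    if z.size == 0:
        raise ValueError("empty block")
    if z.ndim == 1:
        z = z[None, :]
    z = z.copy()
    nr, nc = z.shape
    t = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_sweeps):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        t += delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        t += delta
        change = max(np.max(np.abs(rdelta)), np.max(np.abs(cdelta)), abs(delta))
        if change < tol:
            break
    return t, row, col, z


def median_polish_summarize(block: np.ndarray, tol: float = 0.01, max_sweeps: int = 10) -> np.ndarray:
    """Per-sample probeset expression: overall effect + column effects."""
    z = np.asarray(block, dtype=float)
    if z.size == 0:
        raise ValueError("empty block")
    if z.ndim == 1 or z.shape[0] == 1:
        return z.reshape(-1).astype(float).copy()
    t, _, col, _ = median_polish(z, tol=tol, max_sweeps=max_sweeps)
    return t + col


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def rma(
    probes: ExpressionMatrix,
    probeset_of: pd.Series | dict,
    skip_background: bool = False,
    tol: float = 0.01,
    max_sweeps: int = 10,
) -> ExpressionMatrix:
    """Background-correct, quantile-normalize, log2, and summarize.

    Parameters
    ----------
    probes : ExpressionMatrix
        Raw probe-level intensities.
    probeset_of : mapping probe id -> probeset id
        Defines the blocks handed to median polish.
    """
    if probes.scale != "raw" and not skip_background:
        raise ValueError("background correction expects raw intensities")
    X = probes.values.to_numpy(dtype=float).copy()
    if not skip_background:
        for j in range(X.shape[1]):
            X[:, j] = background_correct(X[:, j])
    df = pd.DataFrame(X, index=probes.values.index, columns=probes.values.columns)
    df = quantile_normalize(df)
    df = np.log2(df)
    mapping = pd.Series(probeset_of)
    mapping = mapping.reindex(df.index)
    if mapping.isna().any():
        missing = df.index[mapping.isna()][:3].tolist()
        raise ValueError(f"probes without probeset annotation, e.g. {missing}")
    rows = []
    ids = []
    for ps, block in df.groupby(mapping, sort=True):
        rows.append(median_polish_summarize(block.to_numpy(), tol=tol, max_sweeps=max_sweeps))
        ids.append(ps)
    out = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="probeset_id"),
                       columns=df.columns)
    return ExpressionMatrix(values=out, scale="log2")


@dataclass
class RMANormalizer:
    """Sklearn-style transformer wrapping the RMA preprocessing pipeline.

    ``fit_transform(probes, probeset_of)`` runs the joint batch pipeline and
    stores the quantile reference distribution; ``transform`` maps further
    arrays onto that stored reference.
    """

    skip_background: bool = False
    tol: float = 0.01
    max_sweeps: int = 10
    reference_: np.ndarray = field(default=None, repr=False, compare=False)

    def get_params(self, deep: bool = True) -> dict:
        return {"skip_background": self.skip_background, "tol": self.tol,
                "max_sweeps": self.max_sweeps}

    def set_params(self, **params) -> "RMANormalizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, probes: ExpressionMatrix, probeset_of) -> ExpressionMatrix:
        X = probes.values.to_numpy(dtype=float).copy()
        if not self.skip_background:
            for j in range(X.shape[1]):
                X[:, j] = background_correct(X[:, j])
        self.reference_ = np.mean(np.sort(X, axis=0), axis=1)
        self.probeset_of_ = pd.Series(probeset_of)
        return rma(probes, probeset_of, skip_background=self.skip_background,
                   tol=self.tol, max_sweeps=self.max_sweeps)

    def fit(self, probes: ExpressionMatrix, probeset_of) -> "RMANormalizer":
        self.fit_transform(probes, probeset_of)
        return self

    def transform(self, probes: ExpressionMatrix) -> ExpressionMatrix:
        if self.reference_ is None:
            raise ValueError("RMANormalizer is not fitted")
        X = probes.values.to_numpy(dtype=float).copy()
        if not self.skip_background:
            for j in range(X.shape[1]):
                X[:, j] = background_correct(X[:, j])
        ranks = np.argsort(np.argsort(X, axis=0, kind="stable"), axis=0)
        X = self.reference_[ranks]
        df = np.log2(pd.DataFrame(X, index=probes.values.index,
                                  columns=probes.values.columns))
        rows, ids = [], []
        for ps, block in df.groupby(self.probeset_of_.reindex(df.index), sort=True):
            rows.append(median_polish_summarize(block.to_numpy(), tol=self.tol,
                                                max_sweeps=self.max_sweeps))
            ids.append(ps)
        out = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="probeset_id"),
                           columns=df.columns)
        return ExpressionMatrix(values=out, scale="log2")
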