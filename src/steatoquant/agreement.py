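"""Inter-rater agreement statistics for steatosis scoring.

Implements the single-rater two-way mixed-effects intraclass correlation
(consistency ICC(3,1) and absolute-agreement ICC(2,1) variants) from the
two-way ANOVA decomposition with exact F-based 95% confidence bounds,
plus Pearson correlation, ordinary least squares, and the count of
subjects with rater scores straddling a clinical decision threshold.

A rater table is a complete subjects x raters matrix of percent
estimates; it is carried as a pandas DataFrame (rows = subjects,
columns = raters).  A benchmark table of expert liver-pathologist strict
and gestalt estimates on ten control images, together with the
pixel-based algorithm estimate, ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import IccUndefinedError

__all__ = [
    "IccResult",
    "icc_two_way",
    "pearson_correlation",
    "linear_fit",
    "threshold_disagreement_count",
    "load_rater_table",
    "load_control_scores",
    "pairwise_pearson",
    "plot_agreement_heatmap",
]


@dataclass
class IccResult:
    """Single-rater two-way mixed-effects ICC with a 95% CI."""

    icc: float
    ci_low: float
    ci_high: float
    model: str
    n_subjects: int
    n_raters: int

    @property
    def ci_low_clipped(self) -> float:
        """Lower bound clipped at zero (common display convention)."""
        return max(0.0, self.ci_low)


def _as_matrix(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    values = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("rater table must be at least 2 subjects x 2 raters")
    if np.isnan(values).any():
        raise ValueError("rater table must be complete (no missing cells)")
    return values


def icc_two_way(
    table: pd.DataFrame | np.ndarray,
    agreement_type: str = "consistency",
    confidence: float = 0.95,
) -> IccResult:
    """Single-rater two-way mixed-effects intraclass correlation.

    Parameters
    ----------
    table : subjects x raters matrix of scores (complete).
    agreement_type : ``"consistency"`` (ICC(3,1): rater main effects
        ignored) or ``"absolute"`` (ICC(2,1)-style: rater main effects
        penalize agreement).
    confidence : two-sided confidence level for the F-based interval.

    Raises
    ------
    IccUndefinedError
        For a constant matrix (zero between-subject variance).
    """
    X = _as_matrix(table)
    n, k = X.shape
    alpha = 1.0 - confidence

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((X - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    if np.isclose(sst, 0.0):
        raise IccUndefinedError("constant rating matrix: between-subject variance is zero")

    if agreement_type == "consistency":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise IccUndefinedError("zero variance in every direction")
        icc = (msr - mse) / denom
        if mse == 0:
            lo = hi = 1.0
        else:
            fobs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
        model = "two-way mixed, single rater, consistency (ICC3,1)"
    elif agreement_type == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise IccUndefinedError("zero variance in every direction")
        icc = (msr - mse) / denom
        if mse == 0 and msc == 0:
            lo = hi = 1.0
        else:
            # Satterthwaite-approximated F bounds (McGraw & Wong)
            a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
            b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
            if np.isfinite(a) and np.isfinite(b):
                v_num = (a * msc + b * mse) ** 2
                v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = v_num / v_den
                f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f1 * mse) / (
                    f1 * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                hi = n * (f2 * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f2 * msr
                )
            else:
                lo = hi = 1.0
        model = "two-way mixed/random, single rater, absolute agreement (ICC2,1)"
    else:
        raise ValueError("agreement_type must be 'consistency' or 'absolute'")

    return IccResult(
        icc=float(icc), ci_low=float(lo), ci_high=float(hi),
        model=model, n_subjects=n, n_raters=k,
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, r_squared).

    A constant y returns slope 0 and r_squared 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if np.std(x) == 0:
        raise ValueError("OLS undefined for zero-variance predictor")
    if np.std(y) == 0:
        return 0.0, float(y[0]), 0.0
    slope, intercept, r, _, _ = stats.linregress(x, y)
    return float(slope), float(intercept), float(r * r)


def threshold_disagreement_count(
    table: pd.DataFrame | np.ndarray, threshold_percent: float = 30.0
) -> int:
    """Subjects whose raters straddle a clinical decision threshold.

    Counts subjects for which at least one rater scores strictly above
    the threshold and at least one scores at or below it — the cases
    where the transplant decision depends on which rater is asked.
    """
    X = _as_matrix(table)
    above = (X > threshold_percent).any(axis=1)
    at_or_below = (X <= threshold_percent).any(axis=1)
    return int((above & at_or_below).sum())


def load_rater_table(path: str | Path) -> pd.DataFrame:
    """Read a rater CSV (first column subject id, remaining columns raters)."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError("rater CSV needs a subject column plus >= 2 rater columns")
    df = df.set_index(df.columns[0])
    if df.isna().any().any():
        cell = next(
            (idx, col) for col in df.columns for idx in df.index if pd.isna(df.at[idx, col])
        )
        raise ValueError(f"missing value for subject {cell[0]!r}, rater {cell[1]!r}")
    return df.astype(float)


def load_control_scores() -> pd.DataFrame:
    """Bundled benchmark: expert strict/gestalt estimates on 10 control images.

    Columns: ``algorithm`` (pixel-based estimate) and ``LP{1,2,3}_strict``
    / ``LP{1,2,3}_gestalt`` percent estimates from three expert liver
    pathologists; index is the control image number.
    """
    with resources.files("steatoquant.data").joinpath("control_image_scores.csv").open() as fh:
        return pd.read_csv(fh, index_col=0)


def pairwise_pearson(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r matrix over the table's columns."""
    cols = list(table.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i < j:
                r, _ = pearson_correlation(table[a], table[b])
                out.iat[i, j] = out.iat[j, i] = r
    return out


def plot_agreement_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """Save a heatmap of a pairwise correlation matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(matrix.columns) + 2, 1.2 * len(matrix) + 1.5))
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(len(matrix.index)):
        for j in range(len(matrix.columns)):
            ax.text(j, i, f"{matrix.iat[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
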