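"""Descriptive and inferential statistics around the freezing phenotypes.

Covers the masked Pearson correlation matrices (only coefficients with
p < alpha are shown), pooled-SD Cohen's d effect sizes, Welch/pooled two-
sample t tests, pooled-OLS extinction slopes across repeated retrievals,
per-bin variance profiles, and the z-score outlier screen.

No multiple-testing correction is applied to the correlation matrices:
cells are masked at the raw per-pair p-value, which matches how such
matrices are usually displayed but inflates the family-wise error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import FreezingSession, phasic_window, sustained_window

#: |z| threshold for the outlier screen: two-sided p < 0.005 under the
#: standard normal, rounded to two decimals
ZSCORE_THRESHOLD = 2.81


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with a significance mask."""

    variables: list[str]
    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray  # True where p < alpha (shown in a masked display)
    alpha: float

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        idx = pd.Index(self.variables)
        return (pd.DataFrame(self.r, index=idx, columns=idx),
                pd.DataFrame(self.p, index=idx, columns=idx),
                pd.DataFrame(self.mask, index=idx, columns=idx))


def pearson_matrix(table: pd.DataFrame, alpha: float = 0.05) -> CorrelationResult:
    """Pairwise-complete Pearson correlation matrix with p < alpha mask.

    p-values come from the t transform with n − 2 degrees of freedom,
    two-sided.  Variable pairs with fewer than 3 complete observations
    or a constant variable get NaN r/p and are masked out.
    """
    cols = list(table.columns)
    m = len(cols)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    mask = np.zeros((m, m), dtype=bool)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(mask, True)
    for i in range(m):
        for j in range(i + 1, m):
            pair = table[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                warnings.warn(
                    f"pair ({cols[i]}, {cols[j]}): fewer than 3 complete "
                    "observations; masked out", stacklevel=2)
                continue
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                warnings.warn(
                    f"constant variable in pair ({cols[i]}, {cols[j]}); masked out",
                    stacklevel=2)
                continue
            res = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
            mask[i, j] = mask[j, i] = res.pvalue < alpha
    return CorrelationResult(cols, r, p, mask, alpha)


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d with the classic pooled standard deviation.

    Sign convention: mean(a) − mean(b); call as (sustained, phasic) so a
    positive d means higher freezing in the sustained group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if pooled_var == 0.0:
        raise ValueError("pooled standard deviation is zero; effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def welch_t(a: Sequence[float], b: Sequence[float],
            equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sample t test; Welch–Satterthwaite df unless ``equal_var``.

    Returns (t, df, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0 and a.mean() == b.mean():
        warnings.warn("zero variance in both samples with equal means; p = 1",
                      stacklevel=2)
        df = a.size + b.size - 2.0 if equal_var else float("nan")
        return 0.0, df, 1.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class SlopeResult:
    """Pooled-OLS extinction slope for one group (percent per retrieval)."""

    group: str
    slope: float
    p_value: float
    intercept: float
    n_points: int


def extinction_slope(sessions: Iterable[FreezingSession], component: str = "sustained",
                     sex: str | None = None, group: str | None = None) -> SlopeResult:
    """Extinction of a freezing component across retrievals MR1..MR6.

    Per animal-session the component mean (phasic: bins 13-17,
    sustained: bins 18-24) is computed; all animal-session points in the
    group are pooled and regressed on the session index (MR1 = 1 …
    MR6 = 6) by ordinary least squares.  A negative slope indicates
    extinction.
    """
    if component == "phasic":
        window = phasic_window
    elif component == "sustained":
        window = sustained_window
    else:
        raise ValueError("component must be 'phasic' or 'sustained'")

    xs, ys = [], []
    per_animal_sessions: dict[str, int] = {}
    for s in sessions:
        if not s.session.startswith("MR"):
            continue
        if sex is not None and s.sex != sex:
            continue
        xs.append(int(s.session.removeprefix("MR")))
        ys.append(float(np.mean(window(s))))
        per_animal_sessions[s.animal_id] = per_animal_sessions.get(s.animal_id, 0) + 1
    if len(set(xs)) < 2:
        raise ValueError("extinction regression needs at least 2 retrieval sessions")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.ptp(y) == 0.0:
        # flat response: zero slope, no evidence of extinction
        return SlopeResult(group or (sex or "all") + f"_{component}", 0.0, 1.0,
                           float(y[0]), len(y))
    res = sps.linregress(x, y)
    return SlopeResult(
        group=group or (sex or "all") + f"_{component}",
        slope=float(res.slope),
        p_value=float(res.pvalue),
        intercept=float(res.intercept),
        n_points=len(y),
    )


def variance_by_bin(sessions: Iterable[FreezingSession],
                    sex: str | None = None) -> tuple[np.ndarray, int]:
    """Per-bin sample variance of freezing across animals.

    Returns (24 variances, argmax bin as a 1-based index; ties go to
    the smallest index).  Expects sessions from a single session label.
    """
    rows = [s.bins for s in sessions if sex is None or s.sex == sex]
    if len(rows) < 2:
        raise ValueError("variance profile needs at least 2 animals")
    mat = np.asarray(rows, dtype=float)
    var = np.var(mat, axis=0, ddof=1)
    return var, int(np.argmax(var)) + 1


def zscore_screen(values: Sequence[float], threshold: float = ZSCORE_THRESHOLD) -> np.ndarray:
    """Boolean outlier mask: True where |z| exceeds the threshold.

    z uses the (n−1)-denominator SD; a zero-SD sample flags nothing.
    The default threshold 2.81 is the two-sided standard-normal critical
    value at p = 0.005, rounded to two decimals.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("outlier screen needs n >= 3")
    sd = np.std(x, ddof=1)
    if sd == 0.0:
        return np.zeros(x.size, dtype=bool)
    z = (x - x.mean()) / sd
    return np.abs(z) > threshold


def plot_correlation_heatmap(result: CorrelationResult, path=None):
    """Heatmap of the masked correlation matrix (non-significant cells blank)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = np.where(result.mask, result.r, np.nan)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(result.variables),) * 2)
    im = ax.imshow(shown, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(result.variables)), result.variables, rotation=90)
    ax.set_yticks(range(len(result.variables)), result.variables)
    fig.colorbar(im, ax=ax, label="Pearson r (p < %.2g)" % result.alpha)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
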