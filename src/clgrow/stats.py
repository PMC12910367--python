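"""Statistical design of the photoperiod experiment.

The experiment is a split-plot design: four replicate experiments in time
are blocks, photoperiod (18-h vs continuous light) is the main-plot factor
randomised to growth compartments within each block, and cultivar is the
sub-plot factor.  Accordingly the photoperiod F-test uses the
block x photoperiod stratum as its error, while cultivar and the
photoperiod x cultivar interaction are tested against the pooled
within-plot residual.

The module provides the full chain used on every trait: Tukey-fence
outlier flags computed within block x treatment x cultivar groups, the
stratified ANOVA with standard errors of means at the main and interaction
levels, Shapiro-Wilk residual normality, and Fisher's protected LSD letter
display (mean separation is attempted only when the gating F-probability
is below alpha).

Sums of squares use Type-III conventions with sum-to-zero contrasts (RSS
difference between the full model and the model without the term), which
coincides with the classical balanced-design partition; equal variance is
assumed throughout (four blocks do not support variance modelling).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "tukey_outliers",
    "tukey_fences",
    "split_plot_anova",
    "SplitPlotResult",
    "protected_lsd",
    "shapiro_wilk",
]


def tukey_fences(values: np.ndarray) -> tuple[float, float]:
    """Tukey's outlier fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation (the numpy default); the rule is
    invariant to adding a constant and to positive scaling.
    """
    q1, q3 = np.quantile(np.asarray(values, dtype=float), [0.25, 0.75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def tukey_outliers(
    table: pd.DataFrame,
    value: str = "value",
    by: tuple[str, ...] = ("block", "treatment", "cultivar"),
    min_group: int = 4,
) -> pd.Series:
    """Flag outliers outside the Tukey fences within each group.

    Returns a boolean Series aligned to ``table``; groups smaller than
    ``min_group`` are skipped (no flags) with a warning.
    """
    flags = pd.Series(False, index=table.index)
    for key, grp in table.groupby(list(by), sort=False, observed=True):
        if len(grp) < min_group:
            warnings.warn(
                f"group {key}: only {len(grp)} values, skipping outlier screen",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        lo, hi = tukey_fences(grp[value].to_numpy())
        vals = grp[value]
        flags.loc[grp.index] = (vals < lo) | (vals > hi)
    return flags


# --------------------------------------------------------------------------
# split-plot ANOVA

def _sum_contrasts(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero contrast columns for a factor, shape (n, n_levels - 1)."""
    out = np.zeros((len(codes), n_levels - 1))
    for j in range(n_levels - 1):
        out[codes == j, j] = 1.0
        out[codes == n_levels - 1, j] = -1.0
    return out


def _interact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    cols = [a[:, i] * b[:, j] for i in range(a.shape[1]) for j in range(b.shape[1])]
    return np.column_stack(cols) if cols else np.empty((len(a), 0))


def _rss(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def _f_prob(ss: float, df: float, ms_err: float, df_err: float) -> float:
    """F probability with the degenerate-data conventions.

    Zero treatment SS yields p = 1 (nothing to test); zero error MS with
    positive treatment SS yields F = inf, p = 0.
    """
    if df <= 0 or df_err <= 0:
        return 1.0
    if ss <= 1e-12:
        return 1.0
    if ms_err <= 1e-12:
        return 0.0
    f = (ss / df) / ms_err
    return float(sps.f.sf(f, df, df_err))


@dataclass
class SplitPlotResult:
    """Split-plot ANOVA summary for one trait.

    ``anova`` is the full table (term, df, ss, ms, f, p).  F-probabilities,
    SEMs and LSD inputs are exposed separately for the main (photoperiod)
    and interaction (photoperiod x cultivar) levels; ``letters_main`` and
    ``letters_interaction`` hold the protected-LSD display.
    """

    anova: pd.DataFrame
    f_prob_main: float
    f_prob_cultivar: float
    f_prob_interaction: float
    sem_main: float
    sem_interaction: float
    df_main_error: int
    df_sub_error: int
    ms_main_error: float
    ms_residual: float
    means_main: pd.Series
    means_cell: pd.Series
    n_per_main: float
    n_per_cell: float
    residuals: np.ndarray
    letters_main: dict[str, str] = field(default_factory=dict)
    letters_interaction: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def se_diff_main(self) -> float:
        return float(np.sqrt(max(2.0 * self.ms_main_error, 0.0) / self.n_per_main))

    @property
    def se_diff_interaction(self) -> float:
        return float(np.sqrt(max(2.0 * self.ms_residual, 0.0) / self.n_per_cell))


def split_plot_anova(
    table: pd.DataFrame,
    value: str = "value",
    block: str = "block",
    treatment: str = "treatment",
    cultivar: str = "cultivar",
    alpha: float = 0.05,
) -> SplitPlotResult:
    """Split-plot ANOVA with blocks for one trait.

    Strata: blocks; main plots (photoperiod tested against the
    block x photoperiod mean square); sub plots (cultivar and the
    interaction tested against the pooled residual).  Near-balanced tables
    (unequal plants per cell after outlier removal) are handled by
    Type-III RSS differences under sum-to-zero coding; missing whole cells
    are a design error.

    SEM conventions (documented): the main-level SEM is
    ``sqrt(MS_mainplot_error / n_per_main)`` with ``n_per_main`` the
    (harmonic-mean) observation count per main-level mean; the
    interaction-level SEM is ``sqrt(MS_residual / n_per_cell)``.
    """
    df = table[[block, treatment, cultivar, value]].dropna().copy()
    blocks = np.sort(df[block].unique())
    treats = list(pd.unique(df[treatment]))
    cults = list(pd.unique(df[cultivar]))
    b, t, c = len(blocks), len(treats), len(cults)
    if b < 2:
        raise ValueError("split-plot ANOVA needs >= 2 blocks")
    cell_counts = df.groupby([treatment, cultivar], observed=True)[value].count()
    if len(cell_counts) < t * c or (cell_counts == 0).any():
        raise ValueError("design error: missing whole treatment x cultivar cells")

    y = df[value].to_numpy(float)
    n = len(y)
    bc = _sum_contrasts(pd.Categorical(df[block], categories=blocks).codes, b)
    tc = _sum_contrasts(pd.Categorical(df[treatment], categories=treats).codes, t)
    cc = _sum_contrasts(pd.Categorical(df[cultivar], categories=cults).codes, c)
    terms = {
        "block": bc,
        "treatment": tc,
        "block:treatment": _interact(bc, tc),
        "cultivar": cc,
        "treatment:cultivar": _interact(tc, cc),
    }
    dfs = {
        "block": b - 1,
        "treatment": t - 1,
        "block:treatment": (b - 1) * (t - 1),
        "cultivar": c - 1,
        "treatment:cultivar": (t - 1) * (c - 1),
    }
    intercept = np.ones((n, 1))
    x_full = np.column_stack([intercept] + list(terms.values()))
    rss_full = _rss(y, x_full)
    df_resid = n - x_full.shape[1]
    ss = {}
    for name in terms:
        x_red = np.column_stack(
            [intercept] + [m for k, m in terms.items() if k != name]
        )
        ss[name] = _rss(y, x_red) - rss_full
    ss_total = float(np.sum((y - y.mean()) ** 2))

    ms_ea = ss["block:treatment"] / dfs["block:treatment"]
    ms_res = rss_full / df_resid if df_resid > 0 else 0.0
    p_main = _f_prob(ss["treatment"], dfs["treatment"], ms_ea, dfs["block:treatment"])
    p_cult = _f_prob(ss["cultivar"], dfs["cultivar"], ms_res, df_resid)
    p_int = _f_prob(ss["treatment:cultivar"], dfs["treatment:cultivar"], ms_res, df_resid)

    rows = []
    for name in ("block", "treatment", "block:treatment", "cultivar", "treatment:cultivar"):
        ms = ss[name] / dfs[name]
        if name == "treatment":
            err_ms, err_df, p = ms_ea, dfs["block:treatment"], p_main
        elif name in ("cultivar", "treatment:cultivar"):
            err_ms, err_df, p = ms_res, df_resid, {"cultivar": p_cult, "treatment:cultivar": p_int}[name]
        else:
            err_ms, err_df, p = np.nan, np.nan, np.nan
        f = ms / err_ms if err_ms and err_ms > 1e-12 else np.inf if ms > 1e-12 else np.nan
        rows.append((name, dfs[name], ss[name], ms, f, p))
    rows.append(("residual", df_resid, rss_full, ms_res, np.nan, np.nan))
    rows.append(("total", n - 1, ss_total, np.nan, np.nan, np.nan))
    anova = pd.DataFrame(rows, columns=["term", "df", "ss", "ms", "f", "p"])

    n_per_main = len(df) / t
    n_per_cell = float(sps.hmean(cell_counts.to_numpy()))
    means_main = df.groupby(treatment, observed=True)[value].mean().reindex(treats)
    means_cell = (
        df.groupby([treatment, cultivar], observed=True)[value].mean()
        .reindex(pd.MultiIndex.from_product([treats, cults]))
    )
    beta, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    residuals = y - x_full @ beta

    res = SplitPlotResult(
        anova=anova,
        f_prob_main=p_main,
        f_prob_cultivar=p_cult,
        f_prob_interaction=p_int,
        sem_main=float(np.sqrt(ms_ea / n_per_main)) if ms_ea > 0 else 0.0,
        sem_interaction=float(np.sqrt(ms_res / n_per_cell)) if ms_res > 0 else 0.0,
        df_main_error=dfs["block:treatment"],
        df_sub_error=df_resid,
        ms_main_error=ms_ea,
        ms_residual=ms_res,
        means_main=means_main,
        means_cell=means_cell,
        n_per_main=n_per_main,
        n_per_cell=n_per_cell,
        residuals=residuals,
    )
    res.letters_main = protected_lsd(
        means_main.to_dict(), res.se_diff_main, res.df_main_error,
        alpha=alpha, gate_p=p_main,
    )
    res.letters_interaction = protected_lsd(
        means_cell.to_dict(), res.se_diff_interaction, res.df_sub_error,
        alpha=alpha, gate_p=p_int,
    )
    return res


def protected_lsd(
    means: dict,
    se_diff: float,
    df_error: int,
    alpha: float = 0.05,
    gate_p: float = 0.0,
) -> dict:
    """Fisher's protected LSD letter display.

    Means whose difference exceeds ``LSD = t(1 - alpha/2, df_error) *
    se_diff`` receive different letters, assigned by descending mean with
    standard interval chaining.  "Protected": when the gating ANOVA
    F-probability ``gate_p`` is not below ``alpha``, no comparisons are
    made and all means share one letter.
    """
    keys = sorted(means, key=lambda k: -means[k])
    if gate_p >= alpha or len(keys) == 1 or se_diff <= 0 or df_error <= 0:
        return {k: "a" for k in keys}
    lsd = float(sps.t.ppf(1.0 - alpha / 2.0, df_error)) * se_diff
    vals = [means[k] for k in keys]
    # maximal runs of mutually non-separated means (constant LSD => runs
    # are intervals in the sorted order)
    intervals = []
    for i in range(len(vals)):
        j = i
        while j + 1 < len(vals) and vals[i] - vals[j + 1] <= lsd:
            j += 1
        if not intervals or j > intervals[-1][1]:
            if intervals and intervals[-1][0] == i:
                intervals[-1] = (i, j)
            else:
                intervals.append((i, j))
    letters = {k: "" for k in keys}
    for letter, (i, j) in zip(string.ascii_lowercase, intervals):
        for k in keys[i:j + 1]:
            letters[k] += letter
    return letters


def shapiro_wilk(residuals) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000 residuals."""
    r = np.asarray(residuals, dtype=float)
    if not 3 <= len(r) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(r)}")
    if np.ptp(r) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant residuals")
    w, p = sps.shapiro(r)
    return float(w), float(p)
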