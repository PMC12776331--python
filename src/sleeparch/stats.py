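"""Factorial group statistics for sleep-architecture and spectral endpoints.

Covers the designs used for telemetry cohorts of wildtype vs knock-in mice:

* two-factor between-subject ANOVA (e.g. Genotype × Sex) with Type III sums
  of squares, so unbalanced cells (group sizes such as 8/6/9/8) are handled
  the way mainstream statistics packages do;
* split-plot (repeated-measures) ANOVA with one between-subject factor and
  one within-subject factor (e.g. time of day, 24 ZT-hour levels), complete
  cases only — subjects missing any within level are dropped with a warning.
  This matches a REML mixed-effects analysis exactly when the data are
  complete, and approximates it otherwise;
* Fisher's LSD post-hoc pairwise tests on the ANOVA's pooled error term
  (unadjusted, per the LSD convention);
* per-frequency-bin unpaired t-tests between groups with Holm-Šídák
  step-down multiple-comparison correction across the analyzed range, and
  extraction of contiguous significant frequency ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaTable", "PosthocResult", "BinComparison",
    "twoway_anova", "repeated_anova", "fishers_lsd",
    "holm_sidak", "per_bin_compare",
]


@dataclass(frozen=True)
class AnovaTable:
    """Effect decomposition: one row per effect with SS, df, MS, F, p."""

    table: pd.DataFrame  # index: effect name; columns: SS, df, MS, F, p
    error_term: str      # index label of the error row used for F of the
                         # between effects (LSD draws MS/df from here)

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]

    @property
    def error_ms(self) -> float:
        return float(self.table.loc[self.error_term, "MS"])

    @property
    def error_df(self) -> float:
        return float(self.table.loc[self.error_term, "df"])


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    mean_diff: float
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class BinComparison:
    """Per-bin group comparison with step-down-corrected decisions."""

    freqs_hz: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    reject: np.ndarray
    significant_ranges_hz: tuple[tuple[float, float], ...]


# ---------------------------------------------------------------------------
# factorial ANOVA
# ---------------------------------------------------------------------------

def twoway_anova(values, factor_a, factor_b,
                 names: tuple[str, str] = ("A", "B")) -> AnovaTable:
    """Two-factor between-subject ANOVA with Type III sums of squares.

    ``values`` is one observation per subject; ``factor_a``/``factor_b`` the
    subject's levels.  Type III SS (sum-to-zero contrasts) are used so main
    effects are tested in the presence of the interaction even when cell
    sizes are unequal; on balanced data this coincides with the sequential
    decomposition.  Raises on empty design cells, naming the cell.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "A": np.asarray(factor_a, dtype=object),
                       "B": np.asarray(factor_b, dtype=object)})
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least two levels")
    counts = df.groupby(["A", "B"], observed=True).size()
    for a in df["A"].unique():
        for b in df["B"].unique():
            if (a, b) not in counts.index:
                raise ValueError(f"design cell ({a}, {b}) is empty")
    name_a, name_b = names
    if np.ptp(df["y"].to_numpy()) == 0:
        logger.warning("all observations identical; ANOVA is degenerate "
                       "(every F reported as 0)")
        n = len(df)
        na, nb = df["A"].nunique(), df["B"].nunique()
        dfs = {name_a: na - 1.0, name_b: nb - 1.0,
               f"{name_a} x {name_b}": (na - 1.0) * (nb - 1.0)}
        dfs["Error"] = n - na * nb
        out = pd.DataFrame({"SS": 0.0, "df": pd.Series(dfs), "MS": 0.0,
                            "F": 0.0, "p": 1.0})
        out.loc["Error", ["F", "p"]] = np.nan
        return AnovaTable(out, error_term="Error")
    model = smf.ols("y ~ C(A, Sum) * C(B, Sum)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    rename = {"C(A, Sum)": name_a, "C(B, Sum)": name_b,
              "C(A, Sum):C(B, Sum)": f"{name_a} x {name_b}", "Residual": "Error"}
    aov = aov.rename(index=rename).drop(index="Intercept")
    out = pd.DataFrame({
        "SS": aov["sum_sq"],
        "df": aov["df"],
        "MS": aov["sum_sq"] / aov["df"],
        "F": aov["F"],
        "p": aov["PR(>F)"],
    })
    if out.loc["Error", "MS"] == 0:
        logger.warning("zero error mean square (all residuals zero); "
                       "F statistics are degenerate")
        effects = out.index != "Error"
        out.loc[effects, "F"] = np.where(out.loc[effects, "SS"] == 0, 0.0, np.inf)
        out.loc[effects, "p"] = np.where(out.loc[effects, "SS"] == 0, 1.0, 0.0)
    return AnovaTable(out, error_term="Error")


def repeated_anova(data: pd.DataFrame, subject: str, between: str,
                   within: str, value: str = "value") -> AnovaTable:
    """Split-plot ANOVA: one between-subject and one within-subject factor.

    ``data`` is long-form with one row per subject × within-level.  Subjects
    missing any within level are excluded (complete-case) with a warning.
    The between effect is tested against the subject-within-group error; the
    within effect and the interaction against the subject × within residual.
    With g groups, n_i subjects per group (N total) and t within levels:
    between df = g-1 vs N-g; within df = t-1 and interaction (g-1)(t-1),
    both vs (N-g)(t-1).
    """
    d = data[[subject, between, within, value]].dropna().copy()
    levels = sorted(d[within].unique(), key=str)
    t = len(levels)
    complete = d.groupby(subject)[within].nunique() == t
    dropped = complete.index[~complete]
    if len(dropped):
        logger.warning("excluding %d subject(s) missing within-factor levels: %s",
                       len(dropped), list(dropped))
        d = d[d[subject].isin(complete.index[complete])]
    if d.groupby([subject, within]).size().max() > 1:
        raise ValueError("multiple observations per subject x within level; "
                         "aggregate first")
    subjects = d[subject].unique()
    n_total = len(subjects)
    groups = d.groupby(subject)[between].first()
    g = groups.nunique()
    if g < 2 or t < 2:
        raise ValueError("need >= 2 between groups and >= 2 within levels")

    y = d[value].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    # subject means (over within levels) and cell means (group x within)
    subj_mean = d.groupby(subject)[value].mean()
    group_mean = d.groupby(between)[value].mean()
    n_per_group = groups.value_counts()

    ss_between_subjects = float(t * ((subj_mean - grand) ** 2).sum())
    ss_group = float(sum(t * n_per_group[gr] * (group_mean[gr] - grand) ** 2
                         for gr in group_mean.index))
    ss_subj_within = ss_between_subjects - ss_group

    within_mean = d.groupby(within)[value].mean()
    ss_within_factor = float(n_total * ((within_mean - grand) ** 2).sum())
    cell_mean = d.groupby([between, within])[value].mean()
    ss_cells = float(sum(n_per_group[gr] * (cell_mean[(gr, w)] - grand) ** 2
                         for gr, w in cell_mean.index))
    ss_interaction = ss_cells - ss_group - ss_within_factor
    ss_resid = ss_total - ss_cells - ss_subj_within

    df_group, df_serr = g - 1, n_total - g
    df_within, df_inter = t - 1, (g - 1) * (t - 1)
    df_resid = (n_total - g) * (t - 1)

    rows = {}
    ms_serr = ss_subj_within / df_serr
    ms_resid = ss_resid / df_resid
    def row(ss, df, ms_err, df_err):
        ms = ss / df
        if ms_err <= 0:
            f = 0.0 if ss <= 1e-12 else np.inf
            p = 1.0 if ss <= 1e-12 else 0.0
        else:
            f = ms / ms_err
            p = float(sps.f.sf(f, df, df_err))
        return {"SS": ss, "df": float(df), "MS": ms, "F": f, "p": p}

    rows[between] = row(ss_group, df_group, ms_serr, df_serr)
    rows["Subject(Group) Error"] = {"SS": ss_subj_within, "df": float(df_serr),
                                    "MS": ms_serr, "F": np.nan, "p": np.nan}
    rows[within] = row(ss_within_factor, df_within, ms_resid, df_resid)
    rows[f"{between} x {within}"] = row(ss_interaction, df_inter, ms_resid, df_resid)
    rows["Within Error"] = {"SS": ss_resid, "df": float(df_resid),
                            "MS": ms_resid, "F": np.nan, "p": np.nan}
    return AnovaTable(pd.DataFrame(rows).T, error_term="Subject(Group) Error")


def fishers_lsd(anova: AnovaTable, cell_means: dict[str, float],
                ns: dict[str, int],
                pairs: list[tuple[str, str]] | None = None) -> list[PosthocResult]:
    """Fisher's LSD pairwise tests on the parent ANOVA's pooled error.

    t = Δmean / sqrt(MS_error·(1/n1 + 1/n2)) with the ANOVA's error df;
    two-sided p, unadjusted (the LSD convention relies on the omnibus F for
    familywise protection).
    """
    if pairs is None:
        keys = list(cell_means)
        pairs = [(keys[i], keys[j]) for i in range(len(keys))
                 for j in range(i + 1, len(keys))]
    ms_e, df_e = anova.error_ms, anova.error_df
    out = []
    for a, b in pairs:
        if a not in cell_means or b not in cell_means:
            raise ValueError(f"unknown cell in pair ({a}, {b})")
        diff = cell_means[a] - cell_means[b]
        se = np.sqrt(ms_e * (1.0 / ns[a] + 1.0 / ns[b]))
        if se == 0:
            t = 0.0 if diff == 0 else np.sign(diff) * np.inf
        else:
            t = diff / se
        p = float(2 * sps.t.sf(abs(t), df_e)) if np.isfinite(t) else 0.0
        if t == 0:
            p = 1.0
        out.append(PosthocResult((a, b), float(diff), float(t), df_e, p))
    return out


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------

def holm_sidak(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Šídák step-down correction.

    Sort the m raw p-values ascending; at step i (1-based) the threshold is
    1 − (1−α)^{1/(m−i+1)}; testing stops at the first p above its threshold
    and everything from there on is retained.  Adjusted p-values are the
    running maximum of 1 − (1−p_(i))^{m−i+1}, clipped to 1, mapped back to
    the input order.  Returns (adjusted_p, reject).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    k = m - np.arange(m)  # m, m-1, ..., 1
    with np.errstate(divide="ignore", invalid="ignore"):  # p == 1 -> log1p(-1)
        adj_sorted = np.minimum(
            1.0, np.maximum.accumulate(-np.expm1(k * np.log1p(-ps))))
    thresh = 1.0 - (1.0 - alpha) ** (1.0 / k)
    fail = ps > thresh
    first_fail = int(np.argmax(fail)) if fail.any() else m
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:first_fail] = True
    adj = np.empty(m)
    rej = np.empty(m, dtype=bool)
    adj[order] = adj_sorted
    rej[order] = reject_sorted
    return adj, rej


def per_bin_compare(spectra_a: np.ndarray, spectra_b: np.ndarray,
                    freqs_hz: np.ndarray, alpha: float = 0.05,
                    welch: bool = False,
                    family_range_hz: tuple[float, float] | None = None
                    ) -> BinComparison:
    """Per-frequency-bin unpaired t-tests with Holm-Šídák correction.

    ``spectra_a``/``spectra_b`` are (animals × bins) arrays on the same bin
    grid.  Pooled-variance t-tests by default (``welch=True`` for unequal
    variances); the correction family is all bins inside ``family_range_hz``
    (default: every supplied bin).  Contiguous runs of rejected bins are
    reported as (lo_hz, hi_hz) frequency ranges, inclusive of the bin
    centres at both ends.
    """
    a = np.asarray(spectra_a, dtype=float)
    b = np.asarray(spectra_b, dtype=float)
    f = np.asarray(freqs_hz, dtype=float)
    if a.shape[1] != b.shape[1] or a.shape[1] != f.size:
        raise ValueError("groups must share one bin grid matching freqs_hz")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 animals per group")
    if family_range_hz is not None:
        sel = (f >= family_range_hz[0]) & (f <= family_range_hz[1])
        a, b, f = a[:, sel], b[:, sel], f[sel]
    t, p = sps.ttest_ind(a, b, axis=0, equal_var=not welch)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical bins
    t = np.where(np.isnan(t), 0.0, t)
    p_adj, reject = holm_sidak(p, alpha)
    ranges = []
    i = 0
    while i < reject.size:
        if reject[i]:
            j = i
            while j + 1 < reject.size and reject[j + 1]:
                j += 1
            ranges.append((float(f[i]), float(f[j])))
            i = j + 1
        else:
            i += 1
    return BinComparison(f, a.mean(axis=0), b.mean(axis=0), t, p, p_adj,
                         reject, tuple(ranges))
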