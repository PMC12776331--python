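"""Factorial ANOVA, Fisher's LSD, Holm-Šídák and per-bin comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sleeparch import (fishers_lsd, holm_sidak, per_bin_compare,
                       repeated_anova, twoway_anova)


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

def _cohort(rng, ns=(8, 6, 9, 8)):
    cells = [("WT", "M"), ("KI", "M"), ("WT", "F"), ("KI", "F")]
    a, b, y = [], [], []
    for (geno, sex), n in zip(cells, ns):
        a += [geno] * n
        b += [sex] * n
        y += list(rng.normal(size=n))
    return np.array(y), a, b


def test_unbalanced_2x2_df_bookkeeping(rng):
    """Group sizes 8/6/9/8 give error df 27 and interaction df 1."""
    y, a, b = _cohort(rng)
    tab = twoway_anova(y, a, b, names=("Genotype", "Sex"))
    assert tab.error_df == 27
    assert tab["Genotype x Sex"]["df"] == 1
    assert tab["Genotype"]["df"] == 1 and tab["Sex"]["df"] == 1


def test_identical_observations_degenerate():
    y = np.full(16, 3.14)
    a = ["WT"] * 8 + ["KI"] * 8
    b = (["M"] * 4 + ["F"] * 4) * 2
    tab = twoway_anova(y, a, b)
    assert (tab.table.drop(index="Error")["F"] == 0).all()


def test_empty_cell_named_in_error(rng):
    y = rng.normal(size=12)
    a = ["WT"] * 8 + ["KI"] * 4
    b = ["M"] * 4 + ["F"] * 4 + ["M"] * 4  # no KI/F cell
    with pytest.raises(ValueError, match="KI.*F"):
        twoway_anova(y, a, b)


def balanced_anova_oracle(y, a_levels, b_levels):
    """Closed-form balanced two-way ANOVA from cell means."""
    y = np.asarray(y, float)
    a_levels, b_levels = np.asarray(a_levels), np.asarray(b_levels)
    A, B = np.unique(a_levels), np.unique(b_levels)
    n = int(y.size // (A.size * B.size))
    grand = y.mean()
    ssa = sum(n * B.size * (y[a_levels == ai].mean() - grand) ** 2 for ai in A)
    ssb = sum(n * A.size * (y[b_levels == bi].mean() - grand) ** 2 for bi in B)
    ss_cells = sum(n * (y[(a_levels == ai) & (b_levels == bi)].mean() - grand) ** 2
                   for ai in A for bi in B)
    ssab = ss_cells - ssa - ssb
    sse = sum(((y[(a_levels == ai) & (b_levels == bi)]
                - y[(a_levels == ai) & (b_levels == bi)].mean()) ** 2).sum()
              for ai in A for bi in B)
    return ssa, ssb, ssab, sse


def test_balanced_matches_cell_mean_oracle(rng):
    y, a, b = _cohort(rng, ns=(6, 6, 6, 6))
    tab = twoway_anova(y, a, b, names=("A", "B"))
    ssa, ssb, ssab, sse = balanced_anova_oracle(y, a, b)
    assert tab["A"]["SS"] == pytest.approx(ssa)
    assert tab["B"]["SS"] == pytest.approx(ssb)
    assert tab["A x B"]["SS"] == pytest.approx(ssab)
    assert tab["Error"]["SS"] == pytest.approx(sse)
    dfe = 24 - 4
    f = (ssa / 1) / (sse / dfe)
    assert tab["A"]["F"] == pytest.approx(f)
    assert tab["A"]["p"] == pytest.approx(float(sps.f.sf(f, 1, dfe)))


# ---------------------------------------------------------------------------
# repeated-measures (split-plot) ANOVA
# ---------------------------------------------------------------------------

def _longform(rng, n_per_group=8, n_time=24, effect=0.0):
    rows = []
    for geno in ("WT", "KI"):
        for s in range(n_per_group):
            subj = f"{geno}{s}"
            subj_fx = rng.normal(scale=0.5)
            for t in range(n_time):
                rows.append({"subject": subj, "genotype": geno, "time": t,
                             "value": rng.normal() + subj_fx
                             + (effect if geno == "KI" else 0.0)
                             + np.sin(2 * np.pi * t / n_time)})
    return pd.DataFrame(rows)


def test_within_factor_df_matches_design(rng):
    """24 within levels give a Time df of 23."""
    tab = repeated_anova(_longform(rng), "subject", "genotype", "time")
    assert tab["time"]["df"] == 23
    assert tab["genotype"]["df"] == 1
    assert tab["Subject(Group) Error"]["df"] == 14
    assert tab["Within Error"]["df"] == 14 * 23


def test_constant_within_responses_give_zero_time_f(rng):
    rows = []
    for geno in ("WT", "KI"):
        for s in range(4):
            level = rng.normal()
            for t in range(6):
                rows.append({"subject": f"{geno}{s}", "genotype": geno,
                             "time": t, "value": level})
    tab = repeated_anova(pd.DataFrame(rows), "subject", "genotype", "time")
    assert tab["time"]["F"] == pytest.approx(0.0, abs=1e-9)


def test_split_plot_matches_projection_oracle(rng):
    """SS terms recomputed with explicit design-matrix projections."""
    df = _longform(rng, n_per_group=4, n_time=5, effect=0.8)
    tab = repeated_anova(df, "subject", "genotype", "time")
    y = df["value"].to_numpy()

    def proj_ss(cols):
        X = pd.get_dummies(df[cols].astype(str).agg("|".join, axis=1)).to_numpy(float)
        hat = X @ np.linalg.pinv(X)
        return float(y @ hat @ y)

    grand = y.size * y.mean() ** 2
    ss_group = proj_ss(["genotype"]) - grand
    ss_subj = proj_ss(["subject"]) - grand
    ss_time = proj_ss(["time"]) - grand
    ss_cells = proj_ss(["genotype", "time"]) - grand
    ss_total = float(((y - y.mean()) ** 2).sum())
    assert tab["genotype"]["SS"] == pytest.approx(ss_group)
    assert tab["Subject(Group) Error"]["SS"] == pytest.approx(ss_subj - ss_group)
    assert tab["time"]["SS"] == pytest.approx(ss_time)
    assert tab["genotype x time"]["SS"] == pytest.approx(
        ss_cells - ss_group - ss_time)
    assert tab["Within Error"]["SS"] == pytest.approx(
        ss_total - ss_cells - (ss_subj - ss_group))


def test_split_plot_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    df = _longform(rng, n_per_group=6, n_time=8, effect=0.5)
    tab = repeated_anova(df, "subject", "genotype", "time")
    mx = pg.mixed_anova(data=df, dv="value", within="time",
                        subject="subject", between="genotype").set_index("Source")
    assert tab["genotype"]["F"] == pytest.approx(mx.loc["genotype", "F"])
    assert tab["time"]["F"] == pytest.approx(mx.loc["time", "F"])
    assert tab["genotype x time"]["F"] == pytest.approx(mx.loc["Interaction", "F"])
    assert tab["genotype"]["p"] == pytest.approx(mx.loc["genotype", "p_unc"])


def test_incomplete_subject_dropped_with_warning(rng, caplog):
    df = _longform(rng, n_per_group=4, n_time=6)
    df = df[~((df["subject"] == "WT0") & (df["time"] == 3))]
    with caplog.at_level("WARNING"):
        tab = repeated_anova(df, "subject", "genotype", "time")
    assert any("missing within-factor levels" in r.message for r in caplog.records)
    assert tab["Subject(Group) Error"]["df"] == 7 - 2  # 7 complete subjects


# ---------------------------------------------------------------------------
# Fisher's LSD
# ---------------------------------------------------------------------------

def test_lsd_identical_means_and_symmetry(rng):
    y, a, b = _cohort(rng)
    tab = twoway_anova(y, a, b)
    means = {"x": 1.0, "y": 1.0, "z": 2.0}
    ns = {"x": 8, "y": 8, "z": 8}
    res = fishers_lsd(tab, means, ns, [("x", "y"), ("x", "z"), ("z", "x")])
    assert res[0].t == 0.0 and res[0].p == 1.0
    assert res[1].t == -res[2].t
    assert res[1].p == pytest.approx(res[2].p)


def test_lsd_two_groups_equals_pooled_t(rng):
    """With only two cells, LSD reduces to the pooled two-sample t-test."""
    y1, y2 = rng.normal(size=8), rng.normal(loc=0.9, size=8)
    y = np.concatenate([y1, y2])
    a = ["g1"] * 8 + ["g2"] * 8
    b = (["M"] * 8 + ["M"] * 8)
    # one-way via two-way with a constant second factor is singular; use a
    # direct one-way table built from the pooled variance instead
    import pandas as pd
    from sleeparch.stats import AnovaTable
    sse = ((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum()
    tab = AnovaTable(pd.DataFrame(
        {"SS": [np.nan, sse], "df": [1.0, 14.0],
         "MS": [np.nan, sse / 14.0], "F": [np.nan, np.nan],
         "p": [np.nan, np.nan]}, index=["g", "Error"]), error_term="Error")
    res = fishers_lsd(tab, {"g1": y1.mean(), "g2": y2.mean()},
                      {"g1": 8, "g2": 8}, [("g1", "g2")])[0]
    t_ref, p_ref = sps.ttest_ind(y1, y2, equal_var=True)
    assert res.t == pytest.approx(float(t_ref))
    assert res.p == pytest.approx(float(p_ref))
    assert res.df == 14


# ---------------------------------------------------------------------------
# Holm-Šídák
# ---------------------------------------------------------------------------

def holm_sidak_literal(pvals, alpha):
    """Step-by-step published procedure, no vectorization."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    reject = [False] * m
    for step, idx in enumerate(order):
        k = m - step
        if pvals[idx] <= 1 - (1 - alpha) ** (1.0 / k):
            reject[idx] = True
        else:
            break
    return reject


def test_single_pvalue_unchanged():
    adj, rej = holm_sidak([0.03])
    assert adj[0] == pytest.approx(0.03)
    assert rej[0]


def test_three_pvalue_example():
    adj, rej = holm_sidak([0.001, 0.8, 0.9], alpha=0.05)
    assert list(rej) == [True, False, False]
    assert (adj >= [0.001, 0.8, 0.9]).all()


def test_decisions_match_literal_oracle(rng):
    for _ in range(200):
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m)
        if rng.random() < 0.3:
            p[: m // 2] *= 1e-3  # make some rejections likely
        adj, rej = holm_sidak(p, alpha=0.05)
        assert list(rej) == holm_sidak_literal(list(p), 0.05)
        # adjusted p monotone in sorted order, never below raw
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


def test_adjusted_p_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(25):
        p = rng.uniform(size=30)
        adj, rej = holm_sidak(p)
        sm_rej, sm_adj, *_ = multipletests(p, alpha=0.05, method="holm-sidak")
        assert np.allclose(adj, sm_adj)
        assert (rej == sm_rej).all()


def test_permutation_invariance(rng):
    p = rng.uniform(size=25)
    perm = rng.permutation(25)
    adj, rej = holm_sidak(p)
    adj_p, rej_p = holm_sidak(p[perm])
    assert np.allclose(adj_p, adj[perm])
    assert (rej_p == rej[perm]).all()


def test_fwer_under_global_null(rng):
    """Empirical FWER at m=100 independent uniform nulls stays at alpha."""
    reps = 10_000
    hits = 0
    t1 = 1 - 0.95 ** (1 / 100)  # step-down rejects anything iff min p < t1
    pmin = rng.uniform(size=(reps, 100)).min(axis=1)
    hits = int((pmin <= t1).sum())
    fwer = hits / reps
    mc_se = np.sqrt(0.05 * 0.95 / reps)
    assert fwer <= 0.05 + 3 * mc_se
    # spot-check the shortcut against the full procedure on a subsample
    sub = rng.uniform(size=(200, 100))
    full = np.array([holm_sidak(row)[1].any() for row in sub])
    assert (full == (sub.min(axis=1) <= t1)).all()


# ---------------------------------------------------------------------------
# per-bin comparisons
# ---------------------------------------------------------------------------

def test_identical_spectra_no_rejections(rng):
    base = rng.uniform(1, 2, size=50)
    spectra = np.tile(base, (6, 1))
    res = per_bin_compare(spectra, spectra, np.linspace(0.5, 25, 50))
    assert not res.reject.any()
    assert res.significant_ranges_hz == ()


def test_contiguous_range_extraction_matches_scan(rng):
    freqs = np.arange(100) * 0.5
    a = rng.normal(10, 1, size=(8, 100))
    b = a.copy() + rng.normal(0, 1, size=(8, 100))
    b[:, 30:40] += 50  # gross injected difference
    res = per_bin_compare(a, b, freqs)
    # brute-force scan of the reject flags
    ranges, i = [], 0
    while i < 100:
        if res.reject[i]:
            j = i
            while j + 1 < 100 and res.reject[j + 1]:
                j += 1
            ranges.append((freqs[i], freqs[j]))
            i = j + 1
        else:
            i += 1
    assert res.significant_ranges_hz == tuple(ranges)
    assert any(lo >= 14.5 and hi <= 20.0 for lo, hi in res.significant_ranges_hz)


def test_per_bin_requires_matching_grids(rng):
    with pytest.raises(ValueError):
        per_bin_compare(rng.normal(size=(4, 10)), rng.normal(size=(4, 12)),
                        np.arange(10.0))
    with pytest.raises(ValueError):
        per_bin_compare(rng.normal(size=(1, 10)), rng.normal(size=(4, 10)),
                        np.arange(10.0))
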