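"""Statistical layer: mixed-design ANOVA, t tests, multiplicity control.

The study design is one between-subjects factor (group: sham vs TBI,
unbalanced 9 vs 12) crossed with one within-subjects factor (chamber:
social vs nonsocial).  :func:`mixed_anova` implements the classical
mixed-design decomposition: the group effect is tested against the
between-subject error (subjects within groups), the chamber and
group x chamber effects against the subject x chamber error.  Reported
degrees of freedom for the 2 x 2 design are (1, N-2), matching F(1, 19)
for 9 + 12 animals.

Repeated-measures factors with >= 3 levels get a Greenhouse-Geisser
sphericity correction (:func:`rm_anova_gg`): the correction factor
epsilon is estimated from the double-centred within-subject covariance
and multiplies both F degrees of freedom; epsilon is bounded below by
1/(levels-1), attained when all levels are perfectly correlated.

Multiplicity: Sidak familywise correction ``p_adj = 1 - (1 - p)^m`` for
small planned families, and Benjamini-Hochberg step-up FDR adjustment for
larger exploratory families (per-frequency contrasts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mixed_anova",
    "rm_anova_gg",
    "gg_epsilon",
    "t_test_ind",
    "t_test_paired",
    "sidak",
    "bh_fdr",
    "per_frequency_contrast",
    "STATS_COLUMNS",
]

STATS_COLUMNS = ["effect", "statistic", "stat_type", "df1", "df2",
                 "p", "p_adj", "method", "family_size"]


def _stats_row(effect, statistic, stat_type, df1, df2, p,
               p_adj=None, method="", family_size=1):
    return {"effect": effect, "statistic": float(statistic),
            "stat_type": stat_type, "df1": float(df1), "df2": float(df2),
            "p": float(p), "p_adj": float(p if p_adj is None else p_adj),
            "method": method, "family_size": int(family_size)}


def mixed_anova(table: pd.DataFrame, dv: str = "value", subject: str = "animal_id",
                between: str = "group", within: str = "chamber") -> pd.DataFrame:
    """Classical mixed-design ANOVA (one between, one within factor).

    ``table`` is long-format with one value per (subject, within-level);
    every subject must have all within levels (missing cells raise with
    the offending subjects listed).  Unequal group sizes are allowed.

    Returns a stats table with rows for the between effect, the within
    effect, and their interaction.
    """
    wide = table.pivot_table(index=[subject, between], columns=within,
                             values=dv, aggfunc="mean")
    bad = wide.index[wide.isna().any(axis=1)].get_level_values(0).tolist()
    if bad:
        raise ValueError(f"missing within-factor cells for subjects: {bad}")
    x = wide.to_numpy(float)                       # (N subjects, b levels)
    grp = wide.index.get_level_values(1).to_numpy()
    groups = pd.unique(grp)
    a, (n_subj, b) = len(groups), x.shape
    if a < 2:
        raise ValueError("need at least two groups")
    ng = np.array([(grp == g).sum() for g in groups])
    if (ng < 2).any():
        raise ValueError("each group needs at least 2 subjects")

    grand = x.mean()
    m_subj = x.mean(axis=1)
    m_lvl = x.mean(axis=0)
    m_grp = np.array([x[grp == g].mean() for g in groups])
    m_cell = np.vstack([x[grp == g].mean(axis=0) for g in groups])

    ss_subj = b * ((m_subj - grand) ** 2).sum()
    ss_between = b * (ng * (m_grp - grand) ** 2).sum()
    ss_err_between = ss_subj - ss_between
    ss_within = n_subj * ((m_lvl - grand) ** 2).sum()
    ss_cells = (ng[:, None] * (m_cell - grand) ** 2).sum()
    ss_inter = ss_cells - ss_between - ss_within
    gidx = np.searchsorted(groups, grp) if groups.dtype.kind in "iu" else \
        np.array([list(groups).index(g) for g in grp])
    resid = x - m_subj[:, None] - m_cell[gidx] + m_grp[gidx][:, None]
    ss_err_within = (resid ** 2).sum()

    df_b, df_eb = a - 1, n_subj - a
    df_w, df_ew = b - 1, (n_subj - a) * (b - 1)

    def _f(ss, df, ss_err, df_err):
        ms, ms_err = ss / df, ss_err / df_err
        if ms_err == 0:
            f = 0.0 if ms == 0 else np.inf
        else:
            f = ms / ms_err
        return f, sstats.f.sf(f, df, df_err) if np.isfinite(f) else 0.0

    f_g, p_g = _f(ss_between, df_b, ss_err_between, df_eb)
    f_w, p_w = _f(ss_within, df_w, ss_err_within, df_ew)
    f_i, p_i = _f(max(ss_inter, 0.0), df_b * df_w, ss_err_within, df_ew)

    rows = [
        _stats_row(between, f_g, "F", df_b, df_eb, p_g, method="mixed_anova"),
        _stats_row(within, f_w, "F", df_w, df_ew, p_w, method="mixed_anova"),
        _stats_row(f"{between} x {within}", f_i, "F", df_b * df_w, df_ew, p_i,
                   method="mixed_anova"),
    ]
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x levels data matrix.

    Computed from the double-centred covariance of the within-subject
    scores; equals 1 under perfect sphericity and 1/(levels-1) when the
    covariance is rank one (all levels perfectly correlated).
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need >= 2 within levels")
    s = np.cov(x, rowvar=False, ddof=1)
    # double centring
    s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) \
        + s.mean()
    tr = np.trace(s_dc)
    denom = (k - 1) * (s_dc ** 2).sum()
    lower = 1.0 / (k - 1)
    if denom <= 0 or not np.isfinite(denom):
        return lower
    eps = tr ** 2 / denom
    return float(min(1.0, max(lower, eps)))


def rm_anova_gg(x: np.ndarray, level_names=None) -> pd.DataFrame:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``x`` is subjects x levels (>= 3 levels).  Returns both the
    uncorrected and the epsilon-corrected test; corrected degrees of
    freedom are ``eps * (k-1)`` and ``eps * (k-1)(n-1)`` and may be
    non-integer.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if k < 3:
        raise ValueError("GG correction needs >= 3 within levels")
    grand = x.mean()
    ss_lvl = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_lvl - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    f = np.inf if ms_err == 0 else (ss_lvl / df1) / ms_err
    eps = gg_epsilon(x)
    p_unc = sstats.f.sf(f, df1, df2) if np.isfinite(f) else 0.0
    p_gg = sstats.f.sf(f, eps * df1, eps * df2) if np.isfinite(f) else 0.0
    rows = [
        _stats_row("within", f, "F", df1, df2, p_unc, method="rm_anova"),
        _stats_row("within (GG)", f, "F", eps * df1, eps * df2, p_gg,
                   p_adj=p_gg, method=f"rm_anova_gg(eps={eps:.4f})"),
    ]
    out = pd.DataFrame(rows, columns=STATS_COLUMNS)
    out.attrs["epsilon"] = eps
    return out


def t_test_ind(a, b, label: str = "group") -> dict:
    """Two-sided pooled-variance (Student) independent t test.

    Pooled df = n1 + n2 - 2, the convention behind the reported t(19)
    for 9 + 12 animals.  Zero pooled variance is flagged with NaN.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    res = sstats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        t, p = np.nan, np.nan
    return _stats_row(label, t, "t", 1, df, p, method="t_ind_pooled")


def t_test_paired(a, b, label: str = "chamber") -> dict:
    """Two-sided paired t test; zero-variance differences are flagged NaN."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need >= 2 complete pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return _stats_row(label, 0.0, "t", 1, a.size - 1, 1.0,
                              method="t_paired")
        return _stats_row(label, np.nan, "t", 1, a.size - 1, np.nan,
                          method="t_paired(zero-variance)")
    res = sstats.ttest_rel(a, b)
    return _stats_row(label, float(res.statistic), "t", 1, a.size - 1,
                      float(res.pvalue), method="t_paired")


def sidak(p, m: int):
    """Sidak familywise correction ``1 - (1 - p)^m``, capped at 1."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    p = np.asarray(p, dtype=float)
    out = 1.0 - (1.0 - p) ** m
    return np.minimum(out, 1.0) if out.ndim else float(min(out, 1.0))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def per_frequency_contrast(psd_a: np.ndarray, psd_b: np.ndarray,
                           freqs: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Per-frequency-bin independent t tests between two groups of PSDs.

    ``psd_a``/``psd_b`` are (n_animals, n_freqs) arrays for the two
    groups.  Returns a per-bin table with the t statistic, raw p, BH
    adjusted p, and boolean masks at ``alpha`` both uncorrected and after
    FDR adjustment (the adjusted mask is always a subset).
    """
    psd_a, psd_b = np.atleast_2d(psd_a), np.atleast_2d(psd_b)
    if psd_a.shape[1] != psd_b.shape[1] or psd_a.shape[1] != len(freqs):
        raise ValueError("PSD arrays and frequency grid must align")
    res = sstats.ttest_ind(psd_a, psd_b, axis=0, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)
    p_adj = bh_fdr(p)
    return pd.DataFrame({
        "freq_hz": np.asarray(freqs, float),
        "t": np.asarray(res.statistic, float),
        "p": p,
        "p_fdr": p_adj,
        "sig_uncorrected": p < alpha,
        "sig_fdr": p_adj < alpha,
    })
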