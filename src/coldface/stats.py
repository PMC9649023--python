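"""Gated statistical testing for condition and time comparisons.

The testing protocol is assumption-gated: Shapiro-Wilk decides between
parametric and rank-based two-sample / paired comparisons, Levene decides
between pooled and Welch (unequal-variance) t-tests, and the Mauchly test
decides whether repeated-measures F-tests receive Greenhouse-Geisser
degree-of-freedom correction.  Effect sizes are Hedges' g (small-sample
corrected standardised mean difference) for mean comparisons and partial
eta-squared with noncentral-F confidence intervals for ANOVA effects.

The repeated-measures and mixed (split-plot) ANOVAs are computed from the
classical sums-of-squares decompositions; designs with one within-subject
factor, optionally crossed with one between-subject factor, are supported
(the designs used throughout the MIST analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps


@dataclass
class StatsConfig:
    alpha: float = 0.05
    gate_alpha: float = 0.05          # level of the assumption gates
    ci_level: float = 0.95
    posthoc_correction: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class StatResult:
    """One test outcome: statistic, df, p, effect size, applied gates."""

    test: str
    statistic: float
    df: float | tuple
    p_raw: float
    effect_name: str = ""
    effect: float = np.nan
    effect_ci: tuple | None = None
    p_adjusted: float | None = None
    gates: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_adjusted is None:
            self.p_adjusted = self.p_raw
        if not np.isnan(self.p_raw):
            assert 0 <= self.p_raw <= 1
            assert self.p_adjusted >= self.p_raw - 1e-12

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05

    def as_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic, "df": self.df,
             "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
             "effect_name": self.effect_name, "effect": self.effect,
             "effect_ci": self.effect_ci}
        d.update(self.extra)
        return d


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def _hedges_j(df: float) -> float:
    """Exact small-sample bias correction factor J(df)."""
    return float(np.exp(special.gammaln(df / 2)
                        - np.log(np.sqrt(df / 2))
                        - special.gammaln((df - 1) / 2)))


def cohens_d_two_sample(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0 if x.mean() == y.mean() else np.nan
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def hedges_g_two_sample(x, y, ci_level: float = 0.95):
    """Hedges' g for independent samples, with a noncentral-t CI."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    d = cohens_d_two_sample(x, y)
    if np.isnan(d):
        warnings.warn("zero pooled variance: Hedges' g undefined", stacklevel=2)
        return np.nan, None
    j = _hedges_j(df)
    g = j * d
    scale = np.sqrt(n1 * n2 / (n1 + n2))
    ci = _smd_ci(d, df, scale, ci_level)
    return g, (j * ci[0], j * ci[1])


def hedges_g_paired(x, y, ci_level: float = 0.95):
    """Hedges' g for paired samples on the difference scale (d_z, corrected)."""
    d_raw = np.asarray(x, float) - np.asarray(y, float)
    n = d_raw.size
    sd = d_raw.std(ddof=1)
    if sd == 0:
        if d_raw.mean() == 0:
            return 0.0, (0.0, 0.0)
        warnings.warn("zero difference variance: Hedges' g undefined", stacklevel=2)
        return np.nan, None
    dz = float(d_raw.mean() / sd)
    df = n - 1
    j = _hedges_j(df)
    ci = _smd_ci(dz, df, np.sqrt(n), ci_level)
    return j * dz, (j * ci[0], j * ci[1])


def _smd_ci(d: float, df: float, scale: float, ci_level: float) -> tuple:
    """CI for a standardised mean difference by noncentral-t inversion.

    ``scale`` converts the SMD into the noncentrality parameter
    (delta = d * scale).
    """
    t_obs = d * scale
    lo_q, hi_q = (1 + ci_level) / 2, (1 - ci_level) / 2

    def solve(q):
        fn = lambda nc: sps.nct.cdf(t_obs, df, nc) - q
        lo, hi = t_obs - 20 - 10 * abs(t_obs), t_obs + 20 + 10 * abs(t_obs)
        try:
            return optimize.brentq(fn, lo, hi, xtol=1e-10)
        except ValueError:
            return np.nan
    return solve(lo_q) / scale, solve(hi_q) / scale


def partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    tot = ss_effect + ss_error
    return float(ss_effect / tot) if tot > 0 else np.nan


def partial_eta_sq_ci(f_obs: float, df1: float, df2: float,
                      ci_level: float = 0.95) -> tuple:
    """CI for partial eta-squared by noncentral-F inversion (Steiger)."""
    lo_q, hi_q = (1 + ci_level) / 2, (1 - ci_level) / 2

    def solve(q):
        if sps.ncf.cdf(f_obs, df1, df2, 0.0) < q:
            return 0.0
        fn = lambda nc: sps.ncf.cdf(f_obs, df1, df2, nc) - q
        hi = 10.0
        while fn(hi) > 0 and hi < 1e7:
            hi *= 4
        try:
            nc = optimize.brentq(fn, 0.0, hi, xtol=1e-10)
        except ValueError:
            return np.nan
        return nc

    def to_eta(nc):
        return nc / (nc + df1 + df2 + 1)
    return to_eta(solve(lo_q)), to_eta(solve(hi_q))


# ---------------------------------------------------------------------------
# gated comparisons
# ---------------------------------------------------------------------------

def gate_and_compare_conditions(x, y, cfg: StatsConfig | None = None) -> StatResult:
    """Two-sample comparison with normality and variance gates.

    Shapiro-Wilk on each group: if either departs from normality a
    two-sided Mann-Whitney U test is used, otherwise a t-test whose
    pooled/Welch form is chosen by the Levene test (Welch degrees of
    freedom are fractional).  Hedges' g is reported for either branch.
    """
    cfg = cfg or StatsConfig()
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs n >= 3")
    sw_x, sw_y = sps.shapiro(x).pvalue, sps.shapiro(y).pvalue
    normal = sw_x >= cfg.gate_alpha and sw_y >= cfg.gate_alpha
    gates = {"shapiro_x_p": sw_x, "shapiro_y_p": sw_y, "normal": normal}
    g, g_ci = hedges_g_two_sample(x, y, cfg.ci_level)
    if not normal:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        return StatResult(test="mann-whitney-u", statistic=float(res.statistic),
                          df=np.nan, p_raw=float(res.pvalue),
                          effect_name="hedges_g", effect=g, effect_ci=g_ci,
                          gates=gates)
    lev = sps.levene(x, y).pvalue
    equal_var = lev >= cfg.gate_alpha
    gates.update(levene_p=lev, equal_var=equal_var)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return StatResult(test="t-test" if equal_var else "welch-t-test",
                      statistic=float(res.statistic), df=float(res.df),
                      p_raw=float(res.pvalue), effect_name="hedges_g",
                      effect=g, effect_ci=g_ci, gates=gates)


def gate_and_compare_paired(x, y, cfg: StatsConfig | None = None) -> StatResult:
    """Paired comparison: Shapiro-Wilk on the differences gates between a
    paired t-test and the Wilcoxon signed-rank test (zero-differences
    handled by the Pratt convention so all-tie data remain testable)."""
    cfg = cfg or StatsConfig()
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    d = x - y
    g, g_ci = hedges_g_paired(x, y, cfg.ci_level)
    if np.allclose(d, 0):
        # identical series: zero effect by convention, p = 1
        return StatResult(test="paired-t-test", statistic=0.0, df=x.size - 1,
                          p_raw=1.0, effect_name="hedges_g", effect=0.0,
                          effect_ci=(0.0, 0.0), gates={"identical": True})
    if np.ptp(d) <= 1e-9 * max(1.0, float(np.abs(d).max())):
        # exactly constant nonzero shift: the paired t statistic diverges
        warnings.warn("zero-variance nonzero differences: deterministic shift",
                      stacklevel=2)
        return StatResult(test="paired-t-test",
                          statistic=float(np.sign(d[0]) * np.inf),
                          df=x.size - 1, p_raw=0.0, effect_name="hedges_g",
                          effect=np.nan, effect_ci=None,
                          gates={"constant_shift": True})
    sw = sps.shapiro(d).pvalue
    normal = sw >= cfg.gate_alpha
    gates = {"shapiro_diff_p": sw, "normal": normal}
    if not normal:
        res = sps.wilcoxon(x, y, zero_method="pratt", alternative="two-sided")
        return StatResult(test="wilcoxon", statistic=float(res.statistic),
                          df=np.nan, p_raw=float(res.pvalue),
                          effect_name="hedges_g", effect=g, effect_ci=g_ci,
                          gates=gates)
    res = sps.ttest_rel(x, y)
    return StatResult(test="paired-t-test", statistic=float(res.statistic),
                      df=float(x.size - 1), p_raw=float(res.pvalue),
                      effect_name="hedges_g", effect=g, effect_ci=g_ci,
                      gates=gates)


# ---------------------------------------------------------------------------
# repeated-measures / mixed ANOVA
# ---------------------------------------------------------------------------

def _pivot(data: pd.DataFrame, dv: str, within: str, subject: str) -> pd.DataFrame:
    piv = data.pivot_table(index=subject, columns=within, values=dv,
                           aggfunc="mean", observed=True)
    if piv.isna().any().any():
        raise ValueError("within-subject design has missing cells")
    return piv

def gg_epsilon(piv: pd.DataFrame | np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of the
    subject x level table (1 with only two levels)."""
    X = np.asarray(piv, float)
    k = X.shape[1]
    if k <= 2:
        return 1.0
    S = np.cov(X, rowvar=False, ddof=1)
    mean_var = np.diag(S).mean()
    s_mean = S.mean()
    ss_mat = (S ** 2).sum()
    ss_rows = (S.mean(axis=1) ** 2).sum()
    num = (k * (mean_var - s_mean)) ** 2
    den = (k - 1) * (ss_mat - 2 * k * ss_rows + k ** 2 * s_mean ** 2)
    if den == 0:  # zero between-level covariance structure
        return 1.0
    return float(min(num / den, 1.0))


def mauchly_test(piv: pd.DataFrame | np.ndarray):
    """Mauchly sphericity test (eigenvalues of the double-centred covariance).

    Returns (W, chi2, dof, p).  With two levels sphericity holds trivially
    (W = NaN, p = 1).
    """
    X = np.asarray(piv, float)
    n, k = X.shape
    d = k - 1
    if k <= 2:
        return np.nan, np.nan, 1, 1.0
    S = np.cov(X, rowvar=False, ddof=1)
    S_pop = S - S.mean(0)[:, None] - S.mean(1)[None, :] + S.mean()
    eig = np.linalg.eigvalsh(S_pop)[1:]
    if eig.size == 0 or eig.max() <= 0:
        return np.nan, np.nan, int(d * (d + 1) / 2 - 1) or 1, 1.0
    tol = np.finfo(float).eps * eig.max() * d
    eig = eig[eig > tol]
    W = float(np.prod(eig) / (eig.sum() / d) ** d)
    fcorr = 1 - (2 * d ** 2 + d + 2) / (6 * d * (n - 1))
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d ** 3 + 6 * d ** 2 + 3 * k + 2)
          / (288 * ((n - 1) * d * fcorr) ** 2))
    chi2 = -(n - 1) * fcorr * np.log(W)
    dof = int(d * (d + 1) / 2 - 1) or 1
    p1 = sps.chi2.sf(chi2, dof)
    p2 = sps.chi2.sf(chi2, dof + 4)
    return W, float(chi2), dof, float(p1 + w2 * (p2 - p1))


def rm_anova_gg(data: pd.DataFrame, dv: str = "dv", within: str = "within",
                subject: str = "subject", cfg: StatsConfig | None = None) -> StatResult:
    """One-way repeated-measures ANOVA with Mauchly-gated GG correction.

    F is computed from the classical decomposition (effect MS over
    subject-by-level residual MS).  If the Mauchly test rejects sphericity
    at the gate level, both degrees of freedom are multiplied by the
    Greenhouse-Geisser epsilon and p is recomputed; epsilon and the Mauchly
    outcome are reported either way.  Effect size is partial eta-squared
    with a noncentral-F CI.
    """
    cfg = cfg or StatsConfig()
    piv = _pivot(data, dv, within, subject)
    X = piv.to_numpy(float)
    n, k = X.shape
    grand = X.mean()
    ss_with = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_resall = ((X - X.mean(axis=0)) ** 2).sum()
    ss_resbetw = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_reswith = ss_resall - ss_resbetw
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_with, ms_res = ss_with / df1, ss_reswith / df2
    fval = ms_with / ms_res if ms_res > 0 else (0.0 if ms_with == 0 else np.inf)
    p_unc = float(sps.f.sf(fval, df1, df2))

    eps = gg_epsilon(X)
    W, chi2, mdof, p_spher = mauchly_test(X)
    corrected = (k > 2) and (p_spher <= cfg.gate_alpha)
    if corrected:
        cdf1, cdf2 = max(df1 * eps, 1.0), max(df2 * eps, 1.0)
        p = float(sps.f.sf(fval, cdf1, cdf2))
        df_out = (cdf1, cdf2)
    else:
        p, df_out = p_unc, (float(df1), float(df2))

    np2 = partial_eta_sq(ss_with, ss_reswith)
    ci = partial_eta_sq_ci(fval, df_out[0], df_out[1], cfg.ci_level) \
        if np.isfinite(fval) else None
    return StatResult(test="rm-anova", statistic=float(fval), df=df_out, p_raw=p,
                      effect_name="partial_eta_sq", effect=np2, effect_ci=ci,
                      gates={"mauchly_W": W, "mauchly_p": p_spher,
                             "gg_applied": corrected},
                      extra={"eps": eps, "p_uncorrected": p_unc,
                             "ss_effect": ss_with, "ss_error": ss_reswith})


def mixed_anova(data: pd.DataFrame, dv: str = "dv", within: str = "within",
                between: str = "between", subject: str = "subject",
                cfg: StatsConfig | None = None) -> dict[str, StatResult]:
    """Split-plot ANOVA: one between-subject and one within-subject factor.

    Returns results keyed ``between``, ``within`` and ``interaction``.
    The within main effect and the interaction share the within-residual
    error term; GG correction (gated on Mauchly over the full subject x
    level table) applies to both when sphericity is rejected.
    """
    cfg = cfg or StatsConfig()
    piv = _pivot(data, dv, within, subject)
    groups = data.drop_duplicates(subject).set_index(subject)[between]
    groups = groups.loc[piv.index]
    if groups.nunique() < 2 or groups.value_counts().min() < 2:
        raise ValueError("need >= 2 subjects in each of >= 2 groups")
    X = piv.to_numpy(float)
    n, k = X.shape
    glabels = groups.to_numpy()
    grand = X.mean()
    ss_total = ((X - grand) ** 2).sum()

    # within main effect (balanced across subjects)
    ss_with = n * ((X.mean(axis=0) - grand) ** 2).sum()
    # between main effect
    uniq = pd.unique(glabels)
    ss_betw = sum(k * (glabels == g).sum() * (X[glabels == g].mean() - grand) ** 2
                  for g in uniq)
    # residual around each (group, level) cell mean
    ss_resall = sum(((X[glabels == g] - X[glabels == g].mean(axis=0)) ** 2).sum()
                    for g in uniq)
    ss_inter = ss_total - ss_resall - ss_with - ss_betw
    # subject-within-group error (between-subjects residual)
    subj_means = X.mean(axis=1)
    ss_resbetw = k * sum(((subj_means[glabels == g]
                           - X[glabels == g].mean()) ** 2).sum() for g in uniq)
    ss_reswith = ss_resall - ss_resbetw

    n_groups = len(uniq)
    df_betw, df_with = n_groups - 1, k - 1
    df_resbetw = n - n_groups
    df_reswith = df_with * df_resbetw
    df_inter = df_with * df_betw

    def fp(ss_eff, df_eff, ss_err, df_err):
        ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
        fv = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        return fv, float(sps.f.sf(fv, df_eff, df_err))

    f_b, p_b = fp(ss_betw, df_betw, ss_resbetw, df_resbetw)
    f_w, p_w = fp(ss_with, df_with, ss_reswith, df_reswith)
    f_i, p_i = fp(ss_inter, df_inter, ss_reswith, df_reswith)

    eps = gg_epsilon(X)
    W, chi2, mdof, p_spher = mauchly_test(X)
    corrected = (k > 2) and (p_spher <= cfg.gate_alpha)

    def pack(name, fv, p_unc, df_eff, df_err, ss_eff, ss_err, within_term):
        if within_term and corrected:
            d1, d2 = max(df_eff * eps, 1.0), max(df_err * eps, 1.0)
            p = float(sps.f.sf(fv, d1, d2))
            dfs = (d1, d2)
        else:
            p, dfs = p_unc, (float(df_eff), float(df_err))
        np2 = partial_eta_sq(ss_eff, ss_err)
        ci = partial_eta_sq_ci(fv, dfs[0], dfs[1], cfg.ci_level) \
            if np.isfinite(fv) else None
        return StatResult(test=f"mixed-anova:{name}", statistic=float(fv),
                          df=dfs, p_raw=p, effect_name="partial_eta_sq",
                          effect=np2, effect_ci=ci,
                          gates={"mauchly_W": W, "mauchly_p": p_spher,
                                 "gg_applied": within_term and corrected},
                          extra={"eps": eps if within_term else np.nan,
                                 "p_uncorrected": p_unc})

    return {
        "between": pack("between", f_b, p_b, df_betw, df_resbetw,
                        ss_betw, ss_resbetw, False),
        "within": pack("within", f_w, p_w, df_with, df_reswith,
                       ss_with, ss_reswith, True),
        "interaction": pack("interaction", f_i, p_i, df_inter, df_reswith,
                            ss_inter, ss_reswith, True),
    }


# ---------------------------------------------------------------------------
# post-hoc pairwise comparisons
# ---------------------------------------------------------------------------

def posthoc_pairwise(data: pd.DataFrame, dv: str = "dv", within: str = "within",
                     subject: str = "subject", cfg: StatsConfig | None = None,
                     paired: bool = True) -> list[StatResult]:
    """All pairwise level comparisons with Bonferroni correction.

    The correction family is the set of comparisons produced by this call
    (all level pairs of one measure): ``p_adj = min(1, p_raw * m)``.
    """
    cfg = cfg or StatsConfig()
    piv = _pivot(data, dv, within, subject)
    levels = list(piv.columns)
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    m = len(pairs)
    results = []
    for a, b in pairs:
        if paired:
            r = gate_and_compare_paired(piv[a].to_numpy(), piv[b].to_numpy(), cfg)
        else:
            r = gate_and_compare_conditions(piv[a].to_numpy(), piv[b].to_numpy(), cfg)
        r.p_adjusted = min(1.0, r.p_raw * m)
        r.extra.update(level_a=a, level_b=b, n_comparisons=m)
        results.append(r)
    return results


def results_table(results: dict | list) -> pd.DataFrame:
    """Tidy DataFrame from StatResults (dict keys or list order preserved)."""
    if isinstance(results, dict):
        rows = [{"name": k, **v.as_dict()} for k, v in results.items()]
    else:
        rows = [r.as_dict() for r in results]
    return pd.DataFrame(rows)
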