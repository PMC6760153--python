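"""The study's group-statistics procedure.

Fixed pipeline per metric: single-pass 2-SD outlier screening per group, a
Shapiro-Wilk normality check (p > 0.05 to pass), Levene's homogeneity-of-
variance test, then the omnibus test — one-way ANOVA for single-session
endpoints, or a mixed-design repeated-measures ANOVA (between: genotype and
dose; within: phase = baseline vs treatment) for the circadian endpoints —
followed by Tukey HSD post-hoc comparisons only when the omnibus is
significant at 0.05.

The mixed ANOVA for a 2-level within factor is computed exactly by
decomposition: between-subject effects are a factorial ANOVA on per-subject
phase means (error = subjects within groups), and the within-subject effects
(phase and its interactions) are a factorial ANOVA on per-subject phase
differences, whose intercept tests the phase main effect (error =
phase x subject). With only two within levels sphericity is not an issue.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "StatsResult",
    "PosthocComparison",
    "StatsError",
    "exclude_outliers",
    "normality_check",
    "variance_homogeneity",
    "one_way_anova",
    "mixed_rm_anova",
    "tukey_hsd",
    "analyze_metric",
    "format_effect",
]

ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass
class PosthocComparison:
    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float


@dataclass
class StatsResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float
    ss: float | None = None
    posthoc: list[PosthocComparison] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.F < 0 or not (0 <= self.p <= 1):
            raise StatsError("invalid F or p")


def format_effect(r: StatsResult) -> str:
    """Render an effect the way the study reports it: ``F(a,b) = x, p < y``."""
    for cut in (0.001, 0.01, 0.05):
        if r.p < cut:
            return f"{r.effect}: F({r.df[0]},{r.df[1]}) = {r.F:.2f}, p < {cut}"
    return f"{r.effect}: F({r.df[0]},{r.df[1]}) = {r.F:.2f}, p = {r.p:.2f} (n.s.)"


# ---------------------------------------------------------------------------
# screening


def exclude_outliers(values: np.ndarray, k: float = 2.0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass outlier screen: drop points at or beyond k SD of the group
    mean.

    Mean and population SD are computed once on the full group, candidate
    included; the rule is not iterated. The boundary is inclusive (a point
    exactly k SD out is excluded): a single extreme point among n values can
    reach at most sqrt(n-1) population SDs, so at n = 5 a gross outlier sits
    exactly on the 2-SD boundary and the screen must still catch it. Groups
    with n < 3 are returned unscreened with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        warnings.warn("group too small (n < 3) for outlier screening", stacklevel=2)
        return x, np.empty(0)
    sd = x.std(ddof=0)
    if sd == 0:
        return x, np.empty(0)
    keep = np.abs(x - x.mean()) < k * sd * (1 - 1e-12)
    return x[keep], x[~keep]


def normality_check(values: np.ndarray) -> tuple[float, float, bool]:
    """Shapiro-Wilk test; pass = p > 0.05 (normality not rejected)."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise StatsError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise StatsError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p > ALPHA)


def variance_homogeneity(groups: list[np.ndarray]) -> tuple[float, float]:
    """Levene's test (center = mean, i.e. the classical form)."""
    if len(groups) < 2:
        raise StatsError("Levene's test needs at least 2 groups")
    if any(np.asarray(g).size < 2 for g in groups):
        raise StatsError("each group needs n >= 2")
    stat, p = sps.levene(*[np.asarray(g, float) for g in groups], center="mean")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# omnibus tests


def one_way_anova(groups: list[np.ndarray], effect: str = "group") -> StatsResult:
    """Classical one-way between-subjects ANOVA."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(g.size == 0 for g in gs):
        raise StatsError("one-way ANOVA needs >= 2 non-empty groups")
    n_total = sum(g.size for g in gs)
    k = len(gs)
    if n_total <= k:
        raise StatsError("no residual degrees of freedom")
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else float("inf")
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f, df1, df2))
    return StatsResult(effect=effect, F=float(f), df=(df1, df2), p=p,
                       ss=float(ss_between))


def tukey_hsd(groups: dict[str, np.ndarray]) -> list[PosthocComparison]:
    """Tukey-Kramer all-pairwise comparisons via the studentized range.

    Unequal group sizes use the Kramer correction (scipy's implementation).
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], float) for n in names]
    if len(arrays) < 2:
        raise StatsError("Tukey HSD needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise StatsError("Tukey HSD needs n >= 2 per group")
    res = sps.tukey_hsd(*arrays)
    out = []
    for i, j in itertools.combinations(range(len(names)), 2):
        out.append(PosthocComparison(
            group_a=names[i], group_b=names[j],
            mean_difference=float(arrays[i].mean() - arrays[j].mean()),
            p_adjusted=float(res.pvalue[i, j])))
    return out


def _factor_terms(df: pd.DataFrame, factors: list[str]) -> str:
    """Patsy RHS from the between factors that actually vary, Sum-coded so that
    Type-III tests (and the intercept test on difference scores) are sensible."""
    live = [f for f in factors if df[f].nunique() > 1]
    if not live:
        return "1"
    return " * ".join(f"C({f}, Sum)" for f in live)


def mixed_rm_anova(table: pd.DataFrame, value: str = "value",
                   subject: str = "subject_id", within: str = "phase",
                   between: tuple[str, ...] = ("genotype", "dose")
                   ) -> list[StatsResult]:
    """Mixed-design repeated-measures ANOVA with a 2-level within factor.

    ``table`` is long-format with one row per subject x phase. Subjects missing
    either phase are dropped with a warning. Returns one StatsResult per
    effect: each between factor and their interaction (tested against
    subject-within-group error), the within factor, and each
    within x between interaction (tested against the phase x subject error).
    The ``ss`` fields are scaled so that, for balanced designs, all effect and
    error sums of squares add up to the total sum of squares of the raw
    observations.
    """
    df = table.copy()
    levels = sorted(df[within].unique())
    if len(levels) != 2:
        raise StatsError(f"within factor must have exactly 2 levels, got {levels}")
    wide = df.pivot_table(index=[subject] + [b for b in between if b in df],
                          columns=within, values=value, aggfunc="first")
    incomplete = wide[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} subject(s) missing a phase: "
            f"{[i[0] if isinstance(i, tuple) else i for i in incomplete.index]}",
            stacklevel=2)
        wide = wide.dropna()
    if len(wide) < 3:
        raise StatsError("too few complete subjects for the mixed ANOVA")
    wide = wide.reset_index()
    a, b = levels
    wide["_m"] = (wide[a] + wide[b]) / 2.0
    wide["_d"] = wide[b] - wide[a]

    bet = [f for f in between if f in wide]
    rhs = _factor_terms(wide, bet)
    results: list[StatsResult] = []

    # between-subject part: factorial ANOVA on subject means (x2 scale)
    model_m = smf.ols(f"_m ~ {rhs}", data=wide).fit()
    if rhs != "1":
        tab_m = sm.stats.anova_lm(model_m, typ=3)
        for name, row in tab_m.iterrows():
            if name in ("Intercept", "Residual"):
                continue
            results.append(StatsResult(
                effect=_clean_term(name), F=float(row["F"]),
                df=(int(row["df"]), int(tab_m.loc["Residual", "df"])),
                p=float(row["PR(>F)"]), ss=2.0 * float(row["sum_sq"])))
    results.append(StatsResult(
        effect="subjects(within groups)", F=0.0,
        df=(int(model_m.df_resid), int(model_m.df_resid)),
        p=1.0, ss=2.0 * float(model_m.ssr)))

    # within-subject part: factorial ANOVA on phase differences (x1/2 scale);
    # the intercept tests the phase main effect
    model_d = smf.ols(f"_d ~ {rhs}", data=wide).fit()
    err_df = int(model_d.df_resid)
    sse_d = float(model_d.ssr)
    mse_d = sse_d / err_df
    icpt = model_d.params["Intercept"]
    se_icpt = model_d.bse["Intercept"]
    f_phase = float((icpt / se_icpt) ** 2)
    results.append(StatsResult(
        effect=within, F=f_phase, df=(1, err_df),
        p=float(sps.f.sf(f_phase, 1, err_df)),
        ss=0.5 * f_phase * mse_d))
    if rhs != "1":
        tab_d = sm.stats.anova_lm(model_d, typ=3)
        for name, row in tab_d.iterrows():
            if name in ("Intercept", "Residual"):
                continue
            results.append(StatsResult(
                effect=f"{within}:{_clean_term(name)}", F=float(row["F"]),
                df=(int(row["df"]), err_df), p=float(row["PR(>F)"]),
                ss=0.5 * float(row["sum_sq"])))
    results.append(StatsResult(
        effect=f"{within}:subjects", F=0.0, df=(err_df, err_df), p=1.0,
        ss=0.5 * sse_d))
    return results


def _clean_term(name: str) -> str:
    return (name.replace("C(", "").replace(", Sum)", "").replace(")", "")
            .replace(":", " x "))


# ---------------------------------------------------------------------------
# the study's fixed per-metric pipeline


@dataclass
class MetricAnalysis:
    metric: str
    excluded: dict[str, list[float]]
    normality: dict[str, tuple[float, float, bool]]
    levene: tuple[float, float]
    omnibus: list[StatsResult]
    posthoc: list[PosthocComparison]
    notes: list[str] = field(default_factory=list)

    def report(self) -> str:
        lines = [f"== {self.metric} =="]
        n_excl = sum(len(v) for v in self.excluded.values())
        lines.append(f"outliers excluded (|x - mean| > 2 SD): {n_excl}")
        fails = [g for g, (_, _, ok) in self.normality.items() if not ok]
        lines.append("normality (Shapiro-Wilk): " +
                     ("confirmed in all groups" if not fails
                      else f"NOT confirmed in {fails}"))
        lines.append(f"homogeneity (Levene): W = {self.levene[0]:.2f}, p = {self.levene[1]:.3f}")
        lines += [format_effect(r) for r in self.omnibus if r.F or r.p < 1]
        for c in self.posthoc:
            star = "*" if c.p_adjusted < ALPHA else ""
            lines.append(f"  Tukey {c.group_a} vs {c.group_b}: "
                         f"diff = {c.mean_difference:.3g}, p = {c.p_adjusted:.3f}{star}")
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


def analyze_metric(table: pd.DataFrame, metric: str, value: str = "value",
                   subject: str = "subject_id",
                   between: tuple[str, ...] = ("genotype", "dose"),
                   within: str | None = "phase",
                   outlier_k: float = 2.0) -> MetricAnalysis:
    """Run the study's fixed pipeline on one metric of a tidy group table.

    Order: per-group 2-SD outlier exclusion, Shapiro-Wilk per group, Levene
    across groups, then the omnibus (mixed RM ANOVA when ``within`` is given
    and present, else one-way ANOVA over the crossed between groups), then
    Tukey HSD — only when an omnibus between-effect is significant.
    """
    df = table[table["metric"] == metric].copy() if "metric" in table else table.copy()
    bet = [b for b in between if b in df and df[b].nunique() > 1]
    df["_group"] = df[bet].astype(str).agg("/".join, axis=1) if bet else "all"
    notes: list[str] = []

    # outlier screening per group (per phase if within-design)
    excluded: dict[str, list[float]] = {}
    keep_mask = np.ones(len(df), bool)
    cells = [df.index[df["_group"] == g] for g in df["_group"].unique()]
    if within and within in df:
        cells = [df.index[(df["_group"] == g) & (df[within] == ph)]
                 for g in df["_group"].unique() for ph in df[within].unique()]
    for idx in cells:
        vals = df.loc[idx, value].to_numpy(float)
        if vals.size < 3:
            continue
        sd = vals.std(ddof=0)
        if sd == 0:
            continue
        bad = np.abs(vals - vals.mean()) >= outlier_k * sd * (1 - 1e-12)
        if bad.any():
            keep_mask[df.index.get_indexer(idx[bad])] = False
            excluded.setdefault(str(df.loc[idx[0], "_group"]), []).extend(
                float(v) for v in vals[bad])
    df = df[keep_mask]

    normality = {}
    for g, sub in df.groupby("_group"):
        vals = sub[value].to_numpy(float)
        try:
            normality[str(g)] = normality_check(vals)
        except StatsError as exc:
            notes.append(f"normality check skipped for {g}: {exc}")
    levene = variance_homogeneity(
        [sub[value].to_numpy(float) for _, sub in df.groupby("_group")])

    if within and within in df and df[within].nunique() == 2:
        omnibus = mixed_rm_anova(df, value=value, subject=subject,
                                 within=within, between=tuple(bet))
        sig = any(r.p < ALPHA for r in omnibus if "subjects" not in r.effect)
    else:
        groups = {str(g): sub[value].to_numpy(float) for g, sub in df.groupby("_group")}
        omnibus = [one_way_anova(list(groups.values()), effect="group")]
        sig = omnibus[0].p < ALPHA

    posthoc: list[PosthocComparison] = []
    if sig:
        if within and within in df and df[within].nunique() == 2:
            # post-hoc family: the crossed between-group cells, averaged over phase
            agg = df.groupby(["_group", subject])[value].mean().reset_index()
            groups = {str(g): sub[value].to_numpy(float)
                      for g, sub in agg.groupby("_group")}
        if len(groups) >= 2 and all(v.size >= 2 for v in groups.values()):
            posthoc = tukey_hsd(groups)
    else:
        notes.append("omnibus not significant: no post-hoc tests run")
    return MetricAnalysis(metric=metric, excluded=excluded, normality=normality,
                          levene=levene, omnibus=omnibus, posthoc=posthoc,
                          notes=notes)
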