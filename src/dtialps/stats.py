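"""Cohort statistics: correlations, age-adjusted ANCOVA, NfL regression.

The chain mirrors the standard analysis of a TBI-vs-control glymphatic
cohort: Pearson correlations among injury features and imaging metrics
(pairwise deletion), ANCOVA comparing each metric between groups while
controlling for age (partial, Type-III F via nested-model residual sums
of squares — the SPSS default), and multiple regression of plasma NfL on
ALPS index, PVS volume and age in the injured group (listwise deletion),
reporting both raw and standardized coefficients plus partial-regression
residuals for added-variable plots.

OLS fits go through statsmodels; the partial-F and standardization logic
is assembled here so every reported quantity has an explicit definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class AncovaResult:
    """Group comparison adjusted for covariates.

    ``f_group``/``p_group`` are the partial (Type-III) test of the group
    term; ``df`` is (numerator, denominator). ``adjusted_group_means``
    are model predictions at the covariate grand means.
    """

    f_group: float
    p_group: float
    covariate_tests: dict  # name -> (F, p)
    df: tuple[int, int]
    adjusted_group_means: dict
    raw_group_means: dict
    raw_group_sds: dict
    n: int


@dataclass
class RegressionResult:
    r_squared: float
    f_overall: float
    p_overall: float
    coefficients: pd.DataFrame  # index = predictor; columns b_raw, b_std, p
    n: int
    partial_residuals: dict = field(repr=False, default_factory=dict)


def _finite(x) -> np.ndarray:
    return np.isfinite(np.asarray(x, dtype=float))


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with pairwise deletion of missing values.

    Two-sided p from the t distribution with n-2 df. Raises on fewer
    than three complete pairs or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = _finite(x) & _finite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >=3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


def _design(group: np.ndarray, covariates: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {list(levels)}")
    X = pd.DataFrame({"group": (group == levels[0]).astype(float)})
    for c in covariates.columns:
        X[c] = covariates[c].to_numpy(dtype=float)
    return X, list(levels)


def ancova_group(dep, group, covariates) -> AncovaResult:
    """OLS ANCOVA of ``dep ~ group + covariates`` with partial F tests.

    Each term's F is the nested-model comparison
    ``((RSS_reduced - RSS_full)/d_df) / (RSS_full/df_resid)`` — the
    Type-III (partial) sum of squares for this two-group additive design.
    Listwise deletion; adjusted group means are evaluated at the
    covariate grand means of the analyzed sample.
    """
    dep = np.asarray(dep, dtype=float)
    group = np.asarray(group)
    if isinstance(covariates, (pd.Series, np.ndarray, list)):
        covariates = pd.DataFrame({"age": np.asarray(covariates, dtype=float)})
    covariates = covariates.copy()

    ok = _finite(dep)
    for c in covariates.columns:
        ok &= _finite(covariates[c])
    dep, group, covariates = dep[ok], group[ok], covariates.loc[ok].reset_index(drop=True)
    X, levels = _design(group, covariates)
    n, p = len(dep), X.shape[1] + 1
    if n <= p + 1:
        raise ValueError(f"too few complete cases (n={n}) for {p} parameters")

    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("singular design: group or a covariate is collinear")
    full = sm.OLS(dep, Xc).fit()
    df_resid = int(full.df_resid)

    tss = float(((dep - dep.mean()) ** 2).sum())

    def partial_f(term):
        reduced = sm.OLS(dep, Xc.drop(columns=[term])).fit()
        num = max(reduced.ssr - full.ssr, 0.0)  # guard tiny negative round-off
        if full.ssr <= 1e-12 * max(tss, 1e-300):
            # exact separation of residuals: the full model is a perfect fit
            return (np.inf, 0.0) if num > 0 else (0.0, 1.0)
        f = num / (full.ssr / df_resid)
        return float(f), float(sps.f.sf(f, 1, df_resid))

    f_group, p_group = partial_f("group")
    cov_tests = {c: partial_f(c) for c in covariates.columns}

    grand = {c: float(covariates[c].mean()) for c in covariates.columns}
    adjusted = {}
    for lev in levels:
        row = {"const": 1.0, "group": 1.0 if lev == levels[0] else 0.0, **grand}
        adjusted[str(lev)] = float(full.predict(pd.DataFrame([row])[Xc.columns])[0])
    raw_means = {str(lev): float(dep[group == lev].mean()) for lev in levels}
    raw_sds = {str(lev): float(dep[group == lev].std(ddof=1)) for lev in levels}
    return AncovaResult(
        f_group=f_group,
        p_group=p_group,
        covariate_tests=cov_tests,
        df=(1, df_resid),
        adjusted_group_means=adjusted,
        raw_group_means=raw_means,
        raw_group_sds=raw_sds,
        n=n,
    )


def multiple_regression(dep, predictors: pd.DataFrame, cond_threshold: float = 1e8) -> RegressionResult:
    """OLS of ``dep`` on named predictors, with standardized coefficients.

    Listwise deletion (n reported). Standardized coefficients come from
    refitting after z-scoring dependent and predictors, so
    ``b_std = b_raw * SD(x)/SD(y)`` holds by construction. Partial-
    regression residual pairs (dep residualized on the other predictors
    vs the focal predictor residualized on the others) are returned for
    added-variable plots.
    """
    dep = np.asarray(dep, dtype=float)
    predictors = predictors.copy()
    ok = _finite(dep)
    for c in predictors.columns:
        ok &= _finite(predictors[c])
    dep = dep[ok]
    predictors = predictors.loc[ok].reset_index(drop=True)
    n, k = len(dep), predictors.shape[1]
    if n <= k + 2:
        raise ValueError(f"too few complete cases (n={n}) for {k} predictors")

    Z = (predictors - predictors.mean()) / predictors.std(ddof=1)
    cond = np.linalg.cond(Z.to_numpy())
    if not np.isfinite(cond) or cond > cond_threshold:
        corr = predictors.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"collinear predictors (condition number {cond:.3g}): check {list(worst)}"
        )

    Xc = sm.add_constant(predictors, has_constant="add")
    fit = sm.OLS(dep, Xc).fit()
    zdep = (dep - dep.mean()) / dep.std(ddof=1)
    zfit = sm.OLS(zdep, sm.add_constant(Z, has_constant="add")).fit()

    coefs = pd.DataFrame(
        {
            "b_raw": fit.params.drop("const"),
            "b_std": zfit.params.drop("const"),
            "p": fit.pvalues.drop("const"),
        }
    )

    partial = {}
    for c in predictors.columns:
        others = sm.add_constant(predictors.drop(columns=[c]), has_constant="add")
        ry = dep - sm.OLS(dep, others).fit().predict(others)
        rx = predictors[c] - sm.OLS(predictors[c], others).fit().predict(others)
        partial[c] = (np.asarray(rx), np.asarray(ry))

    return RegressionResult(
        r_squared=float(fit.rsquared),
        f_overall=float(fit.fvalue),
        p_overall=float(fit.f_pvalue),
        coefficients=coefs,
        n=n,
        partial_residuals=partial,
    )


# ---------------------------------------------------------------------------
# full cohort report


REQUIRED_COLUMNS = ("group", "age", "sex", "alps_mean")


def group_compare(table: pd.DataFrame, nfl_predictors=("alps_mean", "pvs_volume", "age")) -> dict:
    """The full cohort battery as one structured, JSON-serializable report.

    Demographics (t-tests for continuous variables, chi-square for sex),
    ANCOVA (age-adjusted) for every imaging/biomarker metric present,
    Pearson correlations among injury features and metrics, and the NfL
    multiple regression within the TBI group.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")

    tbi = table[table["group"] == "TBI"]
    ctl = table[table["group"] != "TBI"]
    report: dict = {"n_tbi": int(len(tbi)), "n_control": int(len(ctl))}

    # demographics
    t, p = sps.ttest_ind(tbi["age"].dropna(), ctl["age"].dropna())
    demo = {"age_t": float(t), "age_p": float(p)}
    contingency = pd.crosstab(table["group"], table["sex"])
    if contingency.shape == (2, 2):
        chi2, p, _, _ = sps.chi2_contingency(contingency, correction=False)
        demo["sex_chi2"], demo["sex_p"] = float(chi2), float(p)
    report["demographics"] = demo

    # ANCOVA battery, age-adjusted
    metrics = [
        c
        for c in (
            "alps_mean", "fa_proj", "fa_assoc", "md_proj", "md_assoc",
            "pvs_volume", "pvs_count", "pvs_score", "nfl",
        )
        if c in table.columns
    ]
    ancova = {}
    for m in metrics:
        try:
            res = ancova_group(table[m], table["group"].to_numpy(), table["age"])
        except ValueError as exc:
            ancova[m] = {"error": str(exc)}
            continue
        ancova[m] = {
            "f_group": res.f_group,
            "p_group": res.p_group,
            "f_age": res.covariate_tests["age"][0],
            "p_age": res.covariate_tests["age"][1],
            "df": list(res.df),
            "adjusted_means": res.adjusted_group_means,
            "raw_means": res.raw_group_means,
            "raw_sds": res.raw_group_sds,
            "n": res.n,
        }
    report["ancova"] = ancova

    # correlations: injury features vs metrics, and PVS internal structure
    pairs = [("gcs", m) for m in ("alps_mean", "pvs_volume", "nfl") if m in table.columns]
    pairs += [("days_since_injury", m) for m in ("alps_mean", "nfl") if m in table.columns]
    pairs += [(a, b) for a, b in (
        ("pvs_volume", "pvs_count"), ("pvs_volume", "pvs_score"), ("alps_mean", "pvs_volume"),
    ) if a in table.columns and b in table.columns]
    corrs = {}
    for a, b in pairs:
        if a not in table.columns:
            continue
        sub = tbi if a in ("gcs", "days_since_injury") else table
        try:
            c = pearson(sub[a], sub[b])
            corrs[f"{a}~{b}"] = {"r": c.r, "p": c.p, "n": c.n}
        except ValueError as exc:
            corrs[f"{a}~{b}"] = {"error": str(exc)}
    report["correlations"] = corrs

    # NfL regression in the injured group
    if "nfl" in table.columns:
        preds = [c for c in nfl_predictors if c in table.columns]
        try:
            reg = multiple_regression(tbi["nfl"], tbi[preds])
            report["nfl_regression"] = {
                "r_squared": reg.r_squared,
                "f_overall": reg.f_overall,
                "p_overall": reg.p_overall,
                "n": reg.n,
                "coefficients": {
                    name: {
                        "b_raw": float(row["b_raw"]),
                        "b_std": float(row["b_std"]),
                        "p": float(row["p"]),
                    }
                    for name, row in reg.coefficients.iterrows()
                },
            }
        except ValueError as exc:
            report["nfl_regression"] = {"error": str(exc)}
    return report


def report_markdown(report: dict) -> str:
    """Render a group_compare report as a human-readable Markdown summary."""
    lines = [
        "# Cohort statistical report",
        "",
        f"TBI n = {report['n_tbi']}, control n = {report['n_control']}",
        "",
        "## Demographics",
    ]
    d = report["demographics"]
    lines.append(f"- age: t = {d['age_t']:.3f}, p = {d['age_p']:.3g}")
    if "sex_chi2" in d:
        lines.append(f"- sex: chi-square = {d['sex_chi2']:.3f}, p = {d['sex_p']:.3g}")
    lines += ["", "## Age-adjusted group comparisons (ANCOVA)", ""]
    lines.append("| metric | F(group) | p | F(age) | p | adj. means |")
    lines.append("|---|---|---|---|---|---|")
    for m, r in report["ancova"].items():
        if "error" in r:
            lines.append(f"| {m} | — | — | — | — | {r['error']} |")
            continue
        adj = ", ".join(f"{k}: {v:.3f}" for k, v in r["adjusted_means"].items())
        lines.append(
            f"| {m} | {r['f_group']:.3f} | {r['p_group']:.3g} | "
            f"{r['f_age']:.3f} | {r['p_age']:.3g} | {adj} |"
        )
    lines += ["", "## Correlations", ""]
    for k, r in report["correlations"].items():
        if "error" in r:
            lines.append(f"- {k}: {r['error']}")
        else:
            lines.append(f"- {k}: r = {r['r']:.3f}, p = {r['p']:.3g} (n = {r['n']})")
    if "nfl_regression" in report:
        reg = report["nfl_regression"]
        lines += ["", "## NfL multiple regression (TBI group)", ""]
        if "error" in reg:
            lines.append(f"- {reg['error']}")
        else:
            lines.append(
                f"R² = {reg['r_squared']:.3f}, F = {reg['f_overall']:.3f}, "
                f"p = {reg['p_overall']:.3g}, n = {reg['n']}"
            )
            for name, c in reg["coefficients"].items():
                lines.append(
                    f"- {name}: b = {c['b_raw']:.4g} (standardized {c['b_std']:.3f}), p = {c['p']:.3g}"
                )
    return "\n".join(lines) + "\n"
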