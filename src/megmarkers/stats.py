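"""Group-comparison and regression battery for the subject-level markers.

Reproduces the analysis structure of a two-group (control vs patient)
marker study: Welch's unequal-variance t test on LZsum, a Shapiro-Wilk
normality check that motivates the Wilcoxon rank-sum test for TAR, and an
OLS battery regressing each marker on group (with age / sex / site / TAR
covariates, fitted one pairing at a time) and on MMSE, across all
participants and within the patient group alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("megmarkers.stats")

__all__ = [
    "GroupTestResult",
    "NormalityResult",
    "RegressionResult",
    "AnalysisReport",
    "welch_t_test",
    "wilcoxon_rank_sum",
    "check_normality",
    "fit_model",
    "run_battery",
    "BATTERY_MODELS",
]

CATEGORICAL_LEVELS = {"group": ["control", "patient"]}  # others: alphabetical


@dataclass
class GroupTestResult:
    test_name: str                     # "welch_t" | "wilcoxon_rank_sum"
    statistic: float                   # t, or W (rank sum of first sample)
    df: float | None
    p_value: float
    group_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"test_name": self.test_name, "statistic": self.statistic,
                "df": self.df, "p_value": self.p_value,
                "group_summary": self.group_summary}


@dataclass
class NormalityResult:
    verdict: bool | None               # True=normal, False=non-normal, None=inconclusive
    statistic: float | None
    p_value: float | None
    note: str = ""

    def to_dict(self) -> dict:
        return {"verdict": self.verdict, "statistic": self.statistic,
                "p_value": self.p_value, "note": self.note}


@dataclass
class RegressionResult:
    model_name: str
    formula: str
    coefficients: dict                 # term -> beta
    p_values: dict                     # term -> p
    r_squared: float
    f_statistic: float
    df1: float
    df2: float
    f_pvalue: float
    nobs: int

    def to_dict(self) -> dict:
        return {"model_name": self.model_name, "formula": self.formula,
                "coefficients": self.coefficients, "p_values": self.p_values,
                "r_squared": self.r_squared, "f_statistic": self.f_statistic,
                "df1": self.df1, "df2": self.df2, "f_pvalue": self.f_pvalue,
                "nobs": self.nobs}


@dataclass
class AnalysisReport:
    descriptives: dict
    group_tests: dict                  # marker -> GroupTestResult dict
    normality: dict                    # marker -> NormalityResult dict
    models: dict                       # model name -> RegressionResult dict
    bh_adjusted: dict                  # label -> BH-adjusted p (reported only)
    conventions: dict

    def to_dict(self) -> dict:
        return {
            "descriptives": self.descriptives,
            "group_tests": self.group_tests,
            "normality": self.normality,
            "models": self.models,
            "bh_adjusted": self.bh_adjusted,
            "conventions": self.conventions,
        }


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def welch_t_test(a, b) -> GroupTestResult:
    """Unequal-variance t test with Welch-Satterthwaite fractional df."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance: t undefined")
    res = sst.ttest_ind(a, b, equal_var=False)
    return GroupTestResult(
        test_name="welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        group_summary={"mean_a": float(a.mean()), "mean_b": float(b.mean()),
                       "n_a": int(a.size), "n_b": int(b.size)},
    )


def wilcoxon_rank_sum(a, b) -> GroupTestResult:
    """Two-sample Wilcoxon rank-sum test.

    W is the sum of pooled midranks of the FIRST sample.  p is exact
    (enumeration) when n1+n2 <= 20 and the data are tie-free, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs >= 1 value")
    pooled = np.concatenate([a, b])
    ranks = sst.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sst.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupTestResult(
        test_name="wilcoxon_rank_sum",
        statistic=w,
        df=None,
        p_value=float(res.pvalue),
        group_summary={"median_a": float(np.median(a)),
                       "median_b": float(np.median(b)),
                       "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                       "n_a": int(a.size), "n_b": int(b.size),
                       "p_method": method},
    )


def check_normality(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk normality check; inconclusive for n < 8 or constants."""
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < 8:
        return NormalityResult(None, None, None, note="n < 8: inconclusive")
    if np.ptp(x) == 0:
        return NormalityResult(None, None, None,
                               note="constant input: inconclusive")
    stat, p = sst.shapiro(x)
    return NormalityResult(bool(p >= alpha), float(stat), float(p))


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def _prepare_table(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    for col in ("group", "sex", "site"):
        if col in df.columns:
            levels = CATEGORICAL_LEVELS.get(col, sorted(df[col].dropna().unique()))
            df[col] = pd.Categorical(df[col], categories=levels)
    return df


def fit_model(
    table: pd.DataFrame,
    outcome: str,
    terms: list[str],
    model_name: str | None = None,
) -> RegressionResult:
    """OLS with intercept; categorical terms dummy-coded, reference = control
    / first-alphabetical level.  Complete-case rows only."""
    cols = [outcome] + list(terms)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns: {missing}")
    df = _prepare_table(table)[cols].dropna()
    if len(df) < len(terms) + 2:
        raise ValueError(
            f"only {len(df)} complete cases for {len(terms)} terms"
        )
    if len(df) < len(table):
        logger.info("dropped %d incomplete rows", len(table) - len(df))
    formula = f"{outcome} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    rank = np.linalg.matrix_rank(fit.model.exog)
    if rank < fit.model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient design for terms {terms}: collinear predictors"
        )
    name = model_name or f"{outcome} ~ {' + '.join(terms)}"
    return RegressionResult(
        model_name=name,
        formula=formula,
        coefficients={k: float(v) for k, v in fit.params.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df1=float(fit.df_model),
        df2=float(fit.df_resid),
        f_pvalue=float(fit.f_pvalue),
        nobs=int(fit.nobs),
    )


def _descriptives(table: pd.DataFrame) -> dict:
    out = {}
    for group, sub in table.groupby("group", observed=True):
        entry = {"n": int(len(sub))}
        if "age" in sub:
            entry["age_mean"] = float(sub["age"].mean())
            entry["age_range"] = [float(sub["age"].min()), float(sub["age"].max())]
        if "sex" in sub:
            entry["sex_counts"] = {k: int(v) for k, v in
                                   sub["sex"].value_counts().sort_index().items()}
        if "mmse" in sub:
            entry["mmse_mean"] = float(sub["mmse"].mean())
            entry["mmse_range"] = [float(sub["mmse"].min()),
                                   float(sub["mmse"].max())]
        if "site" in sub:
            entry["site_counts"] = {k: int(v) for k, v in
                                    sub["site"].value_counts().sort_index().items()}
        for marker in ("lzsum", "tar"):
            if marker in sub:
                entry[f"{marker}_mean"] = float(sub[marker].mean())
                entry[f"{marker}_median"] = float(sub[marker].median())
        out[str(group)] = entry
    return out


BATTERY_MODELS: list[tuple[str, str, list[str], str]] = [
    # (name, outcome, terms, subset)
    ("lzsum_group", "lzsum", ["group"], "all"),
    ("tar_group", "tar", ["group"], "all"),
    ("lzsum_group_age", "lzsum", ["group", "age"], "all"),
    ("lzsum_group_site", "lzsum", ["group", "site"], "all"),
    ("lzsum_group_sex", "lzsum", ["group", "sex"], "all"),
    ("lzsum_group_tar", "lzsum", ["group", "tar"], "all"),
    ("tar_group_age", "tar", ["group", "age"], "all"),
    ("tar_group_site", "tar", ["group", "site"], "all"),
    ("lzsum_mmse_all", "lzsum", ["mmse"], "all"),
    ("tar_mmse_all", "tar", ["mmse"], "all"),
    ("lzsum_mmse_patients", "lzsum", ["mmse"], "patient"),
    ("tar_mmse_patients", "tar", ["mmse"], "patient"),
]


def run_battery(table: pd.DataFrame) -> AnalysisReport:
    """Run the full analysis battery on a subject-level marker table.

    Expects one row per subject with columns participant_id, group, age,
    sex, site, mmse, lzsum, tar.  Produces descriptives, the two group
    tests, the normality checks, and the OLS battery; Benjamini-Hochberg
    adjusted p values are reported alongside but never used for verdicts.
    """
    required = {"participant_id", "group", "lzsum", "tar", "mmse"}
    absent = sorted(required - set(table.columns))
    if absent:
        raise ValueError(f"marker table lacks required columns: {absent}")
    if table["participant_id"].duplicated().any():
        raise ValueError("duplicated participant_id in marker table")
    groups = set(table["group"].dropna().unique())
    if groups != {"control", "patient"}:
        raise ValueError(f"need both groups present, got {sorted(groups)}")
    counts = table.groupby("group", observed=True).size()
    if (counts < 2).any():
        raise ValueError("each group needs >= 2 subjects for the battery")

    ctrl = table.loc[table["group"] == "control"]
    pat = table.loc[table["group"] == "patient"]

    normality = {m: check_normality(table[m].dropna()).to_dict()
                 for m in ("lzsum", "tar")}
    group_tests = {
        "lzsum": welch_t_test(ctrl["lzsum"].dropna(),
                              pat["lzsum"].dropna()).to_dict(),
        # the normality check motivates the rank-based test for TAR
        "tar": wilcoxon_rank_sum(ctrl["tar"].dropna(),
                                 pat["tar"].dropna()).to_dict(),
    }

    models = {}
    for name, outcome, terms, subset in BATTERY_MODELS:
        data = table if subset == "all" else table.loc[table["group"] == subset]
        try:
            models[name] = fit_model(data, outcome, terms, model_name=name).to_dict()
        except ValueError as exc:
            raise ValueError(f"battery model {name!r} failed: {exc}") from exc

    labels, pvals = [], []
    for marker, res in group_tests.items():
        labels.append(f"group_test_{marker}")
        pvals.append(res["p_value"])
    for name, res in models.items():
        labels.append(f"model_{name}")
        pvals.append(res["f_pvalue"])
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    bh = {lab: float(p) for lab, p in zip(labels, adj)}

    conventions = {
        "wilcoxon_statistic": "rank sum of the control sample (first sample)",
        "dummy_coding": "reference = control / first-alphabetical level",
        "alpha": 0.05,
        "missing_data": "complete-case per model",
    }
    return AnalysisReport(
        descriptives=_descriptives(table),
        group_tests=group_tests,
        normality=normality,
        models=models,
        bh_adjusted=bh,
        conventions=conventions,
    )
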