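"""Adjusted association models and the family-history / PGS comparison suite.

All binary outcomes are fit by maximum-likelihood logistic regression
(statsmodels); age of diagnosis by OLS.  Unless stated otherwise, adjusted
models condition on decade of age (age/10, continuous), female sex,
standardized log-BMI and first-degree family history.  Model comparison fits
the four nested prevalence models (base covariates; +FH; +PGS; +both) on a
seeded, outcome-stratified 75/25 split, reporting training Cox-Snell
pseudo-R² and held-out AUC with bootstrap CIs.  A study-wise Bonferroni
threshold over the registered comparisons (28 by default, alpha/n = 0.0018)
is applied when labelling significance.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import train_test_split

from .gwas_ct import auc_with_ci

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "ModelComparison",
    "fit_logistic",
    "fit_ols",
    "cox_snell_r2",
    "compare_prevalence_models",
    "fh_pgs_association",
    "fit_aod_model",
    "fit_prediabetes_model",
    "fit_incidence_model",
    "fit_severity_models",
    "bonferroni_threshold",
    "comparison_registry",
    "significance_report",
]


class DataError(ValueError):
    pass


class ParameterError(ValueError):
    pass


@dataclass
class FitResult:
    outcome: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    llf: float
    n: int
    converged: bool
    method: str = "logit"
    r_squared: float | None = None
    diagnostic: str = ""

    def odds_ratios(self) -> pd.DataFrame:
        """exp(coefficient) with exponentiated CI bounds (logit fits)."""
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "lo": np.exp(self.conf_int[0]),
                "hi": np.exp(self.conf_int[1]),
                "p_value": self.pvalues,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "term": self.params.index,
                "coef": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "p_value": self.pvalues.to_numpy(),
                "ci_lo": self.conf_int[0].to_numpy(),
                "ci_hi": self.conf_int[1].to_numpy(),
            }
        )
        if self.method == "logit":
            out["OR"] = np.exp(out["coef"])
        return out


@dataclass
class ModelComparison:
    fits: dict[str, FitResult]            # base / fh_only / pgs_only / combined
    cox_snell: dict[str, float]
    test_auc: dict[str, tuple[float, float, float]]
    split: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            auc, lo, hi = self.test_auc[name]
            rows.append({"model": name, "n_train": fit.n, "llf": fit.llf,
                         "cox_snell_r2": self.cox_snell[name],
                         "test_auc": auc, "auc_lo": lo, "auc_hi": hi})
        return pd.DataFrame(rows)


def _as_binary(y: np.ndarray, positive: str | None = None) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OU":
        if positive is None:
            raise DataError("string outcome needs an explicit positive label")
        y = (y == positive).astype(float)
    return y.astype(float)


def fit_logistic(
    outcome: np.ndarray,
    design: pd.DataFrame,
    add_intercept: bool = True,
    name: str = "outcome",
) -> FitResult:
    """ML logistic fit with Wald SEs.

    Perfect separation or non-convergence yields a flagged result
    (``converged=False`` with a diagnostic) rather than an exception.
    """
    y = _as_binary(outcome)
    if np.unique(y).size != 2:
        raise DataError(f"{name}: outcome must contain both classes")
    X = design.astype(float).copy()
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise DataError(f"{name}: constant non-intercept column {col!r}")
    if add_intercept:
        X = sm.add_constant(X, prepend=True)
    empty = pd.Series(np.nan, index=X.columns)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # e.g. PerfectSeparationError
        return FitResult(name, empty, empty.copy(), empty.copy(),
                         pd.DataFrame({0: empty, 1: empty}), np.nan, len(y),
                         False, diagnostic=f"{type(exc).__name__}: {exc}")
    ok = bool(res.mle_retvals.get("converged", True)) and np.isfinite(
        res.params.to_numpy()).all() and np.isfinite(res.bse.to_numpy()).all()
    return FitResult(name, res.params, res.bse, res.pvalues, res.conf_int(),
                     float(res.llf), int(y.size), ok,
                     diagnostic="" if ok else "non-convergence or separation")


def fit_ols(
    outcome: np.ndarray,
    design: pd.DataFrame,
    add_intercept: bool = True,
    name: str = "outcome",
) -> FitResult:
    X = design.astype(float).copy()
    if add_intercept:
        X = sm.add_constant(X, prepend=True)
    res = sm.OLS(np.asarray(outcome, dtype=float), X).fit()
    return FitResult(name, res.params, res.bse, res.pvalues, res.conf_int(),
                     float(res.llf), int(len(design)), True, method="ols",
                     r_squared=float(res.rsquared))


def cox_snell_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Cox-Snell pseudo-R²: 1 - exp((2/n)(ll_null - ll_model))."""
    if n <= 0:
        raise ParameterError("n must be positive")
    if loglik_model < loglik_null - 1e-8:
        raise ParameterError("model log-likelihood below null (not nested?)")
    return 1.0 - float(np.exp((2.0 / n) * (loglik_null - loglik_model)))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# shared design helpers
# ---------------------------------------------------------------------------

def _std(x: np.ndarray, mean: float | None = None, sd: float | None = None):
    x = np.asarray(x, dtype=float)
    mean = float(np.mean(x)) if mean is None else mean
    sd = float(np.std(x)) if sd is None else sd
    return (x - mean) / sd, mean, sd


def _analytic_subset(cohort: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Rows with non-missing values in the given columns; empty-string FH is
    treated as missing."""
    df = cohort.copy()
    if "fh_t2d" in cols:
        df = df[df["fh_t2d"].isin(["positive", "negative"])]
    need = [c for c in cols if c != "fh_t2d"]
    return df.dropna(subset=need)


def _base_design(df: pd.DataFrame, logbmi_mean=None, logbmi_sd=None):
    logbmi_std, m, s = _std(np.log(df["bmi"].to_numpy()), logbmi_mean, logbmi_sd)
    X = pd.DataFrame(
        {
            "female": (df["sex"] == "female").astype(float).to_numpy(),
            "decade_of_age": df["age"].to_numpy(dtype=float) / 10.0,
            "logbmi_std": logbmi_std,
        },
        index=df.index,
    )
    return X, m, s


def compare_prevalence_models(
    cohort: pd.DataFrame,
    split_fraction: float = 0.75,
    seed: int = 0,
    n_boot: int = 2000,
    min_n: int = 200,
) -> ModelComparison:
    """Four nested prevalence models: base covariates, +FH, +PGS, +both.

    Standardization of log-BMI and PGS uses the training subset's mean/SD,
    applied unchanged to test rows.  Pseudo-R² is computed on the training
    set against the intercept-only null; AUC with a percentile-bootstrap CI
    on the held-out fraction.
    """
    df = _analytic_subset(cohort, ["fh_t2d", "pgs_std", "age", "sex", "bmi"])
    if len(df) < min_n:
        raise DataError(f"analytic subset has {len(df)} rows (min {min_n})")
    y = (df["t2d_status"] == "case").astype(float).to_numpy()
    idx_train, idx_test = train_test_split(
        np.arange(len(df)), train_size=split_fraction, random_state=seed % (2**32),
        stratify=y)
    tr, te = df.iloc[idx_train], df.iloc[idx_test]
    ytr, yte = y[idx_train], y[idx_test]

    Xtr, m_bmi, s_bmi = _base_design(tr)
    Xte, _, _ = _base_design(te, m_bmi, s_bmi)
    fh_tr = (tr["fh_t2d"] == "positive").astype(float).to_numpy()
    fh_te = (te["fh_t2d"] == "positive").astype(float).to_numpy()
    if float(np.std(tr["pgs_std"].to_numpy())) == 0.0:
        # degenerate score carries no information: drop the PGS term so the
        # PGS models collapse onto their nested counterparts
        logger.warning("PGS has zero variance on the training split; "
                       "PGS term dropped from the comparison designs")
        designs = {
            "base": (Xtr, Xte),
            "fh_only": (Xtr.assign(fh=fh_tr), Xte.assign(fh=fh_te)),
            "pgs_only": (Xtr, Xte),
            "combined": (Xtr.assign(fh=fh_tr), Xte.assign(fh=fh_te)),
        }
    else:
        pgs_tr, m_p, s_p = _std(tr["pgs_std"].to_numpy())
        pgs_te, _, _ = _std(te["pgs_std"].to_numpy(), m_p, s_p)
        designs = {
            "base": (Xtr, Xte),
            "fh_only": (Xtr.assign(fh=fh_tr), Xte.assign(fh=fh_te)),
            "pgs_only": (Xtr.assign(pgs_std=pgs_tr), Xte.assign(pgs_std=pgs_te)),
            "combined": (Xtr.assign(fh=fh_tr, pgs_std=pgs_tr),
                         Xte.assign(fh=fh_te, pgs_std=pgs_te)),
        }
    ll_null = float(sm.Logit(ytr, np.ones((ytr.size, 1))).fit(disp=0).llf)
    fits, r2, aucs = {}, {}, {}
    for name, (Xa, Xb) in designs.items():
        fit = fit_logistic(ytr, Xa, name=f"t2d~{name}")
        fits[name] = fit
        r2[name] = cox_snell_r2(ll_null, fit.llf, ytr.size)
        Xb_c = sm.add_constant(Xb.astype(float), prepend=True)
        prob = 1.0 / (1.0 + np.exp(-(Xb_c.to_numpy() @ fit.params.to_numpy())))
        aucs[name] = auc_with_ci(prob, yte, n_boot=n_boot, seed=seed)
    return ModelComparison(
        fits=fits, cox_snell=r2, test_auc=aucs,
        split={"fraction": split_fraction, "seed": seed,
               "n_train": int(ytr.size), "n_test": int(yte.size),
               "stratified": True, "ll_null_train": ll_null},
    )


def fh_pgs_association(
    cohort: pd.DataFrame,
    adjust: bool = False,
) -> FitResult:
    """Logistic fit of positive family history on the standardized PGS.

    The PGS term's exp(coefficient) is the odds ratio of reporting a positive
    first-degree family history per SD of score.
    """
    df = _analytic_subset(cohort, ["fh_t2d", "pgs_std"])
    y = (df["fh_t2d"] == "positive").astype(float).to_numpy()
    pgs, _, _ = _std(df["pgs_std"].to_numpy())
    X = pd.DataFrame({"pgs_std": pgs}, index=df.index)
    if adjust:
        base, _, _ = _base_design(df)
        X = pd.concat([X, base], axis=1)
    return fit_logistic(y, X, name="fh~pgs")


def fit_aod_model(cases: pd.DataFrame, min_n: int = 50,
                  score_col: str = "pgs_std",
                  standardize_score: bool = True) -> FitResult:
    """OLS of age of diagnosis on standardized PGS, standardized log-BMI and
    family history, among cases.

    ``standardize_score=False`` uses the score column as-is, for scores
    already expressed in the units of interest (e.g. population SD units).
    """
    if (cases["t2d_status"] != "case").any():
        raise DataError("fit_aod_model expects cases only")
    df = _analytic_subset(cases, ["fh_t2d", score_col, "aod", "bmi"])
    if len(df) < min_n:
        raise DataError(f"{len(df)} usable cases (min {min_n})")
    pgs = (_std(df[score_col].to_numpy())[0] if standardize_score
           else df[score_col].to_numpy(dtype=float))
    logbmi, _, _ = _std(np.log(df["bmi"].to_numpy()))
    X = pd.DataFrame(
        {
            "pgs_std": pgs,
            "logbmi_std": logbmi,
            "fh": (df["fh_t2d"] == "positive").astype(float).to_numpy(),
        },
        index=df.index,
    )
    return fit_ols(df["aod"].to_numpy(), X, name="aod")


def fit_prediabetes_model(controls: pd.DataFrame,
                          score_col: str = "pgs_std",
                          standardize_score: bool = True) -> FitResult:
    """Logistic fit of prediabetes on decade of age, sex, standardized
    log-BMI, family history and the standardized PGS, among controls."""
    if (controls["t2d_status"] != "control").any():
        raise DataError("fit_prediabetes_model expects controls only")
    df = controls[controls["prediabetes"].isin(["yes", "no"])]
    df = _analytic_subset(df, ["fh_t2d", score_col, "bmi", "age"])
    y = (df["prediabetes"] == "yes").astype(float).to_numpy()
    X, _, _ = _base_design(df)
    pgs = (_std(df[score_col].to_numpy())[0] if standardize_score
           else df[score_col].to_numpy(dtype=float))
    X = X.assign(fh=(df["fh_t2d"] == "positive").astype(float).to_numpy(),
                 pgs_std=pgs)
    return fit_logistic(y, X, name="prediabetes")


def fit_incidence_model(
    followed: pd.DataFrame,
    followup_window: tuple[int, int] = (365, 730),
    score_col: str = "pgs_std",
    standardize_score: bool = True,
) -> FitResult:
    """Logistic fit of one-year incident conversion among baseline controls
    followed for (365, 730] days, on decade of age, standardized log-BMI,
    family history and the standardized PGS."""
    df = followed[followed["incident_t2d"].isin(["yes", "no"])]
    lo, hi = followup_window
    fd = df["followup_days"].to_numpy(dtype=float)
    df = df[(fd > lo) & (fd <= hi)]
    df = _analytic_subset(df, ["fh_t2d", score_col, "bmi", "age"])
    y = (df["incident_t2d"] == "yes").astype(float).to_numpy()
    if y.sum() == 0:
        raise DataError("no incident events in the follow-up window")
    X, _, _ = _base_design(df)
    X = X.drop(columns=["female"])
    pgs = (_std(df[score_col].to_numpy())[0] if standardize_score
           else df[score_col].to_numpy(dtype=float))
    X = X.assign(fh=(df["fh_t2d"] == "positive").astype(float).to_numpy(),
                 pgs_std=pgs)
    return fit_logistic(y, X, name="incident_t2d")


SEVERITY_OUTCOMES = {
    "insulin": ("treat_insulin", False),
    "metformin": ("treat_metformin", False),
    "lifestyle_only": ("treat_lifestyle_only", False),
    "neuropathy": ("comp_neuropathy", True),
    "nephropathy": ("comp_nephropathy", True),
    "retinopathy": ("comp_retinopathy", True),
}


def fit_severity_models(cases: pd.DataFrame,
                        score_col: str = "pgs_std") -> dict[str, FitResult]:
    """Six logistic severity models among cases: three treatment outcomes
    (adjusted for PGS, decade of age, sex, standardized log-BMI, FH) and three
    microvascular complications (additionally for years since diagnosis).

    Outcomes with zero observed prevalence (or none absent) in the subset are
    skipped with a warning and omitted from the returned dict.
    """
    if (cases["t2d_status"] != "case").any():
        raise DataError("fit_severity_models expects cases only")
    out: dict[str, FitResult] = {}
    for name, (col, with_duration) in SEVERITY_OUTCOMES.items():
        need = ["fh_t2d", score_col, "bmi", "age", col]
        if with_duration:
            need.append("years_since_dx")
        df = _analytic_subset(cases, need)
        y = df[col].to_numpy(dtype=float)
        if y.size == 0 or y.min() == y.max():
            logger.warning("severity outcome %s has a single class; skipped", name)
            continue
        X, _, _ = _base_design(df)
        pgs, _, _ = _std(df[score_col].to_numpy())
        X = X.assign(fh=(df["fh_t2d"] == "positive").astype(float).to_numpy(),
                     pgs_std=pgs)
        if with_duration:
            X = X.assign(years_since_dx=df["years_since_dx"].to_numpy(dtype=float))
        out[name] = fit_logistic(y, X, name=name)
    return out


# ---------------------------------------------------------------------------
# study-wise significance bookkeeping
# ---------------------------------------------------------------------------

def comparison_registry() -> list[str]:
    """The default registry of study-wise comparisons (28 tests) to which the
    Bonferroni threshold applies.  Reconstructed from the reported analyses;
    fully replaceable by the caller."""
    reg = ["fh~pgs_std"]
    reg += [f"combined~{t}" for t in
            ("fh", "pgs_std", "female", "decade_of_age", "logbmi_std")]
    reg += ["fh_only~fh", "pgs_only~pgs_std"]
    reg += [f"aod~{t}" for t in ("pgs_std", "logbmi_std", "fh")]
    reg += [f"prediabetes~{t}" for t in ("pgs_std", "logbmi_std", "fh", "female")]
    reg += [f"incident~{t}" for t in ("pgs_std", "logbmi_std", "fh")]
    for o in ("insulin", "metformin", "lifestyle_only"):
        reg += [f"{o}~pgs_std", f"{o}~fh"]
    reg += [f"{o}~pgs_std" for o in ("neuropathy", "nephropathy", "retinopathy")]
    reg += ["replication:fh~pgs_std"]
    assert len(reg) == 28
    return reg


def significance_report(
    p_values: dict[str, float],
    alpha: float = 0.05,
    registry: list[str] | None = None,
) -> pd.DataFrame:
    """Label each registered comparison against the study-wise Bonferroni
    threshold alpha / n_registered; missing p-values are reported as NaN."""
    registry = registry if registry is not None else comparison_registry()
    thr = bonferroni_threshold(alpha, len(registry))
    rows = [
        {
            "comparison": name,
            "p_value": p_values.get(name, np.nan),
            "threshold": thr,
            "significant": bool(p_values.get(name, np.nan) < thr)
            if name in p_values and np.isfinite(p_values[name]) else False,
        }
        for name in registry
    ]
    return pd.DataFrame(rows)
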