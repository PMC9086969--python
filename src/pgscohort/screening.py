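"""Declarative screening rules and their sensitivity/specificity.

A rule is a disjunction of criteria; each criterion is a conjunction of an
age interval, a BMI interval, a family-history requirement and a minimum PGS
percentile.  Built-in guidelines:

* ``uspstf``: screen adults 35-70 years old who are overweight or obese
  (BMI >= 25).
* ``ada_simplified``: screen everyone 45 or older, plus overweight/obese
  adults (18+) with a positive first-degree family history.

The PGS augmentation adds a disjunct screening normal-BMI adults at or above
a score percentile (90th by default): from age 35 for the USPSTF variant,
from age 18 for the ADA variant.  Evaluation follows the convention that a
case's age criterion is tested at its age of diagnosis and a control's at its
current age, since screening value lies in catching cases before onset.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .stratify import percentile_ranks

__all__ = [
    "Criterion",
    "ScreeningRule",
    "RuleEvaluation",
    "build_rule",
    "evaluate_rule",
    "compare_rules",
]


class ParameterError(ValueError):
    pass


class ProtocolError(RuntimeError):
    pass


@dataclass(frozen=True)
class Criterion:
    """Conjunction of interval requirements; ``None`` means unconstrained.
    Age bounds are inclusive; BMI lower bound inclusive, upper exclusive."""

    age_min: float | None = None
    age_max: float | None = None
    bmi_min: float | None = None
    bmi_max: float | None = None
    fh_positive: bool = False
    pgs_pct_min: float | None = None

    def matches(self, age, bmi, fh, pct) -> np.ndarray:
        ok = np.ones(len(age), dtype=bool)
        if self.age_min is not None:
            ok &= age >= self.age_min
        if self.age_max is not None:
            ok &= age <= self.age_max
        if self.bmi_min is not None:
            ok &= bmi >= self.bmi_min
        if self.bmi_max is not None:
            ok &= bmi < self.bmi_max
        if self.fh_positive:
            ok &= fh == "positive"
        if self.pgs_pct_min is not None:
            ok &= pct >= self.pgs_pct_min
        return ok


@dataclass(frozen=True)
class ScreeningRule:
    name: str
    criteria: tuple[Criterion, ...] = field(default_factory=tuple)

    def screened(self, age, bmi, fh, pct) -> np.ndarray:
        out = np.zeros(len(age), dtype=bool)
        for c in self.criteria:
            out |= c.matches(age, bmi, fh, pct)
        return out

    def to_dict(self) -> dict:
        return {"name": self.name, "criteria": [asdict(c) for c in self.criteria]}

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningRule":
        return cls(name=d["name"],
                   criteria=tuple(Criterion(**c) for c in d["criteria"]))


@dataclass
class RuleEvaluation:
    rule_name: str
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def sensitivity_ci(self) -> tuple[float, float]:
        return proportion_confint(self.tp, self.tp + self.fn, method="wilson")

    def specificity_ci(self) -> tuple[float, float]:
        return proportion_confint(self.tn, self.tn + self.fp, method="wilson")

    def to_row(self) -> dict:
        slo, shi = self.sensitivity_ci()
        plo, phi = self.specificity_ci()
        return {
            "rule": self.rule_name, "tp": self.tp, "fp": self.fp,
            "tn": self.tn, "fn": self.fn, "n_excluded": self.n_excluded,
            "sensitivity": self.sensitivity, "sens_lo": float(slo),
            "sens_hi": float(shi), "specificity": self.specificity,
            "spec_lo": float(plo), "spec_hi": float(phi), "ci_method": "wilson",
        }


NORMAL_BMI = (18.5, 25.0)


def build_rule(
    guideline: str,
    with_pgs: bool = False,
    pgs_percentile: float = 90.0,
    uspstf_age_cap: bool = False,
) -> ScreeningRule:
    """Construct a built-in guideline rule, optionally PGS-augmented.

    ``uspstf_age_cap`` bounds the PGS disjunct at age 70 like the base USPSTF
    criterion (off by default: the augmentation is stated as "35 or older").
    """
    if not 0.0 < pgs_percentile < 100.0:
        raise ParameterError("pgs_percentile must lie in (0, 100)")
    if guideline == "uspstf":
        crits = [Criterion(age_min=35, age_max=70, bmi_min=25.0)]
        if with_pgs:
            crits.append(Criterion(age_min=35,
                                   age_max=70 if uspstf_age_cap else None,
                                   bmi_min=NORMAL_BMI[0], bmi_max=NORMAL_BMI[1],
                                   pgs_pct_min=pgs_percentile))
        name = "uspstf+pgs" if with_pgs else "uspstf"
    elif guideline == "ada_simplified":
        crits = [
            Criterion(age_min=45),
            Criterion(age_min=18, bmi_min=25.0, fh_positive=True),
        ]
        if with_pgs:
            crits.append(Criterion(age_min=18, bmi_min=NORMAL_BMI[0],
                                   bmi_max=NORMAL_BMI[1],
                                   pgs_pct_min=pgs_percentile))
        name = "ada_simplified+pgs" if with_pgs else "ada_simplified"
    else:
        raise ParameterError(f"unknown guideline {guideline!r}")
    return ScreeningRule(name=name, criteria=tuple(crits))


def _evaluation_arrays(
    cohort: pd.DataFrame, pgs_pct: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray,
           np.ndarray, int]:
    """(age_eval, bmi, fh, pct, is_case, pgs_std, n_excluded) after dropping
    cases with a missing AOD.  Age is evaluated at AOD for cases and at
    current age for controls."""
    is_case = (cohort["t2d_status"] == "case").to_numpy()
    aod = (cohort["aod"].to_numpy(dtype=float) if "aod" in cohort
           else np.full(len(cohort), np.nan))
    bad = is_case & np.isnan(aod)
    keep = ~bad
    is_case = is_case[keep]
    age_eval = np.where(is_case, aod[keep],
                        cohort["age"].to_numpy(dtype=float)[keep])
    bmi = cohort["bmi"].to_numpy(dtype=float)[keep]
    fh = (cohort["fh_t2d"].fillna("").to_numpy()[keep] if "fh_t2d" in cohort
          else np.full(keep.sum(), "", dtype=object))
    pgs_std = (cohort["pgs_std"].to_numpy(dtype=float)[keep]
               if "pgs_std" in cohort else np.full(int(keep.sum()), np.nan))
    if pgs_pct is not None:
        pct = np.asarray(pgs_pct, dtype=float)[keep]
    elif "pgs_pct" in cohort.columns:
        pct = cohort["pgs_pct"].to_numpy(dtype=float)[keep]
    elif not np.isnan(pgs_std).any():
        pct = percentile_ranks(pgs_std)
    else:
        pct = np.full(int(keep.sum()), np.nan)
    return age_eval, bmi, fh, pct, is_case, pgs_std, int(bad.sum())


def evaluate_rule(
    cohort: pd.DataFrame,
    rule: ScreeningRule,
    pgs_pct: np.ndarray | None = None,
) -> RuleEvaluation:
    """Confusion counts of a rule on a cohort.

    PGS percentiles are taken from ``pgs_pct`` if given, else from a
    ``pgs_pct`` column, else computed within the evaluation cohort from
    ``pgs_std``.  TP = screened case, FN = unscreened case, FP = screened
    control, TN = unscreened control.
    """
    age, bmi, fh, pct, case, _, n_excluded = _evaluation_arrays(cohort, pgs_pct)
    screened = rule.screened(age, bmi, fh, pct)
    return RuleEvaluation(
        rule_name=rule.name,
        tp=int((screened & case).sum()),
        fp=int((screened & ~case).sum()),
        tn=int((~screened & ~case).sum()),
        fn=int((~screened & case).sum()),
        n_excluded=n_excluded,
    )


def compare_rules(
    cohort: pd.DataFrame,
    base: ScreeningRule,
    augmented: ScreeningRule,
    pgs_pct: np.ndarray | None = None,
) -> dict:
    """Delta report for an augmented rule versus its base.

    Requires the augmented criteria to be a superset of the base criteria, so
    Δsensitivity >= 0 and Δspecificity <= 0 hold by construction; the newly
    screened subgroup is described by size, case fraction and mean PGS.
    """
    if not set(base.criteria).issubset(set(augmented.criteria)):
        raise ProtocolError("augmented rule criteria are not a superset of base")
    ev_base = evaluate_rule(cohort, base, pgs_pct=pgs_pct)
    ev_aug = evaluate_rule(cohort, augmented, pgs_pct=pgs_pct)

    age, bmi, fh, pct, case, pgs_std, _ = _evaluation_arrays(cohort, pgs_pct)
    new = augmented.screened(age, bmi, fh, pct) & ~base.screened(age, bmi, fh, pct)
    n_new = int(new.sum())
    sub = {
        "n": n_new,
        "case_fraction": float(case[new].mean()) if n_new else float("nan"),
        "mean_pgs_std": float(np.nanmean(pgs_std[new])) if n_new else float("nan"),
    }
    return {
        "base": ev_base,
        "augmented": ev_aug,
        "delta_sensitivity": ev_aug.sensitivity - ev_base.sensitivity,
        "delta_specificity": ev_aug.specificity - ev_base.specificity,
        "newly_screened": sub,
    }
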