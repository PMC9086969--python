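"""Family-based synthetic cohorts under a liability-threshold disease model.

The generator produces trios (two parents + one offspring) with Mendelian
transmission of biallelic dosages, builds a standardized latent liability

    L = G + C + E,      Var(G) = h2_snp,  Var(C) = c2_shared,  Var(E) = 1 - h2 - c2,

where G is the aggregate effect of the modelled SNPs, C is a family-shared
environment term (identical for parents and offspring of one family) and E is
independent noise.  Disease status follows a probit-style threshold on
liability shifted by standardized age and log-BMI terms; every downstream
phenotype (age of diagnosis, first-degree family history, prediabetes among
controls, one-year incident conversion, treatment escalation and microvascular
complications) is driven by the same latent liability, so the generator
reproduces the qualitative co-movement of these outcomes with genetic risk
from a single mechanism.  Full ground truth (per-individual liability
components, calibrated thresholds and intercepts) is retained for
parameter-recovery tests.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "TrueScoreModel",
    "GenotypeSet",
    "TruthRecord",
    "PhenotypeParams",
    "SimConfig",
    "draw_score_model",
    "simulate_families",
    "assign_phenotypes",
    "apply_exclusion_filters",
    "generate_cohort",
    "EXCLUSION_RULES",
]


class ParameterError(ValueError):
    """Invalid generator parameterisation."""


class DataError(ValueError):
    """Generated or supplied data violates a structural requirement."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TrueScoreModel:
    """Ground-truth per-SNP generative model behind the polygenic score.

    ``true_beta`` is on the liability scale per effect-allele copy; betas are
    scaled at construction so the aggregate genetic term sum(beta*(x-2p)) has
    variance ``h2_snp`` under Hardy-Weinberg dosages.
    """

    snp_id: list[str]
    position: np.ndarray
    allele_freq: np.ndarray
    true_beta: np.ndarray
    h2_snp: float
    c2_shared: float

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def validate(self) -> None:
        if not (0.0 <= self.h2_snp < 1.0 and 0.0 <= self.c2_shared < 1.0):
            raise ParameterError("h2_snp and c2_shared must lie in [0, 1)")
        if self.h2_snp + self.c2_shared >= 1.0:
            raise ParameterError("h2_snp + c2_shared must be < 1")
        if np.any(self.allele_freq <= 0) or np.any(self.allele_freq >= 1):
            raise ParameterError("allele frequencies must lie in (0, 1)")

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "position": self.position,
                "allele_freq": self.allele_freq,
                "true_beta": self.true_beta,
            }
        )

    def genetic_values(self, dosage: np.ndarray) -> np.ndarray:
        """Centred aggregate genetic term for a dosage matrix (n x m)."""
        centred = dosage - 2.0 * self.allele_freq
        return centred @ self.true_beta


@dataclass
class GenotypeSet:
    """Trio dosage matrices; rows are families, columns SNPs, values {0,1,2}."""

    offspring: np.ndarray
    mother: np.ndarray
    father: np.ndarray

    @property
    def n(self) -> int:
        return self.offspring.shape[0]


@dataclass
class TruthRecord:
    """Per-individual liability decomposition plus all calibrated generator
    parameters, kept for recovery tests; never used by the analysis modules."""

    table: pd.DataFrame  # participant_id, liability_* columns, score_true
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# phenotype parameters
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeParams:
    """Tunable phenotype model.  Defaults emulate a large direct-to-consumer
    adult cohort: mean age 47.6 (SD 15.8) truncated to [20, 79], 60.4% female,
    log-normal BMI around 27 kg/m2, 3.2% T2D prevalence, AOD falling 1.37
    years per liability SD, prediabetes and one-year incident conversion odds
    rising by factors 1.23 and 1.43 per liability SD."""

    prevalence: float = 0.032
    age_mean: float = 47.6
    age_sd: float = 15.8
    age_range: tuple[float, float] = (20.0, 79.0)
    female_frac: float = 0.604
    bmi_log_mean: float = 3.29        # exp(3.29) ~ 26.8 kg/m2
    bmi_log_sd: float = 0.17
    bmi_range: tuple[float, float] = (18.5, 69.0)
    beta_age: float = 0.35            # liability-threshold shift per age SD
    beta_logbmi: float = 0.35         # per log-BMI SD
    aod_mean: float = 49.0
    aod_slope: float = 1.37           # years earlier per liability SD
    aod_sd: float = 8.0
    dx_delay_sd: float = 12.0         # half-normal years between dx and report
    parent_age_offset_mean: float = 28.0
    parent_age_offset_sd: float = 6.0
    fh_missing_frac: float = 0.30
    prediab_prevalence: float = 0.025
    prediab_slope: float = float(np.log(1.23))
    incidence_per_1000py: float = 4.86
    incidence_slope: float = float(np.log(1.43))
    followup_frac: float = 0.35
    followup_mean_days: float = 446.0
    followup_sd_days: float = 102.0
    followup_range_days: tuple[int, int] = (366, 730)
    # treatment / complication models: (base rate, slope per liability SD,
    # slope per year since diagnosis)
    treatment_params: dict = field(
        default_factory=lambda: {
            "insulin": (0.25, float(np.log(1.14)), 0.0),
            "metformin": (0.55, 0.05, 0.0),
            "lifestyle_only": (0.25, -0.12, 0.0),
        }
    )
    complication_params: dict = field(
        default_factory=lambda: {
            "neuropathy": (0.15, float(np.log(1.10)), 0.04),
            "nephropathy": (0.05, 0.05, 0.04),
            "retinopathy": (0.06, 0.07, 0.05),
        }
    )
    strata: tuple = (("european", 1.0),)

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 0.5:
            raise ParameterError(f"infeasible prevalence target {self.prevalence}")
        z = stats.norm.ppf(1.0 - self.prevalence)
        if not np.isfinite(z):
            raise ParameterError("prevalence target yields non-finite threshold")
        fracs = [w for _, w in self.strata]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ParameterError("stratum fractions must sum to 1")


@dataclass
class SimConfig:
    """Everything needed to regenerate one cohort deterministically."""

    n: int = 10_000
    m_snps: int = 500
    n_causal: int = 100
    h2_snp: float = 0.3
    c2_shared: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    pheno: PhenotypeParams = field(default_factory=PhenotypeParams)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def draw_score_model(
    m_snps: int,
    n_causal: int,
    h2_snp: float,
    c2_shared: float = 0.0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> TrueScoreModel:
    """Draw SNP positions, frequencies and causal effects.

    Exactly ``n_causal`` SNPs receive nonzero effects; effects are rescaled so
    that sum(beta^2 * 2p(1-p)) = h2_snp, i.e. the aggregate genetic term has
    variance ``h2_snp`` under independent Hardy-Weinberg dosages.
    ``n_causal = 0`` is permitted only in the null-heritability case.
    """
    if h2_snp + c2_shared >= 1.0 or h2_snp < 0 or c2_shared < 0:
        raise ParameterError("require h2_snp + c2_shared < 1, both nonnegative")
    if n_causal > m_snps or n_causal < 0:
        raise ParameterError("require 0 <= n_causal <= m_snps")
    if n_causal == 0 and h2_snp > 0:
        raise ParameterError("h2_snp > 0 requires at least one causal SNP")
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ParameterError("maf_range must satisfy 0 < lo < hi <= 0.5")

    rng = substream(seed, "score_model")
    gaps = rng.integers(1_000, 100_000, size=m_snps)
    position = np.cumsum(gaps).astype(np.int64)
    freq = rng.uniform(lo, hi, size=m_snps)
    beta = np.zeros(m_snps)
    if n_causal > 0 and h2_snp > 0:
        causal = rng.choice(m_snps, size=n_causal, replace=False)
        raw = rng.normal(size=n_causal)
        var_raw = np.sum(raw**2 * 2.0 * freq[causal] * (1.0 - freq[causal]))
        beta[causal] = raw * np.sqrt(h2_snp / var_raw)
    snp_id = [f"rs{i + 1}" for i in range(m_snps)]
    model = TrueScoreModel(snp_id, position, freq, beta, h2_snp, c2_shared)
    model.validate()
    return model


def simulate_families(n: int, model: TrueScoreModel, seed: int = 0) -> GenotypeSet:
    """Simulate ``n`` trios with Mendelian transmission.

    Parents draw dosages Binomial(2, p) per SNP; each parent transmits one
    allele, Bernoulli(dosage/2), so a homozygous parent transmits its allele
    deterministically.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = substream(seed, "genotypes")
    p = model.allele_freq
    mother = rng.binomial(2, p, size=(n, model.n_snps)).astype(np.int8)
    father = rng.binomial(2, p, size=(n, model.n_snps)).astype(np.int8)
    tm = rng.binomial(1, mother / 2.0).astype(np.int8)
    tf = rng.binomial(1, father / 2.0).astype(np.int8)
    return GenotypeSet(offspring=tm + tf, mother=mother, father=father)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(size=size)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _calibrate_intercept(liability: np.ndarray, slope: float, target_mean: float,
                         extra: np.ndarray | float = 0.0) -> float:
    """Root-solve a logistic intercept so mean sigmoid(a + slope*L + extra)
    equals target_mean on the supplied sample."""

    def f(a):
        return float(np.mean(_sigmoid(a + slope * liability + extra))) - target_mean

    return float(optimize.brentq(f, -30.0, 30.0, xtol=1e-10))


def assign_phenotypes(
    genotypes: GenotypeSet,
    model: TrueScoreModel,
    pheno_params: PhenotypeParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Assign demographics and all disease phenotypes from the shared liability.

    Returns the cohort table (one row per offspring) and a TruthRecord with
    the liability decomposition and every calibrated constant.
    """
    pp = pheno_params or PhenotypeParams()
    pp.validate()
    model.validate()
    rng = substream(seed, "phenotypes")
    n = genotypes.n
    h2, c2 = model.h2_snp, model.c2_shared
    e2 = 1.0 - h2 - c2

    g_off = model.genetic_values(genotypes.offspring)
    g_mom = model.genetic_values(genotypes.mother)
    g_dad = model.genetic_values(genotypes.father)
    shared = rng.normal(0.0, np.sqrt(c2), size=n) if c2 > 0 else np.zeros(n)
    L = g_off + shared + rng.normal(0.0, np.sqrt(e2), size=n)

    # demographics
    age = _truncnorm(rng, pp.age_mean, pp.age_sd, *pp.age_range, size=n)
    female = rng.uniform(size=n) < pp.female_frac
    bmi = np.clip(np.exp(rng.normal(pp.bmi_log_mean, pp.bmi_log_sd, size=n)),
                  *pp.bmi_range)
    age_std = (age - pp.age_mean) / pp.age_sd
    logbmi_std = (np.log(bmi) - pp.bmi_log_mean) / pp.bmi_log_sd

    # disease threshold calibrated against the realized total-score spread so
    # the marginal prevalence matches the target
    S = L + pp.beta_age * age_std + pp.beta_logbmi * logbmi_std
    thr = stats.norm.ppf(1.0 - pp.prevalence) * float(np.std(S))
    if not np.isfinite(thr):
        raise ParameterError("prevalence target yields non-finite threshold")
    case = S > thr

    # parents: own demographics, same family-shared term, same threshold
    fh_parent_case = []
    for g_par in (g_mom, g_dad):
        p_age = np.clip(age + rng.normal(pp.parent_age_offset_mean,
                                         pp.parent_age_offset_sd, size=n),
                        pp.age_range[0], 95.0)
        p_age_std = (p_age - pp.age_mean) / pp.age_sd
        p_bmi_std = rng.normal(size=n)
        Lp = g_par + shared + rng.normal(0.0, np.sqrt(e2), size=n)
        Sp = Lp + pp.beta_age * p_age_std + pp.beta_logbmi * p_bmi_std
        fh_parent_case.append(Sp > thr)
    fh_pos = fh_parent_case[0] | fh_parent_case[1]
    fh = np.where(fh_pos, "positive", "negative").astype(object)
    fh[rng.uniform(size=n) < pp.fh_missing_frac] = ""

    # age of diagnosis: linear in liability, truncated to the eligible age
    # span.  A case's reported current age is AOD plus a half-normal
    # reporting delay, independent of liability, so diagnosis precedes
    # report and years-since-diagnosis carries no information about L
    # (see docs/methods.md)
    aod = np.full(n, np.nan)
    idx = np.where(case)[0]
    aod_draw = pp.aod_mean - pp.aod_slope * L[idx] + rng.normal(0.0, pp.aod_sd,
                                                                size=idx.size)
    aod_draw = np.clip(aod_draw, 20.0, pp.age_range[1])
    delay = np.abs(rng.normal(0.0, pp.dx_delay_sd, size=idx.size))
    age[idx] = np.minimum(aod_draw + delay, pp.age_range[1])
    aod[idx] = aod_draw
    years_since_dx = np.where(case, age - aod, np.nan)

    # prediabetes among controls, logistic in liability
    ctrl = ~case
    prediab = np.full(n, "", dtype=object)
    a_pre = _calibrate_intercept(L[ctrl], pp.prediab_slope, pp.prediab_prevalence)
    p_pre = _sigmoid(a_pre + pp.prediab_slope * L[ctrl])
    prediab[ctrl] = np.where(rng.uniform(size=ctrl.sum()) < p_pre, "yes", "no")

    # one-year incident conversion among a followed subset of controls
    incident = np.full(n, "not_followed", dtype=object)
    incident[case] = ""
    followup = np.zeros(n, dtype=np.int64)
    followed = ctrl & (rng.uniform(size=n) < pp.followup_frac)
    nf = int(followed.sum())
    fdays = np.clip(rng.normal(pp.followup_mean_days, pp.followup_sd_days, size=nf),
                    *pp.followup_range_days).round().astype(np.int64)
    followup[followed] = fdays
    target_events = pp.incidence_per_1000py / 1000.0 * fdays.sum() / 365.25
    a_inc = _calibrate_intercept(L[followed], pp.incidence_slope,
                                 target_events / max(nf, 1))
    p_inc = _sigmoid(a_inc + pp.incidence_slope * L[followed])
    incident[followed] = np.where(rng.uniform(size=nf) < p_inc, "yes", "no")

    # treatment / complications among cases
    flags = {}
    ncase = int(case.sum())
    intercepts = {}
    for group, params in (("treat", pp.treatment_params),
                          ("comp", pp.complication_params)):
        for name, (base, b_l, b_y) in params.items():
            col = np.full(n, np.nan)
            if ncase:
                extra = b_y * years_since_dx[case]
                a0 = _calibrate_intercept(L[case], b_l, base, extra=extra)
                p = _sigmoid(a0 + b_l * L[case] + extra)
                col[case] = (rng.uniform(size=ncase) < p).astype(float)
                intercepts[f"{group}_{name}"] = a0
            flags[f"{group}_{name}"] = col

    labels, fracs = zip(*pp.strata)
    ancestry = np.asarray(labels, dtype=object)[
        rng.choice(len(labels), size=n, p=np.asarray(fracs))
    ]

    score_true = g_off / np.sqrt(h2) if h2 > 0 else np.zeros(n)
    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i:07d}" for i in range(n)],
            "age": np.round(age, 2),
            "sex": np.where(female, "female", "male"),
            "bmi": np.round(bmi, 2),
            "ancestry_label": ancestry,
            "fh_t2d": fh,
            "t2d_status": np.where(case, "case", "control"),
            "aod": np.round(aod, 2),
            "prediabetes": prediab,
            "incident_t2d": incident,
            "followup_days": followup,
            "years_since_dx": np.round(years_since_dx, 2),
            **{k: v for k, v in flags.items()},
            "pgs_raw": np.nan,
            "pgs_std": np.nan,
        }
    )
    truth_table = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"],
            "liability_genetic": g_off,
            "liability_shared": shared,
            "liability_env": L - g_off - shared,
            "liability": L,
            "score_true": score_true,
        }
    )
    params = {
        "threshold": thr,
        "prediab_intercept": a_pre,
        "incidence_intercept": a_inc,
        "severity_intercepts": intercepts,
        "pheno": dataclasses.asdict(pp),
        "seed": seed,
        "h2_snp": h2,
        "c2_shared": c2,
    }
    return cohort, TruthRecord(table=truth_table, params=params)


# §-style eligibility filters: name -> vectorised violation predicate
EXCLUSION_RULES = {
    "age_out_of_range": lambda d: (d["age"] < 20) | (d["age"] > 79),
    "bmi_out_of_range": lambda d: (d["bmi"] < 18.5) | (d["bmi"] > 69),
    "aod_below_20": lambda d: d["aod"].notna() & (d["aod"] < 20),
    "aod_above_age": lambda d: d["aod"].notna() & (d["aod"] > d["age"]),
    "duration_above_40y": lambda d: d["years_since_dx"].notna()
    & (d["years_since_dx"] > 40),
}


def apply_exclusion_filters(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the cohort eligibility filters; returns (kept, tally).

    Tally counts each rule's violations on the incoming table (a row failing
    several rules is counted under each).
    """
    bad = np.zeros(len(cohort), dtype=bool)
    tally = {}
    for name, rule in EXCLUSION_RULES.items():
        mask = rule(cohort).to_numpy(dtype=bool)
        tally[name] = int(mask.sum())
        bad |= mask
    tally["excluded_total"] = int(bad.sum())
    kept = cohort.loc[~bad].reset_index(drop=True)
    if tally["excluded_total"]:
        logger.info("exclusion filters removed %d rows: %s",
                    tally["excluded_total"], tally)
    return kept, tally


def generate_cohort(
    sim_config: SimConfig,
) -> tuple[pd.DataFrame, GenotypeSet, TrueScoreModel, TruthRecord]:
    """End-to-end cohort generation: score model, trios, phenotypes, filters.

    The genotype set and truth record are subset to the post-filter rows so
    all returned objects stay row-aligned.
    """
    cfg = sim_config
    model = draw_score_model(cfg.m_snps, cfg.n_causal, cfg.h2_snp, cfg.c2_shared,
                             cfg.maf_range, seed=cfg.seed)
    genos = simulate_families(cfg.n, model, seed=cfg.seed)
    cohort, truth = assign_phenotypes(genos, model, cfg.pheno, seed=cfg.seed)
    kept, tally = apply_exclusion_filters(cohort)
    if kept.empty:
        raise DataError("no rows survive the eligibility filters")
    keep_idx = np.flatnonzero(
        cohort["participant_id"].isin(kept["participant_id"]).to_numpy()
    )
    genos = GenotypeSet(
        offspring=genos.offspring[keep_idx],
        mother=genos.mother[keep_idx],
        father=genos.father[keep_idx],
    )
    truth = TruthRecord(
        table=truth.table.iloc[keep_idx].reset_index(drop=True),
        params={**truth.params, "exclusions": tally,
                "sim": {k: v for k, v in dataclasses.asdict(cfg).items()
                        if k != "pheno"}},
    )
    return kept, genos, model, truth
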