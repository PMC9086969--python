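import numpy as np
import pandas as pd
import pytest

from pgscohort.synthetic_cohort import PhenotypeParams, SimConfig, generate_cohort


def attach_oracle_pgs(cohort: pd.DataFrame, truth) -> pd.DataFrame:
    """Use the generator's standardized true genetic score as the PGS."""
    out = cohort.copy()
    s = truth.table["score_true"].to_numpy()
    out["pgs_raw"] = s
    sd = s.std()
    out["pgs_std"] = (s - s.mean()) / (sd if sd > 0 else 1.0)
    return out


@pytest.fixture(scope="session")
def signal_sim():
    """Moderate cohort with genetic signal (h2=0.3, c2=0.1), oracle PGS."""
    cfg = SimConfig(n=20_000, m_snps=300, n_causal=60, h2_snp=0.3,
                    c2_shared=0.1, seed=11)
    cohort, genos, model, truth = generate_cohort(cfg)
    return attach_oracle_pgs(cohort, truth), genos, model, truth


@pytest.fixture(scope="session")
def null_sim():
    """Cohort with no genetic or shared-environment signal; the PGS is an
    arbitrary SNP-weight score carrying no information about liability."""
    cfg = SimConfig(n=20_000, m_snps=200, n_causal=0, h2_snp=0.0,
                    c2_shared=0.0, seed=7)
    cohort, genos, model, truth = generate_cohort(cfg)
    rng = np.random.default_rng(5)
    w = rng.normal(size=model.n_snps)
    raw = (genos.offspring - 2.0 * model.allele_freq) @ w
    out = cohort.copy()
    out["pgs_raw"] = raw
    out["pgs_std"] = (raw - raw.mean()) / raw.std()
    return out, genos, model, truth


def random_screening_cohort(seed: int, n: int = 300) -> pd.DataFrame:
    """Small random cohort exercising every screening-rule branch."""
    rng = np.random.default_rng(seed)
    case = rng.uniform(size=n) < 0.3
    age = rng.uniform(20, 79, size=n).round(1)
    aod = np.where(case, rng.uniform(20, age), np.nan).round(1)
    return pd.DataFrame(
        {
            "participant_id": [f"S{i}" for i in range(n)],
            "age": age,
            "sex": rng.choice(["female", "male"], size=n),
            "bmi": rng.uniform(18.5, 55, size=n).round(1),
            "t2d_status": np.where(case, "case", "control"),
            "aod": aod,
            "fh_t2d": rng.choice(["positive", "negative", ""], size=n),
            "pgs_std": rng.normal(size=n),
        }
    )
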