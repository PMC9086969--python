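"""Readers and writers for cohort tables, dosage matrices and scoring files.

Cohorts travel as tab-delimited text with a header and empty fields for
missing values.  Score weights use the PGS Catalog scoring-file layout:
``#key=value`` metadata lines (including the standardization reference mean
and SD) followed by a tab-delimited body with ``rsID``, ``effect_allele``,
``effect_weight`` and optional ``other_allele`` / ``chr_position`` /
``allelefrequency_effect`` columns.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gwas_ct import ScoreWeights
from .synthetic_cohort import PhenotypeParams, SimConfig

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "read_weights",
    "write_weights",
    "read_dosages",
    "write_dosages",
    "read_config",
    "write_config",
]


class SchemaError(ValueError):
    pass


REQUIRED_COHORT_COLUMNS = {
    "participant_id": str,
    "age": float,
    "sex": str,
    "bmi": float,
    "t2d_status": str,
}
OPTIONAL_STRING_COLUMNS = ["ancestry_label", "fh_t2d", "prediabetes",
                           "incident_t2d"]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort(path: str | Path, validate: bool = False,
                apply_filters: bool = False) -> pd.DataFrame:
    """Read a tab-delimited cohort table.

    ``apply_filters=True`` additionally applies the cohort eligibility
    filters (age/BMI bounds, AOD consistency, duration cap); the per-rule
    exclusion tally is logged and attached as ``df.attrs['exclusions']``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str},
                     keep_default_na=True, na_values=[""])
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing required column(s): {missing}")
    for col in OPTIONAL_STRING_COLUMNS:
        if col in df.columns:
            df[col] = df[col].fillna("")
    if "followup_days" in df.columns:
        df["followup_days"] = df["followup_days"].fillna(0).astype(np.int64)
    if validate:
        bad = validate_cohort(df)
        if len(bad):
            raise SchemaError(
                f"{len(bad)} out-of-domain rows; first: "
                f"{bad.iloc[0].to_dict()}"
            )
    if apply_filters:
        from .synthetic_cohort import apply_exclusion_filters

        if "aod" not in df.columns:
            df["aod"] = np.nan
        if "years_since_dx" not in df.columns:
            df["years_since_dx"] = df["age"] - df["aod"]
        df, tally = apply_exclusion_filters(df)
        df.attrs["exclusions"] = tally
    return df


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Row-level domain violations as a tidy (row, column, value, rule) frame."""
    problems = []

    def flag(mask: pd.Series, column: str, rule: str) -> None:
        for i in df.index[mask.fillna(False)]:
            problems.append({"row": int(i), "column": column,
                             "value": df.at[i, column], "rule": rule})

    flag((df["age"] < 0) | (df["age"] > 120), "age", "age outside [0,120]")
    flag((df["bmi"] < 10) | (df["bmi"] > 100), "bmi", "bmi outside [10,100]")
    flag(~df["sex"].isin(["female", "male"]), "sex", "unknown sex label")
    flag(~df["t2d_status"].isin(["case", "control"]), "t2d_status",
         "unknown status label")
    if "fh_t2d" in df.columns:
        flag(~df["fh_t2d"].isin(["positive", "negative", ""]), "fh_t2d",
             "unknown family-history label")
    if "aod" in df.columns:
        flag(df["aod"].notna() & (df["t2d_status"] == "control"), "aod",
             "aod present for a control")
    return pd.DataFrame(problems)


# ---------------------------------------------------------------------------
# PGS scoring files
# ---------------------------------------------------------------------------

_WEIGHT_COLMAP = {
    "rsID": "snp_id",
    "chr_position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_weight": "effect_weight",
    "allelefrequency_effect": "allele_freq",
}


def write_weights(weights: ScoreWeights, path: str | Path) -> None:
    t = weights.table
    cols = {"rsID": t["snp_id"]}
    if "position" in t.columns:
        cols["chr_position"] = t["position"]
    cols["effect_allele"] = t.get("effect_allele", "A")
    if "other_allele" in t.columns:
        cols["other_allele"] = t["other_allele"]
    cols["effect_weight"] = t["effect_weight"]
    if "allele_freq" in t.columns:
        cols["allelefrequency_effect"] = t["allele_freq"]
    body = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write("## polygenic scoring file\n")
        if weights.ref_mean is not None:
            fh.write(f"#reference_mean={weights.ref_mean!r}\n")
        if weights.ref_sd is not None:
            fh.write(f"#reference_sd={weights.ref_sd!r}\n")
        for k, v in sorted(weights.meta.items()):
            fh.write(f"#{k}={v}\n")
        body.to_csv(fh, sep="\t", index=False, na_rep="")


def read_weights(path: str | Path) -> ScoreWeights:
    import io as _io

    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if line.startswith("##"):
            n_header += 1
            continue
        if line.startswith("#"):
            key, _, val = line[1:].rstrip("\n").partition("=")
            meta[key] = val
            n_header += 1
            continue
        break
    body = pd.read_csv(_io.StringIO("".join(lines[n_header:])), sep="\t")
    if "effect_weight" not in body.columns or "rsID" not in body.columns:
        raise SchemaError("scoring file must have rsID and effect_weight columns")
    table = body.rename(columns=_WEIGHT_COLMAP)
    if table["snp_id"].duplicated().any():
        dup = table.loc[table["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise SchemaError(f"duplicate rsID in scoring file: {dup}")
    ref_mean = float(meta["reference_mean"]) if "reference_mean" in meta else None
    ref_sd = float(meta["reference_sd"]) if "reference_sd" in meta else None
    extra = {k: v for k, v in meta.items()
             if k not in ("reference_mean", "reference_sd")}
    return ScoreWeights(table=table, ref_mean=ref_mean, ref_sd=ref_sd,
                        meta=extra)


# ---------------------------------------------------------------------------
# dosage matrices
# ---------------------------------------------------------------------------

def write_dosages(
    dosages: np.ndarray,
    participant_ids: list[str],
    snp_meta: pd.DataFrame,
    path: str | Path,
) -> None:
    """Individuals-by-SNPs dosage matrix with a SNP metadata header block
    (``#field<TAB>v1<TAB>v2...`` lines aligned with the dosage columns)."""
    snp_ids = list(snp_meta["snp_id"])
    with open(path, "w") as fh:
        for col in ("position", "effect_allele", "allele_freq"):
            if col in snp_meta.columns:
                vals = "\t".join(str(v) for v in snp_meta[col])
                fh.write(f"#{col}\t{vals}\n")
        fh.write("participant_id\t" + "\t".join(snp_ids) + "\n")
        for pid, row in zip(participant_ids, np.asarray(dosages)):
            fh.write(pid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_dosages(path: str | Path) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Inverse of :func:`write_dosages`; returns (matrix, ids, snp_meta)."""
    import io as _io

    meta_rows: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        name, _, rest = line[1:].rstrip("\n").partition("\t")
        meta_rows[name] = rest.split("\t")
        n_header += 1
    body = pd.read_csv(_io.StringIO("".join(lines[n_header:])), sep="\t",
                       dtype={"participant_id": str})
    snp_ids = [c for c in body.columns if c != "participant_id"]
    meta = pd.DataFrame({"snp_id": snp_ids})
    for name, vals in meta_rows.items():
        if len(vals) == len(snp_ids):
            meta[name] = (vals if name == "effect_allele"
                          else pd.to_numeric(pd.Series(vals)))
    mat = body[snp_ids].to_numpy(dtype=np.int8)
    return mat, list(body["participant_id"]), meta


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration; one global seed feeds every stage
    through named substreams."""

    seed: int = 0
    n_gwas: int = 6000
    n_tuning: int = 3000
    n_study: int = 6000
    m_snps: int = 400
    n_causal: int = 80
    h2_snp: float = 0.3
    c2_shared: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    p_grid: tuple[float, ...] = (1e-2, 1e-4, 1e-6)
    window_grid: tuple[int, ...] = (50_000, 250_000, 500_000)
    gwas_covariates: tuple[str, ...] = ("female", "decade_of_age")
    bin_scheme: str = "ventiles"
    pgs_screen_percentile: float = 90.0
    split_fraction: float = 0.75
    n_boot: int = 500
    privacy_floor: int = 5
    pheno: PhenotypeParams = field(default_factory=PhenotypeParams)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n=self.n_gwas + self.n_tuning + self.n_study,
            m_snps=self.m_snps, n_causal=self.n_causal, h2_snp=self.h2_snp,
            c2_shared=self.c2_shared, maf_range=tuple(self.maf_range),
            seed=self.seed, pheno=self.pheno,
        )


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def _tupleize(d: dict, keys: list[str]) -> None:
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(tuple(v) if isinstance(v, list) else v for v in d[k])


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    pheno = d.pop("pheno", None)
    _tupleize(d, ["maf_range", "p_grid", "window_grid", "gwas_covariates"])
    cfg = RunConfig(**d)
    if pheno is not None:
        _tupleize(pheno, ["age_range", "bmi_range", "followup_range_days",
                          "strata"])
        for key in ("treatment_params", "complication_params"):
            if key in pheno:
                pheno[key] = {k: tuple(v) for k, v in pheno[key].items()}
        cfg.pheno = PhenotypeParams(**pheno)
    return cfg
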