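"""End-to-end pipeline: simulate -> GWAS -> build/tune score -> score ->
stratify -> screen -> models -> report bundle.

Every stage draws randomness from a named substream of the single global
seed, all outputs are delimited text, and the manifest records seeds, sizes
and content hashes (no timestamps), so re-running a config reproduces the
bundle bit for bit.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import child_seed, substream
from .gwas_ct import auc_with_ci, build_candidates, compute_pgs, run_gwas, tune_and_select
from .io import RunConfig, _to_plain, write_cohort, write_dosages, write_weights
from .riskmodels import (
    bonferroni_threshold,
    compare_prevalence_models,
    comparison_registry,
    fh_pgs_association,
    fit_aod_model,
    fit_incidence_model,
    fit_prediabetes_model,
    fit_severity_models,
    significance_report,
)
from .screening import build_rule, compare_rules
from .stratify import BinScheme, assign_bins, bin_or_vs_total, incidence_rate, summarize_by_bin, trend_test
from .synthetic_cohort import generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""


def _covariates(cohort: pd.DataFrame, names: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    logbmi = np.log(cohort["bmi"].to_numpy(dtype=float))
    for name in names:
        if name == "female":
            cols[name] = (cohort["sex"] == "female").astype(float).to_numpy()
        elif name == "decade_of_age":
            cols[name] = cohort["age"].to_numpy(dtype=float) / 10.0
        elif name == "logbmi_std":
            cols[name] = (logbmi - logbmi.mean()) / logbmi.std()
        else:
            raise ValueError(f"unknown GWAS covariate {name!r}")
    return pd.DataFrame(cols, index=cohort.index)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle under ``out_dir``.

    Returns a summary dict of the headline quantities (also serialized as
    ``results.json`` in the bundle).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    summary: dict = {}
    try:
        cohort, genos, model, truth = generate_cohort(config.sim_config())
        n = len(cohort)
        perm = substream(config.seed, "partition").permutation(n)
        tot = config.n_gwas + config.n_tuning + config.n_study
        n_g = int(round(n * config.n_gwas / tot))
        n_t = int(round(n * config.n_tuning / tot))
        part = np.full(n, "study", dtype=object)
        part[perm[:n_g]] = "gwas"
        part[perm[n_g:n_g + n_t]] = "tuning"
        gwas_m, tune_m, study_m = (part == "gwas"), (part == "tuning"), (part == "study")

        stage = "gwas"
        cov = (_covariates(cohort[gwas_m], config.gwas_covariates)
               if config.gwas_covariates else None)
        snp_meta = model.meta_frame()
        assoc = run_gwas(genos.offspring[gwas_m],
                         cohort.loc[gwas_m, "t2d_status"].to_numpy(),
                         covariates=cov, snp_meta=snp_meta)
        assoc = assoc.merge(snp_meta[["snp_id", "allele_freq"]], on="snp_id")
        _write_tsv(assoc, out / "assoc.tsv")

        stage = "build_score"
        grid = build_candidates(assoc, list(config.p_grid),
                                list(config.window_grid))
        weights = tune_and_select(
            grid, genos.offspring[tune_m], list(snp_meta["snp_id"]),
            cohort.loc[tune_m, "t2d_status"].to_numpy(),
            tuning_ids=cohort.loc[tune_m, "participant_id"],
            gwas_ids=cohort.loc[gwas_m, "participant_id"])
        weights.table = weights.table.merge(
            snp_meta[["snp_id", "position"]], on="snp_id")
        write_weights(weights, out / "weights.txt")
        _write_tsv(
            pd.DataFrame([{"p_threshold": c.p_threshold, "window": c.window,
                           "n_snps": len(c.snp_ids), "tuning_auc": c.auc}
                          for c in grid.candidates]),
            out / "candidates.tsv")

        stage = "score"
        study = cohort[study_m].reset_index(drop=True).copy()
        scores = compute_pgs(genos.offspring[study_m],
                             list(snp_meta["snp_id"]), weights)
        study["pgs_raw"] = scores["pgs_raw"].to_numpy()
        study["pgs_std"] = scores["pgs_std"].to_numpy()
        write_cohort(study, out / "cohort.tsv")
        write_dosages(genos.offspring[study_m],
                      list(study["participant_id"]), snp_meta,
                      out / "dosages.tsv")
        truth_study = truth.table.iloc[np.flatnonzero(study_m)].reset_index(drop=True)
        _write_tsv(truth_study, out / "truth.tsv")
        with open(out / "truth_params.json", "w") as fh:
            json.dump(_to_plain(truth.params), fh, indent=1, sort_keys=True,
                      default=float)
        auc_sel, auc_lo, auc_hi = auc_with_ci(
            study["pgs_std"].to_numpy(),
            study["t2d_status"].to_numpy(),
            n_boot=config.n_boot, seed=child_seed(config.seed, "auc_study"))
        summary["selected_score"] = {
            "n_snps": int(weights.n_snps),
            "p_threshold": weights.meta.get("p_threshold"),
            "window": weights.meta.get("window"),
            "tuning_auc": weights.meta.get("tuning_auc"),
            "study_auc": auc_sel, "study_auc_ci": [auc_lo, auc_hi],
        }

        stage = "stratify"
        floor = config.privacy_floor
        scheme = (BinScheme.ventiles() if config.bin_scheme == "ventiles"
                  else BinScheme.from_ranges(json.loads(config.bin_scheme)))
        bins = assign_bins(study["pgs_std"].to_numpy(), scheme)
        seed_b = child_seed(config.seed, "stratify_boot")
        prev_or = bin_or_vs_total(bins, study["t2d_status"].to_numpy(),
                                  suppress_below=floor)
        _write_tsv(prev_or, out / "ventile_or.tsv")
        fh_known = study["fh_t2d"].isin(["positive", "negative"]).to_numpy()
        fh_frac = summarize_by_bin(
            bins[fh_known],
            (study.loc[fh_known, "fh_t2d"] == "positive").to_numpy(float),
            stat="proportion", n_boot=config.n_boot, seed=seed_b,
            suppress_below=floor)
        _write_tsv(fh_frac, out / "ventile_fh.tsv")
        aod_mean = summarize_by_bin(bins, study["aod"].to_numpy(dtype=float),
                                    stat="mean", n_boot=config.n_boot,
                                    seed=seed_b, suppress_below=floor)
        _write_tsv(aod_mean, out / "ventile_aod.tsv")
        ctrl = (study["t2d_status"] == "control").to_numpy()
        prediab = summarize_by_bin(
            bins[ctrl],
            (study.loc[ctrl, "prediabetes"] == "yes").to_numpy(float),
            stat="proportion", n_boot=config.n_boot, seed=seed_b,
            suppress_below=floor)
        _write_tsv(prediab, out / "ventile_prediabetes.tsv")
        followed = study["incident_t2d"].isin(["yes", "no"]).to_numpy()
        rate = incidence_rate(
            int((study.loc[followed, "incident_t2d"] == "yes").sum()),
            study.loc[followed, "followup_days"].to_numpy())
        summary["incidence"] = rate
        trend_prev = trend_test(bins, study["t2d_status"].to_numpy())
        summary["ventile_prevalence_trend"] = trend_prev
        binned_aod = aod_mean.dropna(subset=["stat"])
        if len(binned_aod) >= 2:
            # reported as lowest-ventile mean minus highest (positive when
            # higher scores mean earlier diagnosis)
            summary["aod_bottom_minus_top_ventile"] = float(
                binned_aod["stat"].iloc[0] - binned_aod["stat"].iloc[-1])

        stage = "screen"
        rows, deltas = [], []
        for guideline in ("uspstf", "ada_simplified"):
            base = build_rule(guideline)
            aug = build_rule(guideline, with_pgs=True,
                             pgs_percentile=config.pgs_screen_percentile)
            rep = compare_rules(study, base, aug)
            rows += [rep["base"].to_row(), rep["augmented"].to_row()]
            deltas.append({"base": base.name, "augmented": aug.name,
                           "delta_sensitivity": rep["delta_sensitivity"],
                           "delta_specificity": rep["delta_specificity"],
                           **{f"new_{k}": v for k, v in rep["newly_screened"].items()}})
            summary[f"screening_{guideline}"] = {
                "sensitivity": rep["base"].sensitivity,
                "specificity": rep["base"].specificity,
                "sensitivity_pgs": rep["augmented"].sensitivity,
                "specificity_pgs": rep["augmented"].specificity,
            }
        _write_tsv(pd.DataFrame(rows), out / "screening.tsv")
        _write_tsv(pd.DataFrame(deltas), out / "screening_deltas.tsv")

        stage = "models"
        comp = compare_prevalence_models(
            study, split_fraction=config.split_fraction,
            seed=child_seed(config.seed, "model_split"), n_boot=config.n_boot)
        _write_tsv(comp.summary_frame(), out / "model_comparison.tsv")
        coef_rows = []
        for mname, fit in comp.fits.items():
            f = fit.to_frame()
            f.insert(0, "model", mname)
            coef_rows.append(f)
        fh_fit = fh_pgs_association(study)
        cases = study[study["t2d_status"] == "case"]
        controls = study[study["t2d_status"] == "control"]
        named_fits = {"fh_assoc": fh_fit}
        pvals = {"fh~pgs_std": float(fh_fit.pvalues.get("pgs_std", np.nan))}
        try:
            aod_fit = fit_aod_model(cases)
            named_fits["aod"] = aod_fit
            summary["aod_years_per_sd"] = float(aod_fit.params["pgs_std"])
            for t in ("pgs_std", "logbmi_std", "fh"):
                pvals[f"aod~{t}"] = float(aod_fit.pvalues[t])
        except Exception as exc:
            logger.warning("AOD model skipped: %s", exc)
        pre_fit = fit_prediabetes_model(controls)
        named_fits["prediabetes"] = pre_fit
        for t, reg in (("pgs_std", "pgs_std"), ("logbmi_std", "logbmi_std"),
                       ("fh", "fh"), ("female", "female")):
            pvals[f"prediabetes~{reg}"] = float(pre_fit.pvalues[t])
        try:
            inc_fit = fit_incidence_model(study)
            named_fits["incidence"] = inc_fit
            summary["incidence_or_per_sd"] = float(np.exp(inc_fit.params["pgs_std"]))
            for t in ("pgs_std", "logbmi_std", "fh"):
                pvals[f"incident~{t}"] = float(inc_fit.pvalues[t])
        except Exception as exc:
            logger.warning("incidence model skipped: %s", exc)
        sev = fit_severity_models(cases)
        named_fits.update(sev)
        for o in ("insulin", "metformin", "lifestyle_only"):
            if o in sev:
                pvals[f"{o}~pgs_std"] = float(sev[o].pvalues["pgs_std"])
                pvals[f"{o}~fh"] = float(sev[o].pvalues["fh"])
        for o in ("neuropathy", "nephropathy", "retinopathy"):
            if o in sev:
                pvals[f"{o}~pgs_std"] = float(sev[o].pvalues["pgs_std"])
        for t in ("fh", "pgs_std", "female", "decade_of_age", "logbmi_std"):
            pvals[f"combined~{t}"] = float(comp.fits["combined"].pvalues[t])
        pvals["fh_only~fh"] = float(comp.fits["fh_only"].pvalues["fh"])
        pvals["pgs_only~pgs_std"] = float(comp.fits["pgs_only"].pvalues["pgs_std"])
        for mname, fit in named_fits.items():
            f = fit.to_frame()
            f.insert(0, "model", mname)
            coef_rows.append(f)
        _write_tsv(pd.concat(coef_rows, ignore_index=True), out / "model_coefficients.tsv")
        summary["fh_pgs_or_per_sd"] = float(np.exp(fh_fit.params["pgs_std"]))
        summary["prediabetes_or_per_sd"] = float(np.exp(pre_fit.params["pgs_std"]))
        summary["model_ns"] = {name: int(fit.n)
                               for name, fit in named_fits.items()}
        summary["model_ns"]["comparison_train"] = int(comp.split["n_train"])
        summary["model_ns"]["comparison_test"] = int(comp.split["n_test"])
        summary["model_comparison"] = {
            m: {"cox_snell_r2": comp.cox_snell[m], "test_auc": comp.test_auc[m][0]}
            for m in comp.fits
        }
        summary["bonferroni_threshold"] = bonferroni_threshold(
            0.05, len(comparison_registry()))

        stage = "replication"
        labels = study["ancestry_label"].unique()
        if len(labels) > 1:
            strata_dir = out / "strata"
            strata_dir.mkdir(exist_ok=True)
            for label in sorted(labels):
                sub = study[study["ancestry_label"] == label].reset_index(drop=True)
                if len(sub) < 200 or sub["t2d_status"].nunique() < 2:
                    logger.warning("stratum %s too small; skipped", label)
                    continue
                sub_bins = assign_bins(sub["pgs_std"].to_numpy(), scheme)
                _write_tsv(
                    bin_or_vs_total(sub_bins, sub["t2d_status"].to_numpy(),
                                    suppress_below=floor),
                    strata_dir / f"{label}_ventile_or.tsv")
                fh_sub = fh_pgs_association(sub)
                _write_tsv(fh_sub.to_frame(), strata_dir / f"{label}_fh_assoc.tsv")
                pvals["replication:fh~pgs_std"] = float(
                    fh_sub.pvalues.get("pgs_std", np.nan))

        stage = "report"
        _write_tsv(significance_report(pvals), out / "significance.tsv")
        with open(out / "results.json", "w") as fh:
            json.dump(_to_plain(summary), fh, indent=1, sort_keys=True,
                      default=float)
        files = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
        manifest = {
            "package_version": __version__,
            "config": _to_plain(config),
            "n_simulated": int(config.sim_config().n),
            "n_post_filter": int(n),
            "partition": {"gwas": int(gwas_m.sum()),
                          "tuning": int(tune_m.sum()),
                          "study": int(study_m.sum())},
            "exclusions": truth.params.get("exclusions", {}),
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=float)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary
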