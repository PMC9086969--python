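"""Percentile-bin descriptive analytics for a polygenic score.

Bins are defined on percentile ranks of the supplied score vector (average
rank for ties, rank r of n mapping to percentile 100*(r-1)/n), so 20 ventiles
of a tie-free vector contain exactly n/20 individuals each.  Per-bin outputs
are tidy tables: the unadjusted odds ratio of the outcome in a bin versus the
total population, per-bin means/proportions with seeded percentile-bootstrap
CIs, and crude incidence per 1,000 person-years with an exact Poisson CI.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream

__all__ = [
    "BinScheme",
    "percentile_ranks",
    "assign_bins",
    "bin_or_vs_total",
    "summarize_by_bin",
    "incidence_rate",
    "trend_test",
]

UNBINNED = "(unbinned)"


class DataError(ValueError):
    pass


@dataclass
class BinScheme:
    """Ordered half-open percentile intervals [lo, hi); an interval whose
    upper bound is 100 is closed on the right."""

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        prev = -1.0
        for lo, hi in self.intervals:
            if not (0.0 <= lo < hi <= 100.0):
                raise ValueError(f"interval ({lo}, {hi}) outside [0, 100]")
            if lo < prev:
                raise ValueError("intervals must be ordered and non-overlapping")
            prev = hi

    @classmethod
    def ventiles(cls) -> "BinScheme":
        return cls([(5.0 * i, 5.0 * (i + 1)) for i in range(20)])

    @classmethod
    def from_ranges(cls, ranges: list[tuple[float, float]]) -> "BinScheme":
        return cls([(float(a), float(b)) for a, b in ranges])

    @property
    def labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}" for lo, hi in self.intervals]


def percentile_ranks(scores: np.ndarray) -> np.ndarray:
    """Percentile rank in [0, 100): 100*(rank-1)/n with average rank for ties."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise DataError("empty score vector")
    ranks = stats.rankdata(s, method="average")
    return 100.0 * (ranks - 1.0) / s.size


def assign_bins(scores: np.ndarray, scheme: BinScheme) -> pd.Series:
    """Map each score to its percentile interval's label.

    Scores falling outside every interval (partial schemes) get ``(unbinned)``.
    """
    pct = percentile_ranks(scores)
    out = np.full(pct.size, UNBINNED, dtype=object)
    for (lo, hi), label in zip(scheme.intervals, scheme.labels):
        if hi == 100.0:
            mask = (pct >= lo) & (pct <= hi)
        else:
            mask = (pct >= lo) & (pct < hi)
        out[mask] = label
    return pd.Series(pd.Categorical(out, categories=scheme.labels + [UNBINNED]),
                     name="bin")


def _order_bins(bins: pd.Series) -> list[str]:
    if isinstance(bins.dtype, pd.CategoricalDtype):
        return [c for c in bins.cat.categories if (bins == c).any()]
    return sorted(bins.dropna().unique())


def bin_or_vs_total(
    bins: pd.Series,
    outcome: np.ndarray,
    suppress_below: int = 0,
) -> pd.DataFrame:
    """Unadjusted odds ratio of the outcome for each bin versus the total
    population.

    The point estimate is (cases_bin/controls_bin)/(cases_total/controls_total).
    Because bin and total overlap, the 95% CI uses the Woolf log-OR standard
    error from the non-overlapping bin-versus-complement table (method tag
    ``woolf-complement``); zero cells get the Haldane-Anscombe 0.5 correction
    and are flagged.
    """
    y = np.asarray(outcome)
    if y.dtype.kind in "OU":
        y = (y == "case").astype(int)
    y = y.astype(int)
    a_tot, n_tot = int(y.sum()), y.size
    b_tot = n_tot - a_tot
    if a_tot == 0 or b_tot == 0:
        raise DataError("outcome must contain both classes")
    rows = []
    for label in _order_bins(bins):
        mask = (bins == label).to_numpy()
        n = int(mask.sum())
        if n == 0:
            continue
        if suppress_below and n < suppress_below:
            rows.append({"bin": label, "n": n, "stat": np.nan, "lo": np.nan,
                         "hi": np.nan, "method": "suppressed", "flag": "n_below_floor"})
            continue
        a = int(y[mask].sum())
        b = n - a
        ac, bc = a_tot - a, b_tot - b  # complement counts
        flag = ""
        if b > 0:
            or_total = (a / b) / (a_tot / b_tot)
        else:
            or_total = np.inf
            flag = "infinite"
        if min(a, b, ac, bc) == 0:
            # Haldane-Anscombe correction for the CI only
            a_, b_, ac_, bc_ = a + 0.5, b + 0.5, ac + 0.5, bc + 0.5
            flag = flag or "haldane"
        else:
            a_, b_, ac_, bc_ = float(a), float(b), float(ac), float(bc)
        or_ci = (a_ / b_) / ((a_ + ac_) / (b_ + bc_))
        se = np.sqrt(1 / a_ + 1 / b_ + 1 / ac_ + 1 / bc_)
        lo = min(or_ci * np.exp(-1.959963984540054 * se), or_total)
        hi = max(or_ci * np.exp(+1.959963984540054 * se), or_total)
        rows.append({"bin": label, "n": n, "stat": or_total, "lo": lo, "hi": hi,
                     "method": "woolf-complement", "flag": flag})
    return pd.DataFrame(rows)


def summarize_by_bin(
    bins: pd.Series,
    values: np.ndarray,
    stat: str = "mean",
    n_boot: int = 2000,
    seed: int = 0,
    suppress_below: int = 0,
) -> pd.DataFrame:
    """Per-bin mean or proportion with a seeded percentile-bootstrap 95% CI.

    Missing values are dropped within each bin; a bin with fewer than two
    non-missing values gets a suppressed CI.
    """
    if stat not in {"mean", "proportion"}:
        raise ValueError("stat must be 'mean' or 'proportion'")
    v = np.asarray(values, dtype=float)
    rng = substream(seed, f"bin_boot_{stat}")
    rows = []
    for label in _order_bins(bins):
        mask = (bins == label).to_numpy()
        x = v[mask]
        x = x[~np.isnan(x)]
        n = x.size
        if n == 0:
            continue
        if suppress_below and n < suppress_below:
            rows.append({"bin": label, "n": n, "stat": np.nan, "lo": np.nan,
                         "hi": np.nan, "method": "suppressed"})
            continue
        point = float(x.mean())
        if n < 2 or n_boot <= 0:
            lo = hi = np.nan
        else:
            idx = rng.integers(0, n, size=(n_boot, n))
            reps = x[idx].mean(axis=1)
            lo, hi = np.percentile(reps, [2.5, 97.5])
        rows.append({"bin": label, "n": n, "stat": point, "lo": float(lo),
                     "hi": float(hi), "method": f"bootstrap-{stat}"})
    return pd.DataFrame(rows)


def incidence_rate(
    events: int,
    followup_days: np.ndarray,
) -> dict:
    """Crude incidence per 1,000 person-years with an exact Poisson 95% CI.

    ``followup_days`` are summed over followed individuals; person-years use
    365.25 days.
    """
    fd = np.asarray(followup_days, dtype=float)
    if np.any(fd <= 0):
        raise DataError("followup_days must be positive for followed individuals")
    py = fd.sum() / 365.25
    if py <= 0:
        raise DataError("zero person-time")
    k = int(events)
    rate = 1000.0 * k / py
    lo = 0.0 if k == 0 else 1000.0 * stats.chi2.ppf(0.025, 2 * k) / 2.0 / py
    hi = 1000.0 * stats.chi2.ppf(0.975, 2 * (k + 1)) / 2.0 / py
    return {"events": k, "person_years": float(py), "rate_per_1000py": rate,
            "lo": float(lo), "hi": float(hi), "method": "poisson-exact"}


def plot_bins(table: pd.DataFrame, ylabel: str = "", ax=None):
    """Optional plotting hook: point estimates with CI error bars per bin.

    Takes a tidy table from :func:`bin_or_vs_total` or
    :func:`summarize_by_bin`.  Requires matplotlib (not a core dependency).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    x = np.arange(len(table))
    y = table["stat"].to_numpy(dtype=float)
    yerr = np.vstack([y - table["lo"].to_numpy(dtype=float),
                      table["hi"].to_numpy(dtype=float) - y])
    ax.errorbar(x, y, yerr=np.abs(yerr), fmt="o", ms=4, capsize=2)
    ax.set_xticks(x, table["bin"], rotation=60, fontsize=7)
    ax.set_xlabel("score percentile bin")
    ax.set_ylabel(ylabel or table["method"].iloc[0])
    return ax


def trend_test(bins: pd.Series, outcome: np.ndarray) -> dict:
    """Trend of a binary outcome across ordered bins: logistic score on the
    bin index (Cochran-Armitage-style).  Returns slope, z and one/two-sided p."""
    order = _order_bins(bins)
    idx_map = {lab: i for i, lab in enumerate(order)}
    keep = bins.isin(order).to_numpy()
    x = bins[keep].map(idx_map).to_numpy(dtype=float)
    y = np.asarray(outcome)[keep]
    if y.dtype.kind in "OU":
        y = (y == "yes") | (y == "case")
    y = y.astype(float)
    from .gwas_ct import _newton_logistic  # small shared MLE

    X = np.column_stack([np.ones_like(x), x])
    beta, cov, conv = _newton_logistic(X, y)
    if not conv:
        raise DataError("trend fit did not converge")
    z = beta[1] / np.sqrt(cov[1, 1])
    return {
        "slope": float(beta[1]),
        "z": float(z),
        "p_two_sided": float(2 * stats.norm.sf(abs(z))),
        "p_increasing": float(stats.norm.sf(z)),
    }
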