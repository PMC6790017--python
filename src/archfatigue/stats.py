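"""Group-level statistics for the cyclic-loading experiment.

Reproduces the study's statistical battery on an analysed cohort:

* mean and 95% confidence interval per group and checkpoint (t-interval on
  the mean by default; a bootstrap percentile option is available),
* Kolmogorov-Smirnov normality screening (parameters estimated from the
  sample; a Lilliefors-corrected variant is available),
* Kruskal-Wallis omnibus comparison of the three groups with pairwise
  exact Mann-Whitney rank-sum tests, Bonferroni-adjusted, and gatekept on
  the omnibus test being significant,
* Friedman tests of time-dependent change within each group
  (specimens as blocks, checkpoints as treatments),
* the low-arch onset: the earliest checkpoint at which a group's mean BAI
  is significantly below the 0.21 low-arch criterion, operationalized as
  the 95% CI upper bound falling below 0.21.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import LOW_ARCH_THRESHOLD

__all__ = [
    "summarize_group",
    "normality_screen",
    "between_group_test",
    "within_group_trend_test",
    "flag_low_arch_checkpoints",
    "group_series",
    "cohort_stats",
    "ANALYSIS_METRICS",
]

#: metric columns summarized and tested at the cohort level
ANALYSIS_METRICS = ("bai_wb", "flexibility_um_per_N", "energy_J")


def summarize_group(
    values,
    confidence: float = 0.95,
    method: str = "t",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Mean, SD and CI of one group's values at a checkpoint.

    The default CI is the textbook t-interval
    ``mean ± t(1-(1-confidence)/2, n-1) · SD/√n``; ``method="bootstrap"``
    uses percentile bootstrap resampling instead.  With fewer than two
    values the CI is undefined and flagged (``ci_defined=False``).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(x.mean())
    if n < 2:
        return {"n": n, "mean": mean, "sd": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"), "ci_defined": False}
    sd = float(x.std(ddof=1))
    if method == "t":
        half = sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    elif method == "bootstrap":
        rng = rng or np.random.default_rng(0)
        means = rng.choice(x, size=(n_boot, n), replace=True).mean(axis=1)
        q = (1.0 - confidence) / 2.0
        lo, hi = (float(v) for v in np.quantile(means, [q, 1.0 - q]))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return {"n": n, "mean": mean, "sd": sd, "ci_low": float(lo), "ci_high": float(hi),
            "ci_defined": True}


def normality_screen(values, alpha: float = 0.05, variant: str = "ks") -> dict:
    """One-sample normality test against a normal with estimated mean/SD.

    ``variant="ks"`` is the plain Kolmogorov-Smirnov test with plug-in
    parameters; ``variant="lilliefors"`` applies the Lilliefors correction
    for the estimated parameters.  Verdict is "non-normal" when p < alpha.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError(f"normality screening needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0:
        warnings.warn("constant sample; normality test degenerate", stacklevel=2)
        return {"statistic": float("nan"), "p": float("nan"), "verdict": "degenerate"}
    if variant == "ks":
        stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    elif variant == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(x, dist="norm")
    else:
        raise ValueError(f"unknown normality variant {variant!r}")
    return {
        "statistic": float(stat),
        "p": float(p),
        "verdict": "non-normal" if p < alpha else "normal",
    }


def between_group_test(
    groups: Mapping[str, Sequence[float]],
    metric: str = "",
    alpha: float = 0.05,
    pairwise: bool = True,
) -> pd.DataFrame:
    """Kruskal-Wallis omnibus test with gatekept Bonferroni pairwise tests.

    Pairwise exact Mann-Whitney rank-sum tests are run only when the omnibus
    test is significant at ``alpha`` (the gatekeeping used in the study);
    their p-values are Bonferroni-adjusted over the number of pairs.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    pooled = np.concatenate(list(samples.values()))
    rows = []
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*samples.values())
    omnibus_significant = p < alpha
    rows.append(
        {
            "test": "kruskal-wallis",
            "metric": metric,
            "comparison": " vs ".join(names),
            "statistic": float(stat),
            "p_raw": float(p),
            "p_adjusted": float(p),
            "adjustment": "none",
            "significant": bool(omnibus_significant),
        }
    )
    if pairwise and omnibus_significant:
        pairs = list(itertools.combinations(names, 2))
        m = len(pairs)
        for a, b in pairs:
            ustat, praw = sps.mannwhitneyu(
                samples[a], samples[b], alternative="two-sided", method="exact"
            )
            padj = min(1.0, praw * m)
            rows.append(
                {
                    "test": "mann-whitney-exact",
                    "metric": metric,
                    "comparison": f"{a} vs {b}",
                    "statistic": float(ustat),
                    "p_raw": float(praw),
                    "p_adjusted": float(padj),
                    "adjustment": f"bonferroni(m={m})",
                    "significant": bool(padj < alpha),
                }
            )
    return pd.DataFrame(rows)


def within_group_trend_test(block_matrix: pd.DataFrame, metric: str = "", group: str = "") -> dict:
    """Friedman test of time-dependent change within one group.

    ``block_matrix`` is wide-format: one row per specimen (block), one column
    per checkpoint (treatment).  Missing cells are rejected by name.
    """
    if block_matrix.isna().any().any():
        bad = [
            f"specimen {idx} @ checkpoint {col}"
            for idx, row in block_matrix.iterrows()
            for col in block_matrix.columns[row.isna()]
        ]
        raise ValueError("incomplete blocks for Friedman test: " + "; ".join(bad))
    if block_matrix.shape[0] < 2 or block_matrix.shape[1] < 3:
        raise ValueError("Friedman test needs >=2 specimens and >=3 checkpoints")
    columns = [block_matrix[c].to_numpy(dtype=float) for c in block_matrix.columns]
    arr = np.asarray(columns)
    if np.all(arr == arr[0:1, :]):  # every specimen constant over time
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(*columns)
    return {
        "test": "friedman",
        "metric": metric,
        "comparison": f"{group}: {block_matrix.shape[1]} checkpoints",
        "statistic": float(stat),
        "p_raw": float(p),
        "p_adjusted": float(p),
        "adjustment": "none",
        "significant": bool(p < 0.05),
    }


def group_series(
    checkpoint_table: pd.DataFrame,
    metric: str,
    ci_method: str = "t",
) -> pd.DataFrame:
    """Per-group, per-checkpoint summary of one metric.

    ``checkpoint_table`` is long-format with columns ``specimen_id``,
    ``group``, ``cycle`` and the metric columns.
    """
    rows = []
    for (group, cycle), sub in checkpoint_table.groupby(["group", "cycle"], sort=True):
        summ = summarize_group(sub[metric].to_numpy(), method=ci_method)
        rows.append({"group": group, "cycle": int(cycle), "metric": metric, **summ})
    return pd.DataFrame(rows).sort_values(["group", "cycle"]).reset_index(drop=True)


def flag_low_arch_checkpoints(
    series: pd.DataFrame,
    threshold: float = LOW_ARCH_THRESHOLD,
) -> int | None:
    """Earliest checkpoint where the group mean BAI is significantly low.

    "Significantly below the low-arch criterion" means the 95% CI upper
    bound of the group-mean weight-bearing BAI lies below ``threshold``.
    Returns the checkpoint cycle, or None if the group never crosses.
    """
    usable = series[series["ci_defined"].astype(bool)].sort_values("cycle")
    hit = usable[usable["ci_high"] < threshold]
    if len(hit) == 0:
        return None
    return int(hit["cycle"].iloc[0])


def cohort_stats(
    checkpoint_table: pd.DataFrame,
    deltas: pd.DataFrame | None = None,
    inflections: pd.DataFrame | None = None,
    alpha: float = 0.05,
    ci_method: str = "t",
    first_cycle: int = 1,
) -> dict:
    """Run the full statistical battery on an analysed cohort.

    Parameters
    ----------
    checkpoint_table
        Long-format table: specimen_id, group, cycle, and the metric columns
        in :data:`ANALYSIS_METRICS`.
    deltas
        Optional per-specimen first-vs-last deltas (specimen_id, group,
        delta_* columns).
    inflections
        Optional per-specimen inflection cycles (specimen_id, group,
        inflection_cycle).

    Returns
    -------
    dict
        ``summaries`` (per metric group series), ``tests`` (test table),
        ``normality`` (screening table), ``low_arch_onset`` (per group),
        ``inflection_summary`` (per group, when provided).
    """
    summaries = pd.concat(
        [group_series(checkpoint_table, m, ci_method) for m in ANALYSIS_METRICS],
        ignore_index=True,
    )

    test_rows: list[pd.DataFrame] = []
    normality_rows = []

    first = checkpoint_table[checkpoint_table["cycle"] == first_cycle]
    n_per_group = first.groupby("group")["specimen_id"].nunique()
    can_test = (n_per_group >= 2).all() and len(n_per_group) >= 2

    for metric in ANALYSIS_METRICS:
        for group, sub in first.groupby("group"):
            vals = sub[metric].to_numpy()
            if len(vals) >= 3:
                res = normality_screen(vals, alpha=alpha)
                normality_rows.append(
                    {"metric": metric, "group": group, "where": f"cycle {first_cycle}", **res}
                )
        if can_test:
            by_group = {g: s[metric].to_numpy() for g, s in first.groupby("group")}
            test_rows.append(between_group_test(by_group, metric=f"{metric}@cycle{first_cycle}",
                                                alpha=alpha))
        # within-group time trend
        for group, sub in checkpoint_table.groupby("group"):
            wide = sub.pivot(index="specimen_id", columns="cycle", values=metric)
            if wide.shape[0] >= 2 and wide.shape[1] >= 3:
                test_rows.append(pd.DataFrame([
                    within_group_trend_test(wide, metric=metric, group=str(group))
                ]))

    if deltas is not None and can_test:
        for col in [c for c in deltas.columns if c.startswith("delta_")]:
            by_group = {g: s[col].to_numpy() for g, s in deltas.groupby("group")}
            if all(len(v) >= 2 for v in by_group.values()):
                test_rows.append(between_group_test(by_group, metric=col, alpha=alpha))

    inflection_summary = None
    if inflections is not None and len(inflections):
        inf_ok = inflections.dropna(subset=["inflection_cycle"])
        rows = []
        for group, sub in inf_ok.groupby("group"):
            summ = summarize_group(sub["inflection_cycle"].to_numpy(), method=ci_method)
            rows.append({"group": group, **summ})
        inflection_summary = pd.DataFrame(rows)
        by_group = {
            g: s["inflection_cycle"].to_numpy()
            for g, s in inf_ok.groupby("group")
            if len(s) >= 2 and s["inflection_cycle"].std() > 0
        }
        if len(by_group) >= 2:
            test_rows.append(
                between_group_test(by_group, metric="inflection_cycle", alpha=alpha)
            )

    onset_rows = []
    bai_series = summaries[summaries["metric"] == "bai_wb"]
    for group, sub in bai_series.groupby("group"):
        onset = flag_low_arch_checkpoints(sub)
        onset_rows.append({
            "group": group,
            "low_arch_onset_cycle": onset if onset is not None else np.nan,
            "criterion": f"CI upper bound < {LOW_ARCH_THRESHOLD}",
        })

    return {
        "summaries": summaries,
        "tests": pd.concat(test_rows, ignore_index=True) if test_rows else pd.DataFrame(),
        "normality": pd.DataFrame(normality_rows),
        "low_arch_onset": pd.DataFrame(onset_rows),
        "inflection_summary": inflection_summary,
    }
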