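"""Nonparametric statistics battery: oracles and gatekeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import archfatigue as af


def test_summary_matches_textbook_t_interval():
    values = [0.21, 0.20, 0.22, 0.19, 0.205, 0.215]
    out = af.summarize_group(values)
    n = 6
    mean = sum(values) / n
    sd = (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5
    half = 2.5705818356363627 * sd / n**0.5  # t(0.975, 5)
    assert out["mean"] == pytest.approx(mean)
    assert out["ci_low"] == pytest.approx(mean - half, rel=1e-9)
    assert out["ci_high"] == pytest.approx(mean + half, rel=1e-9)


def test_summary_degenerate_and_constant_cases():
    const = af.summarize_group([0.2, 0.2, 0.2])
    assert const["ci_low"] == pytest.approx(0.2)
    assert const["ci_high"] == pytest.approx(0.2)
    assert const["sd"] == pytest.approx(0.0, abs=1e-15)
    single = af.summarize_group([0.2])
    assert single["ci_defined"] is False and np.isnan(single["ci_low"])


def test_bootstrap_ci_brackets_the_mean():
    rng = np.random.default_rng(5)
    x = rng.normal(0.2, 0.01, 30)
    out = af.summarize_group(x, method="bootstrap", rng=np.random.default_rng(1))
    assert out["ci_low"] < out["mean"] < out["ci_high"]


def test_normality_screen_verdicts():
    rng = np.random.default_rng(2)
    skewed = af.normality_screen(rng.exponential(1.0, 300))
    assert skewed["verdict"] == "non-normal"
    with pytest.raises(ValueError):
        af.normality_screen([1.0, 2.0])
    with pytest.warns(UserWarning, match="constant"):
        out = af.normality_screen([1.0, 1.0, 1.0])
    assert out["verdict"] == "degenerate"


def test_normality_screen_holds_level_under_the_null():
    """Gaussian samples are called normal in the vast majority of replicates."""
    rng = np.random.default_rng(7)
    verdicts = [
        af.normality_screen(rng.normal(size=50))["verdict"] == "normal"
        for _ in range(300)
    ]
    assert np.mean(verdicts) >= 0.90


def test_kruskal_statistic_matches_hand_computation():
    """Fully separated ranks: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) = 7.2."""
    out = af.between_group_test(
        {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}, metric="toy"
    )
    omnibus = out.iloc[0]
    assert omnibus["statistic"] == pytest.approx(7.2)
    assert omnibus["p_raw"] == pytest.approx(sps.chi2.sf(7.2, 2), rel=1e-9)
    # omnibus significant -> pairwise rows present, Bonferroni over 3 pairs
    pairwise = out[out["test"] == "mann-whitney-exact"]
    assert len(pairwise) == 3
    assert np.all(pairwise["p_adjusted"] >= pairwise["p_raw"] - 1e-15)
    assert np.all(pairwise["p_adjusted"] <= 1.0)
    np.testing.assert_allclose(
        pairwise["p_adjusted"], np.minimum(1.0, pairwise["p_raw"] * 3)
    )


def test_identical_groups_gatekeep_pairwise():
    out = af.between_group_test(
        {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0], "c": [1.0, 1.0, 1.0]}
    )
    assert len(out) == 1  # omnibus only, no pairwise rows
    assert out.iloc[0]["p_raw"] == pytest.approx(1.0)
    assert out.iloc[0]["statistic"] == pytest.approx(0.0)


def test_friedman_statistic_matches_hand_computation():
    """3 blocks x 3 treatments with identical rank order: chi2_F = 6."""
    wide = pd.DataFrame(
        {"t1": [1.0, 2.0, 3.0], "t2": [4.0, 5.0, 6.0], "t3": [7.0, 8.0, 9.0]},
        index=["s1", "s2", "s3"],
    )
    out = af.within_group_trend_test(wide)
    assert out["statistic"] == pytest.approx(6.0)
    assert out["p_raw"] == pytest.approx(sps.chi2.sf(6.0, 2), rel=1e-6)


def test_friedman_constant_specimens_give_p_one():
    wide = pd.DataFrame({c: [0.2, 0.3] for c in range(5)}, index=["s1", "s2"])
    out = af.within_group_trend_test(wide)
    assert out["p_raw"] == pytest.approx(1.0)
    assert not out["significant"]


def test_friedman_missing_cell_named():
    wide = pd.DataFrame({"t1": [1.0, 2.0], "t2": [np.nan, 3.0], "t3": [2.0, 4.0]},
                        index=["s1", "s2"])
    with pytest.raises(ValueError, match="s1 @ checkpoint t2"):
        af.within_group_trend_test(wide)


def _series(means, halfwidth=0.004):
    return pd.DataFrame(
        {
            "group": "g",
            "cycle": af.default_checkpoints(),
            "metric": "bai_wb",
            "mean": means,
            "sd": 0.005,
            "ci_low": np.asarray(means) - halfwidth,
            "ci_high": np.asarray(means) + halfwidth,
            "ci_defined": True,
            "n": 6,
        }
    )


def test_low_arch_onset_is_earliest_significant_checkpoint():
    means = np.linspace(0.24, 0.18, 11)
    series = _series(means)
    onset = af.flag_low_arch_checkpoints(series)
    expected = int(series.loc[series["ci_high"] < 0.21, "cycle"].iloc[0])
    assert onset == expected
    high = _series(np.full(11, 0.24))
    assert af.flag_low_arch_checkpoints(high) is None


def test_low_arch_onset_uses_ci_not_mean():
    # mean below 0.21 but CI still straddling the criterion: not yet "low"
    means = np.full(11, 0.208)
    assert af.flag_low_arch_checkpoints(_series(means, halfwidth=0.004)) is None
    assert af.flag_low_arch_checkpoints(_series(means, halfwidth=0.001)) == 1
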