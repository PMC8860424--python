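"""Univariate cohort statistics: Levene-gated two-sample t-tests.

For each of the 26 radiomic features the two histology groups are compared
with an independent two-sample t-test; the classic (mean-centred) Levene
test decides, at alpha = 0.05, whether the pooled-variance or the Welch
(unequal-variance) variant is used.  The t-test can also be evaluated from
published per-group summary statistics (n, mean, SD) alone, which is how
cohort tables reporting "mean +/- SD" are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .texture import FEATURE_NAMES

ALPHA = 0.05


@dataclass
class GroupSummary:
    """Per-group sample summary; sd is the n-1 (sample) standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    variant: str  # "pooled" | "welch"
    levene_p: float | None = None


def levene_test(x, y) -> tuple[float, float]:
    """Classic mean-centred Levene test of equal variances.

    Returns (W, p) with an F(1, n1+n2-2) reference distribution.  Two
    samples with no spread at all give (0, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 0.0, 1.0
    w, p = stats.levene(x, y, center="mean")
    return float(w), float(p)


def ttest_from_summary(
    g1: GroupSummary, g2: GroupSummary, variant: str = "pooled"
) -> TestResult:
    """Two-sample t-test evaluated from (n, mean, sd) summaries.

    pooled: sp^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2), df = n1+n2-2.
    welch: SE^2 = s1^2/n1 + s2^2/n2 with Welch-Satterthwaite df.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant: {variant}")
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            df = g1.n + g2.n - 2
            return TestResult(t=0.0, df=float(df), p=1.0, variant=variant)
        raise ValueError("zero variance with unequal means: t is undefined")
    t, p = stats.ttest_ind_from_stats(
        g1.mean,
        g1.sd,
        g1.n,
        g2.mean,
        g2.sd,
        g2.n,
        equal_var=(variant == "pooled"),
    )
    if variant == "pooled":
        df = float(g1.n + g2.n - 2)
    else:
        v1 = g1.sd**2 / g1.n
        v2 = g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return TestResult(t=float(t), df=float(df), p=float(p), variant=variant)


def ttest_raw(x, y) -> TestResult:
    """Levene-gated t-test on two raw samples.

    Pooled when Levene's p >= 0.05, Welch otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _, lev_p = levene_test(x, y)
    variant = "pooled" if lev_p >= ALPHA else "welch"
    res = ttest_from_summary(
        GroupSummary(len(x), float(x.mean()), float(x.std(ddof=1))),
        GroupSummary(len(y), float(y.mean()), float(y.std(ddof=1))),
        variant,
    )
    res.levene_p = lev_p
    return res


def feature_table_report(features, labels) -> pd.DataFrame:
    """Per-feature group summaries and Levene-gated t-tests.

    `features` is an (n, 26) matrix or a DataFrame with canonical feature
    columns; `labels` are SPCH/LPA strings (or 1/0).  Returns one row per
    feature in canonical order with group mean/sd, Levene p, the routed
    t-test variant, the two-sided p and a significance flag at 0.05.
    """
    if hasattr(features, "loc") and hasattr(features, "columns"):
        X = features.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    lab = np.asarray(labels)
    pos = lab == "SPCH" if lab.dtype.kind in "UOS" else lab > 0
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("both classes need n >= 2")
    rows = []
    for k, name in enumerate(FEATURE_NAMES):
        x = X[pos, k]
        y = X[~pos, k]
        res = ttest_raw(x, y)
        rows.append(
            {
                "feature": name,
                "spch_mean": x.mean(),
                "spch_sd": x.std(ddof=1),
                "lpa_mean": y.mean(),
                "lpa_sd": y.std(ddof=1),
                "levene_p": res.levene_p,
                "variant": res.variant,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "significant": res.p < ALPHA,
            }
        )
    return pd.DataFrame(rows)
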