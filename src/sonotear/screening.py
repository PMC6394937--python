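"""Univariate feature screening: normality-routed two-sample tests.

Each feature is tested for a class difference at ``alpha = 0.05``.  The
test is chosen per feature: if *both* class-conditional samples look
normal under a one-sample Kolmogorov-Smirnov test (against a normal law
with sample-estimated mean and SD), a pooled-variance Student t-test is
used; otherwise a two-sided Mann-Whitney U-test.

Using the KS statistic with estimated parameters is the Lilliefors
situation — the naive p-value is conservative for the normality decision.
A Lilliefors-corrected variant (via statsmodels) can be requested; the
routing default keeps the plain KS test.  No multiple-testing correction
is applied: each feature is screened marginally, and the report is meant
for transparency rather than selection (the classifier performs its own
feature selection).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .intensity import INTENSITY_FEATURE_NAMES
from .texture import TEXTURE_FEATURE_NAMES

ALL_FEATURE_NAMES = INTENSITY_FEATURE_NAMES + TEXTURE_FEATURE_NAMES

#: non-feature columns of a feature table
META_COLUMNS = ("case_id", "patient_id", "label")


def ks_normality(values, lilliefors: bool = False) -> float:
    """P-value of a KS test of normality with estimated mean/SD.

    A zero-variance sample is non-normal by convention (p = 0).  With
    ``lilliefors=True`` the parameter-estimation effect is corrected using
    the statsmodels implementation.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError(f"need at least 8 observations, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        return float(_lf(x, dist="norm")[1])
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def two_sample_t(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student t-test (pooled variance; ``welch=True`` for Welch)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test.

    The exact null distribution is used for small tie-free samples,
    otherwise the tie-corrected normal approximation (scipy's ``auto``
    policy).  Returns the U statistic of the first sample.
    """
    res = stats.mannwhitneyu(
        np.asarray(x, float), np.asarray(y, float), alternative="two-sided", method="auto"
    )
    return float(res.statistic), float(res.pvalue)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a feature table (everything but the metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    lilliefors: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Screen every feature of a feature table for a class difference.

    Returns one row per feature with the per-class normality p-values, the
    routed test, its statistic and p-value, a significance flag at `alpha`,
    and per-class summaries (mean, SD, median) for reporting.  Undefined
    (nan) feature values are dropped per feature before testing.
    """
    if "label" not in table.columns:
        raise ValueError("feature table has no 'label' column")
    labels = sorted(table["label"].unique())
    if len(labels) != 2:
        raise ValueError(f"screening needs exactly 2 classes, found {labels}")
    g0, g1 = labels
    rows = []
    for feature in feature_columns(table):
        x = table.loc[table["label"] == g0, feature].dropna().to_numpy(float)
        y = table.loc[table["label"] == g1, feature].dropna().to_numpy(float)
        if len(x) < 8 or len(y) < 8:
            raise ValueError(
                f"feature {feature!r}: need >= 8 defined values per class "
                f"(got {len(x)}/{len(y)})"
            )
        p_norm_x = ks_normality(x, lilliefors=lilliefors)
        p_norm_y = ks_normality(y, lilliefors=lilliefors)
        normal = p_norm_x > normality_alpha and p_norm_y > normality_alpha
        if normal:
            test = "t"
            statistic, pvalue = two_sample_t(x, y, welch=welch)
        else:
            test = "MannWhitneyU"
            statistic, pvalue = mann_whitney_u(x, y)
        rows.append(
            {
                "feature": feature,
                f"normality_p_{g0}": p_norm_x,
                f"normality_p_{g1}": p_norm_y,
                "test": test,
                "statistic": statistic,
                "p_value": pvalue,
                "significant": bool(pvalue < alpha),
                f"mean_{g0}": x.mean(),
                f"sd_{g0}": x.std(ddof=1),
                f"median_{g0}": float(np.median(x)),
                f"mean_{g1}": y.mean(),
                f"sd_{g1}": y.std(ddof=1),
                f"median_{g1}": float(np.median(y)),
            }
        )
    return pd.DataFrame(rows)
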