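"""Histogram-moment (first-order) intensity features of a lesion.

The gray-level distribution inside the delineated lesion is summarised by
its first four moments: mean, variance, skewness and kurtosis.  Tears are
hypoechoic (dark) focal defects, so they sit lower and more peaked/skewed
than the heterogeneous but brighter tendinopathies.

Conventions (configurable nowhere — they define the feature):

* population moments (divide by n, no small-sample correction); lesion ROIs
  have thousands of pixels, where the distinction is negligible;
* kurtosis is the non-excess form ``m4 / m2**2`` (Gaussian reference 3);
* at zero variance, skewness and kurtosis are undefined and reported as
  ``nan`` — the package-wide undefined sentinel — never as a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

INTENSITY_FEATURE_NAMES = ("Mean", "Variance", "Skewness", "Kurtosis")


@dataclass(frozen=True)
class HistogramMoments:
    mean: float
    variance: float
    skewness: float  # nan when variance == 0
    kurtosis: float  # nan when variance == 0; >= 1 when defined

    def as_dict(self) -> dict[str, float]:
        return {
            "Mean": self.mean,
            "Variance": self.variance,
            "Skewness": self.skewness,
            "Kurtosis": self.kurtosis,
        }


def compute_moments(pixels) -> HistogramMoments:
    """First four population central moments of an intensity sample."""
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 pixels, got {x.size}")
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d * d))
    if m2 == 0.0:
        return HistogramMoments(mean, 0.0, math.nan, math.nan)
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return HistogramMoments(mean, m2, m3 / m2**1.5, m4 / m2**2)
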