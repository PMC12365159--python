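"""Application-dose estimation from tank and exposed-filter observations.

During spraying, paper filters exposed at canopy top (and at the ground)
collect the deposited product; the areal dose is the collected mass per
filter area.  Filter-pair estimates are compared with the tank-based
estimate (concentration x applied volume / treated surface) by a Welch
two-sample t-test, which accommodates the small, unequal sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import ng_m2_to_g_ha

__all__ = ["DoseEstimate", "TestSummary", "filter_dose", "compare_doses",
           "welch_from_stats"]


@dataclass
class DoseEstimate:
    """Summary of one dose-estimation method, g ha^-1."""

    method: str          # "tank" | "filter_top" | "filter_ground"
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be >= 0")


@dataclass
class TestSummary:
    statistic: float
    df: float
    pvalue: float


def filter_dose(contents_ng, filter_diameter_m: float = 0.09,
                n_filters_per_pair: int = 2,
                method: str = "filter_top") -> DoseEstimate:
    """Areal dose from filter-pair chlorothalonil contents.

    ``contents_ng`` holds the mass collected by each pooled filter pair
    (the extraction unit); each pair exposes
    ``n_filters_per_pair * pi (diameter/2)^2`` of collecting area.  The
    per-pair doses (ng m^-2) convert to g ha^-1 and are summarised by
    their mean and standard deviation.
    """
    contents = np.asarray(contents_ng, dtype=float)
    if contents.size == 0:
        raise ValueError("no filter contents supplied")
    area = n_filters_per_pair * math.pi * (filter_diameter_m / 2.0) ** 2
    if area <= 0:
        raise ValueError("filter area must be > 0")
    doses = ng_m2_to_g_ha(contents / area)
    sd = float(np.std(doses, ddof=1)) if doses.size > 1 else 0.0
    return DoseEstimate(method=method, mean=float(np.mean(doses)),
                        sd=sd, n=int(doses.size))


def welch_from_stats(mean1, sd1, n1, mean2, sd2, n2) -> TestSummary:
    """Welch two-sample t-test from summary statistics."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups")
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestSummary(statistic=float(res.statistic), df=float(df),
                       pvalue=float(res.pvalue))


def compare_doses(a: DoseEstimate, b: DoseEstimate) -> TestSummary:
    """Welch comparison of two dose estimates from their summaries."""
    if a.n < 2 or b.n < 2:
        raise ValueError("each estimate needs n >= 2")
    return welch_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n)
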