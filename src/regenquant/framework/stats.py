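"""Statistical test dispatch.

Normality of each dataset is assessed with the Shapiro–Wilk test at
α = 0.01 (a dataset passes when its p-value is ≥ 0.01). When every
dataset passes, the parametric branch is taken: unpaired Student's t-test
for two groups, one-way ANOVA for more. Otherwise the nonparametric
branch: Mann-Whitney for two groups, Kruskal-Wallis for more. Only the
dispatch rule is bespoke; the underlying statistics come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from ..errors import InputError

__all__ = ["Dataset", "TestDecision", "dispatch_test", "ALPHA_NORMALITY"]

ALPHA_NORMALITY = 0.01

#: (branch, n_groups == 2) -> test name; completeness of this table is a
#: package invariant.
_TEST_TABLE = {
    ("parametric", True): "t_test",
    ("parametric", False): "anova",
    ("nonparametric", True): "mann_whitney",
    ("nonparametric", False): "kruskal_wallis",
}


@dataclass
class Dataset:
    """A labelled sample of real-valued measurements."""

    label: str
    values: np.ndarray
    grouping: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 3:
            raise InputError(
                f"dataset {self.label!r} needs >= 3 values for normality testing"
            )
        if np.ptp(self.values) == 0:
            raise InputError(
                f"dataset {self.label!r} is constant; tests are undefined"
            )


@dataclass
class TestDecision:
    """Full decision trail of a dispatched comparison."""

    branch: str
    test_name: str
    normality_p_values: dict
    alpha_normality: float
    statistic: float
    p_value: float
    n_groups: int
    notes: list = field(default_factory=list)


def dispatch_test(
    datasets: Sequence[Dataset],
    alpha_normality: float = ALPHA_NORMALITY,
) -> TestDecision:
    """Select and run the mandated comparison for the given datasets."""
    datasets = [
        d if isinstance(d, Dataset) else Dataset(label=f"group{i}", values=d)
        for i, d in enumerate(datasets)
    ]
    if len(datasets) < 2:
        raise InputError("dispatch_test needs at least two datasets to compare")

    normality = {d.label: float(sps.shapiro(d.values).pvalue) for d in datasets}
    all_normal = all(p >= alpha_normality for p in normality.values())
    branch = "parametric" if all_normal else "nonparametric"
    test_name = _TEST_TABLE[(branch, len(datasets) == 2)]

    samples = [d.values for d in datasets]
    if test_name == "t_test":
        res = sps.ttest_ind(*samples)
    elif test_name == "anova":
        res = sps.f_oneway(*samples)
    elif test_name == "mann_whitney":
        res = sps.mannwhitneyu(*samples, alternative="two-sided")
    else:
        res = sps.kruskal(*samples)

    return TestDecision(
        branch=branch,
        test_name=test_name,
        normality_p_values=normality,
        alpha_normality=alpha_normality,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_groups=len(datasets),
    )


def sem(values) -> float:
    """Standard error of the mean (ddof=1), the package-wide error bar."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))
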