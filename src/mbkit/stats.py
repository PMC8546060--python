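"""Reproducibility and pharmacology statistics for contractility assays.

Small, exact building blocks: coefficient of variation, percent
reduction, fold ratio, and the two-sample normal-approximation sample
size for detecting a relative difference between group means when the
between-replicate variability is expressed as a CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV = sd / |mean|; undefined for a zero mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return sd / abs(mean)


def percent_reduction(reference: float, value: float) -> int:
    """100 * (1 - value/reference), rounded to the nearest integer percent."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return round(100.0 * (1.0 - value / reference))


def fold_ratio(a: float, b: float) -> float:
    """Plain ratio a / b (e.g. yield fold between two preparations)."""
    if b == 0:
        raise ValueError("fold undefined for zero denominator")
    return a / b


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a two-group sample-size calculation.

    ``delta_rel`` is the relative difference between group means to be
    detected; ``cv`` the coefficient of variation of the measurement
    across replicates.  Two-sided alpha.
    """

    alpha: float = 0.05
    power: float = 0.90
    delta_rel: float = 0.20
    cv: float = 0.21

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.delta_rel <= 0:
            raise ValueError("delta_rel must be positive")
        if self.cv <= 0:
            raise ValueError("cv must be positive")


def two_group_sample_size(spec: PowerSpec, rounding: str = "nearest") -> int:
    """n per group to detect a relative difference between two means.

    Normal-approximation formula
    ``n = 2 (z_{1-alpha/2} + z_{1-beta})^2 (CV / delta_rel)^2``
    with configurable rounding (``"nearest"`` default, ``"ceil"`` for
    conservative planning).  An iterative t-correction is available via
    :func:`two_group_sample_size_t`.
    """
    z_a = norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = norm.ppf(spec.power)
    n = 2.0 * (z_a + z_b) ** 2 * (spec.cv / spec.delta_rel) ** 2
    if rounding == "nearest":
        n_int = round(n)
    elif rounding == "ceil":
        n_int = math.ceil(n)
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    return max(int(n_int), 2)


def two_group_sample_size_t(spec: PowerSpec, max_iter: int = 100) -> int:
    """Sample size with iterative Student-t correction (conservative)."""
    from scipy.stats import t as t_dist

    n = float(two_group_sample_size(spec, rounding="ceil"))
    for _ in range(max_iter):
        df = max(2.0 * n - 2.0, 1.0)
        t_a = t_dist.ppf(1.0 - spec.alpha / 2.0, df)
        t_b = t_dist.ppf(spec.power, df)
        n_new = math.ceil(2.0 * (t_a + t_b) ** 2 * (spec.cv / spec.delta_rel) ** 2)
        if n_new == n:
            break
        n = n_new
    return max(int(n), 2)
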