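"""Pulse-chase renewal kinetics for rod outer segments.

A heat-shock-induced membrane label forms a fluorescent stripe in the disc
stack at the time of induction.  Discs added afterwards displace the stripe
away from the base, so the base-to-stripe distance (``D^G``) is post-label
growth, while the stripe-to-tip distance (``D^S``) is pre-label growth minus
whatever was shed from the tip during the chase.  This module maps between
those two distances and the underlying per-day growth and shedding rates,
and provides the pooled-control benchmark arithmetic used for hit
thresholds.

All distances are in micrometres (µm), rates in µm/day, times in days post
fertilization (dpf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StudyTimeline",
    "RenewalRates",
    "InferredRates",
    "ExpectedDistances",
    "SuppressionEquivalent",
    "Benchmark",
    "DEFAULT_TIMELINE",
    "expected_distances",
    "infer_rates",
    "suppression_equivalent",
    "percent_change",
    "round_percent",
    "pool_controls",
]


@dataclass(frozen=True)
class StudyTimeline:
    """The pulse-chase clock: rod birth, label induction, fixation.

    Parameters
    ----------
    birth_dpf : int
        Day post fertilization at which most rods are born (outer segment
        growth starts).
    heatshock_dpf : int
        Day of heat shock, i.e. stripe-label induction and start of
        compound treatment.
    fix_dpf : int
        Day of fixation (end of the chase).
    pre_rate : float
        Outer segment growth rate (µm/day) before heat shock, taken from
        untreated fish reared on the same light cycle.
    """

    birth_dpf: int = 3
    heatshock_dpf: int = 6
    fix_dpf: int = 10
    pre_rate: float = 1.6

    def __post_init__(self) -> None:
        if not (self.birth_dpf < self.heatshock_dpf < self.fix_dpf):
            raise ValueError(
                "invalid timeline: need birth_dpf < heatshock_dpf < fix_dpf, "
                f"got ({self.birth_dpf}, {self.heatshock_dpf}, {self.fix_dpf})"
            )
        if self.pre_rate < 0:
            raise ValueError("pre_rate must be >= 0")

    @property
    def treatment_days(self) -> int:
        """Days between heat shock and fixation (the chase window)."""
        return self.fix_dpf - self.heatshock_dpf

    @property
    def pre_days(self) -> int:
        """Days of outer segment growth before heat shock."""
        return self.heatshock_dpf - self.birth_dpf

    @property
    def pre_growth(self) -> float:
        """Expected outer segment length laid down before heat shock (µm)."""
        return self.pre_rate * self.pre_days


DEFAULT_TIMELINE = StudyTimeline()


@dataclass(frozen=True)
class RenewalRates:
    """Post-heat-shock renewal rates: basal growth and apical shedding (µm/day)."""

    growth_rate: float
    shed_rate: float

    def __post_init__(self) -> None:
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")


@dataclass(frozen=True)
class InferredRates(RenewalRates):
    """Rates recovered from mean distances.

    ``negative_shed`` flags a shedding rate that came out negative (the
    observed stripe-to-tip distance exceeded nominal pre-label growth); the
    value is reported as-is rather than clamped so that simulation-vs-
    inference round trips stay honest.
    """

    negative_shed: bool = False


@dataclass(frozen=True)
class ExpectedDistances:
    """Model-expected stripe distances; ``truncated`` marks a D^S floored at 0."""

    dg: float
    ds: float
    truncated: bool = False


@dataclass(frozen=True)
class SuppressionEquivalent:
    """What a percent increase in the D^S benchmark means in shedding terms."""

    ds_threshold: float
    shed_total: float
    shed_per_day: float


@dataclass(frozen=True)
class Benchmark:
    """Pooled control statistics for one metric.

    ``mean``/``sd`` are across fish-level means (the fish is the unit of
    replication); ``rod_mean``/``rod_sd`` pool all rods directly.
    ``sd`` is defined as 0 for a single fish, flagged via ``single_fish``.
    """

    metric: str
    mean: float
    sd: float
    n_rods: int
    n_fish: int
    rod_mean: float
    rod_sd: float
    single_fish: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.n_rods >= self.n_fish >= 1):
            raise ValueError("need n_rods >= n_fish >= 1")


def expected_distances(
    rates: RenewalRates, timeline: StudyTimeline = DEFAULT_TIMELINE
) -> ExpectedDistances:
    """Expected D^G and D^S for given renewal rates.

    D^G is post-label growth: ``growth_rate`` times the chase duration.
    D^S is pre-label growth minus post-label shedding, floored at zero
    (a stripe cannot sit above the tip); the floor sets ``truncated``.
    """
    if rates.shed_rate < 0:
        raise ValueError("shed_rate must be >= 0 for the forward model")
    t = timeline.treatment_days
    dg = rates.growth_rate * t
    ds_raw = timeline.pre_growth - rates.shed_rate * t
    if ds_raw < 0:
        return ExpectedDistances(dg=dg, ds=0.0, truncated=True)
    return ExpectedDistances(dg=dg, ds=ds_raw, truncated=False)


def infer_rates(
    dg_mean: float, ds_mean: float, timeline: StudyTimeline = DEFAULT_TIMELINE
) -> InferredRates:
    """Invert the stripe model: recover growth and shedding rates from mean distances.

    ``growth_rate = dg_mean / chase_days``;
    ``shed_rate = (pre-label growth − ds_mean) / chase_days``.
    A negative shedding rate (D^S above nominal pre-label growth) is
    returned flagged, not clamped.
    """
    if dg_mean < 0 or ds_mean < 0:
        raise ValueError("mean distances must be >= 0")
    t = timeline.treatment_days
    if t == 0:
        raise ZeroDivisionError("fix_dpf == heatshock_dpf: no chase window")
    growth = dg_mean / t
    shed = (timeline.pre_growth - ds_mean) / t
    return InferredRates(growth_rate=growth, shed_rate=shed, negative_shed=shed < 0)


def suppression_equivalent(
    benchmark_ds: float,
    pct_increase: float,
    timeline: StudyTimeline = DEFAULT_TIMELINE,
) -> SuppressionEquivalent:
    """Translate a percent increase of the D^S benchmark into shedding terms.

    Returns the thresholded D^S, the total shed during the chase at that
    threshold, and the equivalent per-day shedding rate.  At
    ``pct_increase=0`` this reproduces the un-thresholded control shedding.
    """
    if benchmark_ds <= 0:
        raise ValueError("benchmark_ds must be > 0")
    if pct_increase < 0:
        raise ValueError("pct_increase must be >= 0")
    ds_threshold = benchmark_ds * (1.0 + pct_increase / 100.0)
    shed_total = timeline.pre_growth - ds_threshold
    return SuppressionEquivalent(
        ds_threshold=ds_threshold,
        shed_total=shed_total,
        shed_per_day=shed_total / timeline.treatment_days,
    )


def percent_change(treated_mean: float, control_mean: float) -> float:
    """Signed percent change of a treated mean relative to its control.

    Full precision; use :func:`round_percent` for the integer reporting form.
    """
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    return 100.0 * (treated_mean - control_mean) / control_mean


def round_percent(pct: float) -> int:
    """Round a percent to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def pool_controls(measurements: pd.DataFrame, metric: str) -> Benchmark:
    """Pool control measurements across weeks into a study-wide benchmark.

    Parameters
    ----------
    measurements : DataFrame
        Control rows only, with columns ``week_id``, ``fish_id`` and the
        metric column (``d_growth_um`` or ``d_shed_um``); rows with a
        missing metric value are dropped.
    metric : str
        The metric column to pool.

    Returns
    -------
    Benchmark
        ``mean``/``sd`` across fish-level means (sample SD, ddof=1), plus
        pooled rod-level statistics and exact counts.
    """
    if metric not in measurements.columns:
        raise KeyError(f"metric column {metric!r} not present")
    sub = measurements.loc[measurements[metric].notna()]
    if len(sub) == 0:
        raise ValueError("empty benchmark: no non-missing control measurements")
    # fish are only unique within a week; key on (week, fish)
    fish_means = sub.groupby(["week_id", "fish_id"], sort=True)[metric].mean()
    n_fish = len(fish_means)
    values = sub[metric].to_numpy(dtype=float)
    single = n_fish == 1
    sd = 0.0 if single else float(np.std(fish_means, ddof=1))
    rod_sd = 0.0 if len(values) == 1 else float(np.std(values, ddof=1))
    return Benchmark(
        metric=metric,
        mean=float(fish_means.mean()),
        sd=sd,
        n_rods=int(len(values)),
        n_fish=int(n_fish),
        rod_mean=float(values.mean()),
        rod_sd=rod_sd,
        single_fish=single,
    )
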