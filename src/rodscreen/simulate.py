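"""Hierarchical synthetic screens with known ground truth.

The generator reproduces the data structure of a weekly pulse-chase
renewal screen: each week has one vehicle-control group and a batch of
compound groups raised from the same clutch, three fish per group, and
tens of rods measured per fish.  Variation is layered as

* a week/clutch baseline shift common to every fish processed that week,
* a fish-level random intercept,
* rod-level residual noise,

with compound effects acting multiplicatively on the post-heat-shock
growth and shedding *rates*, so a growth multiplier of 1.2 means a +20 %
growth-distance change regardless of the week baseline.  Roughly 30 % of
compounds are lethal at the screening concentration and contribute no
measurements.  Qualitative image flags (phagosome accumulation, Rhodopsin
mislocalization, marginal-zone disruption) are Bernoulli per image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import DEFAULT_TIMELINE, RenewalRates, StudyTimeline

__all__ = [
    "SimulationConfig",
    "CompoundEffect",
    "WeekData",
    "ScreenData",
    "simulate_week",
    "simulate_screen",
    "null_effects",
]

#: Control renewal rates the week baselines are centred on (µm/day).
BASELINE_RATES = RenewalRates(growth_rate=1.25, shed_rate=0.35)


@dataclass(frozen=True)
class SimulationConfig:
    """Structure and noise levels of a simulated screen.

    Defaults mirror the screen design: 8–32 compounds per week sharing one
    DMSO control, 3 fish per group, 33–149 growth-distance rods per fish
    with 24–105 of them also yielding a shedding distance, and ~30 %
    compound lethality.  The variance split (week 0.55, fish 0.35, rod
    1.0 µm) is calibrated so the fish-level control SD pools to ≈0.65 µm.
    """

    n_weeks: int = 10
    compounds_per_week: tuple[int, int] = (8, 32)
    fish_per_compound: int = 3
    rods_per_fish_dg: tuple[int, int] = (33, 149)
    rods_per_fish_ds: tuple[int, int] = (24, 105)
    week_sd: float = 0.55
    fish_sd: float = 0.35
    rod_sd: float = 1.0
    lethality_prob: float = 0.3
    control_label: str = "DMSO"
    seed: int = 0
    control_flag_prob: float = 0.02

    def __post_init__(self) -> None:
        for name in ("week_sd", "fish_sd", "rod_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.lethality_prob <= 1:
            raise ValueError("lethality_prob must be in [0, 1]")
        for name in ("compounds_per_week", "rods_per_fish_dg", "rods_per_fish_ds"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} range must be non-empty and positive")
        if self.fish_per_compound < 1:
            raise ValueError("fish_per_compound must be >= 1")


@dataclass(frozen=True)
class CompoundEffect:
    """Ground-truth effect of one compound (the simulation truth table entry).

    Multipliers scale the post-heat-shock growth and shedding rates;
    probabilities drive the per-image qualitative flags.
    """

    compound_id: str
    growth_multiplier: float = 1.0
    shed_multiplier: float = 1.0
    phagosome_prob: float = 0.02
    misloc_prob: float = 0.02
    cmz_prob: float = 0.02
    target: str = "unknown"
    pathway: str = "unannotated"

    def __post_init__(self) -> None:
        if self.growth_multiplier < 0 or self.shed_multiplier < 0:
            raise ValueError("multipliers must be >= 0")
        for p in (self.phagosome_prob, self.misloc_prob, self.cmz_prob):
            if not 0 <= p <= 1:
                raise ValueError("flag probabilities must be in [0, 1]")


@dataclass
class WeekData:
    measurements: pd.DataFrame
    qualitative: pd.DataFrame
    truth: pd.DataFrame


@dataclass
class ScreenData:
    measurements: pd.DataFrame
    qualitative: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame


def null_effects(n: int, week_index: int = 0) -> list[CompoundEffect]:
    """A batch of no-effect compounds with placeholder annotations."""
    return [CompoundEffect(compound_id=f"W{week_index}-C{i + 1}") for i in range(n)]


def _simulate_group(
    rng: np.random.Generator,
    config: SimulationConfig,
    timeline: StudyTimeline,
    week_id: str,
    compound_id: str,
    role: str,
    mu_dg: float,
    mu_ds: float,
) -> list[dict]:
    rows: list[dict] = []
    lo_g, hi_g = config.rods_per_fish_dg
    lo_s, hi_s = config.rods_per_fish_ds
    for f in range(config.fish_per_compound):
        fish_id = f"{compound_id}-F{f + 1}"
        icpt_dg = rng.normal(0.0, config.fish_sd)
        icpt_ds = rng.normal(0.0, config.fish_sd)
        n_dg = int(rng.integers(lo_g, hi_g + 1))
        n_ds = min(n_dg, int(rng.integers(lo_s, hi_s + 1)))
        dg = np.maximum(0.0, rng.normal(mu_dg + icpt_dg, config.rod_sd, n_dg))
        ds = np.maximum(0.0, rng.normal(mu_ds + icpt_ds, config.rod_sd, n_dg))
        # stripe-to-tip distance is unmeasurable for a random subset of rods
        observed = np.zeros(n_dg, dtype=bool)
        observed[rng.permutation(n_dg)[:n_ds]] = True
        for r in range(n_dg):
            rows.append(
                {
                    "week_id": week_id,
                    "compound_id": compound_id,
                    "treatment_role": role,
                    "fish_id": fish_id,
                    "rod_id": f"{fish_id}-R{r + 1}",
                    "d_growth_um": round(float(dg[r]), 4),
                    "d_shed_um": round(float(ds[r]), 4) if observed[r] else np.nan,
                }
            )
    return rows


def _flag_row(
    rng: np.random.Generator,
    week_id: str,
    compound_id: str,
    p_phago: float,
    p_misloc: float,
    p_cmz: float,
) -> dict:
    phago = rng.random(3) < p_phago
    misloc = rng.random(3) < p_misloc
    cmz = bool(rng.random() < p_cmz)
    return {
        "week_id": week_id,
        "compound_id": compound_id,
        "phagosome_1": bool(phago[0]),
        "phagosome_2": bool(phago[1]),
        "phagosome_3": bool(phago[2]),
        "misloc_1": bool(misloc[0]),
        "misloc_2": bool(misloc[1]),
        "misloc_3": bool(misloc[2]),
        "cmz": cmz,
    }


def simulate_week(
    config: SimulationConfig,
    week_index: int,
    effects: Sequence[CompoundEffect],
    timeline: StudyTimeline = DEFAULT_TIMELINE,
    rng: np.random.Generator | None = None,
) -> WeekData:
    """Simulate one screening week: a control group plus ``effects`` compounds.

    The week draws its own baseline growth and shedding rates (Normal
    around the control rates, with ``week_sd`` applied on the distance
    scale), shared by every group that week.  Lethal compounds yield no
    measurement rows but still appear in the truth table.
    """
    if not effects:
        raise ValueError("effects must be non-empty")
    if rng is None:
        # child stream keyed on (seed, week) so weeks reproduce independently
        rng = np.random.default_rng([config.seed, week_index])
    t = timeline.treatment_days
    week_id = f"W{week_index}"
    g_week = max(0.0, BASELINE_RATES.growth_rate + rng.normal(0.0, config.week_sd) / t)
    s_week = max(0.0, BASELINE_RATES.shed_rate + rng.normal(0.0, config.week_sd) / t)

    rows: list[dict] = []
    flags: list[dict] = []
    truth: list[dict] = []

    control_id = f"{week_id}-{config.control_label}"
    rows += _simulate_group(
        rng, config, timeline, week_id, control_id, "control",
        mu_dg=g_week * t, mu_ds=max(0.0, timeline.pre_growth - s_week * t),
    )
    flags.append(
        _flag_row(rng, week_id, control_id,
                  config.control_flag_prob, config.control_flag_prob,
                  config.control_flag_prob)
    )

    for eff in effects:
        lethal = bool(rng.random() < config.lethality_prob)
        truth.append(
            {
                "week_id": week_id,
                "compound_id": eff.compound_id,
                "growth_multiplier": eff.growth_multiplier,
                "shed_multiplier": eff.shed_multiplier,
                "lethal": lethal,
            }
        )
        if lethal:
            continue
        mu_dg = g_week * eff.growth_multiplier * t
        mu_ds = max(0.0, timeline.pre_growth - s_week * eff.shed_multiplier * t)
        rows += _simulate_group(
            rng, config, timeline, week_id, eff.compound_id, "compound",
            mu_dg=mu_dg, mu_ds=mu_ds,
        )
        flags.append(
            _flag_row(rng, week_id, eff.compound_id,
                      eff.phagosome_prob, eff.misloc_prob, eff.cmz_prob)
        )

    from .io import MEASUREMENT_COLUMNS, QUALITATIVE_COLUMNS, TRUTH_COLUMNS

    return WeekData(
        measurements=pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS),
        qualitative=pd.DataFrame(flags, columns=QUALITATIVE_COLUMNS),
        truth=pd.DataFrame(truth, columns=TRUTH_COLUMNS),
    )


def simulate_screen(
    config: SimulationConfig,
    effects: Sequence[Sequence[CompoundEffect]] | None = None,
    timeline: StudyTimeline = DEFAULT_TIMELINE,
) -> ScreenData:
    """Simulate a whole screen: ``n_weeks`` weeks with disjoint week ids.

    ``effects`` may give an explicit per-week list of compound effects;
    otherwise each week draws a null batch whose size is uniform over
    ``compounds_per_week``.
    """
    master = np.random.default_rng([config.seed, 10**6])
    week_effects: list[Sequence[CompoundEffect]] = []
    for w in range(config.n_weeks):
        if effects is not None:
            week_effects.append(effects[w])
        else:
            lo, hi = config.compounds_per_week
            week_effects.append(null_effects(int(master.integers(lo, hi + 1)), w))

    weeks = [
        simulate_week(config, w, week_effects[w], timeline=timeline)
        for w in range(config.n_weeks)
    ]
    annotations = pd.DataFrame(
        [
            {
                "compound_id": e.compound_id,
                "name": e.compound_id,
                "target": e.target,
                "pathway": e.pathway,
            }
            for batch in week_effects
            for e in batch
        ]
    )
    return ScreenData(
        measurements=pd.concat([w.measurements for w in weeks], ignore_index=True),
        qualitative=pd.concat([w.qualitative for w in weeks], ignore_index=True),
        annotations=annotations,
        truth=pd.concat([w.truth for w in weeks], ignore_index=True),
    )
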