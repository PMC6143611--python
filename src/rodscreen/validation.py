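"""End-to-end simulation studies: operating characteristics of the pipeline.

These routines run the full simulate → fit → compare → call pipeline on
synthetic screens with known ground truth and summarise its behaviour:
the false-positive (primary-call) rate on null screens and the recovery
rate for compounds with real effects.  They are the package's own
calibration checks, reusable from both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .hits import ScreenModel, Thresholds
from .simulate import CompoundEffect, SimulationConfig, simulate_week

__all__ = ["null_primary_call_rate", "effect_recovery_rate", "control_fish_sd"]

#: Reduced per-fish rod counts for large replicate studies; the variance
#: structure (week/fish/rod SDs) stays at the screen defaults.
REDUCED_DG_RANGE = (12, 20)
REDUCED_DS_RANGE = (9, 15)


def _week_results(config, week_index, effects, qmc_points, seed):
    wk = simulate_week(config, week_index, effects)
    model = ScreenModel(wk.measurements, thresholds=Thresholds())
    return model.fit(qmc_points=qmc_points, seed=seed)


def null_primary_call_rate(
    n_weeks: int = 500,
    compounds_per_week: int = 8,
    seed: int = 0,
    qmc_points: int = 20_000,
) -> tuple[float, int]:
    """Fraction of null compound-metric comparisons called primary.

    Simulates independent all-null weeks (every multiplier 1) at reduced
    rod counts and runs the full pipeline on each.  Under the joint
    requirement (|change| >= 20 % and family-wise p < 0.001) the rate
    should be essentially zero.

    Returns (rate, number of compound-metric comparisons).
    """
    config = SimulationConfig(
        n_weeks=1,
        rods_per_fish_dg=REDUCED_DG_RANGE,
        rods_per_fish_ds=REDUCED_DS_RANGE,
        lethality_prob=0.0,
        seed=seed,
    )
    effects = [
        CompoundEffect(compound_id=f"N{i + 1}") for i in range(compounds_per_week)
    ]
    n_primary = 0
    n_total = 0
    for w in range(n_weeks):
        res = _week_results(config, w, effects, qmc_points, seed)
        for rec in res.hit_records:
            for call in (rec.dg_call, rec.ds_call):
                n_total += 1
                if call.startswith("primary"):
                    n_primary += 1
    return n_primary / n_total, n_total


def effect_recovery_rate(
    n_weeks: int = 200,
    multipliers: tuple[float, float] = (1.35, 0.65),
    seed: int = 1,
    qmc_points: int = 20_000,
) -> tuple[float, int]:
    """Fraction of true-effect compounds recovered as primary growth hits.

    Each simulated week carries one compound per growth-rate multiplier in
    ``multipliers`` (defaults ±35 %, i.e. ±35 % true D^G change) among
    otherwise null compounds, at the screen's default rod counts, variance
    structure and weekly batch size (8–32 compounds sharing the control;
    the batch size matters because the number of fish in the week drives
    the degrees of freedom available to the family-wise test).

    Returns (rate, number of effect-compound opportunities).
    """
    config = SimulationConfig(n_weeks=1, lethality_prob=0.0, seed=seed)
    effect_ids = {f"E{j + 1}": m for j, m in enumerate(multipliers)}
    lo, hi = config.compounds_per_week
    batch_rng = np.random.default_rng([seed, 2**20])
    n_hit = 0
    n_total = 0
    for w in range(n_weeks):
        n_compounds = int(batch_rng.integers(lo, hi + 1))
        effects = [
            CompoundEffect(compound_id=cid, growth_multiplier=m)
            for cid, m in effect_ids.items()
        ] + [
            CompoundEffect(compound_id=f"N{i + 1}")
            for i in range(n_compounds - len(multipliers))
        ]
        res = _week_results(config, w, effects, qmc_points, seed)
        for rec in res.hit_records:
            if rec.compound_id in effect_ids:
                n_total += 1
                if rec.dg_call.startswith("primary"):
                    n_hit += 1
    return n_hit / n_total, n_total


def control_fish_sd(
    n_weeks: int = 300, seed: int = 2, config: SimulationConfig | None = None
) -> float:
    """Empirical SD of control fish-level mean D^G pooled across weeks.

    At the default variance split this should sit near
    sqrt(week_sd^2 + fish_sd^2) — the quantity the study-wide control
    benchmark dispersion calibrates against.
    """
    if config is None:
        config = SimulationConfig(n_weeks=1, lethality_prob=0.0, seed=seed)
    means = []
    for w in range(n_weeks):
        wk = simulate_week(config, w, [CompoundEffect(compound_id="X")])
        ctl = wk.measurements[wk.measurements["treatment_role"] == "control"]
        means.extend(ctl.groupby("fish_id")["d_growth_um"].mean().tolist())
    return float(np.std(means, ddof=1))
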