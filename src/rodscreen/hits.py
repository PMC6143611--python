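"""Hit calling: dual biological/statistical thresholds and qualitative rules.

A compound is a *primary* hit for a distance metric when its model-estimated
percent change versus the week-matched control is at least the biological
threshold (default 20 %) in magnitude *and* its Dunnett-adjusted p-value is
below the primary level (0.001).  Compounds missing one of the two
thresholds keep a tiered label (p < 0.01, p < 0.05), and a near-miss whose
direction matches an existing primary hit for the same molecular target is
promoted to a same-target follow-up.  Qualitative content areas (phagosome
accumulation, Rhodopsin mislocalization, marginal-zone disruption) use an
at-least-one-image rule.

Threshold comparisons are strict (<) for p-values and non-strict (>=) for
the percent change.  Calling uses full-precision model estimates; the
integer percent is reporting-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dunnett import ComparisonResult, compare_to_control, significance_tier
from .dunnett import DEFAULT_QMC_POINTS, DEFAULT_QMC_SEED
from .kinetics import Benchmark, DEFAULT_TIMELINE, StudyTimeline, pool_controls
from .mixedlm import RandomInterceptModel, RandomInterceptResults

__all__ = [
    "Thresholds",
    "HitRecord",
    "ScreenModel",
    "ScreenResults",
    "call_distance_hit",
    "qualitative_hit",
    "tally_by_pathway",
    "build_report",
    "CONTENT_AREAS",
]

METRICS = {"dg": "d_growth_um", "ds": "d_shed_um"}
CONTENT_AREAS = (
    "dg-increase",
    "dg-decrease",
    "ds-increase",
    "ds-decrease",
    "phagosome",
    "mislocalization",
    "cmz",
)

REPORT_COLUMNS = [
    "compound_id", "name", "target", "pathway", "metric",
    "control_mean_um", "treated_mean_um", "percent_change", "se_um", "df",
    "p_raw", "p_adj", "tier", "call",
    "phagosome_hit", "misloc_hit", "cmz_hit", "lethal",
]


@dataclass(frozen=True)
class Thresholds:
    """Hit thresholds: biological percent change plus the significance ladder."""

    pct_threshold: float = 20.0
    p_primary: float = 0.001
    p_secondary: float = 0.01
    p_tertiary: float = 0.05

    def __post_init__(self) -> None:
        if not (self.p_primary < self.p_secondary < self.p_tertiary):
            raise ValueError("need p_primary < p_secondary < p_tertiary")
        if self.pct_threshold <= 0:
            raise ValueError("pct_threshold must be > 0")


@dataclass
class HitRecord:
    """Per-compound classification across the five content areas."""

    compound_id: str
    target: str = "unknown"
    pathway: str = "unannotated"
    name: str = ""
    dg_result: ComparisonResult | None = None
    ds_result: ComparisonResult | None = None
    dg_call: str = "none"
    ds_call: str = "none"
    phagosome_hit: bool = False
    misloc_hit: bool = False
    cmz_hit: bool = False
    lethal: bool = False


def _direction(result: ComparisonResult) -> str:
    return "increase" if result.percent_change >= 0 else "decrease"


def call_distance_hit(
    result: ComparisonResult,
    thresholds: Thresholds = Thresholds(),
    same_target_primary_exists: bool = False,
) -> str:
    """Classify one compound-vs-control comparison.

    ``same_target_primary_exists`` says whether another compound sharing
    this compound's target already reached a primary call *in the same
    direction* for this metric; such near-misses are promoted to
    ``same-target-followup`` provided they clear at least the weakest
    significance tier.
    """
    d = _direction(result)
    if (
        abs(result.percent_change) >= thresholds.pct_threshold
        and result.p_adj < thresholds.p_primary
    ):
        return f"primary-{d}"
    if same_target_primary_exists and result.p_adj < thresholds.p_tertiary:
        return "same-target-followup"
    if result.p_adj < thresholds.p_tertiary:
        return f"tiered-{d}"
    return "none"


def qualitative_hit(image_flags: Sequence[bool]) -> bool:
    """At-least-one-image rule (1–3 images; the CMZ area has exactly one)."""
    if len(image_flags) == 0:
        raise ValueError("need at least one image flag")
    return any(bool(f) for f in image_flags)


def _call_matches(call: str, result: ComparisonResult | None, area_dir: str) -> bool:
    if call == "none" or result is None:
        return False
    if call == "same-target-followup":
        return _direction(result) == area_dir
    return call.endswith(area_dir)


def tally_by_pathway(hits: Iterable[HitRecord], content_area: str) -> dict[str, int]:
    """Count hit compounds per annotated pathway for one content area.

    Ordering is deterministic: count descending, then pathway label.
    Compounds without an annotation count under ``unannotated``; lethal
    compounds never appear.
    """
    if content_area not in CONTENT_AREAS:
        raise ValueError(f"unknown content area {content_area!r}")
    counts: dict[str, int] = {}
    for h in hits:
        if h.lethal:
            continue
        if content_area == "phagosome":
            match = h.phagosome_hit
        elif content_area == "mislocalization":
            match = h.misloc_hit
        elif content_area == "cmz":
            match = h.cmz_hit
        else:
            metric, area_dir = content_area.split("-")
            call = h.dg_call if metric == "dg" else h.ds_call
            result = h.dg_result if metric == "dg" else h.ds_result
            match = _call_matches(call, result, area_dir)
        if match:
            key = h.pathway or "unannotated"
            counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


class ScreenModel:
    """The whole screen as a fittable object.

    Parameters
    ----------
    measurements : DataFrame
        Rod-level table (see :mod:`rodscreen.io` for the schema).
    annotations : DataFrame, optional
        compound_id → name/target/pathway; compounds present here but
        absent from the measurements are treated as lethal.
    qualitative : DataFrame, optional
        Per-image boolean flags per compound.
    """

    def __init__(
        self,
        measurements: pd.DataFrame,
        annotations: pd.DataFrame | None = None,
        qualitative: pd.DataFrame | None = None,
        thresholds: Thresholds = Thresholds(),
        timeline: StudyTimeline = DEFAULT_TIMELINE,
    ) -> None:
        self.measurements = measurements
        self.annotations = annotations
        self.qualitative = qualitative
        self.thresholds = thresholds
        self.timeline = timeline
        self._validate_controls()

    def _validate_controls(self) -> None:
        weeks = self.measurements["week_id"].unique()
        missing = []
        for wk in weeks:
            sub = self.measurements[self.measurements["week_id"] == wk]
            ctl = sub.loc[sub["treatment_role"] == "control", "compound_id"].unique()
            if len(ctl) != 1:
                missing.append(str(wk))
        if missing:
            raise ValueError(
                f"weeks without exactly one control group: {missing}"
            )

    def fit(
        self,
        qmc_points: int = DEFAULT_QMC_POINTS,
        seed: int = DEFAULT_QMC_SEED,
    ) -> "ScreenResults":
        """Run the full per-week pipeline and assemble one record per compound.

        Per week and metric: REML random-intercept fit → control contrasts →
        Dunnett adjustment → threshold calls; then qualitative rules, the
        pooled control benchmark, and same-target follow-up promotion
        across the whole screen.
        """
        meas = self.measurements
        ann = {}
        if self.annotations is not None:
            for _, row in self.annotations.iterrows():
                ann[str(row["compound_id"])] = row

        records: dict[str, HitRecord] = {}

        def record_for(cid: str) -> HitRecord:
            if cid not in records:
                a = ann.get(cid)
                records[cid] = HitRecord(
                    compound_id=cid,
                    name=str(a["name"]) if a is not None else cid,
                    target=str(a["target"]) if a is not None else "unknown",
                    pathway=str(a["pathway"]) if a is not None else "unannotated",
                )
            return records[cid]

        week_fits: dict[tuple[str, str], RandomInterceptResults] = {}
        comparisons: list[ComparisonResult] = []
        for wk, wk_df in meas.groupby("week_id", sort=True):
            control = wk_df.loc[
                wk_df["treatment_role"] == "control", "compound_id"
            ].iloc[0]
            for short, col in METRICS.items():
                sub = wk_df[wk_df[col].notna()]
                levels = sub["compound_id"].unique()
                if control not in levels or len(levels) < 2:
                    continue
                fit = RandomInterceptModel.from_dataframe(
                    sub, metric=col, control=str(control), week_id=str(wk)
                ).fit()
                week_fits[(str(wk), short)] = fit
                comps = compare_to_control(fit, n_points=qmc_points, seed=seed)
                comparisons.extend(comps)
                for cr in comps:
                    rec = record_for(cr.compound_id)
                    if short == "dg":
                        rec.dg_result = cr
                    else:
                        rec.ds_result = cr

        # provisional calls, then same-target follow-up promotion screen-wide
        for rec in records.values():
            if rec.dg_result is not None:
                rec.dg_call = call_distance_hit(rec.dg_result, self.thresholds)
            if rec.ds_result is not None:
                rec.ds_call = call_distance_hit(rec.ds_result, self.thresholds)
        primaries: dict[tuple[str, str], set[str]] = {}
        for rec in records.values():
            for short, call, res in (
                ("dg", rec.dg_call, rec.dg_result),
                ("ds", rec.ds_call, rec.ds_result),
            ):
                if call.startswith("primary") and res is not None:
                    primaries.setdefault(
                        (short, _direction(res)), set()
                    ).add(rec.target)
        for rec in records.values():
            for short in ("dg", "ds"):
                res = rec.dg_result if short == "dg" else rec.ds_result
                call = rec.dg_call if short == "dg" else rec.ds_call
                if res is None or call.startswith("primary"):
                    continue
                exists = rec.target in primaries.get((short, _direction(res)), set())
                new_call = call_distance_hit(res, self.thresholds, exists)
                if short == "dg":
                    rec.dg_call = new_call
                else:
                    rec.ds_call = new_call

        # qualitative content areas
        if self.qualitative is not None:
            compound_rows = meas.loc[
                meas["treatment_role"] == "compound", "compound_id"
            ].unique()
            measured = set(map(str, compound_rows))
            for _, row in self.qualitative.iterrows():
                cid = str(row["compound_id"])
                if cid not in measured and cid not in records:
                    continue  # control groups are not hit candidates
                rec = record_for(cid)
                rec.phagosome_hit = qualitative_hit(
                    [row["phagosome_1"], row["phagosome_2"], row["phagosome_3"]]
                )
                rec.misloc_hit = qualitative_hit(
                    [row["misloc_1"], row["misloc_2"], row["misloc_3"]]
                )
                rec.cmz_hit = qualitative_hit([row["cmz"]])

        # annotated compounds with no surviving fish are lethal
        for cid in ann:
            if cid not in records:
                rec = record_for(cid)
                rec.lethal = True

        benchmarks: dict[str, Benchmark] = {}
        controls = meas[meas["treatment_role"] == "control"]
        for short, col in METRICS.items():
            if controls[col].notna().any():
                benchmarks[short] = pool_controls(
                    controls[controls[col].notna()], col
                )

        order = sorted(records)
        return ScreenResults(
            model=self,
            hit_records=[records[c] for c in order],
            comparisons=comparisons,
            week_fits=week_fits,
            benchmarks=benchmarks,
        )


@dataclass
class ScreenResults:
    """Everything the pipeline produced for one screen."""

    model: ScreenModel
    hit_records: list[HitRecord]
    comparisons: list[ComparisonResult]
    week_fits: dict[tuple[str, str], RandomInterceptResults]
    benchmarks: dict[str, Benchmark]

    def tally(self, content_area: str) -> dict[str, int]:
        return tally_by_pathway(self.hit_records, content_area)

    def to_frame(self) -> pd.DataFrame:
        """The flat hit-report table (one row per compound and metric)."""
        rows = []
        for rec in self.hit_records:
            base = {
                "compound_id": rec.compound_id,
                "name": rec.name,
                "target": rec.target,
                "pathway": rec.pathway,
                "phagosome_hit": rec.phagosome_hit,
                "misloc_hit": rec.misloc_hit,
                "cmz_hit": rec.cmz_hit,
                "lethal": rec.lethal,
            }
            if rec.lethal:
                rows.append(
                    {**base, "metric": "", "control_mean_um": np.nan,
                     "treated_mean_um": np.nan, "percent_change": np.nan,
                     "se_um": np.nan, "df": np.nan, "p_raw": np.nan,
                     "p_adj": np.nan, "tier": "", "call": ""}
                )
                continue
            for short, res, call in (
                ("dg", rec.dg_result, rec.dg_call),
                ("ds", rec.ds_result, rec.ds_call),
            ):
                if res is None:
                    continue
                rows.append(
                    {
                        **base,
                        "metric": short,
                        "control_mean_um": res.control_mean,
                        "treated_mean_um": res.treated_mean,
                        "percent_change": res.percent_change_int,
                        "se_um": res.se,
                        "df": res.df,
                        "p_raw": res.p_raw,
                        "p_adj": res.p_adj,
                        "tier": significance_tier(res.p_adj),
                        "call": call,
                    }
                )
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)

    def summary(self) -> str:
        """Human-readable screen summary with pathway tallies."""
        n_compounds = sum(1 for r in self.hit_records)
        n_lethal = sum(1 for r in self.hit_records if r.lethal)
        lines = [
            "Screen report",
            f"  compounds: {n_compounds} ({n_lethal} lethal)",
        ]
        for short, label in (("dg", "growth distance D^G"),
                             ("ds", "shedding distance D^S")):
            b = self.benchmarks.get(short)
            if b:
                lines.append(
                    f"  {label} benchmark: {b.mean:.2f} um "
                    f"(fish SD {b.sd:.3f}; {b.n_rods} rods, {b.n_fish} fish)"
                )
        lines.append(
            "  note: increased D^S = suppressed shedding; "
            "decreased D^S = promoted shedding"
        )
        for area in CONTENT_AREAS:
            t = self.tally(area)
            total = sum(t.values())
            lines.append(f"  [{area}] {total} compounds")
            for path, cnt in t.items():
                lines.append(f"      {path}: {cnt}")
        return "\n".join(lines)


def build_report(
    measurements: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    qualitative: pd.DataFrame | None = None,
    thresholds: Thresholds = Thresholds(),
    timeline: StudyTimeline = DEFAULT_TIMELINE,
    qmc_points: int = DEFAULT_QMC_POINTS,
    seed: int = DEFAULT_QMC_SEED,
) -> ScreenResults:
    """Functional wrapper: build a :class:`ScreenModel` and fit it."""
    return ScreenModel(
        measurements,
        annotations=annotations,
        qualitative=qualitative,
        thresholds=thresholds,
        timeline=timeline,
    ).fit(qmc_points=qmc_points, seed=seed)
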