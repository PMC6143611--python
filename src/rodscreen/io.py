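"""Flat-file formats and configuration for screen tables.

Every table is plain comma-separated text.  The measurement table is the
central exchange format::

    week_id,compound_id,treatment_role,fish_id,rod_id,d_growth_um,d_shed_um

Distances are µm with up to 4 decimals; an empty cell is a missing value.
``treatment_role`` is ``control`` or ``compound``; exactly one control
group is expected per week (the week-matched vehicle control).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .hits import Thresholds
from .kinetics import StudyTimeline
from .simulate import SimulationConfig

logger = logging.getLogger("rodscreen")

MEASUREMENT_COLUMNS = [
    "week_id",
    "compound_id",
    "treatment_role",
    "fish_id",
    "rod_id",
    "d_growth_um",
    "d_shed_um",
]
ANNOTATION_COLUMNS = ["compound_id", "name", "target", "pathway"]
QUALITATIVE_COLUMNS = [
    "week_id",
    "compound_id",
    "phagosome_1",
    "phagosome_2",
    "phagosome_3",
    "misloc_1",
    "misloc_2",
    "misloc_3",
    "cmz",
]
TRUTH_COLUMNS = [
    "week_id",
    "compound_id",
    "growth_multiplier",
    "shed_multiplier",
    "lethal",
]

ROLES = {"control", "compound"}


class ValidationError(ValueError):
    """A table failed schema validation; the message names the offending line."""


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement table.

    Returns typed rows: identifiers as strings, distances as floats with
    NaN for empty cells.  Raises :class:`ValidationError` naming the 1-based
    file line for a negative distance, an unknown treatment role, or a row
    missing both distances.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df[MEASUREMENT_COLUMNS].copy()
    for col in ("d_growth_um", "d_shed_um"):
        raw = df[col].str.strip().replace("", None)
        try:
            df[col] = pd.to_numeric(raw, errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw, errors="coerce")
            line = int((bad.isna() & raw.notna()).idxmax()) + 2  # header is line 1
            raise ValidationError(
                f"{path}:{line}: non-numeric value in {col}"
            ) from None
        neg = df.index[df[col] < 0]
        if len(neg):
            raise ValidationError(
                f"{path}:{int(neg[0]) + 2}: negative distance in {col}"
            )
    bad_role = df.index[~df["treatment_role"].isin(ROLES)]
    if len(bad_role):
        i = int(bad_role[0])
        raise ValidationError(
            f"{path}:{i + 2}: unknown treatment_role "
            f"{df.at[i, 'treatment_role']!r} (expected control|compound)"
        )
    both_missing = df.index[df["d_growth_um"].isna() & df["d_shed_um"].isna()]
    if len(both_missing):
        raise ValidationError(
            f"{path}:{int(both_missing[0]) + 2}: both distances missing"
        )
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.4f")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df[ANNOTATION_COLUMNS]


def read_qualitative(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in QUALITATIVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df[QUALITATIVE_COLUMNS].copy()
    flag_cols = QUALITATIVE_COLUMNS[2:]
    for col in flag_cols:
        vals = df[col].str.strip().str.lower()
        bad = df.index[~vals.isin({"true", "false", ""})]
        if len(bad):
            raise ValidationError(
                f"{path}:{int(bad[0]) + 2}: flag {col} must be True/False"
            )
        df[col] = vals == "true"
    return df


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df[TRUTH_COLUMNS].copy()
    for col in ("growth_multiplier", "shed_multiplier"):
        df[col] = pd.to_numeric(df[col])
    df["lethal"] = df["lethal"].str.strip().str.lower() == "true"
    return df


@dataclass
class ScreenConfig:
    """Full run configuration: timeline, thresholds, simulation, output."""

    timeline: StudyTimeline = field(default_factory=StudyTimeline)
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    output_dir: str = "screen_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, source=str(path))

    @classmethod
    def from_dict(cls, raw: dict[str, Any], source: str = "<config>") -> "ScreenConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(
                f"{source}: unknown config keys {sorted(unknown)}; expected {sorted(known)}"
            )
        kwargs: dict[str, Any] = {}
        for name, typ in (
            ("timeline", StudyTimeline),
            ("thresholds", Thresholds),
            ("simulation", SimulationConfig),
        ):
            if name in raw:
                block = raw[name] or {}
                block_known = {f.name for f in fields(typ)}
                bad = set(block) - block_known
                if bad:
                    raise ValidationError(
                        f"{source}: unknown keys {sorted(bad)} in block {name!r}"
                    )
                # ranges arrive as 2-element lists from YAML
                for k, v in list(block.items()):
                    if isinstance(v, list):
                        block[k] = tuple(v)
                kwargs[name] = typ(**block)
        if "output_dir" in raw:
            kwargs["output_dir"] = str(raw["output_dir"])
        if "log_level" in raw:
            kwargs["log_level"] = str(raw["log_level"])
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the configuration (key order independent)."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
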