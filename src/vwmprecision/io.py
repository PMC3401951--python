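"""Canonical on-disk formats and run configuration.

Trial and participant tables are delimited text (CSV): small data, diffable,
lossless round trips. Angles are radians-only on disk, validated to
``[0, pi)``; list-valued fields (the three stimulus orientations/colours of
a sequence) are semicolon-joined. Configuration is YAML with strict
unknown-key rejection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mixture import FitConfig, TrialGeometry
from .simulate import CohortConfig, ParticipantProfile, TrialRecord

__all__ = [
    "TRIAL_COLUMNS",
    "TrialTableError",
    "ConfigSchemaError",
    "RunConfig",
    "AnalysisConfig",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "frame_to_trials",
    "read_participants",
    "write_participants",
    "participants_to_frame",
    "build_geometries",
    "config_hash",
]

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "trial_index",
    "stimulus_orientations",
    "stimulus_colours",
    "probed_index",
    "response_orientation",
]

_CONDITION_N_STIMULI = {"sensorimotor": 1, "vwm1": 1, "vwm3": 3}
_PI = float(np.pi)


class TrialTableError(ValueError):
    """Raised for malformed trial tables; message lists offending lines."""


class ConfigSchemaError(ValueError):
    """Raised when a configuration mapping contains unknown or invalid keys."""


# ---------------------------------------------------------------------------
# trial tables

def _fmt_floats(values) -> str:
    return ";".join(repr(float(v)) for v in values)


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Trial records as the canonical tabular (string-joined) representation."""
    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in records],
            "condition": [t.condition for t in records],
            "trial_index": [t.trial_index for t in records],
            "stimulus_orientations": [
                _fmt_floats(t.stimulus_orientations) for t in records
            ],
            "stimulus_colours": [";".join(t.stimulus_colours) for t in records],
            "probed_index": [t.probed_index for t in records],
            "response_orientation": [repr(float(t.response_orientation)) for t in records],
        },
        columns=TRIAL_COLUMNS,
    )


def _parse_trial_row(row, line_no: int) -> TrialRecord:
    condition = str(row["condition"])
    if condition not in _CONDITION_N_STIMULI:
        raise ValueError(f"unknown condition {condition!r}")
    orientations = tuple(float(x) for x in str(row["stimulus_orientations"]).split(";"))
    colours = tuple(str(row["stimulus_colours"]).split(";"))
    n_expected = _CONDITION_N_STIMULI[condition]
    if len(orientations) != n_expected or len(colours) != n_expected:
        raise ValueError(
            f"condition {condition!r} requires {n_expected} stimuli, "
            f"got {len(orientations)} orientations / {len(colours)} colours"
        )
    response = float(row["response_orientation"])
    for name, vals in (("stimulus", orientations), ("response", (response,))):
        for v in vals:
            if not np.isfinite(v) or not (0.0 <= v < _PI):
                raise ValueError(f"{name} orientation {v} outside [0, pi)")
    probed = int(row["probed_index"])
    if not (0 <= probed < n_expected):
        raise ValueError(f"probed_index {probed} invalid for condition {condition!r}")
    return TrialRecord(
        participant_id=str(row["participant_id"]),
        condition=condition,
        trial_index=int(row["trial_index"]),
        stimulus_orientations=orientations,
        stimulus_colours=colours,
        probed_index=probed,
        response_orientation=response,
    )


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Parse and validate a canonical trial table. Lossless inverse of
    :func:`trials_to_frame`; errors report 1-based file line numbers
    (header is line 1)."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"missing columns: {missing}")
    records = []
    problems = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line_no = pos + 2
        try:
            records.append(_parse_trial_row(row, line_no))
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise TrialTableError(
            "malformed trial rows:\n" + "\n".join(problems[:50])
        )
    return records


def write_trials(records: list[TrialRecord], path) -> None:
    trials_to_frame(records).to_csv(path, index=False)


def read_trials(path) -> list[TrialRecord]:
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        warnings.warn(f"trial table {path} contains no rows")
        if list(df.columns) != TRIAL_COLUMNS and not set(TRIAL_COLUMNS) <= set(df.columns):
            raise TrialTableError(f"missing columns: {TRIAL_COLUMNS}")
        return []
    return frame_to_trials(df)


# ---------------------------------------------------------------------------
# participant tables

def participants_to_frame(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "id": p.id,
            "age": p.age,
            "year_group": p.year_group,
            "fsiq_e": p.fsiq_e,
            "trial_seed": p.trial_seed,
        }
        row.update({f"gen_{f.name}": getattr(p.gen, f.name) for f in fields(p.gen)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_participants(profiles: list[ParticipantProfile], path) -> None:
    participants_to_frame(profiles).to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    """Read a participant table; requires id/age/year_group/fsiq_e columns."""
    df = pd.read_csv(path)
    required = {"id", "age", "year_group", "fsiq_e"}
    missing = required - set(df.columns)
    if missing:
        raise TrialTableError(f"participant table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# geometry construction for the mixture model

def build_geometries(records: list[TrialRecord]) -> list[TrialGeometry]:
    """Doubled-angle trial geometries (target, non-targets, response) for
    the mixture model."""
    geoms = []
    for t in records:
        target = 2.0 * t.stimulus_orientations[t.probed_index]
        nontargets = tuple(
            2.0 * o for i, o in enumerate(t.stimulus_orientations) if i != t.probed_index
        )
        geoms.append(
            TrialGeometry(
                target=target,
                nontargets=nontargets,
                response=2.0 * t.response_orientation,
            )
        )
    return geoms


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class AnalysisConfig:
    """Statistical-analysis settings for the cohort pipeline."""

    outlier_z: float = 2.5
    chance_replicates: int = 10_000
    chance_seed: int = 2025
    corr_method: str = "pearson"  # or "spearman"
    grouping: str = "year"  # or "quintile"
    collapse_years: bool = True  # merge year 3 into year 4 (small N)
    multiple_testing: str | None = None  # None or "holm"
    min_trials_per_cell: int = 5
    sd_floor: float = 1e-6

    def validate(self) -> None:
        if self.corr_method not in ("pearson", "spearman"):
            raise ConfigSchemaError(f"corr_method invalid: {self.corr_method!r}")
        if self.grouping not in ("year", "quintile"):
            raise ConfigSchemaError(f"grouping invalid: {self.grouping!r}")
        if self.multiple_testing not in (None, "holm"):
            raise ConfigSchemaError(
                f"multiple_testing invalid: {self.multiple_testing!r}"
            )
        if self.outlier_z <= 0 or self.chance_replicates < 1000:
            raise ConfigSchemaError("outlier_z must be > 0 and chance_replicates >= 1000")


def _from_mapping(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigSchemaError(f"{context}: expected a mapping, got {type(data).__name__}")
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigSchemaError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigSchemaError(f"{context}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration: cohort, fitter, analysis, seed, logging."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigSchemaError("config must be a mapping")
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ConfigSchemaError(f"config: unknown keys {sorted(unknown)}")
        kwargs = {}
        if "cohort" in data:
            kwargs["cohort"] = _from_mapping(CohortConfig, data["cohort"], "cohort")
        if "fit" in data:
            kwargs["fit"] = _from_mapping(FitConfig, data["fit"], "fit")
        if "analysis" in data:
            kwargs["analysis"] = _from_mapping(AnalysisConfig, data["analysis"], "analysis")
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "log_level" in data:
            kwargs["log_level"] = str(data["log_level"])
        cfg = cls(**kwargs)
        cfg.analysis.validate()
        cfg.cohort.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of a configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
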