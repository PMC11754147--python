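"""Domain types and file I/O for event-level eye-tracking exports.

The unit of analysis is a :class:`Recording`: the ordered fixation and saccade
events of one participant reading one text stimulus, together with the class
label and the recording's tracking ratio (fraction of valid gaze samples, used
as a quality filter).  Event files are delimited text with one row per event;
vendor exports with different column headers are mapped onto the canonical
schema through a :class:`Dialect`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

LABELS = ("control", "dyslexic", "unknown")

#: Canonical column order of the event-file schema.
CANONICAL_COLUMNS = (
    "participant_id",
    "task_id",
    "event_type",
    "start_ms",
    "end_ms",
    "duration_ms",
    "pos_x",
    "pos_y",
    "disp_x",
    "disp_y",
    "label",
    "tracking_ratio",
)

_MANDATORY = ("participant_id", "start_ms", "end_ms", "duration_ms")
_NUMERIC = ("start_ms", "end_ms", "duration_ms", "pos_x", "pos_y",
            "disp_x", "disp_y", "tracking_ratio")

# rows are written with 3 decimals, so duration == end - start only up to
# the rounding quantum
_DURATION_TOL_MS = 2e-3


class EventFileFormatError(ValueError):
    """A mandatory column is missing or the file structure is invalid."""


class EventFileParseError(ValueError):
    """A cell could not be parsed; the message carries the offending line."""


@dataclass
class FixationEvent:
    """One fixation: gaze held (near-)still while visual uptake happens.

    Positions are screen pixels, origin top-left, x rightward, y downward.
    Dispersion is the per-axis spatial extent max - min of the gaze samples
    inside the fixation; it is ``None`` when the source export lacks it.
    """

    start_ms: float
    end_ms: float
    duration_ms: float
    pos_x: float
    pos_y: float
    disp_x: float | None = None
    disp_y: float | None = None

    def __post_init__(self) -> None:
        if not (self.end_ms > self.start_ms):
            raise ValueError(
                f"fixation end ({self.end_ms}) must be after start ({self.start_ms})"
            )
        if abs(self.duration_ms - (self.end_ms - self.start_ms)) > _DURATION_TOL_MS:
            raise ValueError(
                f"fixation duration {self.duration_ms} inconsistent with "
                f"[{self.start_ms}, {self.end_ms}]"
            )
        for name in ("pos_x", "pos_y"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("disp_x", "disp_y"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class SaccadeEvent:
    """One saccade: rapid ballistic movement between two fixations."""

    start_ms: float
    end_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if not (self.end_ms > self.start_ms):
            raise ValueError("saccade end must be after start")
        if abs(self.duration_ms - (self.end_ms - self.start_ms)) > _DURATION_TOL_MS:
            raise ValueError("saccade duration inconsistent with start/end")


@dataclass
class Recording:
    """All events of one participant on one reading task."""

    participant_id: str
    task_id: str
    label: str = "unknown"
    tracking_ratio: float | None = None
    fixations: list[FixationEvent] = field(default_factory=list)
    saccades: list[SaccadeEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.tracking_ratio is not None and not 0 <= self.tracking_ratio <= 100:
            raise ValueError("tracking_ratio must lie in [0, 100]")


@dataclass(frozen=True)
class GazeFeatures:
    """The five per-recording summary features used by the 1NN baseline."""

    fixation_count: int
    saccade_count: int
    total_saccade_time_ms: float
    total_fixation_time_ms: float
    mean_fixation_time_ms: float

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class StimulusSpec:
    """Layout summary of one multi-line text stimulus.

    ``line_geometry`` holds one (x0, y0, x1, y1) screen-pixel box per text
    line; it is required by the scanpath simulator but optional otherwise.
    """

    name: str
    n_lines: int
    n_sentences: int
    n_words: int
    line_geometry: list[tuple[float, float, float, float]] | None = None

    def __post_init__(self) -> None:
        for attr in ("n_lines", "n_sentences", "n_words"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.line_geometry is not None:
            self.line_geometry = [tuple(float(c) for c in box) for box in self.line_geometry]
            if len(self.line_geometry) != self.n_lines:
                raise ValueError("line_geometry length must equal n_lines")


@dataclass(frozen=True)
class Dialect:
    """Mapping from a vendor export's headers onto the canonical schema.

    ``column_map`` maps canonical names (keys of :data:`CANONICAL_COLUMNS`)
    to the source file's header names; unmapped canonical names are looked
    up verbatim.  Files without an event-type column are treated as
    fixations-only.
    """

    delimiter: str = ","
    column_map: Mapping[str, str] = field(default_factory=dict)
    fixation_value: str = "fixation"
    saccade_value: str = "saccade"

    def source_name(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


CANONICAL_DIALECT = Dialect()

#: Tab-separated dialect matching SMI BeGaze-style event exports.
BEGAZE_DIALECT = Dialect(
    delimiter="\t",
    column_map={
        "participant_id": "Participant ID",
        "event_type": "Event Type",
        "start_ms": "Event Start Trial Time [ms]",
        "end_ms": "Event End Trial Time [ms]",
        "duration_ms": "Event Duration [ms]",
        "pos_x": "Fixation Position X [px]",
        "pos_y": "Fixation Position Y [px]",
        "disp_x": "Fixation Dispersion X [px]",
        "disp_y": "Fixation Dispersion Y [px]",
    },
    fixation_value="Fixation",
    saccade_value="Saccade",
)


def _coerce_numeric(df: pd.DataFrame, source: str, path: str) -> pd.Series:
    raw = df[source]
    stripped = raw.astype("string").str.strip()
    present = stripped.notna() & (stripped != "")
    coerced = pd.to_numeric(stripped.where(present), errors="coerce")
    bad = present & coerced.isna()
    if bad.any():
        idx = int(bad.idxmax())
        raise EventFileParseError(
            f"{path}: non-numeric value {raw.iloc[idx]!r} in column "
            f"{source!r} at line {idx + 2}"
        )
    return coerced


def read_event_file(
    path: str | Path,
    dialect: Dialect = CANONICAL_DIALECT,
    manifest: str | Path | None = None,
) -> list[Recording]:
    """Parse a delimited event export into one Recording per (participant, task).

    Events are re-ordered by start time regardless of row order, routed to
    fixation/saccade lists by the event-type column (all rows are fixations
    when the column is absent), and checked for temporal overlap among
    fixations.  Missing dispersion columns yield ``disp_x``/``disp_y`` of
    ``None``, never zero.  ``manifest`` optionally points to a JSON sidecar
    supplying label/tracking-ratio per (participant_id, task_id).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, skipinitialspace=True)
    for canonical in _MANDATORY:
        if dialect.source_name(canonical) not in df.columns:
            raise EventFileFormatError(
                f"{path}: missing required column {dialect.source_name(canonical)!r}"
            )

    cols: dict[str, pd.Series] = {}
    for canonical in CANONICAL_COLUMNS:
        source = dialect.source_name(canonical)
        if source not in df.columns:
            continue
        if canonical in _NUMERIC:
            cols[canonical] = _coerce_numeric(df, source, str(path))
        else:
            cols[canonical] = df[source].astype("string").str.strip()

    meta = _load_manifest(manifest) if manifest is not None else {}

    frame = pd.DataFrame(cols)
    frame["lineno"] = frame.index + 2  # header is line 1
    if "task_id" not in frame:
        frame["task_id"] = "task"
    frame["task_id"] = frame["task_id"].fillna("task")

    recordings: list[Recording] = []
    for (pid, task), group in frame.groupby(["participant_id", "task_id"], sort=False):
        group = group.sort_values("start_ms", kind="stable")
        fixations: list[FixationEvent] = []
        saccades: list[SaccadeEvent] = []
        fix_lines: list[int] = []
        for row in group.itertuples(index=False):
            kind = getattr(row, "event_type", dialect.fixation_value)
            if pd.isna(kind):
                kind = dialect.fixation_value
            if str(kind).lower() == dialect.saccade_value.lower():
                saccades.append(
                    SaccadeEvent(row.start_ms, row.end_ms, row.duration_ms)
                )
            else:
                disp_x = getattr(row, "disp_x", None)
                disp_y = getattr(row, "disp_y", None)
                fixations.append(
                    FixationEvent(
                        start_ms=row.start_ms,
                        end_ms=row.end_ms,
                        duration_ms=row.duration_ms,
                        pos_x=row.pos_x,
                        pos_y=row.pos_y,
                        disp_x=None if disp_x is None or pd.isna(disp_x) else float(disp_x),
                        disp_y=None if disp_y is None or pd.isna(disp_y) else float(disp_y),
                    )
                )
                fix_lines.append(int(row.lineno))
        _check_no_overlap(fixations, fix_lines, str(path))

        label = _first_value(group, "label") or "unknown"
        ratio = _first_value(group, "tracking_ratio")
        key = (str(pid), str(task))
        if key in meta:
            label = meta[key].get("label", label) or label
            ratio = meta[key].get("tracking_ratio", ratio)
        recordings.append(
            Recording(
                participant_id=str(pid),
                task_id=str(task),
                label=str(label),
                tracking_ratio=None if ratio is None else float(ratio),
                fixations=fixations,
                saccades=saccades,
            )
        )
    return recordings


def _first_value(group: pd.DataFrame, column: str):
    if column not in group:
        return None
    series = group[column].dropna()
    if series.empty:
        return None
    return series.iloc[0]


def _check_no_overlap(
    fixations: Sequence[FixationEvent], lines: Sequence[int], path: str
) -> None:
    offending = [
        lines[i]
        for i in range(1, len(fixations))
        if fixations[i].start_ms < fixations[i - 1].end_ms - _DURATION_TOL_MS
    ]
    if offending:
        raise EventFileParseError(
            f"{path}: temporally overlapping fixations at lines {offending}"
        )


def _load_manifest(path: str | Path) -> dict[tuple[str, str], dict]:
    entries = json.loads(Path(path).read_text())
    return {(str(e["participant_id"]), str(e["task_id"])): e for e in entries}


def write_event_file(
    recordings: Sequence[Recording],
    path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    """Write recordings as canonical CSV (numeric fields at 3 decimals).

    Label and tracking ratio travel as per-row columns; ``manifest_path``
    additionally writes them as a JSON sidecar keyed by participant/task.
    """
    if not recordings:
        raise ValueError("cannot write an event file for zero recordings")
    path = Path(path)

    def fmt(v: float | None) -> str:
        return "" if v is None else f"{v:.3f}"

    rows = []
    for rec in recordings:
        common = dict(
            participant_id=rec.participant_id,
            task_id=rec.task_id,
            label=rec.label,
            tracking_ratio=fmt(rec.tracking_ratio),
        )
        for f in rec.fixations:
            rows.append(
                {**common, "event_type": "fixation",
                 "start_ms": fmt(f.start_ms), "end_ms": fmt(f.end_ms),
                 "duration_ms": fmt(f.duration_ms),
                 "pos_x": fmt(f.pos_x), "pos_y": fmt(f.pos_y),
                 "disp_x": fmt(f.disp_x), "disp_y": fmt(f.disp_y)}
            )
        for s in rec.saccades:
            rows.append(
                {**common, "event_type": "saccade",
                 "start_ms": fmt(s.start_ms), "end_ms": fmt(s.end_ms),
                 "duration_ms": fmt(s.duration_ms),
                 "pos_x": "", "pos_y": "", "disp_x": "", "disp_y": ""}
            )
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, index=False)

    if manifest_path is not None:
        manifest = [
            dict(participant_id=r.participant_id, task_id=r.task_id,
                 label=r.label, tracking_ratio=r.tracking_ratio)
            for r in recordings
        ]
        Path(manifest_path).write_text(json.dumps(manifest, indent=1))


def filter_by_tracking_ratio(
    recordings: Iterable[Recording], threshold_pct: float = 70.0
) -> list[Recording]:
    """Drop recordings whose tracking ratio is strictly below the threshold.

    A ratio exactly at the threshold is retained.  Recordings without a
    tracking ratio (e.g. simulator output, which has no raw samples) are
    retained with a logged warning.
    """
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold_pct must lie in [0, 100]")
    kept = []
    for rec in recordings:
        if rec.tracking_ratio is None:
            logger.warning(
                "recording %s/%s has no tracking ratio; retained",
                rec.participant_id, rec.task_id,
            )
            kept.append(rec)
        elif rec.tracking_ratio >= threshold_pct:
            kept.append(rec)
    return kept


def extract_features(recording: Recording) -> GazeFeatures:
    """Summary gaze features of one recording (counts, totals, mean)."""
    n_fix = len(recording.fixations)
    if n_fix == 0:
        raise ValueError("mean fixation time undefined for zero fixations")
    total_fix = float(sum(f.duration_ms for f in recording.fixations))
    total_sac = float(sum(s.duration_ms for s in recording.saccades))
    return GazeFeatures(
        fixation_count=n_fix,
        saccade_count=len(recording.saccades),
        total_saccade_time_ms=total_sac,
        total_fixation_time_ms=total_fix,
        mean_fixation_time_ms=total_fix / n_fix,
    )


def stimulus_words_per_line(spec: StimulusSpec) -> float:
    """Average words per line, rounded half-up to two decimals."""
    if spec.n_lines == 0:
        raise ValueError("n_lines must be positive")
    q = Decimal(spec.n_words) / Decimal(spec.n_lines)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def load_stimulus(path: str | Path) -> StimulusSpec:
    data = yaml.safe_load(Path(path).read_text())
    return StimulusSpec(**data)


def save_stimulus(spec: StimulusSpec, path: str | Path) -> None:
    data = dict(
        name=spec.name,
        n_lines=spec.n_lines,
        n_sentences=spec.n_sentences,
        n_words=spec.n_words,
        line_geometry=None
        if spec.line_geometry is None
        else [list(box) for box in spec.line_geometry],
    )
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
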