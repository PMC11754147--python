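"""Class-conditional synthetic reading scanpaths.

The generator walks a reader word-by-word, left to right and line by line,
over a multi-line text grid, emitting fixation bursts per word (log-normal
durations, Gaussian positional jitter and dispersion) separated by short
saccades, with occasional regressive jumps back to earlier words.  The two
default profiles encode the contrasts reported throughout the reading
literature for dyslexic readers — more and longer fixations, more
regressions, larger dispersion — which for a fixed 2-minute reading budget
also means fewer text lines reached.  The profiles are configuration for
exercising the pipeline, not claims about any particular cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .events import (
    FixationEvent,
    Recording,
    SaccadeEvent,
    StimulusSpec,
    save_stimulus,
    write_event_file,
)
from .fiximage import DEFAULT_GEOMETRY, CanvasGeometry

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ReaderProfile:
    """Generative parameters of one reader class.

    ``fixation_duration_median_ms``/``sigma`` parameterise a log-normal;
    ``regression_prob`` is the per-fixation chance of jumping 1-5 words
    back; ``reading_budget_ms`` is the trial length (2-minute default,
    matching the aloud-reading protocol the pipeline targets).
    """

    fixations_per_word: float = 1.2
    fixation_duration_median_ms: float = 220.0
    fixation_duration_sigma: float = 0.30
    regression_prob: float = 0.02
    regression_back_words: tuple[int, int] = (1, 5)
    dispersion_mean_px: tuple[float, float] = (26.0, 13.0)
    dispersion_sd_px: tuple[float, float] = (8.0, 4.0)
    position_jitter_px: float = 5.0
    reading_budget_ms: float = 120_000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.regression_prob <= 1.0:
            raise ValueError("regression_prob must lie in [0, 1]")
        if self.fixation_duration_median_ms <= 0 or self.reading_budget_ms <= 0:
            raise ValueError("durations and budget must be positive")


CONTROL_PROFILE = ReaderProfile()
DYSLEXIC_PROFILE = ReaderProfile(
    fixations_per_word=2.2,
    fixation_duration_median_ms=330.0,
    fixation_duration_sigma=0.35,
    regression_prob=0.06,  # 3x the control rate
    dispersion_mean_px=(42.0, 20.0),
    dispersion_sd_px=(12.0, 6.0),
    position_jitter_px=8.0,
)

_MIN_FIXATION_MS = 50.0  # event-detection floor of typical vendor pipelines


def default_line_geometry(
    n_lines: int, geometry: CanvasGeometry = DEFAULT_GEOMETRY, margin_px: float = 20.0
) -> list[tuple[float, float, float, float]]:
    """Evenly spaced line boxes inside the displayed-text area."""
    x0 = geometry.text_x0 + margin_px
    x1 = geometry.text_x1 - margin_px
    top = geometry.text_y0 + margin_px
    h = (geometry.text_y1 - geometry.text_y0 - 2 * margin_px) / n_lines
    return [(x0, top + i * h, x1, top + (i + 1) * h) for i in range(n_lines)]


def default_stimuli() -> dict[str, StimulusSpec]:
    """The three bundled stimulus layouts: at-level, below-level, pseudo-text."""
    layouts = {
        "at_level": (11, 11, 166),
        "below_level": (8, 23, 113),
        "pseudo": (8, 24, 139),
    }
    return {
        task: StimulusSpec(
            name=task,
            n_lines=lines,
            n_sentences=sents,
            n_words=words,
            line_geometry=default_line_geometry(lines),
        )
        for task, (lines, sents, words) in layouts.items()
    }


@dataclass
class CohortSpec:
    """Composition of a simulated study cohort (defaults: 13 + 22 subjects)."""

    n_dyslexic: int = 13
    n_control: int = 22
    dyslexic_profile: ReaderProfile = DYSLEXIC_PROFILE
    control_profile: ReaderProfile = CONTROL_PROFILE
    stimuli: Mapping[str, StimulusSpec] = field(default_factory=default_stimuli)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyslexic < 0 or self.n_control < 0:
            raise ValueError("cohort sizes must be non-negative")


def _word_anchors(stimulus: StimulusSpec) -> np.ndarray:
    """(n_words, 2) centre coordinates, words dealt across lines in order."""
    if stimulus.line_geometry is None:
        raise ValueError("simulation requires a stimulus with line_geometry")
    base, extra = divmod(stimulus.n_words, stimulus.n_lines)
    anchors = []
    for i, (x0, y0, x1, y1) in enumerate(stimulus.line_geometry):
        count = base + (1 if i < extra else 0)
        cy = (y0 + y1) / 2.0
        step = (x1 - x0) / max(count, 1)
        anchors.extend((x0 + (j + 0.5) * step, cy) for j in range(count))
    return np.asarray(anchors)


def simulate_recording(
    profile: ReaderProfile,
    stimulus: StimulusSpec,
    seed: int,
    participant_id: str = "sim",
    task_id: str = "task",
    label: str = "unknown",
    tracking_ratio: float | None = None,
) -> Recording:
    """Simulate one reading trial; fully determined by the seed.

    The walk stops when the reading budget would be exceeded or the text
    runs out, so total event time never exceeds the budget.
    """
    anchors = _word_anchors(stimulus)
    n_words = len(anchors)
    rng = np.random.default_rng(seed)
    mu = np.log(profile.fixation_duration_median_ms)
    lo, hi = profile.regression_back_words

    def burst() -> int:
        return max(1, int(rng.poisson(profile.fixations_per_word)))

    fixations: list[FixationEvent] = []
    saccades: list[SaccadeEvent] = []
    t = 0.0
    word = 0
    fix_left = burst()
    while word < n_words:
        dur = max(_MIN_FIXATION_MS, rng.lognormal(mu, profile.fixation_duration_sigma))
        if t + dur > profile.reading_budget_ms:
            break
        cx, cy = anchors[word]
        jitter = rng.normal(0.0, profile.position_jitter_px, size=2)
        disp = np.abs(rng.normal(profile.dispersion_mean_px, profile.dispersion_sd_px))
        disp = np.maximum(disp, 1.0)
        fixations.append(
            FixationEvent(
                start_ms=t,
                end_ms=t + dur,
                duration_ms=dur,
                pos_x=float(cx + jitter[0]),
                pos_y=float(cy + jitter[1]),
                disp_x=float(disp[0]),
                disp_y=float(disp[1]),
            )
        )
        t += dur
        fix_left -= 1
        if rng.random() < profile.regression_prob:
            word = max(0, word - int(rng.integers(lo, hi + 1)))
            fix_left = burst()
        elif fix_left == 0:
            word += 1
            fix_left = burst()
        if word >= n_words:
            break
        sacc = float(rng.uniform(20.0, 80.0))
        if t + sacc > profile.reading_budget_ms:
            break
        saccades.append(SaccadeEvent(start_ms=t, end_ms=t + sacc, duration_ms=sacc))
        t += sacc
    return Recording(
        participant_id=participant_id,
        task_id=task_id,
        label=label,
        tracking_ratio=tracking_ratio,
        fixations=fixations,
        saccades=saccades,
    )


def lines_covered(recording: Recording, stimulus: StimulusSpec) -> int:
    """Number of distinct text lines whose band contains >= 1 fixation centre."""
    boxes = stimulus.line_geometry or []
    hit = set()
    for f in recording.fixations:
        for i, (_, y0, _, y1) in enumerate(boxes):
            if y0 <= f.pos_y < y1:
                hit.add(i)
                break
    return len(hit)


def simulate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[Recording], list[dict]]:
    """Simulate every subject on every task; optionally write event files.

    Subjects are named ``dys01..`` / ``ctl01..``; per-subject-task seeds are
    derived from ``spec.seed`` so the whole cohort is reproducible.  With
    ``out_dir`` one canonical event CSV is written per recording plus a
    ``manifest.json`` of labels/tracking ratios and the stimulus YAMLs.
    """
    subjects = [(f"dys{i + 1:02d}", "dyslexic") for i in range(spec.n_dyslexic)]
    subjects += [(f"ctl{i + 1:02d}", "control") for i in range(spec.n_control)]
    meta_rng = np.random.default_rng(spec.seed)
    recordings: list[Recording] = []
    manifest: list[dict] = []
    for s_idx, (pid, label) in enumerate(subjects):
        profile = spec.dyslexic_profile if label == "dyslexic" else spec.control_profile
        # mild per-subject individuality around the class profile
        speed = float(meta_rng.uniform(0.9, 1.1))
        subject_profile = replace(
            profile,
            fixation_duration_median_ms=profile.fixation_duration_median_ms * speed,
        )
        tracking = float(meta_rng.uniform(85.0, 99.5))
        for t_idx, (task, stimulus) in enumerate(spec.stimuli.items()):
            seed = (spec.seed * 1_000_003 + s_idx * 101 + t_idx) % _SEED_MOD
            rec = simulate_recording(
                subject_profile,
                stimulus,
                seed=seed,
                participant_id=pid,
                task_id=task,
                label=label,
                tracking_ratio=tracking,
            )
            recordings.append(rec)
            manifest.append(
                dict(participant_id=pid, task_id=task, label=label,
                     tracking_ratio=tracking, seed=seed)
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_event_file([rec], out_dir / f"{rec.participant_id}_{rec.task_id}.csv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for task, stimulus in spec.stimuli.items():
            save_stimulus(stimulus, out_dir / f"stimulus_{task}.yaml")
    return recordings, manifest
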