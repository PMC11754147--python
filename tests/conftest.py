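import pytest

from gazescreen import CohortSpec, simulate_cohort
from gazescreen.events import FixationEvent, Recording, SaccadeEvent


def make_fixation(start, dur, x=500.0, y=400.0, dx=30.0, dy=15.0):
    return FixationEvent(
        start_ms=start, end_ms=start + dur, duration_ms=dur,
        pos_x=x, pos_y=y, disp_x=dx, disp_y=dy,
    )


def make_recording(durations, pid="p1", task="at_level", label="control",
                   ratio=95.0, xs=None, ys=None, dxs=None, dys=None):
    """Recording with back-to-back fixations of the given durations."""
    fixations, t = [], 0.0
    for i, d in enumerate(durations):
        fixations.append(
            FixationEvent(
                start_ms=t, end_ms=t + d, duration_ms=d,
                pos_x=xs[i] if xs else 500.0 + 10 * i,
                pos_y=ys[i] if ys else 400.0,
                disp_x=dxs[i] if dxs else 30.0,
                disp_y=dys[i] if dys else 15.0,
            )
        )
        t += d + 30.0
    return Recording(participant_id=pid, task_id=task, label=label,
                     tracking_ratio=ratio, fixations=fixations,
                     saccades=[SaccadeEvent(0.0, 30.0, 30.0)])


@pytest.fixture(scope="session")
def default_cohort():
    """The full simulated study cohort: 13 dyslexic + 22 control, 3 tasks."""
    recordings, manifest = simulate_cohort(CohortSpec(seed=1))
    return recordings, manifest


@pytest.fixture(scope="session")
def cohort_by_task(default_cohort):
    recordings, _ = default_cohort
    labels = {r.participant_id: r.label for r in recordings}
    tasks = {
        t: {r.participant_id: r for r in recordings if r.task_id == t}
        for t in sorted({r.task_id for r in recordings})
    }
    return tasks, labels
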