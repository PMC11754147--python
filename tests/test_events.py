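"""Event-file parsing, filtering, and summary-feature extraction."""


import pytest

from gazescreen.events import (
    BEGAZE_DIALECT,
    EventFileFormatError,
    EventFileParseError,
    Recording,
    StimulusSpec,
    extract_features,
    filter_by_tracking_ratio,
    read_event_file,
    stimulus_words_per_line,
    write_event_file,
)

from conftest import make_recording


def test_parse_fixations_only_file(tmp_path):
    path = tmp_path / "events.csv"
    path.write_text(
        "participant_id,task_id,event_type,start_ms,end_ms,duration_ms,pos_x,pos_y,disp_x,disp_y\n"
        "p1,at_level,fixation,0,100,100,500,400,30,15\n"
        "p1,at_level,fixation,120,300,180,520,400,25,12\n"
        "p1,at_level,fixation,330,500,170,540,402,28,14\n"
    )
    recs = read_event_file(path)
    assert len(recs) == 1
    assert len(recs[0].fixations) == 3
    assert recs[0].saccades == []
    assert recs[0].fixations[0].disp_x == 30.0


def test_missing_dispersion_columns_yield_none(tmp_path):
    path = tmp_path / "nodisp.csv"
    path.write_text(
        "participant_id,start_ms,end_ms,duration_ms,pos_x,pos_y\n"
        "p1,0,100,100,500,400\n"
    )
    recs = read_event_file(path)
    fix = recs[0].fixations[0]
    assert fix.disp_x is None and fix.disp_y is None


def test_begaze_style_dialect(tmp_path):
    path = tmp_path / "begaze.tsv"
    path.write_text(
        "Participant ID\tEvent Type\tEvent Start Trial Time [ms]\t"
        "Event End Trial Time [ms]\tEvent Duration [ms]\t"
        "Fixation Position X [px]\tFixation Position Y [px]\t"
        "Fixation Dispersion X [px]\tFixation Dispersion Y [px]\n"
        "p7\tFixation\t0\t200\t200\t510\t410\t33\t17\n"
        "p7\tSaccade\t200\t240\t40\t\t\t\t\n"
        "p7\tFixation\t240\t400\t160\t530\t412\t30\t16\n"
    )
    recs = read_event_file(path, dialect=BEGAZE_DIALECT)
    assert len(recs) == 1
    assert len(recs[0].fixations) == 2
    assert len(recs[0].saccades) == 1
    assert recs[0].saccades[0].duration_ms == 40.0


def test_events_reordered_by_start_time(tmp_path):
    path = tmp_path / "shuffled.csv"
    path.write_text(
        "participant_id,start_ms,end_ms,duration_ms,pos_x,pos_y\n"
        "p1,330,500,170,540,402\n"
        "p1,0,100,100,500,400\n"
        "p1,120,300,180,520,400\n"
    )
    starts = [f.start_ms for f in read_event_file(path)[0].fixations]
    assert starts == sorted(starts)


def test_missing_mandatory_column_names_it(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("participant_id,start_ms,end_ms\np1,0,100\n")
    with pytest.raises(EventFileFormatError, match="duration_ms"):
        read_event_file(path)


def test_non_numeric_cell_reports_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "participant_id,start_ms,end_ms,duration_ms,pos_x,pos_y\n"
        "p1,0,100,100,500,400\n"
        "p1,120,300,oops,520,400\n"
    )
    with pytest.raises(EventFileParseError, match="line 3"):
        read_event_file(path)


def test_overlapping_fixations_rejected(tmp_path):
    path = tmp_path / "overlap.csv"
    path.write_text(
        "participant_id,start_ms,end_ms,duration_ms,pos_x,pos_y\n"
        "p1,0,100,100,500,400\n"
        "p1,50,200,150,520,400\n"
    )
    with pytest.raises(EventFileParseError, match="overlap"):
        read_event_file(path)


def test_round_trip_preserves_recordings(tmp_path):
    recs = [
        make_recording([100.25, 200.5, 300.125], pid="a", label="dyslexic"),
        make_recording([150.0, 250.0], pid="b", task="pseudo", label="control"),
    ]
    path = tmp_path / "rt.csv"
    write_event_file(recs, path)
    back = read_event_file(path)
    assert len(back) == 2
    for orig, rb in zip(recs, back):
        assert rb.participant_id == orig.participant_id
        assert rb.task_id == orig.task_id
        assert rb.label == orig.label
        assert rb.tracking_ratio == pytest.approx(orig.tracking_ratio, abs=1e-3)
        assert len(rb.fixations) == len(orig.fixations)
        assert len(rb.saccades) == len(orig.saccades)
        for fo, fb in zip(orig.fixations, rb.fixations):
            for attr in ("start_ms", "end_ms", "duration_ms", "pos_x", "pos_y",
                         "disp_x", "disp_y"):
                assert getattr(fb, attr) == pytest.approx(getattr(fo, attr), abs=1e-3)


def test_write_requires_recordings(tmp_path):
    with pytest.raises(ValueError):
        write_event_file([], tmp_path / "empty.csv")


def test_manifest_overrides_metadata(tmp_path):
    rec = make_recording([100.0], pid="p9", label="unknown", ratio=None)
    write_event_file([rec], tmp_path / "e.csv")
    (tmp_path / "m.json").write_text(
        '[{"participant_id": "p9", "task_id": "at_level", '
        '"label": "dyslexic", "tracking_ratio": 88.5}]'
    )
    back = read_event_file(tmp_path / "e.csv", manifest=tmp_path / "m.json")[0]
    assert back.label == "dyslexic"
    assert back.tracking_ratio == pytest.approx(88.5)


class TestTrackingRatioFilter:
    def test_boundary_is_retained(self):
        recs = [make_recording([100], pid=p, ratio=r)
                for p, r in [("a", 69.9), ("b", 70.0), ("c", 95.0)]]
        kept = filter_by_tracking_ratio(recs, 70.0)
        assert [r.participant_id for r in kept] == ["b", "c"]

    def test_threshold_zero_keeps_all(self):
        recs = [make_recording([100], pid=p, ratio=r)
                for p, r in [("a", 10.0), ("b", 0.0)]]
        assert len(filter_by_tracking_ratio(recs, 0.0)) == 2

    def test_all_below_gives_empty_list(self):
        recs = [make_recording([100], ratio=10.0)]
        assert filter_by_tracking_ratio(recs, 50.0) == []

    def test_absent_ratio_retained_with_warning(self, caplog):
        recs = [make_recording([100], ratio=None)]
        with caplog.at_level("WARNING"):
            kept = filter_by_tracking_ratio(recs, 70.0)
        assert len(kept) == 1
        assert "tracking ratio" in caplog.text

    def test_idempotent_subset_in_order(self):
        recs = [make_recording([100], pid=p, ratio=r)
                for p, r in [("a", 90.0), ("b", 60.0), ("c", 80.0)]]
        once = filter_by_tracking_ratio(recs, 70.0)
        assert filter_by_tracking_ratio(once, 70.0) == once
        assert [r.participant_id for r in once] == ["a", "c"]


class TestFeatures:
    def test_counts_and_means(self):
        feats = extract_features(make_recording([100.0, 200.0, 300.0]))
        assert feats.fixation_count == 3
        assert feats.total_fixation_time_ms == pytest.approx(600.0)
        assert feats.mean_fixation_time_ms == pytest.approx(200.0)
        assert feats.saccade_count == 1

    def test_mean_times_count_equals_total(self, default_cohort):
        recordings, _ = default_cohort
        for rec in recordings[:10]:
            f = extract_features(rec)
            assert f.mean_fixation_time_ms * f.fixation_count == pytest.approx(
                f.total_fixation_time_ms, rel=1e-9
            )

    def test_zero_fixations_is_domain_error(self):
        rec = Recording(participant_id="x", task_id="t")
        with pytest.raises(ValueError):
            extract_features(rec)


@pytest.mark.parametrize(
    "words,lines,expected",
    [(166, 11, 15.09), (113, 8, 14.13), (139, 8, 17.38), (100, 10, 10.00)],
)
def test_words_per_line_rounds_half_up(words, lines, expected):
    spec = StimulusSpec(name="s", n_lines=lines, n_sentences=5, n_words=words)
    assert stimulus_words_per_line(spec) == expected
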