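"""Marker placement rules and the measurements/summary tables."""

import numpy as np
import pandas as pd
import pytest

import ergkit as ek
from ergkit.markers import baseline_voltage, MEASUREMENT_COLUMNS
from ergkit.model import Recording, StimulusDescriptor, SubjectInfo, TrialBlock


def _constructed_flash_exam():
    """Trace with planted extrema: min −150 µV at 15 ms, max +300 µV at 50 ms."""
    fs = 1000.0
    t_ms = (np.arange(320) - 20) * 1000.0 / fs
    v = np.zeros_like(t_ms)
    # narrow kernels so the planted extrema are the landmark values exactly
    v -= 150.0 * np.exp(-0.5 * ((t_ms - 15.0) / 4.0) ** 2)
    v += 300.0 * np.exp(-0.5 * ((t_ms - 50.0) / 8.0) ** 2)
    rec = Recording(
        "ERG", "RE", StimulusDescriptor("Flash", 1.0), TrialBlock(v[:, None], fs, 20)
    )
    return ek.new_exam(SubjectInfo("s"), "2024-01-01", [rec])


class TestAutoPlace:
    def test_flash_extrema_define_a_and_b(self):
        exam = _constructed_flash_exam()
        ek.auto_place_markers(exam)
        markers = {m.name: m for m in exam.recordings[0].markers}
        assert markers["a"].time_ms == 15.0
        assert markers["B"].time_ms == pytest.approx(50.0, abs=1.0)
        assert markers["B"].relative_to == "a"
        assert markers["a"].voltage_uv == pytest.approx(-150.0, rel=0.01)

    def test_flicker_p1_t1_within_one_period(self):
        block, _ = ek.synth_flicker(stim_freq_hz=9.0, fund_amp_uv=20.0, noise_sd_uv=0.0)
        rec = Recording(
            "ERG",
            "RE",
            StimulusDescriptor("Flicker", 3.0, adaptation="LA", flicker_freq_hz=9.0),
            block,
        )
        exam = ek.new_exam(SubjectInfo("s"), "2024-01-01", [rec])
        ek.auto_place_markers(exam)
        markers = {m.name: m for m in rec.markers}
        period_ms = 1000.0 / 9.0
        assert markers["P1"].time_ms > period_ms  # steady state only
        assert 0 < markers["P1"].time_ms - markers["T1"].time_ms <= period_ms
        # brute-force oracle: peak and preceding trough of the template
        assert markers["P1"].voltage_uv == pytest.approx(20.0, rel=0.01)
        assert markers["T1"].voltage_uv == pytest.approx(-20.0, rel=0.01)

    def test_op_peaks_between_a_and_b_in_time_order(self):
        block, _ = ek.synth_flash_erg(op_amp_uv=30.0, noise_sd_uv=0.0, n_trials=5)
        rec = Recording(
            "OP",
            "RE",
            StimulusDescriptor("Flash", 1.0),
            block,
            processing=ek.ProcessingSpec(filter=ek.FilterSpec(75.0, 300.0)),
        )
        exam = ek.new_exam(SubjectInfo("s"), "2024-01-01", [rec])
        ek.auto_place_markers(exam)
        ops = [m for m in rec.markers if m.name.startswith("OP")]
        assert len(ops) >= 3
        times = [m.time_ms for m in ops]
        assert times == sorted(times)
        assert all(15.0 <= t <= 50.0 for t in times)
        # oracle: exhaustive local-maxima enumeration on the processed trace
        _, trace = ek.get_processed_trace(exam, 0)
        t_ms = block.times_ms
        sel = (t_ms >= times[0] - 0.5) & (t_ms <= times[-1] + 0.5)
        local_max_times = [
            t_ms[i]
            for i in range(1, len(trace) - 1)
            if sel[i] and trace[i] > trace[i - 1] and trace[i] > trace[i + 1]
        ]
        assert set(np.round(times, 6)) <= set(np.round(local_max_times, 6))

    def test_manual_markers_survive_replacement(self):
        exam = _constructed_flash_exam()
        ek.auto_place_markers(exam)
        ek.place_marker(exam, 0, "custom", 100.0)
        first_auto = {m.name: m.time_ms for m in exam.recordings[0].markers}
        ek.auto_place_markers(exam)
        names = [m.name for m in exam.recordings[0].markers]
        assert "custom" in names and names.count("a") == 1
        assert {m.name: m.time_ms for m in exam.recordings[0].markers} == first_auto


class TestPlaceMarker:
    def test_voltage_read_at_nearest_sample(self):
        exam = _constructed_flash_exam()
        ek.place_marker(exam, 0, "a", 14.8)
        m = exam.recordings[0].get_marker("a")
        assert m.time_ms == 15.0
        _, trace = ek.get_processed_trace(exam, 0)
        t_ms = exam.recordings[0].trials.times_ms
        assert m.voltage_uv == trace[np.argmin(np.abs(t_ms - 15.0))]

    def test_unknown_reference_rejected(self):
        exam = _constructed_flash_exam()
        with pytest.raises(ek.ValidationError):
            ek.place_marker(exam, 0, "B", 50.0, relative_to="zzz")

    def test_outside_epoch_rejected(self):
        exam = _constructed_flash_exam()
        with pytest.raises(ek.ValidationError):
            ek.place_marker(exam, 0, "late", 500.0)

    def test_replacing_same_name_keeps_single_marker(self):
        exam = _constructed_flash_exam()
        ek.place_marker(exam, 0, "a", 15.0)
        n = len(exam.changelog)
        ek.place_marker(exam, 0, "a", 20.0)
        assert [m.name for m in exam.recordings[0].markers].count("a") == 1
        assert exam.recordings[0].get_marker("a").time_ms == 20.0
        assert len(exam.changelog) == n + 1


class TestMeasurements:
    def test_amplitudes_against_stated_references(self):
        exam = _constructed_flash_exam()
        ek.auto_place_markers(exam)
        table = ek.measurements(exam)
        amp = dict(zip(table.marker_name, table.amplitude_uv))
        assert amp["a"] == pytest.approx(-150.0, rel=0.01)  # vs zero baseline
        assert amp["B"] == pytest.approx(450.0, rel=0.01)  # vs the a-trough

    def test_no_markers_yields_empty_table_with_header(self, flash_exam):
        exam, _ = flash_exam
        table = ek.measurements(exam)
        assert table.empty
        assert list(table.columns) == MEASUREMENT_COLUMNS

    def test_rows_match_independent_recomputation(self, clean_flash_exam):
        exam, _ = clean_flash_exam
        ek.set_standard_functions(exam)
        ek.auto_place_markers(exam)
        table = ek.measurements(exam)
        assert len(table) == 12  # 6 recordings x (a, B)
        for _, row in table.iterrows():
            rec = exam.recordings[row.recording_index]
            m = rec.get_marker(row.marker_name)
            _, trace = ek.get_processed_trace(exam, row.recording_index)
            if m.relative_to:
                ref = rec.get_marker(m.relative_to).voltage_uv
            else:
                ref = baseline_voltage(rec, trace)
            assert row.amplitude_uv == pytest.approx(m.voltage_uv - ref)

    def test_pure_function_of_exam_state(self, clean_flash_exam):
        exam, _ = clean_flash_exam
        ek.set_standard_functions(exam)
        ek.auto_place_markers(exam)
        t1 = ek.measurements(exam)
        t2 = ek.measurements(exam)
        pd.testing.assert_frame_equal(t1, t2)


class TestIntensitySequence:
    def _table(self, subject, amp):
        return pd.DataFrame(
            [
                {
                    "subject_id": subject,
                    "recording_index": 0,
                    "channel": "ERG",
                    "eye": "RE",
                    "stim_type": "Flash",
                    "adaptation": "DA",
                    "intensity_value": 1.0,
                    "marker_name": "B",
                    "implicit_time_ms": 50.0,
                    "amplitude_uv": amp,
                }
            ]
        )

    def test_closed_form_summary(self):
        tables = [self._table(f"s{i}", a) for i, a in enumerate([400.0, 450.0, 500.0])]
        out = ek.intensity_sequence(tables, "B")
        assert len(out) == 1
        row = out.iloc[0]
        assert row.n == 3
        assert row.mean_uv == pytest.approx(450.0)
        assert row.sd_uv == pytest.approx(50.0)
        assert row.sem_uv == pytest.approx(50.0 / np.sqrt(3))

    def test_single_subject_sd_missing(self):
        out = ek.intensity_sequence([self._table("s0", 400.0)], "B")
        assert out.iloc[0].n == 1
        assert np.isnan(out.iloc[0].sd_uv) and np.isnan(out.iloc[0].sem_uv)

    def test_absent_marker_gives_empty_summary(self):
        out = ek.intensity_sequence([self._table("s0", 400.0)], "nope")
        assert out.empty

    def test_cohort_summary_matches_brute_force_aggregation(self):
        exams, groups = ek.synth_cohort(2, 3, seed=4, protocol_config={"da_intensities": [0.01, 0.1, 1.0]})
        for e in exams:
            ek.set_standard_functions(e)
            ek.auto_place_markers(e)
        tables = [ek.measurements(e) for e in exams]
        out = ek.intensity_sequence(tables, "B", groups)
        df = pd.concat(tables, ignore_index=True)
        df = df[df.marker_name == "B"]
        for _, row in out.iterrows():
            members = df[
                (df.subject_id.map(groups) == row.group)
                & (df.adaptation == row.adaptation)
                & (df.intensity_value == row.intensity_value)
            ].amplitude_uv.to_numpy()
            assert row.n == len(members)
            assert row.mean_uv == pytest.approx(members.mean())
            assert row.sd_uv == pytest.approx(members.std(ddof=1))
        # sorted by ascending intensity within a group/adaptation
        for (_, _), g in out.groupby(["group", "adaptation"]):
            assert list(g.intensity_value) == sorted(g.intensity_value)

    def test_monotone_truth_yields_monotone_summary(self, clean_flash_exam):
        exam, truth = clean_flash_exam
        ek.set_standard_functions(exam)
        ek.auto_place_markers(exam)
        out = ek.intensity_sequence([ek.measurements(exam)], "B")
        da = out[out.adaptation == "DA"].sort_values("intensity_value")
        assert da.mean_uv.is_monotonic_increasing
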