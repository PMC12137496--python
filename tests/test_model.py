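"""Exam container: construction, querying, subsetting, lazy processing, audit log."""

import numpy as np
import pytest

import ergkit as ek
from ergkit.model import Recording, StimulusDescriptor, SubjectInfo, TrialBlock


def _flash_recording(n_trials=10, adaptation="DA", intensity=1.0, value=0.0):
    samples = np.full((100, n_trials), value)
    return Recording(
        "ERG",
        "RE",
        StimulusDescriptor("Flash", intensity, adaptation=adaptation),
        TrialBlock(samples, 1000.0, t0_index=20),
    )


class TestConstruction:
    def test_new_exam_logs_creation(self):
        exam = ek.new_exam(SubjectInfo("s1"), "2024-01-01", [_flash_recording()])
        assert len(exam.recordings) == 1
        assert len(exam.changelog) == 1
        assert exam.changelog[0].operation == "created"

    def test_empty_recording_list_rejected(self):
        with pytest.raises(ek.ValidationError):
            ek.new_exam(SubjectInfo("s1"), "2024-01-01", [])

    def test_empty_criteria_match_all_recordings(self):
        exam, _ = ek.synth_exam(seed=0)
        assert ek.where(exam, {}) == list(range(6))

    @pytest.mark.parametrize(
        "bad",
        [
            {"subject_id": ""},
        ],
    )
    def test_subject_requires_id(self, bad):
        with pytest.raises(ek.ValidationError):
            SubjectInfo(**bad)

    def test_stimulus_invariants(self):
        with pytest.raises(ek.ValidationError):
            StimulusDescriptor("Flicker", 1.0, flicker_freq_hz=0.0)
        with pytest.raises(ek.ValidationError):
            StimulusDescriptor("Flash", 0.0)

    def test_trial_block_immutable(self):
        block = TrialBlock(np.zeros((10, 2)), 1000.0)
        with pytest.raises(ValueError):
            block.samples[0, 0] = 1.0

    def test_rejection_mask_length_checked(self):
        with pytest.raises(ek.ValidationError):
            Recording(
                "ERG",
                "RE",
                StimulusDescriptor("Flash", 1.0),
                TrialBlock(np.zeros((10, 3)), 1000.0),
                rejection_mask=np.zeros(5, dtype=bool),
            )


class TestWhere:
    def test_adaptation_match(self):
        recs = [
            _flash_recording(adaptation="DA"),
            _flash_recording(adaptation="DA"),
            _flash_recording(adaptation="LA"),
        ]
        exam = ek.new_exam(SubjectInfo("s"), "2024-01-01", recs)
        assert ek.where(exam, {"adaptation": "DA"}) == [0, 1]

    def test_unknown_key_rejected(self):
        exam = ek.new_exam(SubjectInfo("s"), "2024-01-01", [_flash_recording()])
        with pytest.raises(ek.ValidationError):
            ek.where(exam, {"color": "red"})

    def test_intensity_range_inclusive(self):
        exam, _ = ek.synth_exam(seed=0)  # DA at 0.001..1.0 plus LA 1.0
        got = ek.where(exam, {"adaptation": "DA", "intensity": (0.01, 0.3)})
        # brute-force oracle: exhaustive scan of recording metadata
        expect = [
            i
            for i, r in enumerate(exam.recordings)
            if r.stimulus.adaptation == "DA"
            and 0.01 <= r.stimulus.intensity_value <= 0.3
        ]
        assert got == expect and got == [1, 2, 3]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_scan_on_random_criteria(self, seed, random_exam_factory):
        rng = np.random.default_rng(seed + 400)
        exam = random_exam_factory(seed)
        criteria = {}
        if rng.random() < 0.5:
            criteria["adaptation"] = rng.choice(["DA", "LA"])
        if rng.random() < 0.5:
            criteria["stim_type"] = rng.choice(["Flash", "Flicker"])
        if rng.random() < 0.5:
            lo, hi = sorted(rng.uniform(0.0005, 3.5, 2))
            criteria["intensity"] = (lo, hi)

        def oracle(r):
            ok = True
            if "adaptation" in criteria:
                ok &= r.stimulus.adaptation == criteria["adaptation"]
            if "stim_type" in criteria:
                ok &= r.stimulus.stim_type == criteria["stim_type"]
            if "intensity" in criteria:
                lo, hi = criteria["intensity"]
                ok &= lo <= r.stimulus.intensity_value <= hi
            return ok

        expect = [i for i, r in enumerate(exam.recordings) if oracle(r)]
        assert ek.where(exam, criteria) == expect
        if expect:
            sub = ek.subset(exam, expect)
            assert [r.stimulus.intensity_value for r in sub.recordings] == [
                exam.recordings[i].stimulus.intensity_value for i in expect
            ]


class TestSubset:
    def test_da_only(self, flash_exam):
        exam, _ = flash_exam
        sub = ek.subset(exam, ek.where(exam, {"adaptation": "DA"}))
        assert all(r.stimulus.adaptation == "DA" for r in sub.recordings)
        assert len(sub.recordings) == 5

    def test_identity_subset_preserves_data(self, flash_exam):
        exam, _ = flash_exam
        ek.set_standard_functions(exam)
        ek.auto_place_markers(exam)
        sub = ek.subset(exam, range(len(exam.recordings)))
        for a, b in zip(exam.recordings, sub.recordings):
            assert np.array_equal(a.trials.samples, b.trials.samples)
            assert a.processing == b.processing
            assert a.markers == b.markers
            assert np.array_equal(a.rejection_mask, b.rejection_mask)

    def test_order_follows_indices(self, flash_exam):
        exam, _ = flash_exam
        sub = ek.subset(exam, [5, 0])
        assert sub.recordings[0].stimulus.adaptation == exam.recordings[5].stimulus.adaptation
        assert np.array_equal(sub.recordings[1].trials.samples, exam.recordings[0].trials.samples)

    def test_original_unmodified_and_deep_copied(self, flash_exam):
        exam, _ = flash_exam
        before = exam.recordings[0].trials.samples.copy()
        sub = ek.subset(exam, [0])
        sub.recordings[0].markers.append(ek.Marker("x", 10.0, 1.0))
        assert exam.recordings[0].markers == []
        assert np.array_equal(exam.recordings[0].trials.samples, before)

    @pytest.mark.parametrize("bad", [[99], [0, 0]])
    def test_invalid_indices_rejected(self, bad, flash_exam):
        exam, _ = flash_exam
        with pytest.raises(ek.ValidationError):
            ek.subset(exam, bad)


class TestProcessedTrace:
    def test_mean_of_identical_trials_is_the_trial(self):
        rec = _flash_recording(value=3.5)
        exam = ek.new_exam(SubjectInfo("s"), "2024-01-01", [rec])
        _, v = ek.get_processed_trace(exam, 0)
        assert np.array_equal(v, np.full(100, 3.5))

    def test_distance_rejection_excludes_planted_artifact(self):
        block, truth = ek.synth_flash_erg(noise_sd_uv=5.0, n_trials=10, seed=3)
        block = ek.inject_artifact(block, ek.ArtifactSpec("inverted", 4))
        rec = Recording(
            "ERG",
            "RE",
            StimulusDescriptor("Flash", 1.0),
            block,
            processing=ek.ProcessingSpec(rejection=ek.RejectionSpec()),
        )
        exam = ek.new_exam(SubjectInfo("s"), "2024-01-01", [rec])
        _, v = ek.get_processed_trace(exam, 0)
        clean = np.delete(block.samples, 4, axis=1).mean(axis=1)
        assert np.allclose(v, clean)

    def test_purity_and_raw_preservation(self, flash_exam):
        exam, _ = flash_exam
        ek.set_standard_functions(exam)
        raw = exam.recordings[0].trials.samples.copy()
        _, v1 = ek.get_processed_trace(exam, 0)
        _, v2 = ek.get_processed_trace(exam, 0)
        assert np.array_equal(v1, v2)
        assert np.array_equal(exam.recordings[0].trials.samples, raw)

    def test_all_rejected_raises(self):
        rec = _flash_recording(n_trials=3)
        rec.rejection_mask = np.ones(3, dtype=bool)
        exam = ek.new_exam(SubjectInfo("s"), "2024-01-01", [rec])
        with pytest.raises(ek.EmptySelectionError):
            ek.get_processed_trace(exam, 0)


class TestChangelog:
    def test_mutations_append(self, flash_exam):
        exam, _ = flash_exam
        n0 = len(exam.changelog)
        ek.set_standard_functions(exam)
        assert len(exam.changelog) == n0 + 1
        assert exam.changelog[-1].operation == "set_standard_functions"
        ek.auto_place_markers(exam)
        assert len(exam.changelog) == n0 + 2

    def test_empty_operation_name_rejected(self, flash_exam):
        exam, _ = flash_exam
        with pytest.raises(ek.ValidationError):
            ek.log_change(exam, "")

    def test_monotone_across_operation_sequence(self, flash_exam):
        exam, _ = flash_exam
        lengths = [len(exam.changelog)]
        ek.set_standard_functions(exam)
        lengths.append(len(exam.changelog))
        ek.auto_place_markers(exam)
        lengths.append(len(exam.changelog))
        ek.place_marker(exam, 0, "m", 100.0)
        lengths.append(len(exam.changelog))
        assert lengths == sorted(lengths) and len(set(lengths)) == len(lengths)
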