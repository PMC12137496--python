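"""Exam data model.

An :class:`Exam` holds the recordings of one visual-electrophysiology
examination (ERG and/or VEP).  The guiding principle is raw-data
preservation: trial matrices are stored immutably at import time and every
processing step (filtering, trial rejection, averaging) is described by a
declarative :class:`~ergkit.processing.ProcessingSpec` that is applied
lazily when a processed trace is requested.  Nothing ever overwrites the
raw samples, and every mutating operation appends to an audit changelog.

Conventions: time zero is stimulus onset (samples before ``t0_index`` carry
negative times and form the baseline window); voltages are microvolts
throughout; recording indices are 0-based.
"""

from __future__ import annotations

import copy
import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import EmptySelectionError, ValidationError

__all__ = [
    "SubjectInfo",
    "StimulusDescriptor",
    "TrialBlock",
    "Marker",
    "ChangeLogEntry",
    "Recording",
    "Exam",
    "new_exam",
    "where",
    "subset",
    "get_processed_trace",
    "log_change",
    "exams_equal",
]

FORMAT_VERSION = "1.0"

STIM_TYPES = ("Flash", "Flicker")
ADAPTATIONS = ("DA", "LA")
EYES = ("RE", "LE", "both", "unknown")
CHANNELS = ("ERG", "VEP", "OP")


@dataclass
class SubjectInfo:
    """Identity and cohort metadata for the examined subject."""

    subject_id: str
    species: str = "mouse"
    group_label: str = ""
    dob: str = ""
    eye_context: str = ""

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")


@dataclass
class StimulusDescriptor:
    """Stimulus metadata for one recording.

    ``intensity_value`` is the time-integrated luminance of the flash, kept
    together with its unit string verbatim (e.g. ``"cd*s/cm^2"``).
    ``flicker_freq_hz`` is 0 for single flashes.
    """

    stim_type: str
    intensity_value: float
    intensity_unit: str = "cd*s/cm^2"
    adaptation: str = "DA"
    flicker_freq_hz: float = 0.0
    background: str = ""

    def __post_init__(self) -> None:
        if self.stim_type not in STIM_TYPES:
            raise ValidationError(
                f"stim_type must be one of {STIM_TYPES}, got {self.stim_type!r}"
            )
        if self.adaptation not in ADAPTATIONS:
            raise ValidationError(
                f"adaptation must be one of {ADAPTATIONS}, got {self.adaptation!r}"
            )
        if not (self.intensity_value > 0):
            raise ValidationError("intensity_value must be > 0")
        if self.flicker_freq_hz < 0:
            raise ValidationError("flicker_freq_hz must be >= 0")
        if self.stim_type == "Flicker" and not (self.flicker_freq_hz > 0):
            raise ValidationError("Flicker stimuli require flicker_freq_hz > 0")


class TrialBlock:
    """Immutable matrix of raw trial waveforms.

    ``samples`` has shape ``(n_samples, n_trials)`` in microvolts.  The
    array is copied on construction and write-locked: processing functions
    always return new arrays, so the block a recording was imported with is
    bit-identical for the lifetime of the exam.
    """

    __slots__ = ("samples", "sampling_rate_hz", "t0_index")

    def __init__(
        self,
        samples: np.ndarray,
        sampling_rate_hz: float,
        t0_index: int = 0,
    ) -> None:
        arr = np.array(samples, dtype=np.float64, copy=True, order="C")
        if arr.ndim != 2:
            raise ValidationError(
                f"samples must be 2-D (n_samples, n_trials), got shape {arr.shape}"
            )
        n_samples, n_trials = arr.shape
        if n_trials < 1:
            raise ValidationError("at least one trial required")
        if n_samples < 2:
            raise ValidationError("at least two samples per trial required")
        if not (sampling_rate_hz > 0):
            raise ValidationError("sampling_rate_hz must be > 0")
        t0_index = int(t0_index)
        if not (0 <= t0_index < n_samples):
            raise ValidationError(
                f"t0_index {t0_index} outside [0, {n_samples})"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "sampling_rate_hz", float(sampling_rate_hz))
        object.__setattr__(self, "t0_index", t0_index)

    def __setattr__(self, name, value):  # pragma: no cover - guard
        raise AttributeError("TrialBlock is immutable")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_trials(self) -> int:
        return self.samples.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        """Time vector in seconds, 0 at stimulus onset."""
        return (np.arange(self.n_samples) - self.t0_index) / self.sampling_rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return self.times_s * 1000.0

    def copy(self) -> "TrialBlock":
        return TrialBlock(self.samples, self.sampling_rate_hz, self.t0_index)

    def with_samples(self, samples: np.ndarray) -> "TrialBlock":
        """New block with the same timing metadata and different samples."""
        return TrialBlock(samples, self.sampling_rate_hz, self.t0_index)


@dataclass
class Marker:
    """Named time–amplitude landmark on a processed trace.

    ``time_ms`` is the implicit time from stimulus onset; ``voltage_uv`` the
    absolute trace voltage at the marker.  ``relative_to`` optionally names
    another marker on the same recording that serves as amplitude reference
    (e.g. the b-wave is measured from the a-wave trough); when unset the
    pre-stimulus baseline is the reference.  ``manual`` distinguishes
    user-placed markers, which automatic placement never overwrites.
    """

    name: str
    time_ms: float
    voltage_uv: float
    relative_to: str | None = None
    manual: bool = False


@dataclass(frozen=True)
class ChangeLogEntry:
    """One append-only audit record of a mutating operation."""

    timestamp: str
    operation: str
    parameters: Mapping[str, str] = field(default_factory=dict)


@dataclass
class Recording:
    """One stimulus step: raw trials plus descriptive and processing state."""

    channel: str
    eye: str
    stimulus: StimulusDescriptor
    trials: TrialBlock
    processing: "ProcessingSpec | None" = None
    rejection_mask: np.ndarray | None = None
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValidationError(f"eye must be one of {EYES}, got {self.eye!r}")
        if not self.channel:
            raise ValidationError("channel must be non-empty")
        if self.processing is None:
            from .processing import ProcessingSpec

            self.processing = ProcessingSpec()
        if self.rejection_mask is None:
            self.rejection_mask = np.zeros(self.trials.n_trials, dtype=bool)
        else:
            mask = np.asarray(self.rejection_mask, dtype=bool)
            if mask.shape != (self.trials.n_trials,):
                raise ValidationError(
                    "rejection_mask length must equal n_trials "
                    f"({mask.shape} vs {self.trials.n_trials})"
                )
            self.rejection_mask = mask.copy()

    def get_marker(self, name: str) -> Marker | None:
        for m in self.markers:
            if m.name == name:
                return m
        return None

    def copy(self) -> "Recording":
        return Recording(
            channel=self.channel,
            eye=self.eye,
            stimulus=copy.deepcopy(self.stimulus),
            trials=self.trials.copy(),
            processing=copy.deepcopy(self.processing),
            rejection_mask=self.rejection_mask.copy(),
            markers=[copy.deepcopy(m) for m in self.markers],
        )


class Exam:
    """Ordered collection of recordings from one examination session."""

    def __init__(
        self,
        subject: SubjectInfo,
        exam_date: str,
        recordings: Sequence[Recording],
        changelog: Sequence[ChangeLogEntry] | None = None,
        format_version: str = FORMAT_VERSION,
    ) -> None:
        if not recordings:
            raise ValidationError("an exam requires at least one recording")
        self.subject = subject
        self.exam_date = str(exam_date)
        self.recordings: list[Recording] = list(recordings)
        self.changelog: list[ChangeLogEntry] = list(changelog or [])
        self.format_version = format_version

    def __len__(self) -> int:
        return len(self.recordings)

    # thin method facade over the module-level operations
    def where(self, criteria: Mapping | None = None) -> list[int]:
        return where(self, criteria)

    def subset(self, indices: Iterable[int]) -> "Exam":
        return subset(self, indices)

    def get_processed_trace(self, index: int):
        return get_processed_trace(self, index)

    def log_change(self, operation: str, parameters: Mapping | None = None) -> "Exam":
        return log_change(self, operation, parameters)


def log_change(exam: Exam, operation: str, parameters: Mapping | None = None) -> Exam:
    """Append an audit entry; called by every mutating operation."""
    if not operation:
        raise ValidationError("operation name must be non-empty")
    entry = ChangeLogEntry(
        timestamp=_dt.datetime.now().isoformat(timespec="seconds"),
        operation=operation,
        parameters={str(k): str(v) for k, v in (parameters or {}).items()},
    )
    exam.changelog.append(entry)
    return exam


def new_exam(
    subject: SubjectInfo,
    exam_date: str,
    recordings: Sequence[Recording],
) -> Exam:
    """Create an exam; logs an initial ``created`` entry."""
    exam = Exam(subject, exam_date, recordings)
    log_change(exam, "created", {"n_recordings": len(recordings)})
    return exam


_CRITERIA_KEYS = frozenset(
    {"channel", "eye", "stim_type", "adaptation", "intensity", "flicker_freq"}
)


def _in_range(value: float, criterion) -> bool:
    if isinstance(criterion, (tuple, list)) and len(criterion) == 2:
        lo, hi = criterion
        return float(lo) <= value <= float(hi)
    return value == float(criterion)


def where(exam: Exam, criteria: Mapping | None = None) -> list[int]:
    """Indices of recordings matching *all* supplied criteria.

    String criteria (``channel``, ``eye``, ``stim_type``, ``adaptation``)
    match exactly; ``intensity`` and ``flicker_freq`` accept a scalar or an
    inclusive ``(low, high)`` range.  Empty criteria match every recording.
    """
    criteria = dict(criteria or {})
    unknown = set(criteria) - _CRITERIA_KEYS
    if unknown:
        raise ValidationError(
            f"unknown criteria {sorted(unknown)}; allowed: {sorted(_CRITERIA_KEYS)}"
        )
    out = []
    for i, rec in enumerate(exam.recordings):
        ok = True
        for key, want in criteria.items():
            if key == "channel":
                ok = rec.channel == want
            elif key == "eye":
                ok = rec.eye == want
            elif key == "stim_type":
                ok = rec.stimulus.stim_type == want
            elif key == "adaptation":
                ok = rec.stimulus.adaptation == want
            elif key == "intensity":
                ok = _in_range(rec.stimulus.intensity_value, want)
            elif key == "flicker_freq":
                ok = _in_range(rec.stimulus.flicker_freq_hz, want)
            if not ok:
                break
        if ok:
            out.append(i)
    return out


def subset(exam: Exam, indices: Iterable[int]) -> Exam:
    """New exam holding deep copies of the selected recordings, in order."""
    idx = [int(i) for i in indices]
    n = len(exam.recordings)
    for i in idx:
        if not (0 <= i < n):
            raise ValidationError(f"recording index {i} out of range [0, {n})")
    if len(set(idx)) != len(idx):
        raise ValidationError("duplicate recording indices in subset")
    if not idx:
        raise EmptySelectionError("subset selected zero recordings")
    sub = Exam(
        subject=copy.deepcopy(exam.subject),
        exam_date=exam.exam_date,
        recordings=[exam.recordings[i].copy() for i in idx],
        changelog=list(exam.changelog),
        format_version=exam.format_version,
    )
    log_change(sub, "subset", {"indices": ",".join(map(str, idx))})
    return sub


def get_processed_trace(exam: Exam, index: int) -> tuple[np.ndarray, np.ndarray]:
    """Processed single trace ``(time_s, voltage_uv)`` for one recording.

    Computed on demand as averaging(rejection(filter(raw))): each trial is
    filtered per the stored :class:`FilterSpec`, the stored rejection mask is
    OR-combined with the distance-based mask when the spec enables it, and
    the kept trials are averaged.  Raw samples are never modified.
    """
    from . import processing as _proc

    rec = exam.recordings[int(index)]
    spec = rec.processing
    block = rec.trials
    mask = rec.rejection_mask.copy()

    def _apply_rejection(b: TrialBlock, m: np.ndarray) -> np.ndarray:
        if spec.rejection is not None and spec.rejection.method == "distance":
            m = m | _proc.autoreject_by_distance(b, spec.rejection)
        return m

    if spec.reject_before_filter:
        mask = _apply_rejection(block, mask)
    if spec.filter is not None:
        block = _proc.filter_bandpass(block, spec.filter)
    if not spec.reject_before_filter:
        mask = _apply_rejection(block, mask)
    if mask.all():
        raise EmptySelectionError(
            f"all {block.n_trials} trials of recording {index} are rejected"
        )
    trace = _proc.average_trials(block, mask, spec.averaging)
    return block.times_s, trace


def exams_equal(a: Exam, b: Exam) -> bool:
    """Field-wise equality: exact on strings/ints, bit-equality on arrays.

    This is the round-trip contract used by the HDF5 tests.
    """
    if (
        a.subject != b.subject
        or a.exam_date != b.exam_date
        or a.format_version != b.format_version
        or len(a.recordings) != len(b.recordings)
        or list(a.changelog) != list(b.changelog)
    ):
        return False
    for ra, rb in zip(a.recordings, b.recordings):
        if (
            ra.channel != rb.channel
            or ra.eye != rb.eye
            or ra.stimulus != rb.stimulus
            or ra.processing != rb.processing
            or ra.markers != rb.markers
        ):
            return False
        if ra.trials.sampling_rate_hz != rb.trials.sampling_rate_hz:
            return False
        if ra.trials.t0_index != rb.trials.t0_index:
            return False
        if ra.trials.samples.shape != rb.trials.samples.shape:
            return False
        if not np.array_equal(ra.trials.samples, rb.trials.samples):
            return False
        if not np.array_equal(ra.rejection_mask, rb.rejection_mask):
            return False
    return True
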