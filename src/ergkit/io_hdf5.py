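"""Self-documenting HDF5 persistence and generic CSV import.

The on-disk layout mirrors the in-memory exam so that the files stay
readable with any generic HDF5 tool, long after this package:

.. code-block:: text

    /                      attrs: format_version, description
    /subject               attrs: subject_id, species, group_label, dob
    /exam                  attrs: exam_date
    /changelog             table (timestamp, operation, parameters JSON)
    /recordings/0000/
        raw                n_samples × n_trials float64
                           attrs: sampling_rate_hz, t0_index, unit="uV"
        rejection_mask     boolean vector
        markers            table (name, time_ms, voltage_uv, relative_to, manual)
        stimulus/          attrs: stim_type, intensity_value, intensity_unit,
                                  adaptation, flicker_freq_hz, background
        processing/        attrs: spec (JSON)

Only raw trials plus declarative processing specs are stored — never
pipeline-derived averages — so the lazy-processing philosophy survives on
disk.  Unknown extra attributes are ignored on load (forward compatible).
Writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError, VersionError
from .model import (
    ChangeLogEntry,
    Exam,
    Marker,
    Recording,
    StimulusDescriptor,
    SubjectInfo,
    TrialBlock,
)
from .processing import ProcessingSpec

__all__ = ["save", "load", "import_csv", "exam_to_csv"]

_STR = h5py.string_dtype(encoding="utf-8")

_CHANGELOG_DTYPE = np.dtype(
    [("timestamp", _STR), ("operation", _STR), ("parameters", _STR)]
)
_MARKER_DTYPE = np.dtype(
    [
        ("name", _STR),
        ("time_ms", "f8"),
        ("voltage_uv", "f8"),
        ("relative_to", _STR),
        ("manual", "u1"),
    ]
)


def save(exam: Exam, path: str | os.PathLike) -> Path:
    """Write the exam to an HDF5 file; overwrites atomically."""
    path = Path(path)
    tmp = path.with_name(path.name + f".tmp-{os.getpid()}")
    try:
        with h5py.File(tmp, "w") as f:
            f.attrs["format_version"] = exam.format_version
            f.attrs["description"] = (
                "Visual electrophysiology exam: raw trials with declarative "
                "processing specifications (ergkit layout)"
            )
            g = f.create_group("subject")
            g.attrs["description"] = "Subject identity and cohort metadata"
            g.attrs["subject_id"] = exam.subject.subject_id
            g.attrs["species"] = exam.subject.species
            g.attrs["group_label"] = exam.subject.group_label
            g.attrs["dob"] = exam.subject.dob
            g.attrs["eye_context"] = exam.subject.eye_context

            g = f.create_group("exam")
            g.attrs["description"] = "Examination session metadata"
            g.attrs["exam_date"] = exam.exam_date

            log = np.empty(len(exam.changelog), dtype=_CHANGELOG_DTYPE)
            for i, e in enumerate(exam.changelog):
                log[i] = (e.timestamp, e.operation, json.dumps(dict(e.parameters)))
            d = f.create_dataset("changelog", data=log)
            d.attrs["description"] = "Append-only audit log of all mutations"

            recs = f.create_group("recordings")
            recs.attrs["description"] = "One subgroup per recording, in exam order"
            for i, rec in enumerate(exam.recordings):
                rg = recs.create_group(f"{i:04d}")
                rg.attrs["description"] = "Single stimulus step"
                rg.attrs["channel"] = rec.channel
                rg.attrs["eye"] = rec.eye

                raw = rg.create_dataset("raw", data=rec.trials.samples)
                raw.attrs["description"] = "Raw trial matrix, n_samples x n_trials"
                raw.attrs["sampling_rate_hz"] = rec.trials.sampling_rate_hz
                raw.attrs["t0_index"] = rec.trials.t0_index
                raw.attrs["unit"] = "uV"

                sg = rg.create_group("stimulus")
                sg.attrs["description"] = "Stimulus descriptor"
                sg.attrs["stim_type"] = rec.stimulus.stim_type
                sg.attrs["intensity_value"] = rec.stimulus.intensity_value
                sg.attrs["intensity_unit"] = rec.stimulus.intensity_unit
                sg.attrs["adaptation"] = rec.stimulus.adaptation
                sg.attrs["flicker_freq_hz"] = rec.stimulus.flicker_freq_hz
                sg.attrs["background"] = rec.stimulus.background

                pg = rg.create_group("processing")
                pg.attrs["description"] = "Declarative processing spec (JSON)"
                pg.attrs["spec"] = rec.processing.to_json()

                m = rg.create_dataset(
                    "rejection_mask", data=rec.rejection_mask.astype(bool)
                )
                m.attrs["description"] = "True = trial rejected"

                mk = np.empty(len(rec.markers), dtype=_MARKER_DTYPE)
                for j, marker in enumerate(rec.markers):
                    mk[j] = (
                        marker.name,
                        marker.time_ms,
                        marker.voltage_uv,
                        marker.relative_to or "",
                        1 if marker.manual else 0,
                    )
                md = rg.create_dataset("markers", data=mk)
                md.attrs["description"] = "Named time-amplitude landmarks"
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()
    return path


def _require(node, key: str, path: str):
    if key not in node:
        raise FormatError(f"missing required HDF5 entry: {path}/{key}")
    return node[key]


def _attr(node, key: str, path: str):
    if key not in node.attrs:
        raise FormatError(f"missing required HDF5 attribute: {path}@{key}")
    val = node.attrs[key]
    return val.decode() if isinstance(val, bytes) else val


def load(path: str | os.PathLike) -> Exam:
    """Read an exam saved by :func:`save`; round-trips exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        version = _attr(f, "format_version", "/")
        if not str(version).startswith("1."):
            raise VersionError(f"unsupported format_version {version!r}")

        sg = _require(f, "subject", "")
        subject = SubjectInfo(
            subject_id=_attr(sg, "subject_id", "/subject"),
            species=str(sg.attrs.get("species", "")),
            group_label=str(sg.attrs.get("group_label", "")),
            dob=str(sg.attrs.get("dob", "")),
            eye_context=str(sg.attrs.get("eye_context", "")),
        )
        exam_date = _attr(_require(f, "exam", ""), "exam_date", "/exam")

        changelog = []
        for row in np.asarray(_require(f, "changelog", "")):
            params = json.loads(_as_str(row["parameters"]) or "{}")
            changelog.append(
                ChangeLogEntry(_as_str(row["timestamp"]), _as_str(row["operation"]), params)
            )

        recs_group = _require(f, "recordings", "")
        recordings = []
        for name in sorted(recs_group.keys()):
            rg = recs_group[name]
            rpath = f"/recordings/{name}"
            raw = _require(rg, "raw", rpath)
            trials = TrialBlock(
                np.asarray(raw),
                sampling_rate_hz=float(_attr(raw, "sampling_rate_hz", rpath + "/raw")),
                t0_index=int(_attr(raw, "t0_index", rpath + "/raw")),
            )
            sg = _require(rg, "stimulus", rpath)
            stimulus = StimulusDescriptor(
                stim_type=_attr(sg, "stim_type", rpath + "/stimulus"),
                intensity_value=float(_attr(sg, "intensity_value", rpath + "/stimulus")),
                intensity_unit=str(sg.attrs.get("intensity_unit", "")),
                adaptation=str(sg.attrs.get("adaptation", "DA")),
                flicker_freq_hz=float(sg.attrs.get("flicker_freq_hz", 0.0)),
                background=str(sg.attrs.get("background", "")),
            )
            pg = _require(rg, "processing", rpath)
            spec = ProcessingSpec.from_json(_attr(pg, "spec", rpath + "/processing"))
            mask = np.asarray(_require(rg, "rejection_mask", rpath), dtype=bool)
            markers = []
            for row in np.asarray(_require(rg, "markers", rpath)):
                rel = _as_str(row["relative_to"])
                markers.append(
                    Marker(
                        name=_as_str(row["name"]),
                        time_ms=float(row["time_ms"]),
                        voltage_uv=float(row["voltage_uv"]),
                        relative_to=rel or None,
                        manual=bool(row["manual"]),
                    )
                )
            recordings.append(
                Recording(
                    channel=_attr(rg, "channel", rpath),
                    eye=_attr(rg, "eye", rpath),
                    stimulus=stimulus,
                    trials=trials,
                    processing=spec,
                    rejection_mask=mask,
                    markers=markers,
                )
            )
    return Exam(
        subject=subject,
        exam_date=str(exam_date),
        recordings=recordings,
        changelog=changelog,
        format_version=str(version),
    )


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


# ---------------------------------------------------------------------------
# generic long-format CSV import

DEFAULT_SCHEMA: dict = {
    "columns": {
        "time_s": "time_s",
        "voltage": "voltage_uv",
        "trial": "trial",
        "channel": "channel",
        "eye": "eye",
        "stim_type": "stim_type",
        "intensity": "intensity",
        "adaptation": "adaptation",
        "flicker_freq_hz": "flicker_freq_hz",
    },
    "voltage_unit": "uV",
    "intensity_unit": "cd*s/cm^2",
    "separator": ",",
}

_VOLT_FACTORS = {"uV": 1.0, "mV": 1e3, "V": 1e6}

_GROUP_KEYS = ["channel", "eye", "stim_type", "intensity", "adaptation", "flicker_freq_hz"]


def import_csv(
    path: str | os.PathLike,
    schema_config: Mapping | str | os.PathLike | None = None,
    subject: SubjectInfo | None = None,
    exam_date: str = "",
) -> Exam:
    """Assemble an exam from a long-format CSV (one row per sample per trial).

    ``schema_config`` (dict, or path to a YAML/JSON file) maps the logical
    columns onto the file's column names and declares the source voltage
    unit; see ``DEFAULT_SCHEMA``.  Rows are grouped into recordings on
    (channel, eye, stimulus fields); trials within a recording must share
    the sample grid.
    """
    schema = dict(DEFAULT_SCHEMA)
    if schema_config is not None:
        if isinstance(schema_config, (str, os.PathLike)):
            import yaml

            with open(schema_config) as fh:
                user = yaml.safe_load(fh) or {}
        else:
            user = dict(schema_config)
        cols = {**DEFAULT_SCHEMA["columns"], **user.get("columns", {})}
        schema.update(user)
        schema["columns"] = cols

    cols = schema["columns"]
    factor = _VOLT_FACTORS.get(schema.get("voltage_unit", "uV"))
    if factor is None:
        raise ValidationError(
            f"unsupported voltage_unit {schema.get('voltage_unit')!r}"
        )

    # round_trip parsing keeps voltages bit-exact through a text cycle
    df = pd.read_csv(path, sep=schema.get("separator", ","), float_precision="round_trip")
    required = ["time_s", "voltage", "trial", "channel", "eye", "stim_type", "intensity", "adaptation"]
    for logical in required:
        if cols[logical] not in df.columns:
            raise FormatError(
                f"CSV is missing mapped column {cols[logical]!r} (for {logical!r})"
            )
    rename = {v: k for k, v in cols.items() if v in df.columns}
    df = df.rename(columns=rename)
    if "flicker_freq_hz" not in df.columns:
        df["flicker_freq_hz"] = 0.0

    recordings = []
    # preserve first-appearance order of groups
    df["_order"] = np.arange(len(df))
    grouped = sorted(
        df.groupby(_GROUP_KEYS, sort=False),
        key=lambda kv: kv[1]["_order"].iloc[0],
    )
    for key, g in grouped:
        channel, eye, stim_type, intensity, adaptation, flicker = key
        counts = g.groupby("trial").size()
        if counts.nunique() != 1:
            bad = counts[counts != counts.mode().iloc[0]]
            raise ValidationError(
                "ragged trials in recording "
                f"{dict(zip(_GROUP_KEYS, key))}: trial(s) "
                f"{list(bad.index)} have {list(bad.values)} samples, "
                f"expected {int(counts.mode().iloc[0])}"
            )
        trial_ids = sorted(g["trial"].unique())
        first = g[g["trial"] == trial_ids[0]].sort_values("time_s")
        t = first["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        # rounding kills the last-ulp noise of differencing textual times
        fs = float(np.round(1.0 / np.median(dt), 6))
        t0_index = int(np.count_nonzero(t < 0))
        mat = np.column_stack(
            [
                g[g["trial"] == tid].sort_values("time_s")["voltage"].to_numpy(dtype=float)
                for tid in trial_ids
            ]
        )
        recordings.append(
            Recording(
                channel=str(channel),
                eye=str(eye),
                stimulus=StimulusDescriptor(
                    stim_type=str(stim_type),
                    intensity_value=float(intensity),
                    intensity_unit=schema.get("intensity_unit", ""),
                    adaptation=str(adaptation),
                    flicker_freq_hz=float(flicker),
                ),
                trials=TrialBlock(mat * factor, sampling_rate_hz=fs, t0_index=t0_index),
            )
        )
    if not recordings:
        raise ValidationError("CSV produced no recordings")
    exam = Exam(
        subject=subject or SubjectInfo(subject_id=Path(path).stem),
        exam_date=exam_date,
        recordings=recordings,
    )
    from .model import log_change

    log_change(exam, "import_csv", {"path": str(path)})
    return exam


def exam_to_csv(exam: Exam, path: str | os.PathLike) -> Path:
    """Write an exam's raw trials to the importable long CSV dialect."""
    frames = []
    for rec in exam.recordings:
        t = rec.trials.times_s
        for j in range(rec.trials.n_trials):
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "voltage_uv": rec.trials.samples[:, j],
                        "trial": j,
                        "channel": rec.channel,
                        "eye": rec.eye,
                        "stim_type": rec.stimulus.stim_type,
                        "intensity": rec.stimulus.intensity_value,
                        "adaptation": rec.stimulus.adaptation,
                        "flicker_freq_hz": rec.stimulus.flicker_freq_hz,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)
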