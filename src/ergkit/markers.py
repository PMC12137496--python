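"""Wave marker placement and the measurements table.

Automatic placement follows standard clinical measurement conventions,
keyed on the recording channel and stimulus type:

* Flash ERG — the a-wave is the trace minimum in (0, 50] ms after the
  flash, the b-wave the subsequent maximum in (t_a, 300] ms, with its
  amplitude measured from the a-trough.
* Flicker ERG — after skipping the first stimulus cycle (onset transient),
  the dominant peak (P1) within the steady-state window and the trough
  preceding it within one period (T1); peak-to-trough amplitude.
* OP channel — local maxima of the high-pass-extracted oscillations between
  the a-trough and b-peak times, prominence ≥ 10 % of the largest, named
  OP1..OPn in time order.
* VEP — N1 is the first prominent minimum in (0, 100] ms, P1 the subsequent
  maximum in (N1, 200] ms.

All windows are configurable via :class:`MarkerConfig` (defaults are
mouse-like).  Amplitudes are reported signed: voltage at the marker minus
voltage at its reference marker, or minus the pre-stimulus baseline (mean
over [−20, 0) ms) when no reference is set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import ValidationError
from .model import Exam, Marker, Recording, get_processed_trace, log_change
from .processing import average_trials

__all__ = [
    "Marker",
    "MarkerConfig",
    "auto_place_markers",
    "place_marker",
    "measurements",
    "intensity_sequence",
    "MEASUREMENT_COLUMNS",
]


@dataclass(frozen=True)
class MarkerConfig:
    """Search windows (ms) for automatic marker placement."""

    a_window_ms: tuple[float, float] = (0.0, 50.0)
    b_window_end_ms: float = 300.0
    baseline_window_ms: float = 20.0
    op_prominence_frac: float = 0.10
    op_max_count: int = 10
    vep_n1_window_ms: tuple[float, float] = (0.0, 100.0)
    vep_p1_end_ms: float = 200.0


DEFAULT_CONFIG = MarkerConfig()


def _window_mask(t_ms: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Half-open (lo, hi] window on the time axis."""
    return (t_ms > lo) & (t_ms <= hi)


def _extremum(t_ms, v, mask, mode) -> tuple[float, float] | None:
    """Earliest-time extremum of v within mask; None if window is empty."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    vals = v[idx]
    k = idx[int(np.argmin(vals) if mode == "min" else np.argmax(vals))]
    return float(t_ms[k]), float(v[k])


def baseline_voltage(
    rec: Recording, trace: np.ndarray, config: MarkerConfig = DEFAULT_CONFIG
) -> float:
    """Mean voltage over the pre-stimulus interval [−window, 0) ms."""
    t_ms = rec.trials.times_ms
    sel = (t_ms >= -config.baseline_window_ms) & (t_ms < 0)
    if not sel.any():
        sel = t_ms < 0
    if not sel.any():
        return 0.0
    return float(trace[sel].mean())


def _flash_erg_markers(t_ms, v, config: MarkerConfig) -> list[Marker]:
    a = _extremum(t_ms, v, _window_mask(t_ms, *config.a_window_ms), "min")
    if a is None:
        return []
    out = [Marker("a", a[0], a[1])]
    b = _extremum(t_ms, v, _window_mask(t_ms, a[0], config.b_window_end_ms), "max")
    if b is not None:
        out.append(Marker("B", b[0], b[1], relative_to="a"))
    return out


def _flicker_markers(t_ms, v, freq_hz: float) -> list[Marker]:
    period_ms = 1000.0 / freq_hz
    # steady state: skip the first stimulus cycle after onset
    mask = t_ms > period_ms
    p = _extremum(t_ms, v, mask, "max")
    if p is None:
        return []
    trough = _extremum(t_ms, v, _window_mask(t_ms, p[0] - period_ms, p[0]), "min")
    out = []
    if trough is not None:
        out.append(Marker("T1", trough[0], trough[1]))
        out.append(Marker("P1", p[0], p[1], relative_to="T1"))
    else:
        out.append(Marker("P1", p[0], p[1]))
    return out


def _op_markers(rec: Recording, t_ms, v, config: MarkerConfig) -> list[Marker]:
    # locate the a-trough/b-peak interval on the broadband (unfiltered) average
    broadband = average_trials(rec.trials, rec.rejection_mask)
    a = _extremum(t_ms, broadband, _window_mask(t_ms, *config.a_window_ms), "min")
    if a is None:
        return []
    b = _extremum(t_ms, broadband, _window_mask(t_ms, a[0], config.b_window_end_ms), "max")
    if b is None:
        return []
    sel = (t_ms >= a[0]) & (t_ms <= b[0])
    idx = np.flatnonzero(sel)
    if idx.size < 3:
        return []
    seg = v[idx]
    peaks, props = find_peaks(seg, prominence=0.0)
    if peaks.size == 0:
        return []
    keep = props["prominences"] >= config.op_prominence_frac * props["prominences"].max()
    peaks = peaks[keep][: config.op_max_count]
    return [
        Marker(f"OP{j + 1}", float(t_ms[idx[p]]), float(v[idx[p]]))
        for j, p in enumerate(peaks)
    ]


def _vep_markers(t_ms, v, config: MarkerConfig) -> list[Marker]:
    n1 = _extremum(t_ms, v, _window_mask(t_ms, *config.vep_n1_window_ms), "min")
    if n1 is None:
        return []
    out = [Marker("N1", n1[0], n1[1])]
    p1 = _extremum(t_ms, v, _window_mask(t_ms, n1[0], config.vep_p1_end_ms), "max")
    if p1 is not None:
        out.append(Marker("P1", p1[0], p1[1], relative_to="N1"))
    return out


def auto_place_markers(exam: Exam, config: MarkerConfig = DEFAULT_CONFIG) -> Exam:
    """Place markers on every recording by its channel/stimulus rule.

    Previously auto-placed markers are replaced; manual markers are kept.
    Recordings whose epoch is shorter than the search windows get a warning
    and no markers.
    """
    for i, rec in enumerate(exam.recordings):
        try:
            _, trace = get_processed_trace(exam, i)
        except Exception as exc:
            warnings.warn(f"recording {i}: no processed trace ({exc})", stacklevel=2)
            continue
        t_ms = rec.trials.times_ms
        if rec.channel == "OP":
            new = _op_markers(rec, t_ms, trace, config)
        elif rec.channel == "VEP":
            new = _vep_markers(t_ms, trace, config)
        elif rec.stimulus.stim_type == "Flicker":
            new = _flicker_markers(t_ms, trace, rec.stimulus.flicker_freq_hz)
        else:
            new = _flash_erg_markers(t_ms, trace, config)
        if not new:
            warnings.warn(
                f"recording {i}: epoch too short for marker windows", stacklevel=2
            )
        manual = [m for m in rec.markers if m.manual]
        manual_names = {m.name for m in manual}
        rec.markers = manual + [m for m in new if m.name not in manual_names]
    log_change(exam, "auto_place_markers", {})
    return exam


def place_marker(
    exam: Exam,
    recording_index: int,
    name: str,
    time_ms: float,
    relative_to: str | None = None,
) -> Exam:
    """Manually place a marker; voltage read at the nearest sample."""
    rec = exam.recordings[int(recording_index)]
    t_ms = rec.trials.times_ms
    if not (t_ms[0] <= time_ms <= t_ms[-1]):
        raise ValidationError(
            f"time {time_ms} ms outside the recorded epoch "
            f"[{t_ms[0]:.1f}, {t_ms[-1]:.1f}] ms"
        )
    if relative_to is not None and rec.get_marker(relative_to) is None:
        raise ValidationError(f"reference marker {relative_to!r} does not exist")
    k = int(np.argmin(np.abs(t_ms - time_ms)))
    _, trace = get_processed_trace(exam, recording_index)
    marker = Marker(name, float(t_ms[k]), float(trace[k]), relative_to, manual=True)
    rec.markers = [m for m in rec.markers if m.name != name] + [marker]
    log_change(
        exam,
        "place_marker",
        {"recording": recording_index, "name": name, "time_ms": time_ms},
    )
    return exam


MEASUREMENT_COLUMNS = [
    "subject_id",
    "recording_index",
    "channel",
    "eye",
    "stim_type",
    "adaptation",
    "intensity_value",
    "marker_name",
    "implicit_time_ms",
    "amplitude_uv",
]


def measurements(exam: Exam, config: MarkerConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Flat table with one row per (recording, marker).

    Amplitude is the marker voltage minus its reference marker's voltage,
    or minus the pre-stimulus baseline when no reference is set.  Rows are
    ordered by recording index, then marker time.  A pure function of the
    exam state.
    """
    rows = []
    for i, rec in enumerate(exam.recordings):
        if not rec.markers:
            continue
        trace = None
        for m in sorted(rec.markers, key=lambda m: m.time_ms):
            if m.relative_to is not None:
                ref = rec.get_marker(m.relative_to)
                if ref is None:
                    raise ValidationError(
                        f"marker {m.name!r} references missing {m.relative_to!r}"
                    )
                ref_v = ref.voltage_uv
            else:
                if trace is None:
                    _, trace = get_processed_trace(exam, i)
                ref_v = baseline_voltage(rec, trace, config)
            rows.append(
                {
                    "subject_id": exam.subject.subject_id,
                    "recording_index": i,
                    "channel": rec.channel,
                    "eye": rec.eye,
                    "stim_type": rec.stimulus.stim_type,
                    "adaptation": rec.stimulus.adaptation,
                    "intensity_value": rec.stimulus.intensity_value,
                    "marker_name": m.name,
                    "implicit_time_ms": m.time_ms,
                    "amplitude_uv": m.voltage_uv - ref_v,
                }
            )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def intensity_sequence(
    tables: list[pd.DataFrame],
    marker_name: str,
    group_by: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Stimulus–response summary across subjects.

    Aggregates marker amplitudes per (group, adaptation, intensity) into
    n, mean, SD and SEM, sorted by ascending intensity.  ``group_by`` maps
    subject_id to a cohort label; unmapped subjects fall into ``"all"``.
    SD/SEM are NaN for n = 1.
    """
    if not tables:
        return pd.DataFrame(
            columns=["group", "adaptation", "intensity_value", "n", "mean_uv", "sd_uv", "sem_uv"]
        )
    df = pd.concat(tables, ignore_index=True)
    df = df[df["marker_name"] == marker_name].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["group", "adaptation", "intensity_value", "n", "mean_uv", "sd_uv", "sem_uv"]
        )
    group_by = group_by or {}
    df["group"] = df["subject_id"].map(lambda s: group_by.get(s, "all"))
    out = (
        df.groupby(["group", "adaptation", "intensity_value"])["amplitude_uv"]
        .agg(n="count", mean_uv="mean", sd_uv=lambda x: x.std(ddof=1))
        .reset_index()
    )
    out["sem_uv"] = out["sd_uv"] / np.sqrt(out["n"])
    out = out.sort_values(
        ["group", "adaptation", "intensity_value"], kind="stable"
    ).reset_index(drop=True)
    return out
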