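"""Static figure rendering.

Non-interactive matplotlib plots of processed traces and stimulus–response
summaries: one-exam overviews panelled by adaptation state with traces
colour-coded by log10 stimulus strength, multi-exam grids panelled subject
× stimulus condition, and intensity-series plots of mean ± SEM marker
amplitudes.  Rendering never alters the exam, and vector output is
byte-reproducible for fixed inputs (fixed SVG hash salt, no embedded
timestamps).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .exceptions import EmptySelectionError, ValidationError
from .model import Exam, where

__all__ = ["plot_exam", "plot_recordings", "plot_intensity_sequence"]

plt.rcParams["svg.hashsalt"] = "ergkit"

_FORMATS = ("png", "svg", "pdf")


def _check_path(path: str) -> Path:
    p = Path(path)
    if p.suffix.lstrip(".").lower() not in _FORMATS:
        raise ValidationError(f"output format must be one of {_FORMATS}")
    return p


def _save(fig, path: Path) -> Path:
    kwargs = {"metadata": {"Date": None}} if path.suffix == ".svg" else {}
    fig.savefig(path, **kwargs)
    plt.close(fig)
    return path


def _intensity_colors(intensities: np.ndarray):
    logi = np.log10(intensities)
    lo, hi = logi.min(), logi.max()
    span = hi - lo if hi > lo else 1.0
    cmap = plt.get_cmap("viridis")
    return [cmap(0.15 + 0.8 * (x - lo) / span) for x in logi]


def plot_exam(exam: Exam, path: str) -> Path:
    """One panel per adaptation state; traces colour-coded by intensity."""
    path = _check_path(path)
    adaptations = sorted({r.stimulus.adaptation for r in exam.recordings})
    fig, axes = plt.subplots(
        1, len(adaptations), figsize=(4.5 * len(adaptations), 3.5), squeeze=False
    )
    intensities = np.array([r.stimulus.intensity_value for r in exam.recordings])
    colors = _intensity_colors(intensities)
    for ax, adapt in zip(axes[0], adaptations):
        for i in where(exam, {"adaptation": adapt}):
            rec = exam.recordings[i]
            t, v = exam.get_processed_trace(i)
            ax.plot(
                t * 1000.0,
                v,
                color=colors[i],
                lw=1.0,
                label=f"{rec.stimulus.intensity_value:g} {rec.stimulus.intensity_unit}",
            )
        ax.set_title(adapt)
        ax.set_xlabel("time [ms]")
        ax.set_ylabel("voltage [µV]")
        ax.legend(fontsize=6, frameon=False)
    fig.suptitle(f"{exam.subject.subject_id}  {exam.exam_date}")
    fig.tight_layout()
    return _save(fig, path)


def _condition_label(rec) -> str:
    s = rec.stimulus
    lbl = f"{s.adaptation} {s.stim_type} {s.intensity_value:g}"
    if s.flicker_freq_hz:
        lbl += f" @{s.flicker_freq_hz:g}Hz"
    return lbl


def plot_recordings(exams: list[Exam], path: str, criteria: dict | None = None) -> Path:
    """Grid of traces: stimulus conditions as rows, subjects as columns."""
    if not exams:
        raise ValidationError("need at least one exam")
    path = _check_path(path)
    selected = []  # (subject, condition, exam, index)
    for exam in exams:
        for i in where(exam, criteria or {}):
            selected.append(
                (exam.subject.subject_id, _condition_label(exam.recordings[i]), exam, i)
            )
    if not selected:
        raise EmptySelectionError("criteria matched no recordings")
    subjects = sorted({s for s, *_ in selected})
    conditions = sorted({c for _, c, *_ in selected})
    fig, axes = plt.subplots(
        len(conditions),
        len(subjects),
        figsize=(3.0 * len(subjects), 2.2 * len(conditions)),
        squeeze=False,
        sharex=True,
    )
    pos = {(c, s): axes[ci][si] for ci, c in enumerate(conditions) for si, s in enumerate(subjects)}
    for subj, cond, exam, i in selected:
        ax = pos[(cond, subj)]
        t, v = exam.get_processed_trace(i)
        ax.plot(t * 1000.0, v, color="k", lw=0.9)
    for si, s in enumerate(subjects):
        axes[0][si].set_title(s, fontsize=8)
    for ci, c in enumerate(conditions):
        axes[ci][0].set_ylabel(c, fontsize=7)
    for ax in axes[-1]:
        ax.set_xlabel("time [ms]", fontsize=7)
    fig.tight_layout()
    return _save(fig, path)


def plot_intensity_sequence(
    summary: pd.DataFrame, path: str, error_bars: str = "sem"
) -> Path:
    """Mean ± SEM marker amplitude vs log10 intensity, one series per group.

    ``summary`` is the output of :func:`ergkit.markers.intensity_sequence`
    (optionally concatenated over several markers with a ``marker`` column).
    """
    if summary.empty:
        raise ValidationError("summary table is empty")
    path = _check_path(path)
    df = summary.copy()
    if "marker" not in df.columns:
        df["marker"] = ""
    err_col = {"sem": "sem_uv", "sd": "sd_uv"}[error_bars]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for (group, marker), g in df.groupby(["group", "marker"]):
        g = g.sort_values("intensity_value")
        label = f"{group} {marker}".strip()
        x = np.log10(g["intensity_value"])
        err = g[err_col].to_numpy()
        if np.isnan(err).all():
            ax.plot(x, g["mean_uv"], marker="o", label=label)
        else:
            ax.errorbar(x, g["mean_uv"], yerr=err, marker="o", capsize=2, label=label)
    ax.set_xlabel("log10 intensity")
    ax.set_ylabel("amplitude [µV]")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    return _save(fig, path)
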