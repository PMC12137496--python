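"""Seeded generator of physiologically shaped synthetic exams.

The flash template is a sum of two unimodal gamma-shaped kernels — a fast
negative deflection (a-wave, photoreceptor-driven) and a slower positive
one (b-wave, bipolar-cell-driven) — plus optionally a burst of ~120 Hz
oscillatory potentials windowed onto the rising b-wave.  The kernels are
reparameterized by their peak time with unit height, so landmark times are
exact by construction; the recorded ground truth nevertheless reports the
numerically exact extrema of the sampled template, which is what a marker
detector can recover.  Trials are the template plus i.i.d. Gaussian noise
from one seeded generator per call; no global random state is touched.

Default parameters are mouse-like (a-trough 15 ms, b-peak 50 ms, 300 ms
epoch at 1 kHz with 20 ms pre-stimulus baseline).  What the generator does
NOT emulate: baseline drift, line-noise, electrode impedance changes,
inter-trial latency jitter or photoreceptor adaptation between trials —
real recordings are messier than these fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model import (
    Exam,
    Recording,
    StimulusDescriptor,
    SubjectInfo,
    TrialBlock,
    new_exam,
)

__all__ = [
    "FlashERGParams",
    "ArtifactSpec",
    "synth_flash_erg",
    "inject_artifact",
    "synth_flicker",
    "synth_exam",
    "synth_cohort",
    "DEFAULT_PROTOCOL",
]


def gamma_kernel(t_ms: np.ndarray, peak_ms: float, shape: float) -> np.ndarray:
    """Unimodal kernel with unit height peaking exactly at ``peak_ms``.

    ``g(t) = (t/tp)^k · exp(k·(1 − t/tp))`` for t > 0, else 0: a gamma
    density re-scaled to height 1 at its mode, rising faster than it
    decays.  Larger ``shape`` narrows the kernel.
    """
    g = np.zeros_like(t_ms, dtype=float)
    pos = t_ms > 0
    r = t_ms[pos] / peak_ms
    g[pos] = np.exp(shape * (np.log(r) + 1.0 - r))
    return g


@dataclass(frozen=True)
class FlashERGParams:
    """Flash-ERG template and trial-noise parameters (µV, ms, Hz)."""

    a_amp_uv: float = 150.0
    a_peak_ms: float = 15.0
    b_amp_uv: float = 300.0
    b_peak_ms: float = 50.0
    op_amp_uv: float = 0.0
    op_freq_hz: float = 120.0
    noise_sd_uv: float = 10.0
    fs_hz: float = 1000.0
    epoch_ms: float = 300.0
    pre_stim_ms: float = 20.0
    n_trials: int = 10
    seed: int = 0
    a_shape: float = 30.0
    b_shape: float = 20.0

    def __post_init__(self) -> None:
        if not (self.a_amp_uv > 0 and self.b_amp_uv > 0):
            raise ValidationError("a_amp_uv and b_amp_uv must be > 0")
        if not (self.b_peak_ms > self.a_peak_ms > 0):
            raise ValidationError("need 0 < a_peak_ms < b_peak_ms")
        if not (self.b_peak_ms < self.epoch_ms):
            raise ValidationError("b_peak_ms must lie inside the epoch")
        if self.op_amp_uv < 0 or self.noise_sd_uv < 0:
            raise ValidationError("amplitudes and noise SD must be >= 0")
        if not (self.op_freq_hz < self.fs_hz / 2):
            raise ValidationError("op_freq_hz must be below Nyquist")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")


@dataclass(frozen=True)
class ArtifactSpec:
    """Deterministic corruption of one trial (outlier plant)."""

    kind: str  # inverted | flatline | scaled
    trial_index: int
    scale: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("inverted", "flatline", "scaled"):
            raise ValidationError("artifact kind must be inverted|flatline|scaled")


def flash_template(params: FlashERGParams) -> tuple[np.ndarray, np.ndarray]:
    """(time_ms, template_uv) for the noise-free flash waveform."""
    n_pre = int(round(params.pre_stim_ms * params.fs_hz / 1000.0))
    n_total = int(round(params.epoch_ms * params.fs_hz / 1000.0)) + n_pre
    t_ms = (np.arange(n_total) - n_pre) * 1000.0 / params.fs_hz
    v = -params.a_amp_uv * gamma_kernel(t_ms, params.a_peak_ms, params.a_shape)
    v = v + params.b_amp_uv * gamma_kernel(t_ms, params.b_peak_ms, params.b_shape)
    if params.op_amp_uv > 0:
        center = 0.5 * (params.a_peak_ms + params.b_peak_ms)
        width = (params.b_peak_ms - params.a_peak_ms) / 4.0
        window = np.exp(-0.5 * ((t_ms - center) / width) ** 2)
        v = v + params.op_amp_uv * window * np.sin(
            2 * np.pi * params.op_freq_hz * t_ms / 1000.0
        )
    return t_ms, v


def _template_truth(t_ms: np.ndarray, v: np.ndarray, params: FlashERGParams) -> dict:
    """Exact extrema of the sampled template: the recoverable ground truth."""
    a_sel = (t_ms > 0) & (t_ms <= max(50.0, params.a_peak_ms * 2))
    ia = np.flatnonzero(a_sel)[np.argmin(v[a_sel])]
    b_sel = t_ms > t_ms[ia]
    ib = np.flatnonzero(b_sel)[np.argmax(v[b_sel])]
    return {
        "a_time_ms": float(t_ms[ia]),
        "a_voltage_uv": float(v[ia]),
        "a_amplitude_uv": float(v[ia]),  # baseline of the template is 0
        "b_time_ms": float(t_ms[ib]),
        "b_voltage_uv": float(v[ib]),
        "b_amplitude_uv": float(v[ib] - v[ia]),
    }


def synth_flash_erg(params: FlashERGParams | None = None, **kw) -> tuple[TrialBlock, dict]:
    """Generate one flash-ERG trial block and its ground-truth record."""
    params = replace(params, **kw) if params is not None else FlashERGParams(**kw)
    t_ms, template = flash_template(params)
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd_uv, size=(t_ms.size, params.n_trials))
    trials = template[:, None] + noise
    n_pre = int(round(params.pre_stim_ms * params.fs_hz / 1000.0))
    block = TrialBlock(trials, sampling_rate_hz=params.fs_hz, t0_index=n_pre)
    truth = _template_truth(t_ms, template, params)
    truth["template"] = template
    truth["params"] = params
    return block, truth


def inject_artifact(block: TrialBlock, spec: ArtifactSpec) -> TrialBlock:
    """Replace one trial by its corrupted version; other trials untouched."""
    if not (0 <= spec.trial_index < block.n_trials):
        raise ValidationError(
            f"trial_index {spec.trial_index} out of range [0, {block.n_trials})"
        )
    samples = block.samples.copy()
    col = samples[:, spec.trial_index]
    if spec.kind == "inverted":
        samples[:, spec.trial_index] = -col
    elif spec.kind == "flatline":
        samples[:, spec.trial_index] = 0.0
    else:
        samples[:, spec.trial_index] = spec.scale * col
    return block.with_samples(samples)


def synth_flicker(
    stim_freq_hz: float = 9.0,
    fund_amp_uv: float = 20.0,
    harmonic_amps: tuple[float, ...] = (),
    noise_sd_uv: float = 0.0,
    fs_hz: float = 1000.0,
    dur_s: float = 1.0,
    n_trials: int = 10,
    seed: int = 0,
    phase_rad: float = 0.0,
) -> tuple[TrialBlock, dict]:
    """Steady-state flicker response: fundamental + harmonics + noise.

    ``phase_rad`` is the cosine-referenced phase of the fundamental, so
    the ground truth matches :func:`ergkit.spectral.flicker_fundamental`.
    """
    for k, amp in enumerate(harmonic_amps, start=2):
        if amp > 0 and k * stim_freq_hz >= fs_hz / 2:
            raise ValidationError(
                f"harmonic {k} at {k * stim_freq_hz} Hz aliases (fs={fs_hz})"
            )
    if stim_freq_hz >= fs_hz / 2:
        raise ValidationError("stim_freq_hz must be below Nyquist")
    n = int(round(dur_s * fs_hz))
    t = np.arange(n) / fs_hz
    template = fund_amp_uv * np.cos(2 * np.pi * stim_freq_hz * t + phase_rad)
    for k, amp in enumerate(harmonic_amps, start=2):
        template = template + amp * np.cos(2 * np.pi * k * stim_freq_hz * t)
    rng = np.random.default_rng(seed)
    trials = template[:, None] + rng.normal(0.0, noise_sd_uv, size=(n, n_trials))
    block = TrialBlock(trials, sampling_rate_hz=fs_hz, t0_index=0)
    truth = {
        "fundamental_amp_uv": float(fund_amp_uv),
        "fundamental_phase_rad": float(phase_rad),
        "stim_freq_hz": float(stim_freq_hz),
        "template": template,
    }
    return block, truth


# ---------------------------------------------------------------------------
# whole-exam protocol


@dataclass(frozen=True)
class ProtocolStep:
    stim_type: str = "Flash"
    adaptation: str = "DA"
    intensity: float = 0.01
    flicker_freq_hz: float = 0.0
    channel: str = "ERG"
    eye: str = "RE"


# ISCEV-style default: ascending dark-adapted flash series, then one
# light-adapted flash.  Intensities in cd*s/cm^2 as printed on the device.
DEFAULT_PROTOCOL: dict = {
    "da_intensities": [0.001, 0.01, 0.1, 0.3, 1.0],
    "la_intensities": [1.0],
    "flicker": None,  # e.g. {"freq_hz": 9.0, "intensity": 3.0}
    "n_trials": 10,
    "noise_sd_uv": 10.0,
    "fs_hz": 1000.0,
    "epoch_ms": 300.0,
    "pre_stim_ms": 20.0,
    # amplitude growth with log10 intensity (stimulus-response gain)
    "b_base_uv": 200.0,
    "b_gain_uv_per_decade": 80.0,
    "a_base_uv": 60.0,
    "a_gain_uv_per_decade": 30.0,
    "la_scale": 0.4,
    "eye": "RE",
}


def _step_amplitudes(intensity: float, adaptation: str, cfg: dict) -> tuple[float, float]:
    ref = min(cfg["da_intensities"])
    decades = np.log10(intensity / ref)
    a = cfg["a_base_uv"] + cfg["a_gain_uv_per_decade"] * decades
    b = cfg["b_base_uv"] + cfg["b_gain_uv_per_decade"] * decades
    if adaptation == "LA":
        a, b = a * cfg["la_scale"], b * cfg["la_scale"]
    return float(max(a, 1.0)), float(max(b, 1.0))


def synth_exam(
    protocol_config: dict | None = None,
    seed: int = 0,
    subject: SubjectInfo | None = None,
    exam_date: str = "2024-01-01",
) -> tuple[Exam, pd.DataFrame]:
    """Generate a full multi-step exam plus a ground-truth table.

    The default protocol has 5 ascending dark-adapted flash steps and one
    light-adapted flash (6 recordings).  The b-wave amplitude grows
    linearly with log10 intensity so stimulus–response summaries have a
    known monotone truth.  The truth table holds one row per recording and
    landmark with the exact template times/amplitudes.
    """
    cfg = dict(DEFAULT_PROTOCOL)
    cfg.update(protocol_config or {})
    subject = subject or SubjectInfo(subject_id=f"S{seed:03d}")
    rng = np.random.default_rng(seed)

    steps: list[ProtocolStep] = []
    for i in cfg["da_intensities"]:
        steps.append(ProtocolStep(adaptation="DA", intensity=i, eye=cfg["eye"]))
    for i in cfg["la_intensities"]:
        steps.append(ProtocolStep(adaptation="LA", intensity=i, eye=cfg["eye"]))
    if cfg["flicker"]:
        steps.append(
            ProtocolStep(
                stim_type="Flicker",
                adaptation="LA",
                intensity=cfg["flicker"].get("intensity", 3.0),
                flicker_freq_hz=cfg["flicker"]["freq_hz"],
                eye=cfg["eye"],
            )
        )

    recordings = []
    truth_rows = []
    for idx, step in enumerate(steps):
        step_seed = int(rng.integers(0, 2**31 - 1))
        if step.stim_type == "Flicker":
            block, truth = synth_flicker(
                stim_freq_hz=step.flicker_freq_hz,
                fund_amp_uv=20.0,
                harmonic_amps=(6.0, 2.0),
                noise_sd_uv=cfg["noise_sd_uv"],
                fs_hz=cfg["fs_hz"],
                dur_s=cfg["epoch_ms"] / 1000.0,
                n_trials=cfg["n_trials"],
                seed=step_seed,
            )
            truth_rows.append(
                {
                    "recording_index": idx,
                    "marker_name": "fundamental",
                    "time_ms": np.nan,
                    "amplitude_uv": truth["fundamental_amp_uv"],
                    "adaptation": step.adaptation,
                    "intensity": step.intensity,
                }
            )
        else:
            a_amp, b_amp = _step_amplitudes(step.intensity, step.adaptation, cfg)
            params = FlashERGParams(
                a_amp_uv=a_amp,
                b_amp_uv=b_amp,
                noise_sd_uv=cfg["noise_sd_uv"],
                fs_hz=cfg["fs_hz"],
                epoch_ms=cfg["epoch_ms"],
                pre_stim_ms=cfg["pre_stim_ms"],
                n_trials=cfg["n_trials"],
                seed=step_seed,
            )
            block, truth = synth_flash_erg(params)
            for name in ("a", "b"):
                truth_rows.append(
                    {
                        "recording_index": idx,
                        "marker_name": "B" if name == "b" else "a",
                        "time_ms": truth[f"{name}_time_ms"],
                        "amplitude_uv": truth[f"{name}_amplitude_uv"],
                        "adaptation": step.adaptation,
                        "intensity": step.intensity,
                    }
                )
        recordings.append(
            Recording(
                channel=step.channel,
                eye=step.eye,
                stimulus=StimulusDescriptor(
                    stim_type=step.stim_type,
                    intensity_value=step.intensity,
                    adaptation=step.adaptation,
                    flicker_freq_hz=step.flicker_freq_hz,
                ),
                trials=block,
            )
        )
    exam = new_exam(subject, exam_date, recordings)
    return exam, pd.DataFrame(truth_rows)


def synth_cohort(
    n_groups: int = 2,
    subjects_per_group: int = 3,
    seed: int = 0,
    group_gain: float = 0.7,
    protocol_config: dict | None = None,
) -> tuple[list[Exam], dict[str, str]]:
    """Seeded cohort of exams: ``n_groups`` × ``subjects_per_group``.

    Group g scales all response amplitudes by ``group_gain**g`` (group 0 is
    the control).  Returns the exams and a subject→group mapping usable by
    :func:`ergkit.markers.intensity_sequence`.
    """
    rng = np.random.default_rng(seed)
    exams, mapping = [], {}
    base = dict(DEFAULT_PROTOCOL)
    base.update(protocol_config or {})
    for g in range(n_groups):
        scale = group_gain**g
        cfg = dict(base)
        for key in ("a_base_uv", "b_base_uv", "a_gain_uv_per_decade", "b_gain_uv_per_decade"):
            cfg[key] = base[key] * scale
        for s in range(subjects_per_group):
            sid = f"G{g}S{s}"
            subject = SubjectInfo(subject_id=sid, group_label=f"group{g}")
            exam, _ = synth_exam(
                cfg, seed=int(rng.integers(0, 2**31 - 1)), subject=subject
            )
            exams.append(exam)
            mapping[sid] = f"group{g}"
    return exams, mapping
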