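"""Stored processing functions: filtering, trial rejection, averaging.

These are the operations an exam's :class:`ProcessingSpec` describes and
:func:`ergkit.model.get_processed_trace` applies lazily.  All of them are
pure — they return new arrays and never touch the raw trial matrix.

Filtering is a Butterworth bandpass (4th order by default) applied
zero-phase (forward–backward) so marker implicit times are not shifted.
The broadband ERG band is 0.5–300 Hz; oscillatory potentials are extracted
with a 75–300 Hz band.  Automatic trial rejection scores each trial by its
mean Euclidean distance to all other trials and rejects trials whose score
exceeds ``median + k·MAD`` — a user-independent outlier rule for trials
that deviate from all others.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal
from scipy.spatial.distance import pdist, squareform
from scipy.stats import median_abs_deviation

from .exceptions import EmptySelectionError, ValidationError
from .model import Exam, TrialBlock, log_change

__all__ = [
    "FilterSpec",
    "RejectionSpec",
    "AveragingSpec",
    "ProcessingSpec",
    "filter_bandpass",
    "autoreject_by_distance",
    "average_trials",
    "set_standard_functions",
    "STANDARD_BANDS",
]


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass filter configuration.

    ``zero_phase=True`` applies the filter forward and backward
    (``sosfiltfilt``), which cancels the phase response and squares the
    magnitude response.
    """

    low_hz: float
    high_hz: float
    order: int = 4
    kind: str = "bandpass"
    design: str = "butterworth"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind != "bandpass" or self.design != "butterworth":
            raise ValidationError("only butterworth bandpass filters are supported")
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if not (0 < self.low_hz < self.high_hz):
            raise ValidationError("need 0 < low_hz < high_hz")


@dataclass(frozen=True)
class RejectionSpec:
    """Distance-based automatic trial rejection configuration.

    ``threshold_k`` is the robust-deviation multiplier: a trial is rejected
    when its mean distance to the other trials exceeds the median score by
    more than ``threshold_k`` normal-consistent MADs.
    """

    method: str = "distance"
    metric: str = "euclidean"
    threshold_k: float = 3.0
    min_trials: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("none", "distance"):
            raise ValidationError("rejection method must be 'none' or 'distance'")
        if self.metric != "euclidean":
            raise ValidationError("only the euclidean metric is supported")
        if self.method == "distance" and not (
            np.isfinite(self.threshold_k) and self.threshold_k > 0
        ):
            raise ValidationError("threshold_k must be finite and positive")
        if self.min_trials < 3:
            raise ValidationError("min_trials must be >= 3")


@dataclass(frozen=True)
class AveragingSpec:
    method: str = "mean"

    def __post_init__(self) -> None:
        if self.method not in ("mean", "median"):
            raise ValidationError("averaging method must be 'mean' or 'median'")


@dataclass
class ProcessingSpec:
    """Declarative per-recording processing pipeline.

    Applied lazily in the order filter → rejection → averaging (so
    out-of-band noise does not drive rejection); set
    ``reject_before_filter`` to reverse the first two stages.
    """

    filter: FilterSpec | None = None
    rejection: RejectionSpec | None = None
    averaging: AveragingSpec = field(default_factory=AveragingSpec)
    reject_before_filter: bool = False

    def to_json(self) -> str:
        d = {
            "filter": asdict(self.filter) if self.filter else None,
            "rejection": asdict(self.rejection) if self.rejection else None,
            "averaging": asdict(self.averaging),
            "reject_before_filter": self.reject_before_filter,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ProcessingSpec":
        d = json.loads(text)

        def _pick(payload, klass):
            if payload is None:
                return None
            known = {f for f in klass.__dataclass_fields__}
            return klass(**{k: v for k, v in payload.items() if k in known})

        return cls(
            filter=_pick(d.get("filter"), FilterSpec),
            rejection=_pick(d.get("rejection"), RejectionSpec),
            averaging=_pick(d.get("averaging"), AveragingSpec) or AveragingSpec(),
            reject_before_filter=bool(d.get("reject_before_filter", False)),
        )


def _design_sos(spec: FilterSpec, fs_hz: float) -> np.ndarray:
    nyquist = fs_hz / 2.0
    if spec.high_hz >= nyquist:
        raise ValidationError(
            f"high_hz {spec.high_hz} must be below the Nyquist frequency {nyquist}"
        )
    return signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs_hz, output="sos"
    )


def filter_bandpass(trials: TrialBlock, spec: FilterSpec) -> TrialBlock:
    """Filter each trial independently; returns a new block.

    Zero-phase application uses forward–backward filtering with reflected
    edge padding (3 × filter order per pass) to suppress edge transients on
    short epochs.
    """
    sos = _design_sos(spec, trials.sampling_rate_hz)
    padlen = 3 * spec.order * 2  # per-section warm-up, both passes
    if trials.n_samples <= padlen:
        raise ValidationError(
            f"trace of {trials.n_samples} samples too short for the "
            f"filter warm-up length {padlen}"
        )
    x = trials.samples
    if spec.zero_phase:
        y = signal.sosfiltfilt(sos, x, axis=0, padtype="even", padlen=padlen)
    else:
        y = signal.sosfilt(sos, x, axis=0)
    return trials.with_samples(y)


def filter_magnitude_response(spec: FilterSpec, fs_hz: float, freqs_hz) -> np.ndarray:
    """Analytic |H(f)| of the designed digital filter at the given frequencies.

    Squared when ``zero_phase`` since the filter is applied twice.  This is
    the closed-form oracle the empirical sine-attenuation checks compare
    against.
    """
    sos = _design_sos(spec, fs_hz)
    w, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs_hz, float)), fs=fs_hz)
    mag = np.abs(h)
    return mag**2 if spec.zero_phase else mag


def autoreject_by_distance(trials: TrialBlock, spec: RejectionSpec) -> np.ndarray:
    """Boolean mask (True = rejected) from the trial distance matrix.

    Score ``d_i`` = mean distance of trial i to all other trials; trial i is
    rejected iff ``d_i > median(d) + threshold_k · MAD(d)`` with the MAD
    scaled for normal consistency.  When ``MAD(d) = 0`` the spread of the
    majority is zero and any score strictly above the median is rejected —
    so a block of identical trials rejects nothing, while noise-free copies
    plus one deviant trial reject exactly the deviant.  Below
    ``min_trials`` the notion of an outlier is undefined: an all-false mask
    is returned with a warning.
    """
    n = trials.n_trials
    if spec.method == "none":
        return np.zeros(n, dtype=bool)
    if n < spec.min_trials:
        warnings.warn(
            f"only {n} trials (< min_trials={spec.min_trials}); rejection skipped",
            stacklevel=2,
        )
        return np.zeros(n, dtype=bool)
    dmat = squareform(pdist(trials.samples.T, metric=spec.metric))
    scores = dmat.sum(axis=1) / (n - 1)
    med = float(np.median(scores))
    mad = float(median_abs_deviation(scores, scale="normal"))
    if mad == 0.0:
        return scores > med
    return scores > med + spec.threshold_k * mad


def average_trials(
    trials: TrialBlock, mask: np.ndarray, spec: AveragingSpec | None = None
) -> np.ndarray:
    """Pointwise mean or median over the kept (mask False) trials."""
    spec = spec or AveragingSpec()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (trials.n_trials,):
        raise ValidationError("mask length must equal the number of trials")
    kept = trials.samples[:, ~mask]
    if kept.shape[1] == 0:
        raise EmptySelectionError("all trials rejected; nothing to average")
    if spec.method == "median":
        return np.median(kept, axis=1)
    return kept.mean(axis=1)


# default standard-function table by (channel, stim_type); bands in Hz
STANDARD_BANDS: dict[str, tuple[float, float]] = {
    "ERG": (0.5, 300.0),
    "OP": (75.0, 300.0),
    "VEP": (1.0, 100.0),
}


def _standard_spec(channel: str, stim_type: str) -> ProcessingSpec:
    band = STANDARD_BANDS.get(channel, STANDARD_BANDS["ERG"])
    rejection = RejectionSpec() if channel in ("ERG", "OP") else None
    return ProcessingSpec(
        filter=FilterSpec(low_hz=band[0], high_hz=band[1], order=4, zero_phase=True),
        rejection=rejection,
        averaging=AveragingSpec("mean"),
    )


def set_standard_functions(exam: Exam) -> Exam:
    """Assign default processing specs per recording by channel/stimulus.

    ERG flash and flicker recordings get a 0.5–300 Hz band with distance
    rejection and mean averaging; OP channels a 75–300 Hz band; VEP a
    conventional 1–100 Hz band.  Idempotent: re-running overwrites with
    identical specs.  The band can exceed Nyquist only for unusually low
    sampling rates, in which case the high edge is clipped to 0.9 × Nyquist.
    """
    for rec in exam.recordings:
        spec = _standard_spec(rec.channel, rec.stimulus.stim_type)
        nyq = rec.trials.sampling_rate_hz / 2.0
        if spec.filter is not None and spec.filter.high_hz >= nyq:
            spec.filter = FilterSpec(
                low_hz=spec.filter.low_hz,
                high_hz=0.9 * nyq,
                order=spec.filter.order,
                zero_phase=spec.filter.zero_phase,
            )
        rec.processing = spec
    log_change(exam, "set_standard_functions", {})
    return exam
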