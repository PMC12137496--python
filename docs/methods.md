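# Methods

## The exam model and lazy processing

A recording's raw trial matrix (n_samples × n_trials, µV) is write-locked
at construction. Processing is a declarative specification — optional
bandpass filter, optional trial-rejection rule, averaging method — stored
on the recording and executed only when a processed trace is requested,
in the fixed order *filter → rejection → averaging*. Filtering precedes
rejection so that out-of-band noise cannot drive trial rejection; the
`reject_before_filter` flag on `ProcessingSpec` reverses the first two
stages for users who prefer rejection on raw trials. The rejection mask
used for averaging is the union of the stored (manual) mask and the mask
the rejection spec produces on demand; the CLI's `autoreject` command
materializes the computed mask into the stored one so it persists in the
file.

Conventions: t = 0 at stimulus onset, samples before `t0_index` carry
negative times and define the baseline window; voltages are microvolts
everywhere (importers convert); recording indices are 0-based in the
library and displayed 1-based by the CLI. Query criteria combine
conjunctively, numeric ranges inclusive on both ends. Exam equality (the
round-trip contract) is field-wise: exact on strings and integers,
bit-equality on float arrays.

## Filtering

Bandpass filters are digital Butterworth designs (scipy second-order
sections), order 4 by default, applied per trial. With `zero_phase=True`
(default) the filter runs forward and backward (`sosfiltfilt`) with
reflected edge padding of 3 × order samples per pass: the phase response
cancels — marker implicit times are not shifted — and the magnitude
response is squared. The standard band table assigns 0.5–300 Hz to ERG
channels (flash and flicker), 75–300 Hz to OP channels, and a
conventional, configurable 1–100 Hz to VEP channels; the high edge is
clipped to 0.9 × Nyquist for unusually low sampling rates. Traces shorter
than the warm-up length (6 × order samples) are refused rather than
silently filtered.

The test oracle for the filter is the analytic magnitude response of the
designed system (`sosfreqz`), squared for zero-phase application,
compared with single-bin DFT amplitude measurements of filtered probe
sines over integer-cycle windows. Agreement is required to 5% wherever
the analytic response is at least 10⁻³ (−60 dB); below that, finite
windows cannot resolve the response (edge-transient leakage floors near
10⁻⁵ relative), so the check instead requires the measured amplitude to
stay below 1.1 × 10⁻³ — i.e. the attenuation is at least as deep as
−60 dB, the deepest claim an empirical measurement of this length can
support.

## Trial rejection

The outlier score of trial *i* is its mean Euclidean distance to all
other trials, computed from the full pairwise distance matrix. A trial is
rejected when its score exceeds median + k·MAD (MAD scaled by 1.4826 for
normal consistency), k = 3 by default. Degenerate cases: when MAD = 0 the
majority of scores are identical, and any score strictly above the median
is rejected — a block of identical trials rejects nothing, while
noise-free copies plus one deviant reject exactly the deviant. Below
`min_trials` (default 3) an outlier is undefined; an all-false mask is
returned with a warning.

Operating characteristics, as measured by the acceptance script on
10-trial blocks (9 clean noisy trials + 1 planted artifact — sign-flip,
flatline or 5× scaling): sensitivity is 100%, and roughly 94% of blocks
have zero clean-trial rejections. The residual ~6% per-block false-alarm
probability is a family-wise property of thresholding ~10 self-normalized
scores at k = 3: each clean trial's score carries its own noise-energy
term (a scaled χ² variable whose standard deviation is σ/2 independently
of epoch length), which skews the score distribution right relative to
the ideal-normal case (~4.4% family-wise rate). Alternative aggregations
(median or trimmed-mean distance, nearest-neighbour distance, log-scale
robust z) were evaluated and perform the same or worse; raising k trades
this off against sensitivity and is left to the user via `threshold_k`.
Users who need stricter per-block control should raise `threshold_k` to
≈3.5–4 at these trial counts.

## Markers and measurements

Automatic placement is rule-based per channel and stimulus type, with all
windows configurable (`MarkerConfig`; defaults are mouse-like):

- Flash ERG: a = trace minimum in (0, 50] ms; B = maximum in
  (t_a, 300] ms, amplitude relative to the a-trough.
- OP channel: the a→B interval is located on the broadband (unfiltered)
  trial average, then local maxima of the processed (75–300 Hz) trace
  within it with prominence ≥ 10% of the largest are named OP1..OPn in
  time order.
- Flicker: the first stimulus cycle after onset is skipped (onset
  transient); P1 is the dominant peak in the steady-state window, T1 the
  trough within one period before it; amplitude is peak-to-trough.
- VEP: N1 = minimum in (0, 100] ms, P1 = subsequent maximum in
  (N1, 200] ms.

Ties between equal extrema resolve to the earliest time. Re-running
automatic placement replaces previous automatic markers but never touches
manually placed ones. Amplitudes are reported signed, as marker voltage
minus reference-marker voltage, or minus the pre-stimulus baseline (mean
over [−20, 0) ms, or all pre-stimulus samples if fewer) when no reference
is set. Manual placement reads the voltage at the nearest sample to the
requested time. The stimulus–response summary aggregates amplitudes per
(group, adaptation, intensity) into n, mean, SD (ddof = 1, NaN for n = 1)
and SEM, sorted by ascending numeric intensity.

## Spectral analysis

`psd` is a plain rectangular-window periodogram of the mean-detrended
trace — ERG epochs are short, so no Welch segmenting or tapering by
default (a window argument is exposed). Normalization is
Parseval-consistent: one-sided density whose sum × Δf equals the sample
variance; DC and Nyquist bins are not doubled. `peak_frequency` returns
the strongest bin in a band, ties to the lowest frequency.
`flicker_fundamental` trims the trace to a whole number of stimulus
cycles (at least 2 required), removes the mean, and evaluates the
single-bin DFT at the stimulus frequency: amplitude 2|X|/N,
cosine-referenced phase in (−π, π]. Integer-cycle evaluation makes the
estimate exactly orthogonal to harmonics and DC.

## Synthetic exams

The flash template is
v(t) = −a·g(t; t_a) + b·g(t; t_b) + op·w(t)·sin(2π f_op t), where
g(t; t_p) = (t/t_p)^k exp(k(1 − t/t_p)) is a gamma-shaped kernel with
unit height peaking exactly at t_p (rising faster than it decays;
k = 30 for the a-wave, 20 for the b-wave, sharp enough that the two
kernels overlap by < 0.1% and the planted extrema are the landmark
values), and w is a Gaussian window centred between the two peaks for the
~120 Hz oscillatory potentials. Defaults are mouse-like: a-trough 15 ms
(150 µV), b-peak 50 ms (300 µV), 300 ms epoch at 1 kHz with 20 ms
pre-stimulus baseline, 10 trials with 10 µV i.i.d. Gaussian noise per
sample — a realistic single-trial noise floor for rodent corneal
recordings. Ground truth records the numerically exact extrema of the
sampled template rather than the nominal kernel parameters, so recovery
tests compare against what a detector can actually attain.

The default protocol is an ISCEV-style series: five dark-adapted flash
steps at 0.001–1 cd·s/cm² plus one light-adapted flash, with a- and
b-amplitudes growing linearly in log₁₀ intensity (80 µV/decade for B) so
stimulus–response summaries have a known monotone truth; an optional
flicker step adds a fundamental-plus-harmonics steady-state response.
Cohort generation scales amplitudes per group for group-statistics tests.
All randomness comes from one seeded generator per call.

What the generator does **not** emulate: baseline drift, mains
interference, electrode impedance changes, latency jitter between trials,
adaptation across the session, or non-Gaussian artifact shapes beyond the
three planted kinds. Passing tests therefore demonstrate correctness of
the algorithms under controlled conditions, not robustness to every
failure mode of real recordings.

## Storage

The HDF5 layout mirrors the exam structure one-to-one (subject and exam
attribute groups, changelog table, one zero-padded group per recording
with raw matrix, stimulus and processing subgroups, rejection mask and
marker table), every group carrying a human-readable description
attribute. Only raw trials and declarative specs are written — never
pipeline-derived averages — so the lazy-processing philosophy survives on
disk. Strings are UTF-8 variable-length, dates ISO-8601 strings,
processing specs a JSON attribute; unknown extra attributes and keys are
ignored on load (forward compatibility), and the format is versioned
("1.0") with a major-version gate. Writes go to a temporary file renamed
into place. The CSV importer reads long-format tables (one row per sample
per trial) with a configurable column/unit mapping, groups rows into
recordings by stimulus metadata, refuses ragged trials naming the
offender, and uses round-trip float parsing so a CSV → HDF5 cycle
preserves voltages bit-exactly.

## Problem sizes in tests

The test suite and acceptance script use 6-step exams with 320-sample
epochs and 3–12 trials, 50 exams × 20 operations for the immutability
sweep, 100 randomized exams for round-trip checks, 200 blocks for
rejection characteristics, and 100 seeds for Monte-Carlo flicker
recovery — sizes at which every quantity is stable to well inside its
tolerance while the whole suite completes in seconds.
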