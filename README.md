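# ergkit

Processing, measurement, storage and visualisation of visual
electrophysiology exams — electroretinograms (ERG) and visually evoked
potentials (VEP) — for researchers running ISCEV-style flash and flicker
protocols in animal models or the clinic.

The central object is the **exam**: an ordered collection of recordings
(one per stimulus step), each holding the raw trial matrix together with
stimulus metadata (type, time-integrated luminance, adaptation state,
flicker rate). Raw data are immutable; filtering, outlier-trial rejection
and averaging are *declarative specifications* applied lazily whenever a
processed trace is requested, and every mutation is appended to a
changelog. Nothing you do to an exam ever destroys the trials you
imported.

The analysis toolbox on top of that container:

- **Bandpass filtering** — zero-phase 4th-order Butterworth; 0.5–300 Hz
  for the broadband ERG, 75–300 Hz to extract the oscillatory potentials
  (OPs) riding on the b-wave.
- **Automatic trial rejection** — the pairwise Euclidean distance matrix
  between trials is reduced to a per-trial deviation score
  dᵢ = mean distance of trial *i* to all others; trial *i* is rejected
  when dᵢ > median(d) + k·MAD(d) (normal-consistent MAD, k = 3), a
  user-independent outlier rule.
- **Marker placement** — a-wave (trough in (0, 50] ms), b-wave (subsequent
  peak, amplitude measured from the a-trough), OP peaks, flicker P1/T1,
  VEP N1/P1; manual placement is scriptable. A flat measurements table
  (implicit time, amplitude per marker) and cross-subject
  stimulus–response summaries (n, mean, SD, SEM per intensity) derive
  from the markers.
- **Spectral tools** — Parseval-consistent periodogram (PSD), band-limited
  peak-frequency search, and single-bin DFT extraction of the flicker
  fundamental amplitude/phase over an integer number of stimulus cycles.
- **Self-documenting HDF5 storage** — the on-disk layout mirrors the exam
  object (raw trials + processing specs + markers + changelog, with
  human-readable descriptions) and stays readable with any generic HDF5
  tool; a generic long-format CSV importer covers device-independent
  intake.
- **Seeded synthetic exams** — a generator of physiologically shaped
  flash/flicker waveforms with exact ground truth, used by the test suite
  and available for demos and benchmarking.

## Worked example

```python
import ergkit as ek

exam, truth = ek.synth_exam(seed=1)        # 5 DA flash steps + 1 LA step
ek.set_standard_functions(exam)            # per-channel filter/reject/average
ek.auto_place_markers(exam)                # a and B on every processed trace
table = ek.measurements(exam)
print(table[["recording_index", "adaptation", "intensity_value",
             "marker_name", "implicit_time_ms", "amplitude_uv"]].to_string(index=False))
```

```
 recording_index adaptation  intensity_value marker_name  implicit_time_ms  amplitude_uv
               0         DA            0.001           a              15.0    -60.533368
               0         DA            0.001           B              51.0    257.281855
               1         DA            0.010           a              15.0    -84.627787
               1         DA            0.010           B              50.0    369.758768
               2         DA            0.100           a              15.0   -119.133061
               2         DA            0.100           B              50.0    481.810096
               3         DA            0.300           a              15.0   -134.294589
               3         DA            0.300           B              50.0    530.980103
               4         DA            1.000           a              15.0   -149.056540
               4         DA            1.000           B              50.0    589.270038
               5         LA            1.000           a              15.0    -59.169503
               5         LA            1.000           B              50.0    237.272989
```

Each row is one marker on one recording: the a-wave implicit time sits at
15 ms with a signed amplitude against the pre-stimulus baseline, and the
b-wave amplitude (measured from the a-trough) grows monotonically with
log flash intensity across the dark-adapted (DA) series — the classical
stimulus–response behaviour. `ek.intensity_sequence([table], "B")`
aggregates such tables across subjects into mean ± SEM per intensity, and
`ergkit.viz.plot_intensity_sequence` renders the curve.

The same pipeline from a shell:

```sh
ergkit simulate --output exam.h5 --seed 1
ergkit standardize --input exam.h5
ergkit autoreject  --input exam.h5
ergkit markers     --input exam.h5
ergkit measure     --input exam.h5 --output measurements.csv
ergkit plot        --input exam.h5 --output exam.svg
```

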