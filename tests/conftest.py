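import numpy as np
import pytest

import ergkit as ek


def make_random_exam(seed: int) -> ek.Exam:
    """Randomized exam exercising every persisted field (specs, masks, markers)."""
    rng = np.random.default_rng(seed)
    cfg = {
        "n_trials": int(rng.integers(3, 12)),
        "noise_sd_uv": float(rng.uniform(0, 20)),
        "da_intensities": sorted(rng.uniform(0.001, 3.0, size=rng.integers(2, 6))),
        "la_intensities": [float(rng.uniform(0.5, 3.0))],
        "flicker": {"freq_hz": 9.0} if rng.random() < 0.3 else None,
    }
    exam, _ = ek.synth_exam(cfg, seed=seed)
    if rng.random() < 0.7:
        ek.set_standard_functions(exam)
    for rec in exam.recordings:
        if rng.random() < 0.4:
            mask = rec.rejection_mask.copy()
            mask[rng.integers(0, rec.trials.n_trials)] = True
            rec.rejection_mask = mask
    if rng.random() < 0.6:
        ek.auto_place_markers(exam)
    if rng.random() < 0.4:
        ek.place_marker(exam, 0, "manual1", float(rng.uniform(5, 250)))
    return exam


@pytest.fixture
def random_exam_factory():
    return make_random_exam


@pytest.fixture
def flash_exam():
    """Default six-step exam (5 DA + 1 LA) with realistic trial noise."""
    exam, truth = ek.synth_exam(seed=7)
    return exam, truth


@pytest.fixture
def clean_flash_exam():
    """Noise-free six-step exam with exact ground truth."""
    exam, truth = ek.synth_exam({"noise_sd_uv": 0.0}, seed=5)
    return exam, truth
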