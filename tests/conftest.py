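import numpy as np
import pytest

from vocims import preprocess as pp
from vocims import synthetic as syn


@pytest.fixture
def tiny_grid():
    """3x4 grid with distinct hand-set intensities."""
    grid = syn.make_grid([0.0, 1.0, 2.0], [10.0, 11.0, 12.0, 13.0])
    intensity = np.arange(12, dtype=float).reshape(3, 4)
    return syn.ChromatogramGrid(grid.rt_axis, grid.dt_axis, intensity)


def make_test_design(
    seed,
    n_per_class=(20, 20),
    n_discriminative=0,
    effect_multiplier=1.5,
    n_rt=30,
    n_dt=100,
    n_peaks=10,
    noise_sd=1.0,
):
    """Small, fast design used throughout the suite (full-size grids are only
    exercised where the ~10,000-non-zero calibration outcome is at stake)."""
    return syn.default_design(
        n_term=n_per_class[0],
        n_preterm=n_per_class[1],
        n_discriminative=n_discriminative,
        effect_multiplier=effect_multiplier,
        noise_sd=noise_sd,
        seed=seed,
        n_rt=n_rt,
        n_dt=n_dt,
        n_peaks=n_peaks,
    )


def cohort_feature_matrix(design, target_nnz=1000):
    """Generate a cohort and reduce it with the shared crop/threshold recipe."""
    cohort = syn.generate_cohort(design)
    samples = [(r.sample_id, g) for r, g in cohort.samples]
    window = pp.CropWindow.full(samples[0][1])
    tau = pp.calibrate_threshold(samples, target_nnz)
    features = pp.build_matrix(samples, window, tau)
    labels = np.array(
        [0 if r.delivery_class == "term" else 1 for r in cohort.records]
    )
    return features, labels, cohort
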