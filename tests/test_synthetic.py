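import hashlib

import numpy as np
import pytest

from vocims import synthetic as syn
from vocims.errors import ConfigurationError, InvalidAxisError, OutOfRangeError

from conftest import make_test_design


def grid_hash(grid):
    h = hashlib.sha256()
    h.update(grid.rt_axis.tobytes())
    h.update(grid.dt_axis.tobytes())
    h.update(grid.intensity.tobytes())
    return h.hexdigest()


class TestMakeGrid:
    def test_zero_initialized(self):
        g = syn.make_grid([1.0, 2.0, 3.0], [0.1, 0.2, 0.3, 0.4])
        assert g.shape == (3, 4)
        assert np.all(g.intensity == 0)

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(InvalidAxisError):
            syn.make_grid([1.0, 1.0, 2.0], [0.1, 0.2])

    def test_empty_axis_rejected(self):
        with pytest.raises(InvalidAxisError):
            syn.make_grid([], [0.1, 0.2])

    def test_cell_count_is_product_of_lengths(self):
        g = syn.make_grid(np.arange(120.0), np.arange(2500.0) * 0.01 + 200)
        assert g.intensity.size == 300_000


class TestAddPeak:
    def setup_method(self):
        self.grid = syn.make_grid(np.arange(10.0), np.arange(20.0))

    def test_zero_amplitude_is_noop(self):
        peak = syn.PeakSpec(5.0, 10.0, 1.0, 1.0, 0.0)
        out = syn.add_peak(self.grid, peak)
        assert np.array_equal(out.intensity, self.grid.intensity)

    def test_maximum_at_nearest_center_cell(self):
        peak = syn.PeakSpec(4.7, 9.2, 1.5, 2.0, 10.0)
        out = syn.add_peak(self.grid, peak)
        i, j = np.unravel_index(np.argmax(out.intensity), out.shape)
        assert (i, j) == (5, 9)  # nearest cells to (4.7, 9.2)
        assert out.intensity[i, j] == pytest.approx(10.0)

    def test_additivity_cellwise(self):
        peak = syn.PeakSpec(5.0, 10.0, 1.0, 2.0, 7.0)
        once = syn.add_peak(self.grid, peak)
        twice = syn.add_peak(once, peak)
        assert np.allclose(twice.intensity, 2 * once.intensity)

    def test_input_grid_unmodified(self):
        before = self.grid.intensity.copy()
        syn.add_peak(self.grid, syn.PeakSpec(5.0, 10.0, 1.0, 1.0, 3.0))
        assert np.array_equal(self.grid.intensity, before)

    def test_center_out_of_range_rejected(self):
        with pytest.raises(OutOfRangeError):
            syn.add_peak(self.grid, syn.PeakSpec(50.0, 10.0, 1.0, 1.0, 1.0))


class TestAddRip:
    def setup_method(self):
        self.grid = syn.make_grid(np.arange(8.0), np.arange(30.0))

    def test_zero_amplitude_is_noop(self):
        out = syn.add_rip(self.grid, syn.PeakSpec(0.0, 12.0, 1.0, 2.0, 0.0))
        assert np.array_equal(out.intensity, self.grid.intensity)

    def test_every_rt_row_peaks_at_rip_center(self):
        out = syn.add_rip(self.grid, syn.PeakSpec(0.0, 12.3, 1.0, 2.0, 5.0))
        assert np.all(out.intensity.argmax(axis=1) == 12)

    def test_column_sum_equals_nrows_times_amplitude(self):
        out = syn.add_rip(self.grid, syn.PeakSpec(0.0, 12.0, 1.0, 2.0, 5.0))
        assert out.intensity[:, 12].sum() == pytest.approx(8 * 5.0)


class TestGenerateSample:
    def test_no_class_effect_when_multipliers_one(self):
        design = make_test_design(seed=0, noise_sd=0.0)
        a = syn.generate_sample(design, "term", 1)
        b = syn.generate_sample(design, "preterm", 2)
        assert np.allclose(a.intensity, b.intensity)

    def test_same_seed_bitwise_identical(self):
        design = make_test_design(seed=0)
        a = syn.generate_sample(design, "term", 42)
        b = syn.generate_sample(design, "term", 42)
        assert np.array_equal(a.intensity, b.intensity)

    def test_multiplier_doubles_center_cell(self):
        # closed form: a single isolated peak; noise off
        rt = np.arange(20.0)
        dt = np.arange(20.0)
        peak = syn.PeakSpec(10.0, 10.0, 1.0, 1.0, 50.0)
        design = syn.CohortDesign(
            rt_axis=tuple(rt), dt_axis=tuple(dt),
            class_labels=("A", "B"), n_per_class=(1, 1),
            template_peaks=(peak,),
            planted_effects={"A": (1.0,), "B": (2.0,)},
            rip_spec=None, noise_sd=0.0,
        )
        a = syn.generate_sample(design, "A", 0)
        b = syn.generate_sample(design, "B", 0)
        assert b.intensity[10, 10] == pytest.approx(2 * a.intensity[10, 10])
        assert a.intensity[10, 10] == pytest.approx(50.0)

    def test_unknown_class_label_rejected(self):
        design = make_test_design(seed=0)
        with pytest.raises(ConfigurationError):
            syn.generate_sample(design, "no-such-class", 0)

    def test_all_intensities_nonnegative(self):
        design = make_test_design(seed=3, noise_sd=5.0)
        g = syn.generate_sample(design, "term", 7)
        assert np.all(g.intensity >= 0)

    def test_noiseless_sample_is_sum_of_constituents(self):
        # additivity: peaks + RIP, rendered together vs accumulated manually
        design = make_test_design(seed=1, noise_sd=0.0)
        sample = syn.generate_sample(design, "preterm", 0)
        manual = syn.make_grid(design.rt_axis, design.dt_axis)
        for peak, mult in zip(design.template_peaks, design.planted_effects["preterm"]):
            scaled = syn.PeakSpec(peak.rt_center, peak.dt_center, peak.rt_sigma,
                                  peak.dt_sigma, peak.amplitude * mult)
            manual = syn.add_peak(manual, scaled)
        manual = syn.add_rip(manual, design.rip_spec)
        assert np.allclose(sample.intensity, manual.intensity)


class TestGenerateCohort:
    def test_empty_cohort(self):
        design = make_test_design(seed=0, n_per_class=(0, 0))
        cohort = syn.generate_cohort(design)
        assert cohort.samples == []

    def test_class_sizes_match_study_cohort(self):
        design = make_test_design(seed=0, n_per_class=(26, 52), n_rt=10, n_dt=20)
        cohort = syn.generate_cohort(design)
        classes = [r.delivery_class for r in cohort.records]
        assert classes.count("term") == 26
        assert classes.count("preterm") == 52

    def test_fixed_seed_reproducible(self):
        design = make_test_design(seed=11, n_per_class=(3, 3), n_rt=10, n_dt=20)
        c1 = syn.generate_cohort(design)
        c2 = syn.generate_cohort(design)
        assert [grid_hash(g) for g in c1.grids] == [grid_hash(g) for g in c2.grids]
        assert c1.manifest().equals(c2.manifest())

    def test_records_satisfy_invariants(self):
        # SampleRecord.__post_init__ enforces who_group/ga consistency;
        # reaching here without ConfigurationError is the assertion
        design = make_test_design(seed=2, n_per_class=(15, 15), n_rt=10, n_dt=20)
        cohort = syn.generate_cohort(design)
        for r in cohort.records:
            assert (r.ga_delivery_days < syn.TERM_CUTOFF_DAYS) == (
                r.delivery_class == "preterm"
            )

    def test_ground_truth_footprints_within_3_sigma(self):
        design = make_test_design(seed=0, n_discriminative=3, n_per_class=(2, 2),
                                  n_rt=20, n_dt=40)
        cohort = syn.generate_cohort(design)
        fps = cohort.ground_truth["discriminative_peaks"]
        assert len(fps) == 3
        rt = np.asarray(design.rt_axis)
        dt = np.asarray(design.dt_axis)
        for key, fp in fps.items():
            peak = design.template_peaks[fp["peak_index"]]
            for i, j in fp["pixels"]:
                assert abs(rt[i] - peak.rt_center) <= 3 * peak.rt_sigma
                assert abs(dt[j] - peak.dt_center) <= 3 * peak.dt_sigma

    def test_null_design_has_no_discriminative_peaks(self):
        design = make_test_design(seed=0, n_discriminative=0, n_per_class=(1, 1),
                                  n_rt=10, n_dt=20)
        assert syn.discriminative_peaks(design) == []

    def test_class_exchangeability_under_null(self):
        # with all multipliers 1, the grid for a sample depends only on its
        # per-sample seed, not its class: swap labels, regenerate, compare
        design = make_test_design(seed=9, n_discriminative=0, n_per_class=(2, 2),
                                  n_rt=10, n_dt=20)
        swapped = syn.CohortDesign(
            rt_axis=design.rt_axis, dt_axis=design.dt_axis,
            class_labels=("preterm", "term"), n_per_class=(2, 2),
            template_peaks=design.template_peaks,
            planted_effects=design.planted_effects,
            rip_spec=design.rip_spec, noise_sd=design.noise_sd, seed=9,
        )
        c1 = syn.generate_cohort(design)
        c2 = syn.generate_cohort(swapped)
        assert [grid_hash(g) for g in c1.grids] == [grid_hash(g) for g in c2.grids]


class TestIO:
    def test_chromatogram_round_trip(self, tmp_path, tiny_grid):
        path = tmp_path / "g.txt"
        syn.write_chromatogram(tiny_grid, path)
        back = syn.read_chromatogram(path)
        assert np.array_equal(back.rt_axis, tiny_grid.rt_axis)
        assert np.array_equal(back.dt_axis, tiny_grid.dt_axis)
        assert np.array_equal(back.intensity, tiny_grid.intensity)

    def test_cohort_round_trip(self, tmp_path):
        design = make_test_design(seed=4, n_per_class=(2, 3), n_rt=8, n_dt=12)
        cohort = syn.generate_cohort(design)
        syn.write_cohort(cohort, tmp_path)
        manifest = syn.read_manifest(tmp_path / "manifest.csv")
        assert len(manifest) == 5
        assert set(manifest["delivery_class"]) == {"term", "preterm"}
        for row in manifest.itertuples():
            g = syn.read_chromatogram(tmp_path / row.chromatogram_path)
            assert g.shape == (8, 12)
        assert (tmp_path / "ground_truth.json").exists()
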