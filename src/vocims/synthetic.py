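"""Synthetic GC-IMS cohort generation with known ground truth.

A synthetic chromatogram is a retention-time x drift-time intensity grid
built from a shared template of 2D Gaussian analyte peaks, a reactant-ion
ridge constant across retention time, an optional linear baseline drift and
additive Gaussian noise truncated at zero.  Class structure is planted by
scaling template peak amplitudes with per-class multipliers, and every
generated cohort carries a sidecar that records the pixel footprint of each
discriminative peak so downstream feature selection can be scored against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidAxisError, OutOfRangeError

__all__ = [
    "ChromatogramGrid",
    "PeakSpec",
    "CohortDesign",
    "SampleRecord",
    "Cohort",
    "make_grid",
    "add_peak",
    "add_rip",
    "generate_sample",
    "generate_cohort",
    "default_design",
    "discriminative_peaks",
    "peak_footprint",
    "write_chromatogram",
    "read_chromatogram",
    "write_cohort",
    "read_manifest",
]

# Gestational-age bands in days: 24+0..27+6, 28+0..31+6, 32+0..36+6.
GA_BANDS = {1: (168, 195), 2: (196, 223), 3: (224, 258)}
TERM_CUTOFF_DAYS = 259  # 37+0 weeks
MAX_TERM_DELIVERY_DAYS = 293  # ~42 weeks
TERM_GROUPS = {1: "4a", 2: "4b", 3: "4c"}


def _as_axis(values) -> np.ndarray:
    axis = np.asarray(values, dtype=float)
    if axis.ndim != 1 or axis.size == 0:
        raise InvalidAxisError("axis must be a non-empty 1D array")
    if not np.all(np.isfinite(axis)):
        raise InvalidAxisError("axis values must be finite")
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise InvalidAxisError("axis must be strictly increasing")
    return axis


@dataclass(frozen=True, eq=False)
class ChromatogramGrid:
    """A retention-time x drift-time ion-current intensity matrix.

    Attributes
    ----------
    rt_axis : ndarray
        Strictly increasing retention-time coordinates in seconds.
    dt_axis : ndarray
        Strictly increasing drift-time coordinates in milliseconds.
    intensity : ndarray, shape (len(rt_axis), len(dt_axis))
        Finite ion-current values in arbitrary units.
    """

    rt_axis: np.ndarray
    dt_axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt_axis", _as_axis(self.rt_axis))
        object.__setattr__(self, "dt_axis", _as_axis(self.dt_axis))
        inten = np.asarray(self.intensity, dtype=float)
        if inten.shape != (self.rt_axis.size, self.dt_axis.size):
            raise InvalidAxisError(
                f"intensity shape {inten.shape} does not match axes "
                f"({self.rt_axis.size}, {self.dt_axis.size})"
            )
        if not np.all(np.isfinite(inten)):
            raise InvalidAxisError("intensity values must be finite")
        object.__setattr__(self, "intensity", inten)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def allclose(self, other: "ChromatogramGrid", **kw) -> bool:
        return (
            np.array_equal(self.rt_axis, other.rt_axis)
            and np.array_equal(self.dt_axis, other.dt_axis)
            and np.allclose(self.intensity, other.intensity, **kw)
        )


@dataclass(frozen=True)
class PeakSpec:
    """A separable 2D Gaussian peak (or drift-time ridge for the RIP)."""

    rt_center: float
    dt_center: float
    rt_sigma: float
    dt_sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0 or self.dt_sigma <= 0:
            raise ConfigurationError("peak sigmas must be strictly positive")
        if self.amplitude < 0:
            raise ConfigurationError("peak amplitude must be non-negative")


@dataclass(frozen=True)
class CohortDesign:
    """Full recipe for a two-or-more-class synthetic cohort.

    ``planted_effects`` maps each class label to one amplitude multiplier per
    template peak; peaks whose multipliers differ between classes are the
    planted discriminative signal.
    """

    rt_axis: tuple[float, ...]
    dt_axis: tuple[float, ...]
    class_labels: tuple[str, ...]
    n_per_class: tuple[int, ...]
    template_peaks: tuple[PeakSpec, ...]
    planted_effects: Mapping[str, tuple[float, ...]]
    rip_spec: PeakSpec | None = None
    noise_sd: float = 1.0
    baseline_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_labels) != len(self.n_per_class):
            raise ConfigurationError("class_labels and n_per_class lengths differ")
        if any(n < 0 for n in self.n_per_class):
            raise ConfigurationError("n_per_class entries must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for label in self.class_labels:
            if label not in self.planted_effects:
                raise ConfigurationError(f"no planted_effects for class {label!r}")
            mults = self.planted_effects[label]
            if len(mults) != len(self.template_peaks):
                raise ConfigurationError(
                    f"planted_effects[{label!r}] must list one multiplier per peak"
                )
            if any(m < 0 for m in mults):
                raise ConfigurationError("amplitude multipliers must be >= 0")


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample clinical metadata driving group comparisons."""

    sample_id: str
    delivery_class: str  # "term" | "preterm"
    ga_inclusion_days: int
    ga_delivery_days: int
    who_group: str  # "1", "2", "3", "4a", "4b", "4c"
    chorioamnionitis: bool
    uti: bool
    crp: float  # mg/L
    cervical_length: float  # mm
    chromatogram_path: str

    def __post_init__(self) -> None:
        preterm = self.ga_delivery_days < TERM_CUTOFF_DAYS
        if preterm != (self.delivery_class == "preterm"):
            raise ConfigurationError(
                f"{self.sample_id}: delivery_class inconsistent with "
                f"ga_delivery_days={self.ga_delivery_days}"
            )
        if self.who_group in {"1", "2", "3"}:
            lo, hi = GA_BANDS[int(self.who_group)]
            ok = lo <= self.ga_inclusion_days <= hi and lo <= self.ga_delivery_days <= hi
        elif self.who_group in {"4a", "4b", "4c"}:
            band = {"4a": 1, "4b": 2, "4c": 3}[self.who_group]
            lo, hi = GA_BANDS[band]
            ok = lo <= self.ga_inclusion_days <= hi and self.ga_delivery_days >= TERM_CUTOFF_DAYS
        else:
            raise ConfigurationError(f"unknown who_group {self.who_group!r}")
        if not ok:
            raise ConfigurationError(
                f"{self.sample_id}: who_group {self.who_group} inconsistent with "
                f"ga fields ({self.ga_inclusion_days}, {self.ga_delivery_days})"
            )


@dataclass
class Cohort:
    """Generated samples plus the planted-signal ground truth sidecar."""

    samples: list[tuple[SampleRecord, ChromatogramGrid]]
    ground_truth: dict

    @property
    def records(self) -> list[SampleRecord]:
        return [r for r, _ in self.samples]

    @property
    def grids(self) -> list[ChromatogramGrid]:
        return [g for _, g in self.samples]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


# ---------------------------------------------------------------------------
# grid construction


def make_grid(rt_axis, dt_axis) -> ChromatogramGrid:
    """Return a zero-filled grid over the given axes."""
    rt = _as_axis(rt_axis)
    dt = _as_axis(dt_axis)
    return ChromatogramGrid(rt, dt, np.zeros((rt.size, dt.size)))


def _check_center(axis: np.ndarray, center: float, what: str) -> float:
    if not (axis[0] <= center <= axis[-1]):
        raise OutOfRangeError(
            f"{what} center {center} outside axis range [{axis[0]}, {axis[-1]}]"
        )
    # snap to the nearest grid coordinate so the peak attains its amplitude
    # exactly at one cell
    return float(axis[np.argmin(np.abs(axis - center))])


def add_peak(grid: ChromatogramGrid, peak: PeakSpec) -> ChromatogramGrid:
    """Add a separable 2D Gaussian peak; the input grid is not modified.

    The peak center is snapped to the nearest grid cell, which therefore
    carries exactly ``peak.amplitude`` on a zero background.
    """
    rt_c = _check_center(grid.rt_axis, peak.rt_center, "peak rt")
    dt_c = _check_center(grid.dt_axis, peak.dt_center, "peak dt")
    rt_prof = np.exp(-0.5 * ((grid.rt_axis - rt_c) / peak.rt_sigma) ** 2)
    dt_prof = np.exp(-0.5 * ((grid.dt_axis - dt_c) / peak.dt_sigma) ** 2)
    intensity = grid.intensity + peak.amplitude * np.outer(rt_prof, dt_prof)
    return ChromatogramGrid(grid.rt_axis, grid.dt_axis, intensity)


def add_rip(grid: ChromatogramGrid, rip: PeakSpec) -> ChromatogramGrid:
    """Add the reactant-ion ridge: Gaussian in drift time, flat over rt."""
    dt_c = _check_center(grid.dt_axis, rip.dt_center, "RIP dt")
    dt_prof = np.exp(-0.5 * ((grid.dt_axis - dt_c) / rip.dt_sigma) ** 2)
    intensity = grid.intensity + rip.amplitude * dt_prof[np.newaxis, :]
    return ChromatogramGrid(grid.rt_axis, grid.dt_axis, intensity)


# ---------------------------------------------------------------------------
# sample and cohort generation


def generate_sample(design: CohortDesign, class_label: str, seed) -> ChromatogramGrid:
    """Render one chromatogram for ``class_label``.

    Deterministic given ``seed`` (an int, ``SeedSequence`` or ``Generator``).
    Noise is additive Gaussian; the final grid is clipped at zero.
    """
    if class_label not in design.planted_effects:
        raise ConfigurationError(f"unknown class label {class_label!r}")
    grid = make_grid(design.rt_axis, design.dt_axis)
    mults = design.planted_effects[class_label]
    for peak, mult in zip(design.template_peaks, mults):
        if peak.amplitude * mult == 0:
            continue
        scaled = PeakSpec(
            peak.rt_center, peak.dt_center, peak.rt_sigma, peak.dt_sigma,
            peak.amplitude * mult,
        )
        grid = add_peak(grid, scaled)
    if design.rip_spec is not None:
        grid = add_rip(grid, design.rip_spec)
    intensity = grid.intensity
    if design.baseline_drift:
        drift = design.baseline_drift * (grid.rt_axis - grid.rt_axis[0])
        intensity = intensity + drift[:, np.newaxis]
    if design.noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, design.noise_sd, size=intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    return ChromatogramGrid(grid.rt_axis, grid.dt_axis, intensity)


def discriminative_peaks(design: CohortDesign) -> list[int]:
    """Indices of template peaks whose multipliers differ across classes."""
    out = []
    for i in range(len(design.template_peaks)):
        mults = {design.planted_effects[c][i] for c in design.class_labels}
        if len(mults) > 1:
            out.append(i)
    return out


def peak_footprint(design: CohortDesign, peak_index: int) -> dict:
    """Pixel footprint of a template peak: all cells within 3 sigma on both axes."""
    peak = design.template_peaks[peak_index]
    rt = np.asarray(design.rt_axis, dtype=float)
    dt = np.asarray(design.dt_axis, dtype=float)
    rt_idx = np.nonzero(np.abs(rt - peak.rt_center) <= 3 * peak.rt_sigma)[0]
    dt_idx = np.nonzero(np.abs(dt - peak.dt_center) <= 3 * peak.dt_sigma)[0]
    pixels = [(int(i), int(j)) for i in rt_idx for j in dt_idx]
    return {
        "peak_index": int(peak_index),
        "rt_window": [peak.rt_center - 3 * peak.rt_sigma, peak.rt_center + 3 * peak.rt_sigma],
        "dt_window": [peak.dt_center - 3 * peak.dt_sigma, peak.dt_center + 3 * peak.dt_sigma],
        "pixels": pixels,
    }


def _sample_covariates(rng: np.random.Generator, class_label: str, is_first_class: bool):
    """Draw clinical covariates consistent with the SampleRecord invariants.

    The first class of a design plays the role of the term arm; all other
    classes are preterm.  Marginal infection frequencies default to the
    study-like cohort mix (chorioamnionitis confined to preterm deliveries,
    UTI rare in both arms).
    """
    term = is_first_class
    if term:
        band = int(rng.choice([1, 2, 3], p=[10 / 26, 15 / 26, 1 / 26]))
        lo, hi = GA_BANDS[band]
        ga_inclusion = int(rng.integers(lo, hi + 1))
        ga_delivery = int(rng.integers(TERM_CUTOFF_DAYS, MAX_TERM_DELIVERY_DAYS + 1))
        who_group = TERM_GROUPS[band]
        chorio = False
        uti = bool(rng.random() < 3 / 26)
        crp = max(0.1, float(rng.normal(6.7, 7.1)))
    else:
        band = int(rng.choice([1, 2, 3], p=[30 / 52, 17 / 52, 5 / 52]))
        lo, hi = GA_BANDS[band]
        ga_inclusion = int(rng.integers(lo, hi + 1))
        ga_delivery = int(rng.integers(ga_inclusion, hi + 1))
        who_group = str(band)
        chorio = bool(rng.random() < 28 / 52)
        uti = bool(rng.random() < 4 / 52)
        crp = max(0.1, float(rng.normal(21.4, 17.6)))
    cervical_length = float(np.clip(rng.normal(21.0, 10.8), 2.0, 45.0))
    return dict(
        delivery_class="term" if term else "preterm",
        ga_inclusion_days=ga_inclusion,
        ga_delivery_days=ga_delivery,
        who_group=who_group,
        chorioamnionitis=chorio,
        uti=uti,
        crp=round(crp, 2),
        cervical_length=round(cervical_length, 1),
    )


def generate_cohort(design: CohortDesign) -> Cohort:
    """Generate all samples of a design plus the ground-truth sidecar.

    The global seed expands to per-sample seeds through a counter-based
    ``SeedSequence`` scheme, so any sample can be regenerated independently
    of generation order.
    """
    samples: list[tuple[SampleRecord, ChromatogramGrid]] = []
    counter = 0
    for class_idx, (label, n) in enumerate(zip(design.class_labels, design.n_per_class)):
        for _ in range(n):
            ss = np.random.SeedSequence(entropy=design.seed, spawn_key=(counter,))
            grid_ss, cov_ss = ss.spawn(2)
            grid = generate_sample(design, label, grid_ss)
            cov = _sample_covariates(np.random.default_rng(cov_ss), label, class_idx == 0)
            sample_id = f"S{counter:04d}"
            record = SampleRecord(
                sample_id=sample_id,
                chromatogram_path=f"chromatograms/{sample_id}.txt",
                **cov,
            )
            samples.append((record, grid))
            counter += 1
    truth = {
        "class_labels": list(design.class_labels),
        "discriminative_peaks": {
            f"peak_{i}": peak_footprint(design, i) for i in discriminative_peaks(design)
        },
    }
    return Cohort(samples=samples, ground_truth=truth)


# ---------------------------------------------------------------------------
# defaults


def default_axes(n_rt: int = 120, n_dt: int = 2500) -> tuple[np.ndarray, np.ndarray]:
    """Instrument-like axes: rt 0..357 s (3 s steps), dt 5..15 ms (4 us steps)."""
    return np.arange(n_rt) * 3.0, 5.0 + np.arange(n_dt) * 0.004


def default_crop_bounds(rt_axis, dt_axis) -> dict:
    """Central-region crop bounds for the default design conventions.

    Keeps the analyte region (see :func:`default_template`) and excludes the
    reactant-ion ridge near the low drift-time edge.
    """
    rt = np.asarray(rt_axis, dtype=float)
    dt = np.asarray(dt_axis, dtype=float)
    return {
        "rt_min": float(np.quantile(rt, 0.05)),
        "rt_max": float(np.quantile(rt, 0.95)),
        "dt_min": float(np.quantile(dt, 0.12)),
        "dt_max": float(np.quantile(dt, 0.85)),
    }


def default_template(
    rt_axis, dt_axis, n_peaks: int = 30, template_seed: int = 20181207
) -> tuple[PeakSpec, ...]:
    """A fixed pseudo-random template of analyte peaks in the central region."""
    rt = np.asarray(rt_axis, dtype=float)
    dt = np.asarray(dt_axis, dtype=float)
    rng = np.random.default_rng(template_seed)
    rt_lo, rt_hi = np.quantile(rt, [0.1, 0.9])
    dt_lo, dt_hi = np.quantile(dt, [0.15, 0.8])
    peaks = []
    for _ in range(n_peaks):
        peaks.append(
            PeakSpec(
                rt_center=float(rng.uniform(rt_lo, rt_hi)),
                dt_center=float(rng.uniform(dt_lo, dt_hi)),
                rt_sigma=float(rng.uniform(0.02, 0.04) * (rt[-1] - rt[0])),
                dt_sigma=float(rng.uniform(0.005, 0.012) * (dt[-1] - dt[0])),
                amplitude=float(rng.uniform(20.0, 200.0)),
            )
        )
    return tuple(peaks)


def default_design(
    n_term: int = 26,
    n_preterm: int = 52,
    n_discriminative: int = 5,
    effect_multiplier: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_rt: int = 120,
    n_dt: int = 2500,
    n_peaks: int = 30,
) -> CohortDesign:
    """Study-scale default: term vs preterm with a few planted peaks.

    ``n_discriminative`` template peaks (the first ones) carry
    ``effect_multiplier`` in the preterm class; set ``n_discriminative=0``
    (or ``effect_multiplier=1``) for a null cohort.
    """
    rt_axis, dt_axis = default_axes(n_rt, n_dt)
    peaks = default_template(rt_axis, dt_axis, n_peaks=n_peaks)
    base = tuple(1.0 for _ in peaks)
    preterm = tuple(
        effect_multiplier if i < n_discriminative else 1.0 for i in range(len(peaks))
    )
    rip = PeakSpec(
        rt_center=float(rt_axis[0]),
        dt_center=float(np.quantile(dt_axis, 0.08)),
        rt_sigma=1.0,
        dt_sigma=0.008 * (dt_axis[-1] - dt_axis[0]),
        amplitude=400.0,
    )
    return CohortDesign(
        rt_axis=tuple(rt_axis),
        dt_axis=tuple(dt_axis),
        class_labels=("term", "preterm"),
        n_per_class=(n_term, n_preterm),
        template_peaks=peaks,
        planted_effects={"term": base, "preterm": preterm},
        rip_spec=rip,
        noise_sd=noise_sd,
        baseline_drift=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# plain-text I/O


def write_chromatogram(grid: ChromatogramGrid, path) -> None:
    """Write the text format: rt axis line, dt axis line, then intensity rows."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(repr(float(v)) for v in grid.rt_axis) + "\n")
        fh.write(",".join(repr(float(v)) for v in grid.dt_axis) + "\n")
        for row in grid.intensity:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_chromatogram(path) -> ChromatogramGrid:
    path = Path(path)
    with path.open() as fh:
        rt = np.array(fh.readline().strip().split(","), dtype=float)
        dt = np.array(fh.readline().strip().split(","), dtype=float)
        intensity = np.loadtxt(fh, delimiter=",", ndmin=2)
    return ChromatogramGrid(rt, dt, intensity)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write manifest.csv, ground_truth.json and chromatograms/*.txt."""
    outdir = Path(outdir)
    (outdir / "chromatograms").mkdir(parents=True, exist_ok=True)
    for record, grid in cohort.samples:
        write_chromatogram(grid, outdir / record.chromatogram_path)
    cohort.manifest().to_csv(outdir / "manifest.csv", index=False)
    with (outdir / "ground_truth.json").open("w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "who_group" in df.columns:
        df["who_group"] = df["who_group"].astype(str)
    required = {"sample_id", "delivery_class", "chromatogram_path"}
    missing = required - set(df.columns)
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"manifest missing columns: {sorted(missing)}")
    return df
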