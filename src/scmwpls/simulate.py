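"""Synthetic fermentation batches: concentration kinetics plus NIR spectra.

The generator emulates a wine-fermentation monitoring study: a 10-day batch
sampled three times a day in triplicate (33 events x 3 subsamples = 99
spectra per batch), with ethanol rising as total soluble solids (sugars)
fall, and trace organic acids creeping upward.  Spectra follow a
Beer-Lambert mixture of per-component Gaussian band profiles on the
11,536-3,952 cm^-1 axis (8 cm^-1 interval), plus baseline offset/slope,
multiplicative scatter, additive detector noise, and hard clipping of the
saturated water combination band inside 5,248-4,984 cm^-1.

Every band center sits where the corresponding functional group absorbs:
ethanol C-H first overtones around 5,976-5,500 and C-H combinations around
4,504-4,250 cm^-1; sugar O-H/C-H overtones near 7,056, 6,400 and 5,610; the
acids' weak features overlap the majors, which is what makes the acid
calibrations genuinely hard at their low (<0.5%, <0.002%) concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import (
    ANALYTES,
    RegionSet,
    ReferenceTable,
    SpectraSet,
    SpectralRegion,
    WavenumberGrid,
    make_grid,
    merge_regions,
)

__all__ = [
    "KineticsSpec",
    "Band",
    "BandSpec",
    "NoiseSpec",
    "FermentationSchedule",
    "DEFAULT_GRID",
    "kinetic_profiles",
    "component_spectrum",
    "simulate_batch",
    "make_study_dataset",
]

#: Acquisition axis of the emulated FT-NIR instrument.
DEFAULT_GRID = make_grid(11536.0, 3952.0, 8.0)

# day -> (ethanol %, TSS Brix, TA %, TVA %): mean fermentation kinetics
_DEFAULT_KINETICS_TABLE: dict[int, tuple[float, float, float, float]] = {
    0: (0.06, 23.70, 0.29, 1.30e-3),
    1: (0.40, 23.17, 0.32, 1.30e-3),
    2: (3.91, 18.42, 0.35, 1.28e-3),
    3: (5.54, 15.88, 0.38, 1.50e-3),
    4: (6.74, 13.87, 0.39, 1.67e-3),
    5: (7.75, 12.33, 0.41, 1.65e-3),
    6: (8.49, 11.35, 0.42, 1.75e-3),
    7: (9.06, 10.83, 0.44, 1.80e-3),
    8: (9.71, 10.52, 0.44, 1.78e-3),
    9: (10.08, 10.33, 0.45, 1.78e-3),
    10: (10.76, 10.25, 0.46, 1.80e-3),
}


@dataclass(frozen=True)
class KineticsSpec:
    """Concentration-versus-time model.

    ``table`` mode interpolates the daily table linearly in time (holding
    the final-day value for up to 24 h past the last tabulated day — the
    fermentation has plateaued by then).  ``parametric`` mode evaluates
    logistic curves.  ``batch_effect_sd`` scales a per-batch multiplicative
    perturbation of each analyte profile (independent across analytes),
    emulating batch-to-batch variation.  ``reference_noise_sd`` is the
    per-sample measurement error of the wet-chemistry reference methods.
    """

    mode: str = "table"
    table: dict[int, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_KINETICS_TABLE)
    )
    logistic: dict[str, tuple[float, float, float, float]] = field(
        # analyte -> (floor, ceiling, rate per h, midpoint h)
        default_factory=lambda: {
            "ethanol": (0.06, 10.9, 0.035, 80.0),
            "tss": (23.8, 10.1, 0.035, 80.0),
            "ta": (0.29, 0.46, 0.02, 100.0),
            "tva": (1.30e-3, 1.80e-3, 0.02, 110.0),
        }
    )
    batch_effect_sd: float = 0.02
    # chosen so each analyte's attainable prediction error is on the scale
    # a GC / refractometer / titration reference method actually delivers:
    # ethanol and TSS well determined, the trace acids near their floor
    reference_noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "ethanol": 0.30,
            "tss": 0.15,
            "ta": 0.012,
            "tva": 8.0e-5,
        }
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("table", "parametric"):
            raise ValueError(f"unknown kinetics mode {self.mode!r}")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: amplitude per unit concentration."""

    center_cm1: float
    width_cm1: float  # Gaussian sigma
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_cm1 <= 0:
            raise ValueError("band width must be positive")


def _default_bands() -> dict[str, tuple[Band, ...]]:
    return {
        # water: fraction-scale concentration (~0.65-0.77)
        "water": (
            Band(8800.0, 250.0, 0.05),
            Band(6900.0, 180.0, 0.90),
            Band(5150.0, 120.0, 4.00),  # saturated combination band
            Band(4600.0, 200.0, 0.40),
        ),
        # ethanol: %-scale (0-11).  Widths are set so the +/-2 sigma support
        # of each band group tiles the assignment window it models:
        # C-H 2nd overtone 8504-8304, O-H 1st overtone 6900-6700 (primary
        # alcohol), C-H 1st overtones 5976-5500, combinations 4504-4250.
        "ethanol": (
            Band(8404.0, 50.0, 1.2e-3),
            Band(6800.0, 50.0, 2.0e-3),
            Band(5900.0, 45.0, 5.0e-3),
            Band(5750.0, 60.0, 6.0e-3),
            Band(5600.0, 45.0, 4.0e-3),
            Band(4450.0, 30.0, 7.0e-3),
            Band(4340.0, 45.0, 6.0e-3),
        ),
        # sugars: Brix-scale (10-24); O-H 1st 7100-6900, starch O-H
        # 6500-6300, C-H 1st near 5610, combinations 4504-4250
        "sugars": (
            Band(8380.0, 40.0, 4.0e-4),
            Band(7000.0, 50.0, 3.0e-3),
            Band(6400.0, 50.0, 2.0e-3),
            Band(5610.0, 55.0, 4.0e-3),
            Band(4400.0, 55.0, 4.0e-3),
            Band(4300.0, 25.0, 3.0e-3),
        ),
        # citric acid: %-scale (~0.3-0.46); weak, overlapped by the majors
        "citric": (
            Band(8404.0, 50.0, 1.0e-2),
            Band(6896.0, 50.0, 3.0e-2),
            Band(5800.0, 50.0, 5.0e-2),
            Band(4350.0, 50.0, 5.0e-2),
        ),
        # acetic acid: %-scale (~0.0011-0.0019); near the noise floor
        "acetic": (
            Band(6896.0, 50.0, 2.0),
            Band(5700.0, 45.0, 5.0),
            Band(4300.0, 40.0, 5.0),
        ),
    }


@dataclass(frozen=True)
class BandSpec:
    """Gaussian band profile per mixture component."""

    bands: dict[str, tuple[Band, ...]] = field(default_factory=_default_bands)

    def __post_init__(self) -> None:
        for comp, bands in self.bands.items():
            if comp != "water" and len(bands) == 0:
                raise ValueError(f"component {comp!r} needs at least one band")


@dataclass(frozen=True)
class NoiseSpec:
    """Instrumental artefact model (all absorbance-scale SDs >= 0).

    Detector response rolls off toward the third-overtone end of the axis,
    so the additive noise SD rises smoothly by ``edge_noise_factor`` above
    ``edge_noise_onset_cm1`` — the reason that region shows high residues
    and is discarded by wavelength selection in practice.
    """

    additive_sd: float = 3.0e-4
    baseline_offset_sd: float = 1.0e-2
    baseline_slope_sd: float = 2.0e-5  # per channel index
    scatter_sd: float = 1.0e-2  # multiplicative, around 1
    edge_noise_factor: float = 10.0
    edge_noise_onset_cm1: float = 9800.0
    edge_noise_width_cm1: float = 150.0
    saturation_clip: float = 2.5
    saturation_region: tuple[float, float] = (5248.0, 4984.0)
    seed: int | None = None

    def noise_profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Per-channel additive noise SD."""
        ramp = 1.0 / (
            1.0
            + np.exp(-(wavenumbers - self.edge_noise_onset_cm1) / self.edge_noise_width_cm1)
        )
        return self.additive_sd * (1.0 + (self.edge_noise_factor - 1.0) * ramp)

    def __post_init__(self) -> None:
        for name in ("additive_sd", "baseline_offset_sd", "baseline_slope_sd", "scatter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FermentationSchedule:
    """Sampling design: per-day sampling offsets and subsample replicates.

    The default reads "three samplings a day, then an 18 h overnight gap"
    as events at day*24 + {0, 3, 6} h for days 0..10 — 33 events, 99 spectra
    per batch with triplicate subsampling.
    """

    days: tuple[int, ...] = tuple(range(11))
    offsets_h: tuple[float, ...] = (0.0, 3.0, 6.0)
    subsamples: int = 3

    def event_times_h(self) -> np.ndarray:
        return np.array(
            [24.0 * d + off for d in self.days for off in self.offsets_h]
        )

    @property
    def n_spectra(self) -> int:
        return len(self.days) * len(self.offsets_h) * self.subsamples


def _profile_values(times_h: np.ndarray, spec: KineticsSpec) -> np.ndarray:
    """(n_times, 4) analyte concentrations, no noise or batch effect."""
    t = np.asarray(times_h, dtype=float)
    if spec.mode == "table":
        days = np.array(sorted(spec.table))
        t_max = days[-1] * 24.0
        if (t < 0).any() or (t > t_max + 24.0).any():
            raise ValueError(
                f"times must lie in [0, {t_max + 24.0}] h for the tabulated "
                "kinetics"
            )
        tt = np.minimum(t, t_max)  # final-day plateau
        cols = []
        for j in range(4):
            vals = np.array([spec.table[d][j] for d in days])
            cols.append(np.interp(tt / 24.0, days, vals))
        return np.column_stack(cols)
    out = np.empty((len(t), 4))
    for j, analyte in enumerate(ANALYTES):
        lo, hi, rate, mid = spec.logistic[analyte]
        out[:, j] = lo + (hi - lo) / (1.0 + np.exp(-rate * (t - mid)))
    return out


def kinetic_profiles(
    times_h: np.ndarray,
    spec: KineticsSpec | None = None,
    batch_factors: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> ReferenceTable:
    """Analyte concentrations at the given times as a reference table.

    ``batch_factors`` (length 4) multiplicatively perturbs each analyte
    profile, as drawn per batch in :func:`simulate_batch`.
    """
    spec = spec or KineticsSpec()
    values = _profile_values(np.asarray(times_h, dtype=float), spec)
    if batch_factors is not None:
        values = values * np.asarray(batch_factors, dtype=float)[None, :]
    ids = sample_ids or [f"t{t:07.2f}h" for t in np.asarray(times_h, dtype=float)]
    return ReferenceTable(
        pd.DataFrame(values, columns=list(ANALYTES), index=ids)
    )


def component_spectrum(
    bands: tuple[Band, ...] | list[Band], grid: WavenumberGrid = DEFAULT_GRID
) -> np.ndarray:
    """Sum of Gaussian bands per unit concentration on the grid."""
    wn = grid.values
    out = np.zeros_like(wn)
    for band in bands:
        out += band.amplitude * np.exp(
            -0.5 * ((wn - band.center_cm1) / band.width_cm1) ** 2
        )
    return out


_COMPONENT_OF_ANALYTE = {
    "ethanol": "ethanol",
    "tss": "sugars",
    "ta": "citric",
    "tva": "acetic",
}


def simulate_batch(
    kinetics: KineticsSpec | None = None,
    bands: BandSpec | None = None,
    noise: NoiseSpec | None = None,
    schedule: FermentationSchedule | None = None,
    seed: int | np.random.SeedSequence = 0,
    batch_id: str = "b1",
    grid: WavenumberGrid = DEFAULT_GRID,
) -> tuple[SpectraSet, ReferenceTable]:
    """Simulate one fermentation batch.

    Subsamples of one sampling event share the event's true concentrations
    but get independent instrument noise and independent reference-method
    measurement error.  Identical seeds give bit-identical output.
    """
    kinetics = kinetics or KineticsSpec()
    bands = bands or BandSpec()
    noise = noise or NoiseSpec()
    schedule = schedule or FermentationSchedule()
    if schedule.n_spectra < 2:
        raise ValueError("schedule must produce at least 2 spectra")
    rng = np.random.default_rng(seed)

    factors = None
    if kinetics.batch_effect_sd > 0:
        factors = rng.normal(1.0, kinetics.batch_effect_sd, size=4)
    times = schedule.event_times_h()
    event_conc = _profile_values(times, kinetics)
    if factors is not None:
        event_conc = event_conc * factors[None, :]

    comp_spectra = {
        name: component_spectrum(b, grid) for name, b in bands.bands.items()
    }
    wn = grid.values
    idx = np.arange(grid.n_points, dtype=float)
    sat_mask = (wn <= noise.saturation_region[0]) & (
        wn >= noise.saturation_region[1]
    )

    rows, ids, meta = [], [], []
    ref_rows = []
    for e, t in enumerate(times):
        ethanol, tss, ta, tva = event_conc[e]
        water = (100.0 - ethanol - tss) / 100.0
        chem = (
            water * comp_spectra["water"]
            + ethanol * comp_spectra["ethanol"]
            + tss * comp_spectra["sugars"]
            + ta * comp_spectra["citric"]
            + tva * comp_spectra["acetic"]
        )
        for s in range(schedule.subsamples):
            scatter = rng.normal(1.0, noise.scatter_sd) if noise.scatter_sd else 1.0
            offset = (
                rng.normal(0.0, noise.baseline_offset_sd)
                if noise.baseline_offset_sd
                else 0.0
            )
            slope = (
                rng.normal(0.0, noise.baseline_slope_sd)
                if noise.baseline_slope_sd
                else 0.0
            )
            eps = (
                rng.normal(0.0, 1.0, size=grid.n_points) * noise.noise_profile(wn)
                if noise.additive_sd
                else 0.0
            )
            spec_row = scatter * chem + offset + slope * idx + eps
            spec_row = np.where(
                sat_mask, np.minimum(spec_row, noise.saturation_clip), spec_row
            )
            rows.append(spec_row)
            ids.append(f"{batch_id}-e{e:02d}-s{s}")
            meta.append((batch_id, t, s))
            ref_err = np.array(
                [
                    rng.normal(0.0, kinetics.reference_noise_sd[a])
                    if kinetics.reference_noise_sd.get(a, 0.0)
                    else 0.0
                    for a in ANALYTES
                ]
            )
            ref_rows.append(np.maximum(event_conc[e] + ref_err, 0.0))

    metadata = pd.DataFrame(meta, columns=["batch", "time_h", "subsample"])
    spectra = SpectraSet(
        grid.step_cm1,
        RegionSet([grid.region()]),
        np.vstack(rows),
        ids,
        metadata,
    )
    refs = ReferenceTable(
        pd.DataFrame(np.vstack(ref_rows), columns=list(ANALYTES), index=ids)
    )
    return spectra, refs


def ground_truth_regions(
    bands: BandSpec | None = None, grid: WavenumberGrid = DEFAULT_GRID
) -> dict[str, RegionSet]:
    """Planted band support (center +/- 2 sigma, snapped to the grid) per
    analyte — the reference answer for region-recovery checks."""
    bands = bands or BandSpec()
    step = grid.step_cm1
    out: dict[str, RegionSet] = {}
    for analyte, comp in _COMPONENT_OF_ANALYTE.items():
        regs = []
        for band in bands.bands[comp]:
            hi = band.center_cm1 + 2 * band.width_cm1
            lo = band.center_cm1 - 2 * band.width_cm1
            hi_snap = grid.high_cm1 - step * np.ceil((grid.high_cm1 - hi) / step)
            lo_snap = grid.high_cm1 - step * np.floor((grid.high_cm1 - lo) / step)
            hi_snap = min(hi_snap, grid.high_cm1)
            lo_snap = max(lo_snap, grid.low_cm1)
            if hi_snap >= lo_snap:
                regs.append(SpectralRegion(hi_snap, lo_snap))
        out[analyte] = merge_regions(regs, step)
    return out


def make_study_dataset(
    seed: int | np.random.SeedSequence = 0,
    kinetics: KineticsSpec | None = None,
    bands: BandSpec | None = None,
    noise: NoiseSpec | None = None,
    schedule: FermentationSchedule | None = None,
    grid: WavenumberGrid = DEFAULT_GRID,
) -> tuple[
    tuple[SpectraSet, ReferenceTable],
    tuple[SpectraSet, ReferenceTable],
    dict[str, RegionSet],
]:
    """Two-batch calibration set (198 spectra), one-batch test set (99
    spectra) and the planted ground-truth regions per analyte."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    child = ss.spawn(3)
    parts = [
        simulate_batch(
            kinetics, bands, noise, schedule, seed=child[i], batch_id=f"b{i + 1}", grid=grid
        )
        for i in range(3)
    ]
    (s1, r1), (s2, r2), (s3, r3) = parts
    cal_spectra = SpectraSet(
        s1.step_cm1,
        s1.regions,
        np.vstack([s1.absorbance, s2.absorbance]),
        s1.sample_ids + s2.sample_ids,
        pd.concat([s1.metadata, s2.metadata], ignore_index=True),
    )
    cal_refs = ReferenceTable(pd.concat([r1.data, r2.data]))
    return (cal_spectra, cal_refs), (s3, r3), ground_truth_regions(bands, grid)
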