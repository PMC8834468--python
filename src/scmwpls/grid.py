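"""Wavenumber grids, spectral regions and the sample x channel container.

NIR spectra are acquired on a uniform wavenumber axis stored high-to-low
(acquisition order).  Regions are closed intervals ``high-low`` in cm^-1 with
both endpoints included in the point count; all arithmetic on the axis is
exact integer arithmetic on ``(value - low) / step`` — endpoints are never
snapped to the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectralRegion",
    "RegionSet",
    "SpectraSet",
    "ReferenceTable",
    "make_grid",
    "count_points",
    "region_to_indices",
    "exclude_regions",
    "ANALYTES",
]

#: The four analytes tracked through a fermentation run.
ANALYTES = ("ethanol", "tss", "ta", "tva")

_ALIGN_TOL = 1e-9


def _steps_between(high: float, low: float, step: float) -> int:
    """Number of steps between two grid-aligned wavenumbers; raises if the
    span is not an integer multiple of ``step``."""
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    span = high - low
    ratio = span / step
    n = round(ratio)
    if abs(ratio - n) > _ALIGN_TOL:
        raise ValueError(
            f"span {high}-{low} = {span} cm^-1 is not divisible by step "
            f"{step} (remainder {span - n * step:g})"
        )
    return int(n)


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform descending wavenumber axis."""

    high_cm1: float
    low_cm1: float
    step_cm1: float

    def __post_init__(self) -> None:
        if self.high_cm1 < self.low_cm1:
            raise ValueError("high_cm1 must be >= low_cm1")
        _steps_between(self.high_cm1, self.low_cm1, self.step_cm1)

    @property
    def n_points(self) -> int:
        return _steps_between(self.high_cm1, self.low_cm1, self.step_cm1) + 1

    @property
    def values(self) -> np.ndarray:
        return self.high_cm1 - self.step_cm1 * np.arange(self.n_points)

    def index_of(self, wavenumber: float) -> int:
        """Exact index of a wavenumber on the grid (0 = high_cm1)."""
        idx = _steps_between(self.high_cm1, wavenumber, self.step_cm1)
        if wavenumber < self.low_cm1 - _ALIGN_TOL or wavenumber > self.high_cm1 + _ALIGN_TOL:
            raise ValueError(
                f"{wavenumber} cm^-1 outside grid {self.high_cm1}-{self.low_cm1}"
            )
        return idx

    def region(self) -> "SpectralRegion":
        return SpectralRegion(self.high_cm1, self.low_cm1)


@dataclass(frozen=True)
class SpectralRegion:
    """Closed wavenumber interval, written ``high-low`` as in region tables."""

    high_cm1: float
    low_cm1: float

    def __post_init__(self) -> None:
        if self.high_cm1 < self.low_cm1:
            raise ValueError(
                f"region high ({self.high_cm1}) must be >= low ({self.low_cm1})"
            )

    def n_points(self, step_cm1: float) -> int:
        return _steps_between(self.high_cm1, self.low_cm1, step_cm1) + 1

    def contains(self, other: "SpectralRegion") -> bool:
        return self.high_cm1 >= other.high_cm1 and self.low_cm1 <= other.low_cm1

    def overlaps(self, other: "SpectralRegion") -> bool:
        return self.high_cm1 >= other.low_cm1 and other.high_cm1 >= self.low_cm1

    def __str__(self) -> str:
        def fmt(v: float) -> str:
            return f"{v:g}"

        return f"{fmt(self.high_cm1)}-{fmt(self.low_cm1)}"

    @classmethod
    def from_string(cls, text: str) -> "SpectralRegion":
        """Parse ``"9104-7984"`` (en-dash tolerated)."""
        parts = text.replace("–", "-").split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse region {text!r}")
        return cls(float(parts[0]), float(parts[1]))


@dataclass(frozen=True)
class RegionSet:
    """Ordered, pairwise-disjoint regions, descending by high_cm1.

    Regions may not overlap or touch; touching intervals must be merged
    (see :func:`merge_regions`) before constructing a set.
    """

    regions: tuple[SpectralRegion, ...]

    def __init__(self, regions: Iterable[SpectralRegion]):
        regs = tuple(
            r if isinstance(r, SpectralRegion) else SpectralRegion.from_string(r)
            for r in regions
        )
        regs = tuple(sorted(regs, key=lambda r: -r.high_cm1))
        for a, b in zip(regs, regs[1:]):
            if b.high_cm1 >= a.low_cm1:
                raise ValueError(f"regions {a} and {b} overlap or touch")
        object.__setattr__(self, "regions", regs)

    def __iter__(self) -> Iterator[SpectralRegion]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __str__(self) -> str:
        return ", ".join(str(r) for r in self.regions)

    @classmethod
    def from_string(cls, text: str) -> "RegionSet":
        """Parse ``"9104-7984, 7752-6704"``."""
        return cls(
            SpectralRegion.from_string(p) for p in text.split(",") if p.strip()
        )

    def total_points(self, step_cm1: float) -> int:
        return sum(r.n_points(step_cm1) for r in self.regions)

    def union_with(self, region: SpectralRegion, step_cm1: float) -> "RegionSet":
        """Add a region, merging any intervals that overlap or touch on the
        given grid step."""
        return merge_regions([*self.regions, region], step_cm1)


def merge_regions(
    regions: Sequence[SpectralRegion], step_cm1: float
) -> RegionSet:
    """Normalize a collection of regions: sort descending and merge any pair
    that overlaps or whose endpoints are adjacent grid points."""
    regs = sorted(regions, key=lambda r: -r.high_cm1)
    merged: list[SpectralRegion] = []
    for r in regs:
        if merged and r.high_cm1 >= merged[-1].low_cm1 - step_cm1 - _ALIGN_TOL:
            last = merged.pop()
            r = SpectralRegion(last.high_cm1, min(last.low_cm1, r.low_cm1))
        merged.append(r)
    return RegionSet(merged)


def make_grid(high_cm1: float, low_cm1: float, step_cm1: float) -> WavenumberGrid:
    """Build the uniform descending acquisition grid, e.g.
    ``make_grid(11536, 3952, 8)`` for the 949-point FT-NIR axis."""
    return WavenumberGrid(high_cm1, low_cm1, step_cm1)


def count_points(step_cm1: float, regions: RegionSet | SpectralRegion) -> int:
    """Total number of grid channels covered by a region set.

    Both endpoints of every closed region are counted, matching the spectral
    data point counts quoted for instrument acquisition setups.
    """
    if isinstance(regions, SpectralRegion):
        return regions.n_points(step_cm1)
    return regions.total_points(step_cm1)


def region_to_indices(
    grid: WavenumberGrid, region: SpectralRegion
) -> tuple[int, int]:
    """Inclusive (first, last) column indices of a region on a grid."""
    try:
        first = grid.index_of(region.high_cm1)
        last = grid.index_of(region.low_cm1)
    except ValueError as exc:
        step = grid.step_cm1
        near_hi = grid.high_cm1 - step * round((grid.high_cm1 - region.high_cm1) / step)
        near_lo = grid.high_cm1 - step * round((grid.high_cm1 - region.low_cm1) / step)
        raise ValueError(
            f"region {region} endpoints are not on the grid "
            f"(nearest grid values {near_hi:g}, {near_lo:g}): {exc}"
        ) from exc
    return first, last


@dataclass
class SpectraSet:
    """Sample x channel absorbance matrix on a possibly gapped axis.

    The axis is a :class:`RegionSet` of contiguous segments sharing one step;
    matrix columns are the concatenation of the per-segment grids, descending
    within each segment.  Windowed operations must never bridge the gap
    between two segments (physically excluded channels).
    """

    step_cm1: float
    regions: RegionSet
    absorbance: np.ndarray
    sample_ids: list[str]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x channels)")
        n_chan = self.regions.total_points(self.step_cm1)
        if self.absorbance.shape[1] != n_chan:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"region set {self.regions} spans {n_chan} grid points"
            )
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("sample_ids length must match number of rows")
        if not np.isfinite(self.absorbance).all():
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def segment_slices(self) -> list[tuple[SpectralRegion, slice]]:
        """Column slice of each contiguous segment, in storage order."""
        out = []
        start = 0
        for region in self.regions:
            n = region.n_points(self.step_cm1)
            out.append((region, slice(start, start + n)))
            start += n
        return out

    def wavenumbers(self) -> np.ndarray:
        """Concatenated channel wavenumbers (descending within segments)."""
        parts = [
            r.high_cm1 - self.step_cm1 * np.arange(r.n_points(self.step_cm1))
            for r in self.regions
        ]
        return np.concatenate(parts)

    def columns_for(self, regions: RegionSet | SpectralRegion) -> np.ndarray:
        """Column indices covered by sub-regions of the stored axis."""
        wanted = (
            [regions] if isinstance(regions, SpectralRegion) else list(regions)
        )
        cols: list[np.ndarray] = []
        for want in wanted:
            hit = False
            for segment, sl in self.segment_slices():
                if segment.contains(want):
                    first = _steps_between(segment.high_cm1, want.high_cm1, self.step_cm1)
                    last = _steps_between(segment.high_cm1, want.low_cm1, self.step_cm1)
                    cols.append(np.arange(sl.start + first, sl.start + last + 1))
                    hit = True
                    break
            if not hit:
                raise ValueError(
                    f"region {want} is not contained in any stored segment "
                    f"({self.regions})"
                )
        return np.concatenate(cols) if cols else np.empty(0, dtype=int)

    def subset(self, regions: RegionSet | SpectralRegion) -> "SpectraSet":
        cols = self.columns_for(regions)
        regs = (
            RegionSet([regions])
            if isinstance(regions, SpectralRegion)
            else regions
        )
        return SpectraSet(
            self.step_cm1,
            regs,
            self.absorbance[:, cols],
            list(self.sample_ids),
            None if self.metadata is None else self.metadata.copy(),
        )


def exclude_regions(spectra: SpectraSet, exclusions: RegionSet) -> SpectraSet:
    """Drop the channels inside the excluded intervals (e.g. the saturated
    water band) and re-segment the axis so downstream windows never span the
    resulting gap."""
    if len(exclusions) == 0:
        return spectra
    step = spectra.step_cm1
    new_segments: list[SpectralRegion] = []
    keep_cols: list[np.ndarray] = []
    for segment, sl in spectra.segment_slices():
        pieces = [segment]
        for excl in exclusions:
            next_pieces: list[SpectralRegion] = []
            for piece in pieces:
                if not piece.overlaps(excl):
                    next_pieces.append(piece)
                    continue
                if excl.high_cm1 < piece.high_cm1:
                    next_pieces.append(
                        SpectralRegion(piece.high_cm1, excl.high_cm1 + step)
                    )
                if excl.low_cm1 > piece.low_cm1:
                    next_pieces.append(
                        SpectralRegion(excl.low_cm1 - step, piece.low_cm1)
                    )
            pieces = next_pieces
        for piece in pieces:
            first = _steps_between(segment.high_cm1, piece.high_cm1, step)
            last = _steps_between(segment.high_cm1, piece.low_cm1, step)
            keep_cols.append(np.arange(sl.start + first, sl.start + last + 1))
            new_segments.append(piece)
    if not new_segments:
        raise ValueError("exclusions cover the entire spectral axis")
    return SpectraSet(
        step,
        RegionSet(new_segments),
        spectra.absorbance[:, np.concatenate(keep_cols)],
        list(spectra.sample_ids),
        None if spectra.metadata is None else spectra.metadata.copy(),
    )


@dataclass
class ReferenceTable:
    """Per-sample analyte concentrations (the calibration y vectors).

    Columns: ethanol (%), tss (degrees Brix), ta (% as citric acid),
    tva (% as acetic acid), indexed by sample id.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [a for a in ANALYTES if a not in self.data.columns]
        if missing:
            raise ValueError(f"reference table missing analyte columns {missing}")
        if (self.data[list(ANALYTES)] < 0).any().any():
            bad = self.data.index[(self.data[list(ANALYTES)] < 0).any(axis=1)]
            raise ValueError(f"negative concentrations for samples {list(bad)}")

    def __len__(self) -> int:
        return len(self.data)

    def y(self, analyte: str) -> np.ndarray:
        if analyte not in ANALYTES:
            raise KeyError(f"unknown analyte {analyte!r}; expected one of {ANALYTES}")
        return self.data[analyte].to_numpy(dtype=float)

    def aligned_to(self, sample_ids: Sequence[str]) -> "ReferenceTable":
        """Reorder rows to a spectra set's sample ids."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"reference table missing samples {missing}")
        return ReferenceTable(self.data.loc[list(sample_ids)])
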