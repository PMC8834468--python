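"""Spectral pretreatment: Savitzky-Golay second derivative and mean-centering.

The second derivative removes baseline offset and slope contributed by light
scattering and sharpens overlapping overtone bands.  It is computed per
contiguous segment of the axis — windows never bridge an excluded gap — with
a trim edge policy: each segment loses ``(window-1)/2`` channels at each end
rather than fabricating extrapolated edge values.

The derivative is taken with respect to channel index, not cm^-1 (no
``1/step**2`` factor).  PLS calibration after mean-centering is invariant to
a global positive rescaling of X, so this convention cannot change
predictions; it matches common chemometrics software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .grid import RegionSet, SpectraSet, SpectralRegion

__all__ = ["PreprocessSpec", "sg_second_derivative", "mean_center", "apply_preprocess"]


@dataclass(frozen=True)
class PreprocessSpec:
    """Pretreatment configuration.

    method: ``"none"`` (pass-through) or ``"second_derivative"``.
    sg_window_points: full Savitzky-Golay window length (odd).
    sg_polyorder: local polynomial order.
    edge_policy: only ``"trim"`` is supported.
    """

    method: str = "second_derivative"
    sg_window_points: int = 7
    sg_polyorder: int = 2
    edge_policy: str = "trim"

    def __post_init__(self) -> None:
        if self.method not in ("none", "second_derivative"):
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.sg_window_points % 2 != 1:
            raise ValueError("sg_window_points must be odd")
        if self.sg_window_points <= self.sg_polyorder:
            raise ValueError("sg_window_points must exceed sg_polyorder")
        if self.edge_policy != "trim":
            raise ValueError("only the 'trim' edge policy is supported")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "sg_window_points": self.sg_window_points,
            "sg_polyorder": self.sg_polyorder,
            "edge_policy": self.edge_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(**d)


def sg_second_derivative(
    spectra: SpectraSet, spec: PreprocessSpec | None = None
) -> SpectraSet:
    """Savitzky-Golay second derivative per contiguous segment, trim edges.

    Each segment of ``p`` channels yields ``p - (window - 1)`` output
    channels; the output axis regions shrink accordingly.
    """
    spec = spec or PreprocessSpec()
    w = spec.sg_window_points
    half = (w - 1) // 2
    step = spectra.step_cm1
    out_blocks: list[np.ndarray] = []
    out_regions: list[SpectralRegion] = []
    for region, sl in spectra.segment_slices():
        p = sl.stop - sl.start
        if p < w:
            raise ValueError(
                f"segment {region} has {p} channels, fewer than the "
                f"Savitzky-Golay window of {w}"
            )
        block = savgol_filter(
            spectra.absorbance[:, sl],
            window_length=w,
            polyorder=spec.sg_polyorder,
            deriv=2,
            delta=1.0,
            axis=1,
            mode="interp",
        )
        out_blocks.append(block[:, half : p - half])
        out_regions.append(
            SpectralRegion(region.high_cm1 - half * step, region.low_cm1 + half * step)
        )
    return SpectraSet(
        step,
        RegionSet(out_regions),
        np.hstack(out_blocks),
        list(spectra.sample_ids),
        None if spectra.metadata is None else spectra.metadata.copy(),
    )


def apply_preprocess(
    spectra: SpectraSet, spec: PreprocessSpec | None = None
) -> SpectraSet:
    """Dispatch on the spec's method; ``none`` passes spectra through."""
    spec = spec or PreprocessSpec()
    if spec.method == "none":
        return spectra
    return sg_second_derivative(spectra, spec)


def mean_center(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Column-center X and center y; returns (Xc, yc, x_mean, y_mean)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] < 2:
        raise ValueError("mean-centering requires at least 2 samples")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match X rows")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    return X - x_mean, y - y_mean, x_mean, y_mean
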