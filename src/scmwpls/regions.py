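"""Moving-window PLS wavelength selection.

Step 1 — MWPLSR: a fixed-size window slides over every contiguous segment of
the (preprocessed) axis; at each position PLS-1 models with 1..k_max latent
variables are fitted to the calibration samples and log10 of the sum of
squared calibration residues is recorded.  Plotted against window position
these "residue lines" dip where the spectrum carries analyte information.

Step 2 — SCMWPLS: inside each informative region every sub-interval (all
widths, all positions) is fitted and the one with the smallest RMSEC becomes
the base region; each further informative region contributes its best
sub-interval (possibly none) to a greedy combination that only ever lowers
RMSEC.  Windows and sub-intervals are always confined to one contiguous
segment, so the saturated gap is never bridged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import RegionSet, SpectraSet, SpectralRegion, merge_regions
from .pls import batched_pls1_ssr, max_lv_for_region, pls1_fit

__all__ = [
    "ResidueLines",
    "SCMWPLSResult",
    "mwplsr",
    "detect_informative_regions",
    "scmwpls_best_subwindow",
    "scmwpls_combine",
]

_TIE_TOL = 1e-12
# cap on floats per batched window stack (~32 MB); positions are chunked
_CHUNK_FLOATS = 4_000_000


@dataclass
class ResidueLines:
    """MWPLSR output: log10(SSR) per window position per LV count."""

    window_size: int
    k_max: int
    step_cm1: float
    start_wavenumbers: np.ndarray  # window start (high edge), descending
    segment_index: np.ndarray  # contiguous-segment id per position
    loss: np.ndarray  # (n_positions, k_max)

    @property
    def n_positions(self) -> int:
        return len(self.start_wavenumbers)

    def window_region(self, position: int) -> SpectralRegion:
        high = self.start_wavenumbers[position]
        return SpectralRegion(high, high - (self.window_size - 1) * self.step_cm1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.loss, columns=[f"lv{k}" for k in range(1, self.k_max + 1)]
        )
        df.insert(0, "segment", self.segment_index)
        df.insert(0, "window_start_cm1", self.start_wavenumbers)
        return df


@dataclass
class SCMWPLSResult:
    """Optimized region combination with its full search trace."""

    optimized_regions: RegionSet
    lv_used: int
    final_rmsec: float
    rmsec_trace: list[dict] = field(default_factory=list)
    total_models_evaluated: int = 0

    def report(self) -> str:
        lines = [
            f"optimized regions (cm^-1): {self.optimized_regions}",
            f"latent variables: {self.lv_used}",
            f"final RMSEC: {self.final_rmsec:.6g}",
            f"models evaluated: {self.total_models_evaluated}",
            "trace:",
        ]
        for rec in self.rmsec_trace:
            cand = rec["candidate"] if rec["candidate"] else "(none)"
            lines.append(
                f"  step {rec['step']}: base [{rec['base']}] "
                f"candidate {cand} k={rec['lv']} RMSEC={rec['rmsec']:.6g}"
            )
        return "\n".join(lines)


def _sliding(A: np.ndarray, w: int) -> np.ndarray:
    """(n, p) -> view (positions, n, w) of all width-w windows."""
    v = np.lib.stride_tricks.sliding_window_view(A, w, axis=1)  # (n, P, w)
    return v.transpose(1, 0, 2)


def mwplsr(
    spectra: SpectraSet,
    y: np.ndarray,
    window_size: int = 20,
    k_max: int = 10,
) -> ResidueLines:
    """Slide a ``window_size``-channel window across every segment, fitting
    PLS-1 with 1..k_max latent variables at each position."""
    if window_size <= k_max:
        raise ValueError(
            f"window size ({window_size}) must exceed the maximum LV count "
            f"({k_max}) or the residue lines degenerate"
        )
    y = np.asarray(y, dtype=float).ravel()
    starts: list[np.ndarray] = []
    seg_ids: list[np.ndarray] = []
    losses: list[np.ndarray] = []
    for seg_id, (region, sl) in enumerate(spectra.segment_slices()):
        p = sl.stop - sl.start
        if p < window_size:
            warnings.warn(
                f"segment {region} has {p} channels < window {window_size}; "
                "skipped",
                stacklevel=2,
            )
            continue
        windows = _sliding(spectra.absorbance[:, sl], window_size)
        n_pos = windows.shape[0]
        chunk = max(1, _CHUNK_FLOATS // (windows.shape[1] * window_size))
        ssr_rows = []
        for i0 in range(0, n_pos, chunk):
            ssr_rows.append(
                batched_pls1_ssr(
                    np.ascontiguousarray(windows[i0 : i0 + chunk]), y, k_max
                )
            )
        ssr = np.vstack(ssr_rows)
        losses.append(np.log10(np.maximum(ssr, 1e-300)))
        starts.append(region.high_cm1 - spectra.step_cm1 * np.arange(n_pos))
        seg_ids.append(np.full(n_pos, seg_id))
    if not losses:
        raise ValueError("no segment is wide enough for the moving window")
    return ResidueLines(
        window_size=window_size,
        k_max=k_max,
        step_cm1=spectra.step_cm1,
        start_wavenumbers=np.concatenate(starts),
        segment_index=np.concatenate(seg_ids),
        loss=np.vstack(losses),
    )


def detect_informative_regions(
    lines: ResidueLines,
    lv_ref: int = 3,
    quantile_threshold: float = 0.15,
    min_run: int = 3,
    manual_regions: RegionSet | Sequence[str] | None = None,
) -> RegionSet:
    """Turn residue-line valleys into wavenumber regions.

    Contiguous runs (>= ``min_run`` window positions, never crossing a
    segment gap) whose log10(SSR) at ``lv_ref`` latent variables falls below
    the given quantile of that line are converted to the union of the
    contributing windows.  ``manual_regions`` bypasses detection and returns
    the given regions verbatim — the reproduction path for hand-picked
    regions read off a residue-line plot.
    """
    if manual_regions is not None:
        if isinstance(manual_regions, RegionSet):
            return manual_regions
        return RegionSet(SpectralRegion.from_string(s) for s in manual_regions)
    if not (1 <= lv_ref <= lines.k_max):
        raise ValueError(f"lv_ref must be in 1..{lines.k_max}")
    line = lines.loss[:, lv_ref - 1]
    threshold = np.quantile(line, quantile_threshold)
    below = line < threshold
    regions: list[SpectralRegion] = []
    H, step = lines.window_size, lines.step_cm1
    i = 0
    n = lines.n_positions
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and below[j + 1]
            and lines.segment_index[j + 1] == lines.segment_index[i]
        ):
            j += 1
        if j - i + 1 >= min_run:
            high = lines.start_wavenumbers[i]
            low = lines.start_wavenumbers[j] - (H - 1) * step
            regions.append(SpectralRegion(high, low))
        i = j + 1
    if not regions:
        warnings.warn(
            "no informative regions found below the residue-line threshold",
            stacklevel=2,
        )
        return RegionSet([])
    return merge_regions(regions, step)


def _region_for_cols(
    spectra: SpectraSet, segment: SpectralRegion, start: int, width: int
) -> SpectralRegion:
    """Wavenumber region of columns start..start+width-1 within a segment."""
    high = segment.high_cm1 - spectra.step_cm1 * start
    return SpectralRegion(high, high - spectra.step_cm1 * (width - 1))


def _segment_of(spectra: SpectraSet, region: SpectralRegion) -> SpectralRegion:
    for segment, _ in spectra.segment_slices():
        if segment.contains(region):
            return segment
    raise ValueError(
        f"region {region} is not contained in one contiguous segment "
        f"({spectra.regions}); sub-window searches may not bridge gaps"
    )


def _split_to_segments(
    spectra: SpectraSet, regions: RegionSet
) -> list[SpectralRegion]:
    """Clip regions to the stored segments, splitting any that span a gap."""
    out: list[SpectralRegion] = []
    for region in regions:
        matched = False
        for segment, _ in spectra.segment_slices():
            if segment.overlaps(region):
                out.append(
                    SpectralRegion(
                        min(segment.high_cm1, region.high_cm1),
                        max(segment.low_cm1, region.low_cm1),
                    )
                )
                matched = True
        if not matched:
            raise ValueError(f"region {region} lies outside the stored axis")
    return out


def _enumerate_subwindows(
    S: np.ndarray,
    y: np.ndarray,
    k_cap: int,
    base: np.ndarray | None,
    w_min: int,
    w_max: int | None,
    stride: int,
):
    """Fit every sub-interval of the segment block S (n x p), optionally
    prefixed with fixed base columns.  Yields
    (start, width, k, rmsec_array_over_starts) per width; the caller reduces.
    """
    n, p = S.shape
    wb = 0 if base is None else base.shape[1]
    w_hi = p if w_max is None else min(w_max, p)
    for w in range(w_min, w_hi + 1):
        windows = _sliding(S, w)[::stride]  # (P, n, w)
        n_pos = windows.shape[0]
        k = min(k_cap, wb + w, n - 1)
        chunk = max(1, _CHUNK_FLOATS // (n * (wb + w)))
        rmsec = np.empty(n_pos)
        for i0 in range(0, n_pos, chunk):
            block = np.ascontiguousarray(windows[i0 : i0 + chunk])
            if base is not None:
                nb = block.shape[0]
                block = np.concatenate(
                    [np.broadcast_to(base, (nb, n, wb)), block], axis=2
                )
            rmsec[i0 : i0 + block.shape[0]] = np.sqrt(
                batched_pls1_ssr(block, y, k)[:, k - 1] / n
            )
        yield w, k, rmsec


def scmwpls_best_subwindow(
    spectra: SpectraSet,
    y: np.ndarray,
    region: SpectralRegion,
    k_max: int = 10,
    w_min: int = 1,
    w_max: int | None = None,
    stride: int = 1,
    rel_improvement: float = 0.02,
) -> tuple[SpectralRegion, int, float]:
    """Exhaustively search every sub-interval of one informative region.

    The candidate dimensionality is ``min(cap, width, n-1)`` where the cap
    comes from :func:`max_lv_for_region` on the full region; the interval
    with the smallest RMSEC wins.  Ties (within 1e-12) go to fewer channels,
    then to the higher starting wavenumber.
    """
    region_out, lv, rmsec, _ = _best_subwindow(
        spectra, y, region, k_max, w_min, w_max, stride, rel_improvement
    )
    return region_out, lv, rmsec


def _best_subwindow(
    spectra: SpectraSet,
    y: np.ndarray,
    region: SpectralRegion,
    k_max: int,
    w_min: int,
    w_max: int | None,
    stride: int,
    rel_improvement: float,
    base: np.ndarray | None = None,
    k_cap: int | None = None,
) -> tuple[SpectralRegion, int, float, int]:
    y = np.asarray(y, dtype=float).ravel()
    segment = _segment_of(spectra, region)
    cols = spectra.columns_for(region)
    p = len(cols)
    if p < 1:
        raise ValueError(f"region {region} has zero width on the grid")
    S = spectra.absorbance[:, cols]
    if k_cap is None:
        stack = S if base is None else np.hstack([base, S])
        k_cap = max_lv_for_region(stack, y, k_cap=k_max, rel_improvement=rel_improvement)
    if stride != 1 or w_min != 1 or (w_max is not None and w_max < p):
        warnings.warn(
            "sub-window search restricted (w_min/w_max/stride non-default); "
            "result is an approximation of the exhaustive enumeration",
            stacklevel=2,
        )
    seg_offset = round((segment.high_cm1 - region.high_cm1) / spectra.step_cm1)
    best: tuple[float, int, int, int] | None = None  # rmsec, width, start, k
    n_models = 0
    for w, k, rmsec in _enumerate_subwindows(S, y, k_cap, base, w_min, w_max, stride):
        n_models += len(rmsec)
        i = int(np.argmin(rmsec))
        if best is None or rmsec[i] < best[0] - _TIE_TOL:
            best = (float(rmsec[i]), w, i * stride, k)
    assert best is not None
    rmsec_best, w_best, start, k_best = best
    region_best = _region_for_cols(spectra, segment, seg_offset + start, w_best)
    return region_best, k_best, rmsec_best, n_models


def scmwpls_combine(
    spectra: SpectraSet,
    y: np.ndarray,
    informative: RegionSet,
    order_policy: str = "wavenumber",
    k_max: int = 10,
    w_min: int = 1,
    w_max: int | None = None,
    stride: int = 1,
    rel_improvement: float = 0.02,
    min_improvement: float | None = None,
) -> SCMWPLSResult:
    """Greedy combination of informative regions into one optimized set.

    The best sub-interval of the first region becomes the base; every later
    region offers all its sub-intervals plus the empty interval, and the
    best combination becomes the new base.  A candidate is adopted only when
    it lowers RMSEC by at least ``min_improvement`` relative (default: the
    same ``rel_improvement`` fraction that defines an insignificant error
    decrease in the LV-cap rule) — appending channels to a base almost
    always shaves a chance-level sliver off the in-sample error, and
    accepting such slivers would make whole-region discard impossible.
    Accepted steps therefore never increase RMSEC.

    order_policy: ``"wavenumber"`` processes regions high to low (the order
    informative regions are conventionally lettered); ``"by_rmsec"``
    processes them by ascending individual full-region RMSEC.
    """
    if min_improvement is None:
        min_improvement = rel_improvement
    y = np.asarray(y, dtype=float).ravel()
    pieces = _split_to_segments(spectra, informative)
    if not pieces:
        raise ValueError("need at least one informative region")
    if order_policy == "wavenumber":
        ordered = sorted(pieces, key=lambda r: -r.high_cm1)
    elif order_policy == "by_rmsec":

        def solo_rmsec(r: SpectralRegion) -> float:
            X = spectra.absorbance[:, spectra.columns_for(r)]
            cap = max_lv_for_region(X, y, k_cap=k_max, rel_improvement=rel_improvement)
            return pls1_fit(X, y, min(cap, X.shape[1], len(y) - 1)).rmsec

        ordered = sorted(pieces, key=solo_rmsec)
    else:
        raise ValueError(f"unknown order_policy {order_policy!r}")

    trace: list[dict] = []
    total = 0
    first, *rest = ordered
    base_region, lv, rmsec, n_models = _best_subwindow(
        spectra, y, first, k_max, w_min, w_max, stride, rel_improvement
    )
    total += n_models
    base_set = RegionSet([base_region])
    trace.append(
        {
            "step": 0,
            "base": str(base_set),
            "candidate": str(base_region),
            "lv": lv,
            "rmsec": rmsec,
        }
    )
    for step, region in enumerate(rest, start=1):
        base_cols = spectra.columns_for(base_set)
        Xb = spectra.absorbance[:, base_cols]
        # the LV constraint is estimated from the current base region (the
        # informative region accumulated so far); re-estimating it on
        # base + candidate would let appended noise justify an extra LV
        k_cap_step = max_lv_for_region(
            Xb, y, k_cap=k_max, rel_improvement=rel_improvement
        )
        cand_region, cand_lv, cand_rmsec, n_models = _best_subwindow(
            spectra,
            y,
            region,
            k_max,
            w_min,
            w_max,
            stride,
            rel_improvement,
            base=Xb,
            k_cap=k_cap_step,
        )
        total += n_models + 1  # +1 for the empty-interval candidate
        if cand_rmsec < rmsec * (1.0 - min_improvement) - _TIE_TOL:
            base_set = base_set.union_with(cand_region, spectra.step_cm1)
            rmsec, lv = cand_rmsec, cand_lv
            accepted: str | None = str(cand_region)
        else:
            accepted = None  # the empty interval wins: region discarded
        trace.append(
            {
                "step": step,
                "base": str(base_set),
                "candidate": accepted,
                "lv": lv,
                "rmsec": rmsec,
            }
        )
    # refit from scratch on the optimized set: must reproduce the trace
    X_final = spectra.absorbance[:, spectra.columns_for(base_set)]
    final_model = pls1_fit(X_final, y, min(lv, X_final.shape[1], len(y) - 1))
    if abs(final_model.rmsec - rmsec) > 1e-8 * max(1.0, rmsec):
        warnings.warn(
            f"refit RMSEC {final_model.rmsec:.6g} differs from trace "
            f"{rmsec:.6g}",
            stacklevel=2,
        )
    return SCMWPLSResult(
        optimized_regions=base_set,
        lv_used=lv,
        final_rmsec=final_model.rmsec,
        rmsec_trace=trace,
        total_models_evaluated=total,
    )
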