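"""Readers and writers for spectra and reference tables.

Two plain-text formats are supported:

* comma-separated spectra tables — first column the sample id, optional
  ``batch`` / ``time_h`` / ``subsample`` metadata columns, then one column
  per wavenumber in descending order;
* a JCAMP-DX subset — single-block ``##XYDATA=(X++(Y..Y))`` files with AFFN
  (plain decimal) numbers and a uniform descending abscissa, the form
  produced when exporting FT-NIR absorbance spectra.  One spectrum per file;
  a directory of ``.jdx`` files holds a multi-sample set.
"""

from __future__ import annotations

import os
from pathlib import Path
import numpy as np
import pandas as pd

from .grid import (
    ANALYTES,
    RegionSet,
    ReferenceTable,
    SpectraSet,
    SpectralRegion,
)

__all__ = [
    "read_spectra",
    "write_spectra",
    "read_references",
    "write_references",
    "read_jcamp",
    "write_jcamp",
]

_META_COLS = ("batch", "time_h", "subsample")
_ALIGN_TOL = 1e-6


# ---------------------------------------------------------------- CSV

def write_spectra_csv(spectra: SpectraSet, path: str | os.PathLike) -> None:
    wn = spectra.wavenumbers()
    df = pd.DataFrame(
        spectra.absorbance, columns=[f"{v:.10g}" for v in wn]
    )
    df.insert(0, "sample_id", spectra.sample_ids)
    if spectra.metadata is not None:
        for i, col in enumerate(c for c in _META_COLS if c in spectra.metadata):
            df.insert(1 + i, col, spectra.metadata[col].to_numpy())
    df.to_csv(path, index=False, float_format="%.17g")


def _segments_from_wavenumbers(wn: np.ndarray) -> tuple[float, RegionSet]:
    """Infer step and contiguous segments from a descending header axis."""
    if len(wn) < 2:
        raise ValueError("need at least two channels to infer the grid step")
    diffs = -np.diff(wn)
    step = diffs.min()
    if step <= 0:
        raise ValueError("wavenumber header must be strictly descending")
    ratio = diffs / step
    if np.abs(ratio - np.round(ratio)).max() > _ALIGN_TOL:
        raise ValueError(
            "non-uniform abscissa: channel spacings are not integer "
            "multiples of the smallest spacing"
        )
    breaks = np.nonzero(np.round(ratio).astype(int) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(wn) - 1]])
    regions = RegionSet(
        SpectralRegion(wn[s], wn[e]) for s, e in zip(starts, ends)
    )
    return float(step), regions


def read_spectra_csv(path: str | os.PathLike) -> SpectraSet:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty spectra table")
    meta_cols = [c for c in _META_COLS if c in df.columns]
    wn_cols = [c for c in df.columns if c not in ("sample_id", *meta_cols)]
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber header") from exc
    step, regions = _segments_from_wavenumbers(wn)
    metadata = df[meta_cols].reset_index(drop=True) if meta_cols else None
    return SpectraSet(
        step,
        regions,
        df[wn_cols].to_numpy(dtype=float),
        [str(s) for s in df["sample_id"]],
        metadata,
    )


# ---------------------------------------------------------------- JCAMP-DX

def write_jcamp(
    wavenumbers: np.ndarray,
    absorbance: np.ndarray,
    path: str | os.PathLike,
    title: str = "spectrum",
) -> None:
    """Write one spectrum as a minimal JCAMP-DX ``(X++(Y..Y))`` block."""
    wn = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if wn.ndim != 1 or wn.shape != y.shape:
        raise ValueError("wavenumbers and absorbance must be equal-length 1-D")
    n = len(wn)
    delta = (wn[-1] - wn[0]) / (n - 1) if n > 1 else 0.0
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={wn[0]:.10g}",
        f"##LASTX={wn[-1]:.10g}",
        f"##DELTAX={delta:.10g}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##NPOINTS={n}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, n, per_line):
        ys = " ".join(f"{v:.12e}" for v in y[i : i + per_line])
        lines.append(f"{wn[i]:.10g} {ys}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcamp(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a single-block JCAMP-DX file; returns (wavenumbers, absorbance,
    title).  Only uniform-abscissa AFFN ``(X++(Y..Y))`` data are accepted."""
    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise ValueError(f"{path}: unsupported XYDATA form {value!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = value.strip()
        elif in_data:
            data_lines.append(line)
    for req in ("FIRSTX", "LASTX", "NPOINTS"):
        if req not in header:
            raise ValueError(f"{path}: missing ##{req}")
    firstx = float(header["FIRSTX"])
    lastx = float(header["LASTX"])
    npoints = int(header["NPOINTS"])
    xfactor = float(header.get("XFACTOR", "1"))
    yfactor = float(header.get("YFACTOR", "1"))
    ys: list[float] = []
    scale = max(abs(firstx), abs(lastx), 1.0)
    expected_delta = (lastx - firstx) / (npoints - 1) if npoints > 1 else 0.0
    if "DELTAX" in header and npoints > 1:
        declared = float(header["DELTAX"])
        if abs(declared - expected_delta) > 1e-6 * scale:
            raise ValueError(
                f"{path}: ##DELTAX={declared:g} inconsistent with "
                f"FIRSTX/LASTX/NPOINTS (implies {expected_delta:g})"
            )
    for line in data_lines:
        fields = line.replace(",", " ").split()
        x_here = float(fields[0]) * xfactor
        x_expect = firstx + expected_delta * len(ys)
        if abs(x_here - x_expect) > 1e-6 * scale:
            raise ValueError(
                f"{path}: abscissa check failed at point {len(ys)}: "
                f"line X {x_here:g} vs expected {x_expect:g}"
            )
        ys.extend(float(v) * yfactor for v in fields[1:])
    if len(ys) != npoints:
        raise ValueError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values read")
    wn = firstx + expected_delta * np.arange(npoints)
    return wn, np.asarray(ys), header.get("TITLE", Path(path).stem)


def write_spectra_jcamp(spectra: SpectraSet, directory: str | os.PathLike) -> None:
    """Write each sample as ``<directory>/<sample_id>.jdx``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    wn = spectra.wavenumbers()
    if len(spectra.regions) > 1:
        raise ValueError(
            "JCAMP-DX export requires a contiguous axis; got segments "
            f"{spectra.regions}"
        )
    for sid, row in zip(spectra.sample_ids, spectra.absorbance):
        write_jcamp(wn, row, d / f"{sid}.jdx", title=str(sid))


def read_spectra_jcamp(directory: str | os.PathLike) -> SpectraSet:
    d = Path(directory)
    files = sorted(d.glob("*.jdx")) + sorted(d.glob("*.dx"))
    if not files:
        raise ValueError(f"no .jdx/.dx files in {d}")
    rows, ids = [], []
    wn_ref: np.ndarray | None = None
    for f in files:
        wn, y, title = read_jcamp(f)
        if wn_ref is None:
            wn_ref = wn
        elif len(wn) != len(wn_ref) or np.abs(wn - wn_ref).max() > _ALIGN_TOL:
            raise ValueError(f"{f}: abscissa differs from {files[0]}")
        rows.append(y)
        ids.append(title)
    assert wn_ref is not None
    if wn_ref[0] < wn_ref[-1]:  # ascending file: flip to storage order
        wn_ref = wn_ref[::-1]
        rows = [r[::-1] for r in rows]
    step, regions = _segments_from_wavenumbers(wn_ref)
    return SpectraSet(step, regions, np.vstack(rows), ids)


# ---------------------------------------------------------------- dispatch

def read_spectra(path: str | os.PathLike, format: str = "csv") -> SpectraSet:
    if format == "csv":
        return read_spectra_csv(path)
    if format in ("jcampdx", "jcamp", "jdx"):
        p = Path(path)
        if p.is_dir():
            return read_spectra_jcamp(p)
        wn, y, title = read_jcamp(p)
        if wn[0] < wn[-1]:
            wn, y = wn[::-1], y[::-1]
        step, regions = _segments_from_wavenumbers(wn)
        return SpectraSet(step, regions, y[None, :], [title])
    raise ValueError(f"unknown spectra format {format!r}")


def write_spectra(
    spectra: SpectraSet, path: str | os.PathLike, format: str = "csv"
) -> None:
    if format == "csv":
        write_spectra_csv(spectra, path)
    elif format in ("jcampdx", "jcamp", "jdx"):
        write_spectra_jcamp(spectra, path)
    else:
        raise ValueError(f"unknown spectra format {format!r}")


# ---------------------------------------------------------------- references

def read_references(path: str | os.PathLike) -> ReferenceTable:
    """Read the per-sample analyte table (columns ``sample_id`` then the four
    analytes)."""
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty reference table") from exc
    if df.empty:
        raise ValueError(f"{path}: empty reference table")
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
        df.index = df.index.astype(str)
    missing = [a for a in ANALYTES if a not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing analyte columns {missing}")
    return ReferenceTable(df[list(ANALYTES)].astype(float))


def write_references(table: ReferenceTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, index_label="sample_id", float_format="%.12g")


def join_spectra_references(
    spectra: SpectraSet, references: ReferenceTable
) -> ReferenceTable:
    """Align a reference table to a spectra set, erroring with the offending
    ids if any sample lacks a reference row."""
    missing = [s for s in spectra.sample_ids if s not in references.data.index]
    if missing:
        raise KeyError(
            f"samples without reference values: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    return references.aligned_to(spectra.sample_ids)
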