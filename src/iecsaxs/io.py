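"""Reading and writing 1D SAXS curves, frame-series manifests and gradients.

File conventions follow community practice for reduced SAXS data: a curve is
a whitespace-separated three-column text file (q, I, sigma) with ``#``
comment headers; a frame series is a directory of such files plus a CSV
manifest; gradient programs and simulation setups are TOML.  All values are
written with enough digits to round-trip bit-faithfully for practical
purposes (9 significant digits, relative 1e-9).
"""

from __future__ import annotations

import csv
import math
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FrameSeries, GradientProgram, ScatteringCurve, grids_equal

__all__ = [
    "ConfigError",
    "ParseError",
    "load_gradient",
    "load_series",
    "read_dat",
    "write_dat",
    "write_gradient",
    "write_series",
]


class ParseError(ValueError):
    """Raised for malformed .dat or manifest files; names the offending line."""


class ConfigError(ValueError):
    """Raised for invalid gradient or run configuration files."""


_ANGSTROM_TAGS = {"1/a", "a^-1", "a-1", "1/angstrom", "angstrom^-1", "å^-1", "1/å"}
_NM_TAGS = {"1/nm", "nm^-1", "nm-1"}


# ---------------------------------------------------------------------------
# Single curves
# ---------------------------------------------------------------------------

def read_dat(path) -> ScatteringCurve:
    """Read a three-column (q, I, sigma) text curve.

    Lines starting with ``#`` and blank lines are skipped; ``# key: value``
    headers are collected into the curve metadata.  Two-column files are
    accepted with sigma = sqrt(|I|) as a stated fallback, flagged as
    synthetic in the metadata.  A ``# units:`` header selects the q unit;
    Angstrom^-1 data are converted to nm^-1 (factor 10) on load.
    """
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, ...]] = []
    ncols: int | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip().lower()] = value.strip()
                continue
            parts = line.split()
            try:
                values = tuple(float(p) for p in parts)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric payload {line!r}")
            if len(values) not in (2, 3):
                raise ParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(values)}"
                )
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ParseError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(values)} after {ncols})"
                )
            rows.append(values)
    if len(rows) < 5:
        raise ParseError(f"{path}: fewer than 5 data points ({len(rows)})")
    data = np.array(rows, dtype=float)
    q = data[:, 0]
    I = data[:, 1]
    if ncols == 3:
        sigma = data[:, 2]
    else:
        sigma = np.sqrt(np.abs(I))
        meta["synthetic_sigma"] = True
    units = str(meta.pop("units", "1/nm")).lower()
    if units in _ANGSTROM_TAGS:
        q = q * 10.0  # exact: 1 A^-1 = 10 nm^-1
    elif units not in _NM_TAGS:
        raise ParseError(f"{path}: unknown q units tag {units!r}")
    if np.any(np.diff(q) <= 0):
        bad = int(np.argmax(np.diff(q) <= 0)) + 2
        raise ParseError(f"{path}: q not strictly increasing near data row {bad}")
    return ScatteringCurve(q, I, sigma, meta)


def write_dat(curve: ScatteringCurve, path, header: dict | None = None) -> Path:
    """Write a curve as three columns in scientific notation (9+ digits).

    Metadata (units, frame index, subtraction provenance) goes into ``#``
    header lines; the curve's own metadata is written first, then ``header``.
    """
    path = Path(path)
    meta = {**curve.meta, **(header or {})}
    with path.open("w") as fh:
        fh.write("# units: 1/nm\n")
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# columns: q(1/nm) I(a.u.) sigma(a.u.)\n")
        for q, I, s in zip(curve.q, curve.I, curve.sigma):
            fh.write(f"{q:.9e} {I:.9e} {s:.9e}\n")
    return path


# ---------------------------------------------------------------------------
# Frame series
# ---------------------------------------------------------------------------

def write_series(
    series: FrameSeries,
    directory,
    prefix: str = "frame",
    uv_au: np.ndarray | None = None,
    conductivity_mS: np.ndarray | None = None,
) -> Path:
    """Write every frame as a .dat file plus a CSV manifest.

    The manifest records per-frame metadata (index, filename, time in
    seconds, optional UV absorbance and conductivity traces) and carries the
    authoritative frame/flow rates as ``#`` header lines.  Returns the
    manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    width = max(5, len(str(series.frame_numbers[-1])))
    with manifest.open("w", newline="") as fh:
        fh.write(f"# frame_rate: {series.frame_rate!r}\n")
        fh.write(f"# flow_rate: {series.flow_rate!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "filename", "time_s", "uv_au", "conductivity_mS"])
        for row, n in enumerate(series.frame_numbers):
            fname = f"{prefix}_{int(n):0{width}d}.dat"
            write_dat(series.frame(int(n)), directory / fname)
            writer.writerow([
                int(n),
                fname,
                float(n) / series.frame_rate,
                "" if uv_au is None else repr(float(uv_au[row])),
                "" if conductivity_mS is None else repr(float(conductivity_mS[row])),
            ])
    return manifest


def load_series(manifest_path) -> FrameSeries:
    """Load a frame series from its CSV manifest.

    Frames are ordered by frame index; indices must be unique and
    contiguous, filenames resolve relative to the manifest, and every frame
    must share the grid of the first one (the error names the offender).
    """
    manifest_path = Path(manifest_path)
    meta: dict = {}
    with manifest_path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    table = pd.read_csv(manifest_path, comment="#")
    if "frame_index" not in table or "filename" not in table:
        raise ParseError(f"{manifest_path}: manifest needs frame_index and filename columns")
    table = table.sort_values("frame_index")
    idx = table["frame_index"].to_numpy(dtype=int)
    if len(np.unique(idx)) != len(idx):
        raise ParseError(f"{manifest_path}: duplicate frame indices")
    if np.any(np.diff(idx) != 1):
        gap = int(idx[np.argmax(np.diff(idx) != 1)])
        raise ParseError(
            f"{manifest_path}: frame indices not contiguous (gap after frame {gap})"
        )
    curves = []
    q0 = None
    for n, fname in zip(idx, table["filename"]):
        fpath = manifest_path.parent / str(fname)
        if not fpath.exists():
            raise ParseError(f"{manifest_path}: frame {n}: missing file {fpath}")
        curve = read_dat(fpath)
        if q0 is None:
            q0 = curve.q
        elif not grids_equal(q0, curve.q):
            raise ParseError(
                f"{manifest_path}: frame {n} ({fname}) is on a different q grid"
            )
        curves.append(curve)
    frame_rate = float(meta.get("frame_rate", 1.0))
    flow_rate = float(meta.get("flow_rate", 1.0))
    return FrameSeries.from_curves(
        curves,
        frame_rate=frame_rate,
        flow_rate=flow_rate,
        first_frame_index=int(idx[0]),
    )


# ---------------------------------------------------------------------------
# Gradient programs
# ---------------------------------------------------------------------------

def load_gradient(path) -> GradientProgram:
    """Load a gradient program from TOML.

    Linear example::

        cA_mM = 25.0
        cB_mM = 1000.0
        mode = "linear"
        [linear]
        start_frame = 0
        end_frame = 3600
        f_start = 0.0
        f_end = 1.0

    Step example::

        cA_mM = 25.0
        cB_mM = 1000.0
        mode = "step"
        steps = [[0, 0.0], [1290, 0.12]]
    """
    path = Path(path)
    try:
        with path.open("rb") as fh:
            doc = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    try:
        cA = float(doc["cA_mM"])
        cB = float(doc["cB_mM"])
        mode = str(doc["mode"])
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from exc
    if mode == "linear":
        try:
            lin = doc["linear"]
            schedule = (
                int(lin["start_frame"]), int(lin["end_frame"]),
                float(lin["f_start"]), float(lin["f_end"]),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing linear schedule key {exc}") from exc
    elif mode == "step":
        try:
            schedule = tuple((int(s), float(f)) for s, f in doc["steps"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: malformed step schedule: {exc}") from exc
    else:
        raise ConfigError(f"{path}: unknown gradient mode {mode!r}")
    try:
        return GradientProgram(cA, cB, mode, schedule)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_gradient(program: GradientProgram, path) -> Path:
    """Write a gradient program as TOML (inverse of :func:`load_gradient`)."""
    path = Path(path)
    lines = [
        f"cA_mM = {program.cA!r}",
        f"cB_mM = {program.cB!r}",
        f'mode = "{program.mode}"',
    ]
    if program.mode == "linear":
        start, end, f0, f1 = program.schedule
        lines += [
            "",
            "[linear]",
            f"start_frame = {int(start)}",
            f"end_frame = {int(end)}",
            f"f_start = {f0!r}",
            f"f_end = {f1!r}",
        ]
    else:
        steps = ", ".join(f"[{int(s)}, {f!r}]" for s, f in program.schedule)
        lines.append(f"steps = [{steps}]")
    path.write_text("\n".join(lines) + "\n")
    return path
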