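"""Core containers and curve arithmetic for chromatography-coupled SAXS.

Everything downstream (shift-scan background correction, step-transition
modelling, Guinier/Porod analysis) is built on three containers: a single
azimuthally averaged curve (:class:`ScatteringCurve`), a time-ordered stack
of curves sharing one q grid (:class:`FrameSeries`), and the salt-gradient
program of the chromatography run (:class:`GradientProgram`).

Units: the momentum transfer q is expressed in nm^-1 internally; Angstrom^-1
input is converted on I/O with an exact factor of 10.  Intensities are in
arbitrary units (a.u.) unless a curve is tagged otherwise; on the absolute
scale used here 1 a.u. = 8.03e-4 cm^-1, chosen so that the forward
scattering of an idealized protein equals concentration (mg/ml) times molar
mass (kDa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "AU_TO_INV_CM",
    "BandSpec",
    "BandMean",
    "EmptyBandError",
    "FrameSeries",
    "GradientProgram",
    "GridMismatchError",
    "LOW_BAND",
    "MATCH_BAND",
    "MID_BAND",
    "OutOfRangeError",
    "RatioResult",
    "ScatteringCurve",
    "UndefinedRatioError",
    "average_curves",
    "band_mean",
    "beam_passage_time",
    "fraction_at",
    "frames_to_volume",
    "low_mid_ratio",
    "normalize_traces",
    "resample_curve",
    "salt_at",
    "subtract_curves",
    "transition_band",
]

#: Conversion from the arbitrary-unit scale to absolute units (cm^-1).
AU_TO_INV_CM = 8.03e-4

#: Relative per-point tolerance when deciding whether two q grids are equal.
GRID_RTOL = 1e-9


class GridMismatchError(ValueError):
    """Raised when curve arithmetic is attempted across different q grids."""


class EmptyBandError(ValueError):
    """Raised when a q band contains no grid points."""


class UndefinedRatioError(ValueError):
    """Raised when a band ratio has a zero denominator."""


class OutOfRangeError(ValueError):
    """Raised when a frame lies outside the coverage of a gradient program."""


# ---------------------------------------------------------------------------
# Bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSpec:
    """A closed q interval [q_lo, q_hi] in nm^-1.

    Band edges are inclusive on both sides.
    """

    q_lo: float
    q_hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.q_lo < self.q_hi):
            raise ValueError(
                f"invalid band {self.name or ''}: need 0 <= q_lo < q_hi, "
                f"got ({self.q_lo}, {self.q_hi})"
            )

    def mask(self, q: np.ndarray) -> np.ndarray:
        return (q >= self.q_lo) & (q <= self.q_hi)


#: Low-q diagnostic band: reflects overall particle size.
LOW_BAND = BandSpec(0.11, 0.5, "low")
#: Mid-q diagnostic band: shape-sensitive features of globular proteins.
MID_BAND = BandSpec(1.5, 2.5, "mid")
#: Band used to match an averaged buffer from a salt series.
MATCH_BAND = BandSpec(4.25, 4.75, "match")


def transition_band(q_max: float) -> BandSpec:
    """Band above 4.5 nm^-1 used to track the buffer level through a salt step."""
    return BandSpec(4.5, q_max, "transition")


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class ScatteringCurve:
    """One azimuthally averaged 1D scattering pattern.

    Attributes
    ----------
    q : ndarray
        Momentum transfer in nm^-1, strictly increasing.
    I : ndarray
        Intensity, arbitrary units unless tagged otherwise in ``meta``.
    sigma : ndarray
        Per-point standard error, same units as ``I``; non-negative.
    meta : dict
        Free-form provenance (frame index, units tag, subtraction record).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if not (q.ndim == I.ndim == sigma.ndim == 1):
            raise ValueError("q, I, sigma must be one-dimensional")
        if not (len(q) == len(I) == len(sigma)):
            raise ValueError(
                f"length mismatch: q={len(q)}, I={len(I)}, sigma={len(sigma)}"
            )
        if len(q) == 0:
            raise ValueError("empty curve")
        if not (np.isfinite(q).all() and np.isfinite(I).all() and np.isfinite(sigma).all()):
            raise ValueError("q, I, sigma must be finite everywhere")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(sigma < 0):
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        object.__setattr__(self, "sigma", sigma)

    def __len__(self) -> int:
        return len(self.q)

    def with_meta(self, **extra) -> "ScatteringCurve":
        meta = dict(self.meta)
        meta.update(extra)
        return ScatteringCurve(self.q, self.I, self.sigma, meta)


def grids_equal(q_a: np.ndarray, q_b: np.ndarray, rtol: float = GRID_RTOL) -> bool:
    if len(q_a) != len(q_b):
        return False
    return bool(np.allclose(q_a, q_b, rtol=rtol, atol=0.0))


def _require_same_grid(q_a: np.ndarray, q_b: np.ndarray, what: str) -> None:
    if not grids_equal(q_a, q_b):
        if len(q_a) != len(q_b):
            raise GridMismatchError(
                f"{what}: grids have different lengths ({len(q_a)} vs {len(q_b)})"
            )
        worst = int(np.argmax(np.abs(q_a - q_b)))
        raise GridMismatchError(
            f"{what}: grids differ, e.g. point {worst}: {q_a[worst]!r} vs {q_b[worst]!r}"
        )


# ---------------------------------------------------------------------------
# Frame series
# ---------------------------------------------------------------------------

class FrameSeries:
    """Time-ordered scattering curves on a common q grid.

    Frames are indexed by an absolute, contiguous frame number starting at
    ``first_frame_index``; at a frame rate of ``frame_rate`` Hz frame N was
    exposed at time N / frame_rate.  ``flow_rate`` (ml/min) links frame
    numbers to eluted volume.
    """

    def __init__(
        self,
        q: np.ndarray,
        I: np.ndarray,
        sigma: np.ndarray,
        *,
        frame_rate: float = 1.0,
        flow_rate: float = 1.0,
        first_frame_index: int = 0,
        meta: dict | None = None,
    ) -> None:
        q = np.asarray(q, dtype=float)
        I = np.asarray(I, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if q.ndim != 1 or I.ndim != 2 or sigma.shape != I.shape:
            raise ValueError("expected q (n_q,), I and sigma (n_frames, n_q)")
        if I.shape[1] != len(q):
            raise ValueError("I width does not match q grid")
        if I.shape[0] == 0:
            raise ValueError("empty frame series")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q must be strictly increasing")
        if frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        self.q = q
        self.I = I
        self.sigma = sigma
        self.frame_rate = float(frame_rate)
        self.flow_rate = float(flow_rate)
        self.first_frame_index = int(first_frame_index)
        self.meta = dict(meta or {})

    # -- construction -------------------------------------------------------

    @classmethod
    def from_curves(
        cls,
        curves: Sequence[ScatteringCurve],
        *,
        frame_rate: float = 1.0,
        flow_rate: float = 1.0,
        first_frame_index: int = 0,
        meta: dict | None = None,
    ) -> "FrameSeries":
        if len(curves) == 0:
            raise ValueError("empty curve list")
        q = curves[0].q
        for i, c in enumerate(curves[1:], start=1):
            _require_same_grid(q, c.q, f"frame {first_frame_index + i}")
        I = np.stack([c.I for c in curves])
        sigma = np.stack([c.sigma for c in curves])
        return cls(
            q, I, sigma,
            frame_rate=frame_rate, flow_rate=flow_rate,
            first_frame_index=first_frame_index, meta=meta,
        )

    # -- basic access -------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.I.shape[0]

    @property
    def n_q(self) -> int:
        return len(self.q)

    @property
    def frame_numbers(self) -> np.ndarray:
        return np.arange(self.first_frame_index, self.first_frame_index + self.n_frames)

    def __len__(self) -> int:
        return self.n_frames

    def _row(self, frame: int) -> int:
        row = int(frame) - self.first_frame_index
        if not (0 <= row < self.n_frames):
            raise IndexError(
                f"frame {frame} outside series range "
                f"[{self.first_frame_index}, {self.first_frame_index + self.n_frames})"
            )
        return row

    def frame(self, frame: int) -> ScatteringCurve:
        """Return the curve at absolute frame number ``frame``."""
        row = self._row(frame)
        return ScatteringCurve(
            self.q, self.I[row], self.sigma[row], {"frame_index": int(frame), **self.meta}
        )

    def __iter__(self) -> Iterator[ScatteringCurve]:
        for n in self.frame_numbers:
            yield self.frame(int(n))

    def slice_frames(self, start: int, stop: int) -> "FrameSeries":
        """Sub-series covering absolute frame numbers [start, stop)."""
        a = self._row(start)
        b = int(stop) - self.first_frame_index
        if not (a < b <= self.n_frames):
            raise IndexError(f"slice [{start}, {stop}) outside series range")
        return FrameSeries(
            self.q, self.I[a:b], self.sigma[a:b],
            frame_rate=self.frame_rate, flow_rate=self.flow_rate,
            first_frame_index=int(start), meta=self.meta,
        )

    # -- per-frame scalar traces -------------------------------------------

    def band_trace(self, band: BandSpec) -> np.ndarray:
        """Per-frame unweighted mean intensity over the band."""
        mask = band.mask(self.q)
        if not mask.any():
            raise EmptyBandError(
                f"band [{band.q_lo}, {band.q_hi}] contains no grid points "
                f"(grid spans [{self.q[0]}, {self.q[-1]}])"
            )
        return self.I[:, mask].mean(axis=1)

    def band_sem_trace(self, band: BandSpec) -> np.ndarray:
        """Per-frame standard error of the band mean (independent points)."""
        mask = band.mask(self.q)
        if not mask.any():
            raise EmptyBandError(
                f"band [{band.q_lo}, {band.q_hi}] contains no grid points "
                f"(grid spans [{self.q[0]}, {self.q[-1]}])"
            )
        n = mask.sum()
        return np.sqrt((self.sigma[:, mask] ** 2).sum(axis=1)) / n

    def total_trace(self) -> np.ndarray:
        """Per-frame total scattering, the integral of I over the q grid."""
        return np.trapezoid(self.I, self.q, axis=1)

    def average(self, start: int | None = None, stop: int | None = None) -> ScatteringCurve:
        """Average of the frames in [start, stop) (absolute frame numbers)."""
        if start is None:
            start = self.first_frame_index
        if stop is None:
            stop = self.first_frame_index + self.n_frames
        sub = self.slice_frames(start, stop)
        n = sub.n_frames
        I = sub.I.mean(axis=0)
        sigma = np.sqrt((sub.sigma ** 2).sum(axis=0)) / n
        return ScatteringCurve(
            self.q, I, sigma,
            {"averaged_frames": (int(start), int(stop)), "n_averaged": n},
        )


# ---------------------------------------------------------------------------
# Gradient programs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientProgram:
    """Salt-gradient program mapping frame number to buffer-B fraction.

    ``cA`` and ``cB`` are the salt concentrations (mM) of the low- and
    high-salt buffers.  In ``linear`` mode the schedule is a tuple
    ``(start_frame, end_frame, f_start, f_end)`` with the fraction ramped
    linearly between the two frames.  In ``step`` mode the schedule is an
    ordered tuple of ``(start_frame, fraction)`` plateaus; each plateau is
    right-continuous, i.e. the new fraction applies from its start frame
    inclusive.
    """

    cA: float
    cB: float
    mode: str
    schedule: tuple

    def __post_init__(self) -> None:
        if self.cB <= self.cA:
            raise ValueError(f"need cB > cA, got cA={self.cA}, cB={self.cB}")
        if self.mode == "linear":
            if len(self.schedule) != 4:
                raise ValueError("linear schedule must be (start, end, f_start, f_end)")
            start, end, f0, f1 = self.schedule
            if not start < end:
                raise ValueError("linear schedule needs start_frame < end_frame")
            for f in (f0, f1):
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"fraction {f} outside [0, 1]")
        elif self.mode == "step":
            steps = tuple((int(s), float(f)) for s, f in self.schedule)
            if len(steps) == 0:
                raise ValueError("step schedule is empty")
            frames = [s for s, _ in steps]
            if any(b <= a for a, b in zip(frames, frames[1:])):
                raise ValueError("step schedule frames must be strictly increasing")
            for _, f in steps:
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"fraction {f} outside [0, 1]")
            object.__setattr__(self, "schedule", steps)
        else:
            raise ValueError(f"unknown gradient mode {self.mode!r}")

    # Convenience methods mirroring the module-level operations.
    def fraction_at(self, frame, *, clamp: bool = True):
        return fraction_at(self, frame, clamp=clamp)

    def salt_at(self, frame, *, clamp: bool = True):
        return salt_at(self, frame, clamp=clamp)

    def step_frames(self) -> list[int]:
        """Frames at which a step program changes its plateau (step mode only)."""
        if self.mode != "step":
            raise ValueError("step_frames is only defined for step programs")
        out = []
        prev = None
        for s, f in self.schedule:
            if prev is not None and f != prev:
                out.append(s)
            prev = f
        return out


def fraction_at(program: GradientProgram, frame, *, clamp: bool = True):
    """Fraction of buffer B in force at ``frame``.

    Linear mode interpolates linearly inside the ramp; step mode returns the
    plateau in force (right-continuous).  Before the first schedule entry the
    initial fraction applies.  With ``clamp=False`` a frame outside the
    programmed coverage raises :class:`OutOfRangeError` instead of holding
    the boundary composition.
    """
    frame_arr = np.asarray(frame, dtype=float)
    scalar = frame_arr.ndim == 0
    if program.mode == "linear":
        start, end, f0, f1 = program.schedule
        if not clamp and (np.any(frame_arr < start) or np.any(frame_arr > end)):
            raise OutOfRangeError(
                f"frame {frame} outside linear schedule coverage [{start}, {end}]"
            )
        t = np.clip((frame_arr - start) / (end - start), 0.0, 1.0)
        out = f0 + t * (f1 - f0)
    else:
        starts = np.array([s for s, _ in program.schedule], dtype=float)
        fracs = np.array([f for _, f in program.schedule], dtype=float)
        idx = np.searchsorted(starts, frame_arr, side="right") - 1
        out = fracs[np.clip(idx, 0, None)]  # before first entry: initial fraction
    return float(out) if scalar else out


def salt_at(program: GradientProgram, frame, *, clamp: bool = True):
    """Salt concentration (mM) at ``frame``: cA + f * (cB - cA)."""
    f = fraction_at(program, frame, clamp=clamp)
    return program.cA + f * (program.cB - program.cA)


# ---------------------------------------------------------------------------
# Scalar conversions
# ---------------------------------------------------------------------------

def frames_to_volume(n_frames: float, frame_rate: float, flow_rate: float) -> float:
    """Eluted volume (ml) corresponding to ``n_frames`` exposures.

    volume = n_frames / frame_rate / 60 * flow_rate, with frame_rate in Hz
    and flow_rate in ml/min.
    """
    if frame_rate <= 0 or flow_rate <= 0:
        raise ValueError("frame_rate and flow_rate must be positive")
    return n_frames / frame_rate / 60.0 * flow_rate


def beam_passage_time(
    flow_rate: float,
    capillary_diameter_mm: float = 1.8,
    beam_height_um: float = 700.0,
) -> float:
    """Mean time (s) for material to cross the X-ray beam in the capillary.

    The linear flow speed is the volumetric flow (ml/min) divided by the
    capillary cross-section; the passage time is the beam height divided by
    that speed.
    """
    if flow_rate <= 0 or capillary_diameter_mm <= 0 or beam_height_um <= 0:
        raise ValueError("flow rate and geometry must be positive")
    area_mm2 = math.pi * (capillary_diameter_mm / 2.0) ** 2
    speed_mm_s = flow_rate * 1000.0 / 60.0 / area_mm2  # 1 ml = 1000 mm^3
    return (beam_height_um / 1000.0) / speed_mm_s


# ---------------------------------------------------------------------------
# Curve arithmetic
# ---------------------------------------------------------------------------

class BandMean(NamedTuple):
    value: float
    n_points: int


def band_mean(curve: ScatteringCurve, band: BandSpec) -> BandMean:
    """Unweighted arithmetic mean of I over grid points with q in the band."""
    mask = band.mask(curve.q)
    if not mask.any():
        raise EmptyBandError(
            f"band [{band.q_lo}, {band.q_hi}] contains no grid points "
            f"(grid spans [{curve.q[0]}, {curve.q[-1]}])"
        )
    return BandMean(float(curve.I[mask].mean()), int(mask.sum()))


def _band_sem(curve: ScatteringCurve, band: BandSpec) -> float:
    mask = band.mask(curve.q)
    n = mask.sum()
    return float(np.sqrt((curve.sigma[mask] ** 2).sum()) / n)


def subtract_curves(sample: ScatteringCurve, background: ScatteringCurve) -> ScatteringCurve:
    """Point-wise subtraction on a shared grid with quadrature error propagation."""
    _require_same_grid(sample.q, background.q, "subtract_curves")
    I = sample.I - background.I
    sigma = np.sqrt(sample.sigma ** 2 + background.sigma ** 2)
    meta = {"subtracted": True}
    if "frame_index" in sample.meta:
        meta["frame_index"] = sample.meta["frame_index"]
    return ScatteringCurve(sample.q, I, sigma, meta)


def average_curves(curves: Sequence[ScatteringCurve]) -> ScatteringCurve:
    """Mean of curves on a shared grid; errors of the mean assuming independence."""
    if len(curves) == 0:
        raise ValueError("cannot average an empty list of curves")
    q = curves[0].q
    for i, c in enumerate(curves[1:], start=1):
        _require_same_grid(q, c.q, f"average_curves (curve {i})")
    n = len(curves)
    I = np.mean([c.I for c in curves], axis=0)
    sigma = np.sqrt(np.sum([c.sigma ** 2 for c in curves], axis=0)) / n
    return ScatteringCurve(q, I, sigma, {"n_averaged": n})


class RatioResult(NamedTuple):
    value: float
    sigma: float


def low_mid_ratio(
    curve: ScatteringCurve,
    low: BandSpec = LOW_BAND,
    mid: BandSpec = MID_BAND,
) -> RatioResult:
    """Ratio of the low-band mean to the mid-band mean.

    The ratio is constant across an elution peak exactly when a single
    species elutes with a correctly subtracted background.  The propagated
    uncertainty is first-order and carried as a diagnostic only.
    """
    lo = band_mean(curve, low)
    mi = band_mean(curve, mid)
    if mi.value == 0.0:
        raise UndefinedRatioError(
            f"mid band [{mid.q_lo}, {mid.q_hi}] mean is zero; ratio undefined"
        )
    value = lo.value / mi.value
    s_lo = _band_sem(curve, low)
    s_mi = _band_sem(curve, mid)
    sigma = abs(value) * math.sqrt(
        (s_lo / lo.value) ** 2 + (s_mi / mi.value) ** 2
    ) if lo.value != 0 else abs(s_lo / mi.value)
    return RatioResult(value, sigma)


def normalize_traces(
    traces: Sequence[np.ndarray],
    roi: tuple[int, int] | None = None,
) -> list[np.ndarray]:
    """Divide each trace by its own mean over the region of interest.

    ``roi`` is an index range (start, stop) into the traces; all traces then
    have mean 1 over that range, which makes traces from different
    subtractions directly comparable.
    """
    out = []
    for k, t in enumerate(traces):
        t = np.asarray(t, dtype=float)
        seg = t if roi is None else t[roi[0]:roi[1]]
        if len(seg) == 0:
            raise ValueError(f"trace {k}: empty region of interest {roi}")
        m = seg.mean()
        if m == 0.0:
            raise ValueError(f"trace {k}: zero mean over region of interest")
        out.append(t / m)
    return out


def resample_curve(curve: ScatteringCurve, new_q: np.ndarray) -> ScatteringCurve:
    """Explicitly resample a curve onto a new grid by linear interpolation.

    No implicit resampling ever happens in curve arithmetic; this utility is
    the single, explicit way to move between grids.  The new grid must lie
    within the old one.
    """
    new_q = np.asarray(new_q, dtype=float)
    if new_q[0] < curve.q[0] or new_q[-1] > curve.q[-1]:
        raise ValueError("new grid extends beyond the measured q range")
    I = np.interp(new_q, curve.q, curve.I)
    sigma = np.interp(new_q, curve.q, curve.sigma)
    return ScatteringCurve(new_q, I, sigma, {**curve.meta, "resampled": True})
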