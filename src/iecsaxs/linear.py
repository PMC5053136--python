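"""Background correction for linear-gradient runs by shift scanning.

On a linear salt gradient the blank (buffer) run reproduces the background
under the sample run up to a clock offset: non-perfect synchronization and
co-elution of ions make the matching background appear a number of frames
later in the buffer run.  The correction scans that offset on a coarse grid
(default 5 frames), subtracts frame-wise at each trial shift, and scores the
flatness of the normalized low-q/mid-q ratio trace across the elution peak:
a correctly subtracted single species gives a flat (parallel) line, an
under-subtracted background a concave-down trace, an over-subtracted one a
convex trace.

The model object is :class:`ShiftScan`; its :meth:`ShiftScan.fit` returns a
:class:`ShiftScanResult` carrying the per-shift metrics, the chosen shift
with its uncertainty, and the corrected series.  The module-level functions
(`shifted_subtract`, `ratio_flatness`, `scan_shifts`,
`flag_heterogeneous_peak`) expose the same steps functionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    BandSpec,
    FrameSeries,
    LOW_BAND,
    MID_BAND,
    UndefinedRatioError,
    grids_equal,
)

__all__ = [
    "FlatnessResult",
    "HeterogeneityReport",
    "InsufficientOverlapError",
    "ShiftScan",
    "ShiftScanResult",
    "default_roi",
    "flag_heterogeneous_peak",
    "ratio_flatness",
    "scan_shifts",
    "shifted_subtract",
]

#: Minimum number of overlapping frames required after shifting.
MIN_OVERLAP = 10
#: Minimum usable region-of-interest length, in frames.
MIN_ROI = 5


class InsufficientOverlapError(ValueError):
    """Raised when sample and buffer runs overlap too little after shifting."""


# ---------------------------------------------------------------------------
# Frame-wise subtraction at a trial shift
# ---------------------------------------------------------------------------

def shifted_subtract(sample: FrameSeries, buffer: FrameSeries, shift: int) -> FrameSeries:
    """Subtract buffer frame N - shift from sample frame N, frame-wise.

    Positive shift means the matching background arrives ``shift`` frames
    later in the sample run than in the buffer run, so sample frame N pairs
    with buffer frame N - shift.  The output covers the overlapping frame
    range only and propagates per-point errors in quadrature.
    """
    if not grids_equal(sample.q, buffer.q):
        raise ValueError("sample and buffer runs are on different q grids")
    shift = int(shift)
    s_lo = sample.first_frame_index
    s_hi = s_lo + sample.n_frames          # exclusive
    b_lo = buffer.first_frame_index
    b_hi = b_lo + buffer.n_frames
    start = max(s_lo, b_lo + shift)
    stop = min(s_hi, b_hi + shift)
    overlap = stop - start
    if overlap < MIN_OVERLAP:
        raise InsufficientOverlapError(
            f"shift {shift}: only {max(overlap, 0)} overlapping frames "
            f"(need at least {MIN_OVERLAP})"
        )
    srow = start - s_lo
    brow = start - shift - b_lo
    I = sample.I[srow:srow + overlap] - buffer.I[brow:brow + overlap]
    sigma = np.sqrt(
        sample.sigma[srow:srow + overlap] ** 2 + buffer.sigma[brow:brow + overlap] ** 2
    )
    return FrameSeries(
        sample.q, I, sigma,
        frame_rate=sample.frame_rate, flow_rate=sample.flow_rate,
        first_frame_index=int(start),
        meta={**sample.meta, "shift": shift, "subtracted": True},
    )


# ---------------------------------------------------------------------------
# Flatness of the ratio trace
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlatnessResult:
    """Flatness diagnostics of a normalized low-q/mid-q ratio trace.

    ``flatness`` is the inverse-variance-weighted RMS residual about a
    fitted straight line (a sloped but straight trace still counts as flat
    -- the criterion is a *parallel* line, so slope is tolerated and
    curvature is not).  Weighting by the propagated per-frame ratio
    uncertainty keeps frames whose mid-band mean sits close to zero -- where
    the ratio is arbitrarily noisy -- from dominating the metric.
    ``curvature`` is the second-order coefficient of a weighted quadratic
    fit in (centred) frame number; negative curvature (concave down)
    indicates under-subtraction, positive curvature over-subtraction.  On
    noise-free input (all sigmas zero) both fits are unweighted.
    """

    flatness: float
    curvature: float
    frames: np.ndarray          # absolute frame numbers of the trace
    trace: np.ndarray           # normalized ratio trace (mean 1 over ROI)
    trace_sem: np.ndarray       # per-frame standard error of the normalized trace
    n_undefined: int


def default_roi(series: FrameSeries, threshold: float = 0.10) -> tuple[int, int]:
    """Region of interest: contiguous frames around the peak maximum whose
    total subtracted scattering exceeds ``threshold`` of the peak maximum.

    Returned as absolute frame numbers (start, stop exclusive).
    """
    total = series.total_trace()
    return _roi_from_trace(total, series.first_frame_index, threshold)


def _roi_from_trace(total: np.ndarray, first: int, threshold: float) -> tuple[int, int]:
    # peak height is measured above the median baseline, so a residual flat
    # background offset does not drag the ROI across the whole run
    base = float(np.median(total))
    peak = int(np.argmax(total))
    cut = base + threshold * (total[peak] - base)
    lo = peak
    while lo > 0 and total[lo - 1] > cut:
        lo -= 1
    hi = peak
    while hi < len(total) - 1 and total[hi + 1] > cut:
        hi += 1
    return (first + lo, first + hi + 1)


def _flatness_from_bands(
    frames: np.ndarray,
    low_mean: np.ndarray,
    mid_mean: np.ndarray,
    low_var: np.ndarray,
    mid_var: np.ndarray,
) -> FlatnessResult:
    """Shared weighted flatness computation from per-frame band statistics.

    Used identically by :func:`ratio_flatness` (on a subtracted series) and
    by the shift scan (on precomputed band traces, since band averaging and
    subtraction commute) so both paths give the same numbers.
    """
    frames = np.asarray(frames, dtype=float)
    if np.all(mid_mean == 0.0) and np.all(low_mean == 0.0):
        # a background match so perfect that nothing remains: flat by
        # definition (arises for identical sample and buffer runs)
        zeros = np.zeros(len(frames))
        return FlatnessResult(0.0, 0.0, frames, np.ones(len(frames)), zeros,
                              len(frames))
    defined = mid_mean != 0.0
    n_undefined = int((~defined).sum())
    if n_undefined > 0.10 * len(frames):
        raise UndefinedRatioError(
            f"{n_undefined} of {len(frames)} ROI frames have a zero mid-band mean"
        )
    frames = frames[defined]
    l, m = low_mean[defined], mid_mean[defined]
    ratio = l / m
    # first-order variance of l/m
    ratio_var = (low_var[defined] + ratio ** 2 * mid_var[defined]) / m ** 2

    weighted = bool(np.all(ratio_var > 0))
    w = 1.0 / ratio_var if weighted else np.ones_like(ratio)
    mean = float(np.average(ratio, weights=w))
    if mean == 0.0:
        raise UndefinedRatioError("ratio trace has zero mean over the ROI")
    trace = ratio / mean
    trace_sem = np.sqrt(ratio_var) / abs(mean)

    x = frames - np.average(frames, weights=w)
    sw = np.sqrt(w)
    lin = np.polynomial.polynomial.polyfit(x, trace, 1, w=sw)
    resid = trace - np.polynomial.polynomial.polyval(x, lin)
    flatness = float(np.sqrt(np.sum(w * resid ** 2) / np.sum(w)))
    quad = np.polynomial.polynomial.polyfit(x, trace, 2, w=sw)
    curvature = float(quad[2])
    return FlatnessResult(flatness, curvature, frames, trace, trace_sem, n_undefined)


def ratio_flatness(
    subtracted: FrameSeries,
    roi: tuple[int, int] | None = None,
    low: BandSpec = LOW_BAND,
    mid: BandSpec = MID_BAND,
) -> FlatnessResult:
    """Flatness metric and curvature of the ratio trace over the ROI.

    The per-frame low/mid band ratio is normalized to mean 1 over the ROI
    (inverse-variance weighted mean); a straight line is fitted (flatness =
    weighted RMS residual about it) and a quadratic in centred frame number
    (curvature = its second-order coefficient).  Frames with an exactly
    zero mid-band mean are excluded; if more than 10 % of the ROI is
    undefined the trace is rejected.
    """
    if roi is None:
        roi = default_roi(subtracted)
    start, stop = int(roi[0]), int(roi[1])
    lo_f = subtracted.first_frame_index
    hi_f = lo_f + subtracted.n_frames
    if not (lo_f <= start < stop <= hi_f):
        raise ValueError(f"ROI [{start}, {stop}) outside subtracted range [{lo_f}, {hi_f})")
    if stop - start < MIN_ROI:
        raise ValueError(f"ROI [{start}, {stop}) shorter than {MIN_ROI} frames")

    rows = slice(start - lo_f, stop - lo_f)
    return _flatness_from_bands(
        subtracted.frame_numbers[rows],
        subtracted.band_trace(low)[rows],
        subtracted.band_trace(mid)[rows],
        subtracted.band_sem_trace(low)[rows] ** 2,
        subtracted.band_sem_trace(mid)[rows] ** 2,
    )


def _classify(flatness: float, curvature: float, roi_half_width: float) -> str:
    """Concave/convex classification of one trace.

    The curvature only matters when its contribution across the ROI exceeds
    the residual noise level: |curvature| * half_width^2 < 2 * flatness is
    classified as acceptable.
    """
    if abs(curvature) * roi_half_width ** 2 < 2.0 * flatness:
        return "acceptable"
    return "under" if curvature < 0 else "over"


# ---------------------------------------------------------------------------
# The scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftScanResult:
    """Outcome of a shift scan.

    ``best_shift`` minimizes the flatness metric (ties broken toward the
    smaller absolute shift); ``best_uncertainty`` is the half-width of the
    contiguous shift set whose metric lies within one standard error of the
    minimum, floored at the grid step.
    """

    shifts_tested: np.ndarray
    flatness: np.ndarray
    curvature: np.ndarray
    classification: list
    best_shift: int
    best_uncertainty: float
    roi: tuple[int, int]
    subtracted: FrameSeries
    best_diagnostics: FlatnessResult

    @property
    def best_index(self) -> int:
        return int(np.nonzero(self.shifts_tested == self.best_shift)[0][0])

    def summary(self) -> str:
        lines = [
            "Shift scan (linear-gradient background correction)",
            f"  shifts tested : {self.shifts_tested[0]}..{self.shifts_tested[-1]} "
            f"({len(self.shifts_tested)} values)",
            f"  ROI (frames)  : [{self.roi[0]}, {self.roi[1]})",
            f"  best shift    : {self.best_shift} +/- {self.best_uncertainty:g} frames",
            f"  min flatness  : {self.flatness[self.best_index]:.4g}",
            f"  classification: {self.classification[self.best_index]}",
            "",
            f"  {'shift':>7s} {'flatness':>12s} {'curvature':>12s}  class",
        ]
        for s, f, c, k in zip(
            self.shifts_tested, self.flatness, self.curvature, self.classification
        ):
            lines.append(f"  {int(s):>7d} {f:>12.5g} {c:>12.4e}  {k}")
        return "\n".join(lines)

    def table(self):
        """Per-shift metrics as a DataFrame."""
        import pandas as pd

        return pd.DataFrame({
            "shift": self.shifts_tested,
            "flatness": self.flatness,
            "curvature": self.curvature,
            "classification": self.classification,
        })

    def plot(self, ax=None):
        """Flatness metric versus shift, marking the chosen value."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.shifts_tested, self.flatness, "o-", ms=3)
        ax.axvline(self.best_shift, color="tab:red", lw=1,
                   label=f"best shift {self.best_shift}")
        ax.set_xlabel("shift (frames)")
        ax.set_ylabel("ratio-trace flatness (RMS about line)")
        ax.legend()
        return ax


class ShiftScan:
    """Shift-scan model for a sample run and a blank gradient run.

    Parameters
    ----------
    sample, buffer : FrameSeries
        Sample and blank runs on a shared q grid.
    shifts : sequence of int, optional
        Trial shifts; default -100..300 in steps of 5 (shifts that leave
        insufficient overlap are dropped).
    roi : (start, stop), optional
        Region of interest in absolute frame numbers.  By default the
        contiguous region around the peak where the total subtracted
        scattering exceeds 10 % of its maximum, determined at the central
        trial shift.
    low, mid : BandSpec
        Bands of the diagnostic ratio.
    refine : bool
        If true, a second pass at step 1 around the coarse minimum is run.
        Off by default: the coarse 5-frame granularity matches the ten-frame
        precision this method can honestly claim.
    """

    DEFAULT_SHIFTS = np.arange(-100, 301, 5)

    def __init__(
        self,
        sample: FrameSeries,
        buffer: FrameSeries,
        shifts=None,
        roi: tuple[int, int] | None = None,
        low: BandSpec = LOW_BAND,
        mid: BandSpec = MID_BAND,
        refine: bool = False,
    ) -> None:
        if not grids_equal(sample.q, buffer.q):
            raise ValueError("sample and buffer runs are on different q grids")
        self.sample = sample
        self.buffer = buffer
        self.shifts = np.asarray(
            self.DEFAULT_SHIFTS if shifts is None else shifts, dtype=int
        )
        if len(self.shifts) == 0:
            raise ValueError("empty shift grid")
        self.roi = roi
        self.low = low
        self.mid = mid
        self.refine = refine

    # -- internals ----------------------------------------------------------

    def _band_traces(self):
        """Precomputed per-frame band means; subtraction and band averaging
        commute, so the ratio trace at any shift follows from these."""
        s, b = self.sample, self.buffer
        return {
            "s_low": s.band_trace(self.low), "s_mid": s.band_trace(self.mid),
            "b_low": b.band_trace(self.low), "b_mid": b.band_trace(self.mid),
            "s_low_v": s.band_sem_trace(self.low) ** 2,
            "s_mid_v": s.band_sem_trace(self.mid) ** 2,
            "b_low_v": b.band_sem_trace(self.low) ** 2,
            "b_mid_v": b.band_sem_trace(self.mid) ** 2,
            "s_tot": s.total_trace(), "b_tot": b.total_trace(),
        }

    def _overlap(self, shift: int) -> tuple[int, int]:
        s, b = self.sample, self.buffer
        start = max(s.first_frame_index, b.first_frame_index + shift)
        stop = min(
            s.first_frame_index + s.n_frames,
            b.first_frame_index + b.n_frames + shift,
        )
        return start, stop

    def _fit_one(self, tr, shift, roi):
        """Flatness/curvature at one shift from precomputed band traces."""
        start, stop = self._overlap(shift)
        # metrics are only comparable across shifts when the same frames are
        # scored; drop shifts whose overlap does not cover the whole ROI
        if start > roi[0] or stop < roi[1]:
            return None
        start, stop = roi
        s, b = self.sample, self.buffer
        srow = slice(start - s.first_frame_index, stop - s.first_frame_index)
        brow = slice(
            start - shift - b.first_frame_index, stop - shift - b.first_frame_index
        )
        frames = np.arange(start, stop, dtype=float)
        try:
            result = _flatness_from_bands(
                frames,
                tr["s_low"][srow] - tr["b_low"][brow],
                tr["s_mid"][srow] - tr["b_mid"][brow],
                tr["s_low_v"][srow] + tr["b_low_v"][brow],
                tr["s_mid_v"][srow] + tr["b_mid_v"][brow],
            )
        except UndefinedRatioError:
            return None
        return result.flatness, result.curvature, stop - start

    def fit(self) -> ShiftScanResult:
        tr = self._band_traces()

        # ROI fixed once, from the subtracted total-scattering trace at the
        # trial shift closest to zero (the clocks are nominally in sync),
        # so all shifts are scored on the same frames.
        if self.roi is None:
            ref_shift = int(self.shifts[np.argmin(np.abs(self.shifts))])
            start, stop = self._overlap(ref_shift)
            if stop - start < MIN_OVERLAP:
                raise InsufficientOverlapError(
                    f"reference shift {ref_shift} leaves no usable overlap"
                )
            s, b = self.sample, self.buffer
            srow = slice(start - s.first_frame_index, stop - s.first_frame_index)
            brow = slice(
                start - ref_shift - b.first_frame_index,
                stop - ref_shift - b.first_frame_index,
            )
            total = tr["s_tot"][srow] - tr["b_tot"][brow]
            roi = _roi_from_trace(total, start, 0.10)
            if roi[1] - roi[0] < MIN_ROI:
                # degenerate total trace (e.g. identical runs): score the
                # whole reference overlap instead
                roi = (start, stop)
        else:
            roi = (int(self.roi[0]), int(self.roi[1]))

        shifts, flat, curv, widths = [], [], [], []
        for shift in self.shifts:
            out = self._fit_one(tr, int(shift), roi)
            if out is None:
                continue
            shifts.append(int(shift))
            flat.append(out[0])
            curv.append(out[1])
            widths.append(out[2])
        if not shifts:
            raise InsufficientOverlapError("no trial shift leaves a usable ROI overlap")
        shifts = np.asarray(shifts)
        flat = np.asarray(flat)
        curv = np.asarray(curv)

        best_idx = _argmin_prefer_small_shift(flat, shifts)

        if self.refine:
            step = int(np.min(np.diff(shifts))) if len(shifts) > 1 else 5
            if step > 1:
                fine = np.arange(shifts[best_idx] - step, shifts[best_idx] + step + 1)
                fine = fine[~np.isin(fine, shifts)]
                for shift in fine:
                    out = self._fit_one(tr, int(shift), roi)
                    if out is None:
                        continue
                    shifts = np.append(shifts, int(shift))
                    flat = np.append(flat, out[0])
                    curv = np.append(curv, out[1])
                order = np.argsort(shifts)
                shifts, flat, curv = shifts[order], flat[order], curv[order]
                best_idx = _argmin_prefer_small_shift(flat, shifts)

        # uncertainty: contiguous shifts whose metric is within one standard
        # error of the minimum (SE of an RMS over n points ~ RMS / sqrt(2n))
        n_roi = roi[1] - roi[0]
        tol = flat[best_idx] / math.sqrt(2.0 * max(n_roi, 2))
        ok = flat <= flat[best_idx] + tol
        lo = hi = best_idx
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        while hi < len(shifts) - 1 and ok[hi + 1]:
            hi += 1
        grid_step = float(np.min(np.diff(shifts))) if len(shifts) > 1 else 5.0
        half_width = (shifts[hi] - shifts[lo]) / 2.0
        best_uncertainty = float(max(half_width, grid_step))

        half = (roi[1] - roi[0]) / 2.0
        classification = [_classify(f, c, half) for f, c in zip(flat, curv)]

        best_shift = int(shifts[best_idx])
        subtracted = shifted_subtract(self.sample, self.buffer, best_shift)
        diag = ratio_flatness(subtracted, roi, self.low, self.mid)
        return ShiftScanResult(
            shifts_tested=shifts,
            flatness=flat,
            curvature=curv,
            classification=classification,
            best_shift=best_shift,
            best_uncertainty=best_uncertainty,
            roi=roi,
            subtracted=subtracted,
            best_diagnostics=diag,
        )


def _argmin_prefer_small_shift(flat: np.ndarray, shifts: np.ndarray) -> int:
    """Index of the smallest metric; exact ties go to the smaller |shift|."""
    best = np.nonzero(flat == flat.min())[0]
    if len(best) == 1:
        return int(best[0])
    return int(best[np.lexsort((shifts[best], np.abs(shifts[best])))[0]])


def scan_shifts(
    sample: FrameSeries,
    buffer: FrameSeries,
    shifts=None,
    roi: tuple[int, int] | None = None,
    low: BandSpec = LOW_BAND,
    mid: BandSpec = MID_BAND,
    refine: bool = False,
) -> ShiftScanResult:
    """Functional wrapper around :class:`ShiftScan`."""
    return ShiftScan(sample, buffer, shifts, roi, low, mid, refine).fit()


# ---------------------------------------------------------------------------
# Heterogeneous-peak flag
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeterogeneityReport:
    flagged: bool
    min_flatness: float
    threshold: float
    roi: tuple[int, int]

    def __bool__(self) -> bool:
        return self.flagged

    def __str__(self) -> str:
        verdict = "HETEROGENEOUS" if self.flagged else "consistent with one species"
        return (
            f"peak over frames [{self.roi[0]}, {self.roi[1]}): {verdict} "
            f"(min flatness {self.min_flatness:.4g}, threshold {self.threshold:.4g})"
        )


def flag_heterogeneous_peak(
    scan: ShiftScanResult, threshold: float | None = None
) -> HeterogeneityReport:
    """Flag a peak for which no shift yields a flat ratio trace.

    If the flatness minimum over all tested shifts exceeds the threshold,
    the sample scattering is not constant across the peak -- more than one
    species elutes.  The default threshold is five times the null level of
    the weighted flatness metric, which for inverse-variance weights is the
    harmonic-mean ratio uncertainty sqrt(n / sum sem^-2) over the ROI (plus
    a small absolute epsilon so noise-free data are judged against round-off
    rather than zero).
    """
    if len(scan.shifts_tested) == 0:
        raise ValueError("empty shift scan")
    min_flatness = float(scan.flatness.min())
    if threshold is None:
        sem = scan.best_diagnostics.trace_sem
        if len(sem) and np.all(sem > 0):
            floor = math.sqrt(len(sem) / float(np.sum(sem ** -2.0)))
        else:
            floor = 0.0
        threshold = 5.0 * floor + 1e-9
    return HeterogeneityReport(
        flagged=bool(min_flatness > threshold),
        min_flatness=min_flatness,
        threshold=float(threshold),
        roi=scan.roi,
    )
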