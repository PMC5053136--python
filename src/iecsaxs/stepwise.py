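"""Background correction for stepwise salt gradients.

A salt step programmed at the pumps reaches the measurement capillary
neither instantaneously nor sharply: dispersion and co-eluting ions smear it
into a delayed, saturating rise.  With buffer measurements available before
(region I) and after (region II) the elution peak, the background level in
between is modelled as a single exponential approach

    y(N) = II - (II - I) * exp[-(N - N0) / N']     for N >= N0,  y = I below,

fitted to the mean scattering in a high-q band (default above 4.5 nm^-1)
where the protein contribution is negligible.  The whole-curve buffer for
any frame is then the pointwise interpolation between the averaged region-I
and region-II buffers with the same exponential weight, which allows a
frame-by-frame subtraction throughout the peak.

When the background changes irregularly (e.g. a transient high-q overshoot
from co-eluting small ions) the exponential model does not apply; the
fallback is to average the peak frames and subtract a matching buffer chosen
from a salt-concentration series by comparing the mean scattering between
4.25 and 4.75 nm^-1 (:func:`match_buffer`), with neighbouring salt steps
providing under/over-subtraction bounds (:func:`bracket_buffers`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import (
    BandSpec,
    FrameSeries,
    GradientProgram,
    ScatteringCurve,
    band_mean,
    grids_equal,
    subtract_curves,
    transition_band,
)
from .linear import FlatnessResult, default_roi, ratio_flatness

__all__ = [
    "BracketResult",
    "BufferMatchResult",
    "FitError",
    "MisSubtractionReport",
    "StepSubtractionResult",
    "StepTransition",
    "StepTransitionModel",
    "bracket_buffers",
    "fit_transition",
    "fit_transition_auto",
    "framewise_subtract_step",
    "half_life",
    "interpolated_buffer",
    "match_buffer",
    "mis_subtraction_bounds",
]

#: Exponential-fit chi2 above which averaged-curve buffer matching is
#: recommended instead of the transition model.
CHI2_RECOMMEND_MATCH = 5.0


class FitError(RuntimeError):
    """Raised when the transition fit fails to converge."""


def half_life(nprime: float) -> float:
    """Frames for the background to move halfway from buffer I to buffer II."""
    if nprime <= 0:
        raise ValueError("N' must be positive")
    return nprime * math.log(2.0)


# ---------------------------------------------------------------------------
# The transition model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepTransitionModel:
    """Fitted exponential buffer transition between two averaged buffers.

    The scalar levels I and II are the high-q band means of the averaged
    region-I and region-II buffers; they are held fixed in the fit, so only
    the onset frame ``N0`` and the decay constant ``Nprime`` are free.  This
    keeps the q-resolved interpolation consistent with the scalar fit.
    """

    buffer_I: ScatteringCurve
    buffer_II: ScatteringCurve
    N0: float
    Nprime: float
    N0_err: float
    Nprime_err: float
    chi2: float
    fit_band: BandSpec
    region_I: tuple[int, int]
    region_II: tuple[int, int]
    level_I: float
    level_II: float
    flags: tuple[str, ...] = ()
    #: frames and trace actually fitted, for plotting/diagnostics
    fit_frames: np.ndarray = field(default=None, repr=False)
    fit_trace: np.ndarray = field(default=None, repr=False)

    @property
    def half_life_frames(self) -> float:
        return half_life(self.Nprime)

    def predict_level(self, N) -> np.ndarray:
        """Scalar band-level prediction at frame(s) N."""
        N = np.asarray(N, dtype=float)
        w = self._weight(N)
        return w * self.level_I + (1.0 - w) * self.level_II

    def _weight(self, N):
        N = np.asarray(N, dtype=float)
        t = N - self.N0
        return np.where(t < 0, 1.0, np.exp(-np.maximum(t, 0.0) / self.Nprime))

    def interpolated_buffer(self, N: float) -> ScatteringCurve:
        return interpolated_buffer(self, N)

    def recommend_matching(self) -> bool:
        """True when the fit is poor enough that averaged-curve buffer
        matching should be used instead of the exponential model."""
        return self.chi2 > CHI2_RECOMMEND_MATCH

    def summary(self) -> str:
        lines = [
            "Exponential buffer transition  y(N) = II - (II - I) exp[-(N - N0)/N']",
            f"  region I  (frames): [{self.region_I[0]}, {self.region_I[1]})   "
            f"level I  = {self.level_I:.6g}",
            f"  region II (frames): [{self.region_II[0]}, {self.region_II[1]})   "
            f"level II = {self.level_II:.6g}",
            f"  N0     = {self.N0:.2f} +/- {self.N0_err:.2f} frames",
            f"  N'     = {self.Nprime:.2f} +/- {self.Nprime_err:.2f} frames"
            f"   (half-life {self.half_life_frames:.1f} frames)",
            f"  chi2   = {self.chi2:.3g}",
            f"  fit band: {self.fit_band.q_lo}-{self.fit_band.q_hi} nm^-1",
        ]
        if self.flags:
            lines.append(f"  flags  : {', '.join(self.flags)}")
        if self.recommend_matching():
            lines.append(
                "  NOTE: poor fit (chi2 > "
                f"{CHI2_RECOMMEND_MATCH:g}); averaged-curve buffer matching "
                "is recommended for these data."
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Fitted high-q band trace and the exponential model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.fit_frames is not None:
            ax.plot(self.fit_frames, self.fit_trace, ".", ms=2, label="band mean")
            ax.plot(self.fit_frames, self.predict_level(self.fit_frames),
                    "r-", label="exponential model")
        ax.axvline(self.N0, color="k", lw=0.8, ls=":", label=f"N0 = {self.N0:.1f}")
        ax.set_xlabel("frame")
        ax.set_ylabel(f"mean I ({self.fit_band.q_lo}-{self.fit_band.q_hi} nm$^{{-1}}$)")
        ax.legend()
        return ax


class StepTransition:
    """Model object for fitting the exponential buffer transition.

    Parameters
    ----------
    series : FrameSeries
        The chromatography run (sample run or blank) containing buffer
        regions before and after the peak.
    region_I, region_II : (start, stop)
        Frame ranges (absolute, stop exclusive) averaged into buffers I and
        II; region I must lie strictly before region II and both must span
        at least 5 frames.
    fit_band : BandSpec, optional
        High-q band whose per-frame mean is fitted; default 4.5 nm^-1 up to
        the end of the grid.
    """

    def __init__(
        self,
        series: FrameSeries,
        region_I: tuple[int, int],
        region_II: tuple[int, int],
        fit_band: BandSpec | None = None,
    ) -> None:
        region_I = (int(region_I[0]), int(region_I[1]))
        region_II = (int(region_II[0]), int(region_II[1]))
        if region_I[1] - region_I[0] < 5 or region_II[1] - region_II[0] < 5:
            raise ValueError("buffer regions must span at least 5 frames")
        if region_I[1] > region_II[0]:
            raise ValueError("region I must lie strictly before region II")
        self.series = series
        self.region_I = region_I
        self.region_II = region_II
        self.fit_band = fit_band or transition_band(float(series.q[-1]))

    def fit(self, n0_grid_step: int = 5) -> StepTransitionModel:
        """Bounded least squares with multi-start over N0.

        The model is non-convex in N0, so the fit is restarted from a coarse
        grid of onsets (every ``n0_grid_step`` frames across the window
        between the two buffer regions) and the lowest-cost solution kept.
        """
        series = self.series
        buffer_I = series.average(*self.region_I)
        buffer_II = series.average(*self.region_II)
        level_I = band_mean(buffer_I, self.fit_band).value
        level_II = band_mean(buffer_II, self.fit_band).value

        start, stop = self.region_I[0], self.region_II[1]
        sub = series.slice_frames(start, stop)
        frames = sub.frame_numbers.astype(float)
        trace = sub.band_trace(self.fit_band)
        trace_var = sub.band_sem_trace(self.fit_band) ** 2

        lo_n0, hi_n0 = float(self.region_I[1]), float(self.region_II[0])
        span = max(hi_n0 - lo_n0, 1.0)

        def model(params):
            n0, nprime = params
            t = frames - n0
            w = np.where(t < 0, 1.0, np.exp(-np.maximum(t, 0.0) / nprime))
            return w * level_I + (1.0 - w) * level_II

        def resid(params):
            return model(params) - trace

        best = None
        starts = np.arange(lo_n0, hi_n0 + 1e-9, n0_grid_step)
        if len(starts) == 0:
            starts = np.array([(lo_n0 + hi_n0) / 2.0])
        for n0_start in starts:
            for np_start in (5.0, 20.0):
                try:
                    sol = least_squares(
                        resid,
                        x0=[n0_start, np_start],
                        bounds=([lo_n0 - span, 1e-6], [hi_n0 + span, 10.0 * span]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    )
                except Exception:
                    continue
                if sol.success and (best is None or sol.cost < best.cost):
                    best = sol
        if best is None:
            raise FitError(
                "transition fit did not converge from any restart "
                f"(N0 grid {lo_n0}..{hi_n0} step {n0_grid_step})"
            )

        n0, nprime = best.x
        flags = []
        if nprime < 0.5:
            flags.append("hard-step")  # N' -> 0 limit: effectively a sharp step
        eps = 1e-6 * span
        if not (lo_n0 - span + eps < n0 < hi_n0 + span - eps) or nprime > 10.0 * span - eps:
            flags.append("pinned-at-bound")

        # parameter errors from the Gauss-Newton covariance
        resid_best = best.fun
        dof = max(len(frames) - 2, 1)
        s2 = float(resid_best @ resid_best) / dof
        try:
            JTJ = best.jac.T @ best.jac
            cov = s2 * np.linalg.inv(JTJ)
            n0_err = float(np.sqrt(max(cov[0, 0], 0.0)))
            nprime_err = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            n0_err = nprime_err = float("nan")

        mean_var = float(trace_var.mean())
        if mean_var > 0:
            chi2 = float(np.mean(resid_best ** 2)) / mean_var
        else:
            chi2 = float(np.mean(resid_best ** 2))  # noise-free input

        return StepTransitionModel(
            buffer_I=buffer_I,
            buffer_II=buffer_II,
            N0=float(n0),
            Nprime=float(nprime),
            N0_err=n0_err,
            Nprime_err=nprime_err,
            chi2=chi2,
            fit_band=self.fit_band,
            region_I=self.region_I,
            region_II=self.region_II,
            level_I=level_I,
            level_II=level_II,
            flags=tuple(flags),
            fit_frames=frames,
            fit_trace=trace,
        )


def fit_transition(
    series: FrameSeries,
    region_I: tuple[int, int],
    region_II: tuple[int, int],
    fit_band: BandSpec | None = None,
) -> StepTransitionModel:
    """Functional wrapper around :class:`StepTransition`."""
    return StepTransition(series, region_I, region_II, fit_band).fit()


def fit_transition_auto(
    series: FrameSeries,
    program: GradientProgram,
    fit_band: BandSpec | None = None,
    region_len: int = 60,
    gap_before_step: int = 20,
) -> StepTransitionModel:
    """Two-pass fit with default buffer regions derived from the program.

    Region I is ``region_len`` frames ending ``gap_before_step`` frames
    before the first programmed step.  A first pass uses the final
    ``region_len`` frames of the series as region II; region II is then
    recomputed to start five half-lives after the fitted onset and the model
    refitted once.
    """
    steps = program.step_frames()
    if not steps:
        raise ValueError("gradient program has no salt step")
    step = steps[0]
    first = series.first_frame_index
    last = first + series.n_frames
    region_I = (max(first, step - gap_before_step - region_len), step - gap_before_step)
    region_II = (last - region_len, last)
    model = fit_transition(series, region_I, region_II, fit_band)
    start_II = int(math.ceil(model.N0 + 5.0 * model.half_life_frames))
    start_II = min(max(start_II, region_I[1] + 1), last - region_len)
    region_II = (start_II, min(start_II + region_len, last))
    return fit_transition(series, region_I, region_II, fit_band)


def interpolated_buffer(model: StepTransitionModel, N: float) -> ScatteringCurve:
    """Whole-curve buffer at frame N, interpolated pointwise in q.

    For N < N0 this is buffer I exactly; beyond, II(q) - [II(q) - I(q)] *
    exp[-(N - N0)/N'], which is bounded between I(q) and II(q) at every q
    and reaches the pointwise midpoint at N0 + N' ln 2.  Sigma is
    interpolated with the same weights.
    """
    w = float(model._weight(float(N)))
    bI, bII = model.buffer_I, model.buffer_II
    I = w * bI.I + (1.0 - w) * bII.I
    sigma = w * bI.sigma + (1.0 - w) * bII.sigma
    return ScatteringCurve(bI.q, I, sigma, {"interpolated_at_frame": float(N)})


# ---------------------------------------------------------------------------
# Frame-wise subtraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepSubtractionResult:
    """Background-corrected series plus stability diagnostics."""

    series: FrameSeries
    model: StepTransitionModel
    roi: tuple[int, int]
    diagnostics: FlatnessResult

    def summary(self) -> str:
        return "\n".join([
            self.model.summary(),
            f"  ROI (frames): [{self.roi[0]}, {self.roi[1]})",
            f"  ratio-trace flatness over ROI: {self.diagnostics.flatness:.4g}",
            f"  curvature: {self.diagnostics.curvature:.4e}",
        ])


def framewise_subtract_step(
    series: FrameSeries,
    model: StepTransitionModel,
    roi: tuple[int, int] | None = None,
) -> StepSubtractionResult:
    """Subtract the interpolated buffer from every frame individually.

    The low-q/mid-q ratio trace over the region of interest is computed on
    the corrected series to confirm a stable signal throughout the peak.
    """
    w = model._weight(series.frame_numbers.astype(float))
    bI, bII = model.buffer_I, model.buffer_II
    if not grids_equal(series.q, bI.q):
        raise ValueError("series and model buffers are on different q grids")
    buf_I = np.outer(w, bI.I) + np.outer(1.0 - w, bII.I)
    buf_sig = np.outer(w, bI.sigma) + np.outer(1.0 - w, bII.sigma)
    I = series.I - buf_I
    sigma = np.sqrt(series.sigma ** 2 + buf_sig ** 2)
    out = FrameSeries(
        series.q, I, sigma,
        frame_rate=series.frame_rate, flow_rate=series.flow_rate,
        first_frame_index=series.first_frame_index,
        meta={**series.meta, "subtracted": True, "method": "step-interpolate"},
    )
    if roi is None:
        roi = default_roi(out)
    diag = ratio_flatness(out, roi)
    return StepSubtractionResult(series=out, model=model, roi=roi, diagnostics=diag)


# ---------------------------------------------------------------------------
# Mis-subtraction bounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MisSubtractionReport:
    """Deliberate over/under-subtractions bracketing the model subtraction.

    Over-subtraction subtracts buffer II directly; under-subtraction
    subtracts the mean of buffers I and II.  Differences from the model
    subtraction are summarized separately above q = 1 nm^-1 (where buffer
    mismatch appears as an approximately constant offset) and below (where
    capillary scattering makes it q-dependent).
    """

    reference: ScatteringCurve
    under_curve: ScatteringCurve
    over_curve: ScatteringCurve
    split_q: float
    #: per-bound (mean, std, coefficient of variation) of the difference above split_q
    above: dict
    #: per-bound max |difference| / total signal below split_q
    below_max_relative: dict

    def summary(self) -> str:
        lines = [
            "Mis-subtraction bounds (over = buffer II, under = mean(I, II))",
            f"  split at q = {self.split_q} nm^-1",
        ]
        for name in ("under", "over"):
            m, s, cv = self.above[name]
            lines.append(
                f"  {name:>5s}: above split mean diff {m:+.4g} (std {s:.3g}, CV {cv:.3g}); "
                f"below split max relative dev {self.below_max_relative[name]:.3g}"
            )
        return "\n".join(lines)


def mis_subtraction_bounds(
    peak_average: ScatteringCurve,
    model: StepTransitionModel,
    frames,
    split_q: float = 1.0,
) -> MisSubtractionReport:
    """Bracket the model-based subtraction of an averaged peak.

    ``peak_average`` is the raw (unsubtracted) average over the peak
    ``frames``; the reference subtraction removes the mean interpolated
    buffer over those frames.  Relative deviations below ``split_q`` are
    quoted against the total (unsubtracted) signal, which is what a
    mis-subtraction perturbs.
    """
    if not grids_equal(peak_average.q, model.buffer_I.q):
        raise ValueError("peak average and model buffers are on different q grids")
    frames = np.asarray(frames, dtype=float)
    w = model._weight(frames)
    bI, bII = model.buffer_I, model.buffer_II
    buf_model = ScatteringCurve(
        bI.q,
        w.mean() * bI.I + (1.0 - w.mean()) * bII.I,
        w.mean() * bI.sigma + (1.0 - w.mean()) * bII.sigma,
    )
    buf_under = ScatteringCurve(bI.q, 0.5 * (bI.I + bII.I),
                                0.5 * np.sqrt(bI.sigma ** 2 + bII.sigma ** 2))
    reference = subtract_curves(peak_average, buf_model)
    under = subtract_curves(peak_average, buf_under)
    over = subtract_curves(peak_average, bII)

    q = peak_average.q
    hi = q >= split_q
    lo = ~hi
    above = {}
    below = {}
    for name, curve in (("under", under), ("over", over)):
        d = curve.I - reference.I
        m = float(d[hi].mean())
        s = float(d[hi].std())
        above[name] = (m, s, s / abs(m) if m != 0 else float("inf"))
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(d[lo]) / np.abs(peak_average.I[lo])
        below[name] = float(np.nanmax(rel)) if lo.any() else float("nan")
    return MisSubtractionReport(
        reference=reference,
        under_curve=under,
        over_curve=over,
        split_q=split_q,
        above=above,
        below_max_relative=below,
    )


# ---------------------------------------------------------------------------
# Averaged-curve buffer matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BufferMatchResult:
    best_label: float
    best_curve: ScatteringCurve
    sample_level: float
    match_band: BandSpec
    #: rows of (label, band level, residual = level - sample level)
    residuals: tuple

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            self.residuals, columns=["label", "band_mean", "residual"]
        )

    def summary(self) -> str:
        lines = [
            f"Buffer matching in {self.match_band.q_lo}-{self.match_band.q_hi} nm^-1",
            f"  sample band mean: {self.sample_level:.6g}",
            f"  best candidate  : {self.best_label}",
            "",
            f"  {'label':>10s} {'band mean':>12s} {'residual':>12s}",
        ]
        for label, level, res in self.residuals:
            mark = " <-- best" if label == self.best_label else ""
            lines.append(f"  {label:>10} {level:>12.6g} {res:>+12.4g}{mark}")
        return "\n".join(lines)


def match_buffer(
    sample_average: ScatteringCurve,
    candidates,
    match_band: BandSpec = None,
) -> BufferMatchResult:
    """Choose the buffer whose high-q band mean best matches the sample's.

    ``candidates`` is a list of (label, curve) pairs, labels typically the
    salt concentration in mM.  Ties are broken toward the lower-salt label.
    """
    from .core import MATCH_BAND

    if match_band is None:
        match_band = MATCH_BAND
    candidates = list(candidates)
    if len(candidates) == 0:
        raise ValueError("no candidate buffers")
    sample_level = band_mean(sample_average, match_band).value
    rows = []
    for label, curve in candidates:
        level = band_mean(curve, match_band).value
        rows.append((label, level, level - sample_level))
    # sort by |residual| then label: ties go to the lower-salt candidate
    best_label, best_level, _ = min(rows, key=lambda r: (abs(r[2]), r[1], r[0]))
    best_curve = dict((label, c) for label, c in candidates)[best_label]
    return BufferMatchResult(
        best_label=best_label,
        best_curve=best_curve,
        sample_level=sample_level,
        match_band=match_band,
        residuals=tuple(rows),
    )


@dataclass(frozen=True)
class BracketResult:
    lower: tuple | None     # (label, curve) from the next lower salt step
    higher: tuple | None    # (label, curve) from the next higher salt step
    at_edge: bool


def bracket_buffers(candidates, best_label) -> BracketResult:
    """Adjacent lower- and higher-salt candidates around the chosen buffer.

    Candidates must be ordered by salt label.  At the ends of the series the
    available neighbour is returned together with an ``at_edge`` flag; the
    bracket provides deliberate under/over-subtractions for error bounds.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to bracket")
    labels = [label for label, _ in candidates]
    if any(b <= a for a, b in zip(labels, labels[1:])):
        raise ValueError("candidates must be strictly ordered by salt label")
    if best_label not in labels:
        raise ValueError(f"label {best_label!r} not among candidates")
    k = labels.index(best_label)
    lower = candidates[k - 1] if k > 0 else None
    higher = candidates[k + 1] if k < len(candidates) - 1 else None
    return BracketResult(lower=lower, higher=higher, at_edge=(lower is None or higher is None))
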