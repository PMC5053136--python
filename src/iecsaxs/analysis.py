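"""Per-curve and per-frame structural analysis of subtracted SAXS data.

Implements the standard invariants of solution scattering:

* Guinier analysis: ln I = ln I0 - (q Rg)^2 / 3 at small q, with an
  automatic, deterministic window search limited to q Rg <= 1.3;
* Porod volume Vp = 2 pi^2 I0 / Q with the invariant
  Q = integral q^2 (I - B) dq, a fitted flat background B, and Guinier /
  Porod-law extrapolation beyond the measured range; protein mass follows
  as Vp / 1.7 nm^3 per kDa;
* mass from the volume of correlation Vc = I0 / integral q I dq
  (Rambo-Tainer), which is concentration-independent;
* concentration from the calibrated forward scattering, I0 = c * M;
* the correlation-map (CorMap) similarity test between curves: the longest
  same-sign run of pointwise differences against an exact fair-coin null,
  with Bonferroni adjustment across a comparison set;
* stable-region selection across an elution peak, combining per-frame
  CorMap tests against a reference frame with the low/mid ratio trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AU_TO_INV_CM,
    BandSpec,
    FrameSeries,
    LOW_BAND,
    MID_BAND,
    ScatteringCurve,
    grids_equal,
)

__all__ = [
    "CormapResult",
    "GuinierError",
    "GuinierResult",
    "PorodResult",
    "StableRegionResult",
    "adjusted_pvalues",
    "auto_guinier",
    "concentration_from_forward",
    "cormap_compare",
    "guinier_fit",
    "longest_run_pvalue",
    "mass_from_porod",
    "mass_from_vc",
    "porod_volume",
    "per_frame_parameters",
    "stable_region",
]

#: Upper limit of the Guinier regime used throughout: q Rg <= 1.3.
QRG_MAX = 1.3
#: Porod mass conversion: protein volume per unit mass, nm^3 per kDa.
POROD_VOLUME_PER_KDA = 1.7
#: Rambo-Tainer mass conversion for proteins: mass (Da) = QR (A^3) / 0.1231.
VC_MASS_CONSTANT = 0.1231


class GuinierError(ValueError):
    """Raised when no valid Guinier region exists."""


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuinierResult:
    """Result of a Guinier fit: Rg and forward scattering with errors.

    ``i_min``/``i_max`` are the first and last fitted point indices
    (inclusive); ``qRg_min``/``qRg_max`` the dimensionless window bounds.
    """

    Rg: float
    Rg_err: float
    I0: float
    I0_err: float
    i_min: int
    i_max: int
    qRg_min: float
    qRg_max: float
    residuals: np.ndarray = field(repr=False)

    def summary(self) -> str:
        return (
            f"Guinier fit: Rg = {self.Rg:.4g} +/- {self.Rg_err:.2g} nm, "
            f"I0 = {self.I0:.4g} +/- {self.I0_err:.2g} a.u., "
            f"points {self.i_min}-{self.i_max}, "
            f"qRg {self.qRg_min:.3f}-{self.qRg_max:.3f}"
        )

    def plot(self, curve: ScatteringCurve, ax=None):
        """Guinier plot (ln I vs q^2) with the fitted window highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sel = slice(self.i_min, self.i_max + 1)
        q2 = curve.q ** 2
        pos = curve.I > 0
        ax.plot(q2[pos], np.log(curve.I[pos]), ".", ms=3, color="0.6")
        fit = math.log(self.I0) - q2[sel] * self.Rg ** 2 / 3.0
        ax.plot(q2[sel], fit, "-", color="tab:green",
                label=f"Rg = {self.Rg:.3g} nm")
        ax.set_xlabel(r"$q^2$ (nm$^{-2}$)")
        ax.set_ylabel(r"$\ln I$")
        ax.legend()
        return ax


def guinier_fit(curve: ScatteringCurve, i_range: tuple[int, int]) -> GuinierResult:
    """Weighted linear regression of ln I on q^2 over points [i_min, i_max].

    Weights are (I/sigma)^2, the first-order variance of ln I; if any sigma
    in the window is zero (noise-free data) the fit is unweighted.  A
    non-negative slope means no Guinier decay and raises
    :class:`GuinierError`.
    """
    i_min, i_max = int(i_range[0]), int(i_range[1])
    if i_max - i_min + 1 < 5:
        raise GuinierError("Guinier window needs at least 5 points")
    sel = slice(i_min, i_max + 1)
    q = curve.q[sel]
    I = curve.I[sel]
    sigma = curve.sigma[sel]
    if np.any(I <= 0):
        raise GuinierError("non-positive intensity inside the Guinier window")
    x = q ** 2
    y = np.log(I)
    if np.any(sigma <= 0):
        # no stated errors: assume counting statistics, sigma ~ sqrt(I)
        w = I.copy()
    else:
        w = (I / sigma) ** 2
    slope, intercept, var_slope, var_intercept = _weighted_linfit(x, y, w)
    if slope >= 0:
        raise GuinierError("no Guinier decay (non-negative slope of ln I vs q^2)")
    Rg = math.sqrt(-3.0 * slope)
    Rg_err = 3.0 * math.sqrt(var_slope) / (2.0 * Rg)
    I0 = math.exp(intercept)
    I0_err = I0 * math.sqrt(var_intercept)
    residuals = y - (intercept + slope * x)
    return GuinierResult(
        Rg=Rg, Rg_err=Rg_err, I0=I0, I0_err=I0_err,
        i_min=i_min, i_max=i_max,
        qRg_min=float(q[0] * Rg), qRg_max=float(q[-1] * Rg),
        residuals=residuals,
    )


def _weighted_linfit(x, y, w):
    """Weighted least squares y = a + b x; returns (b, a, var_b, var_a).

    Parameter variances come from the unscaled normal-equation covariance
    multiplied by the reduced chi-square, so they are meaningful for both
    weighted and unweighted input.
    """
    W = w.sum()
    xb = (w * x).sum() / W
    yb = (w * y).sum() / W
    Sxx = (w * (x - xb) ** 2).sum()
    Sxy = (w * (x - xb) * (y - yb)).sum()
    slope = Sxy / Sxx
    intercept = yb - slope * xb
    resid = y - (intercept + slope * x)
    dof = max(len(x) - 2, 1)
    s2 = (w * resid ** 2).sum() / dof
    var_slope = s2 / Sxx
    var_intercept = s2 * (1.0 / W + xb ** 2 / Sxx)
    return slope, intercept, var_slope, var_intercept


def auto_guinier(
    curve: ScatteringCurve,
    qrg_max: float = QRG_MAX,
    stability: float = 0.05,
    min_points: int = 5,
    t_min: float = 3.0,
) -> GuinierResult:
    """Deterministic automatic Guinier window selection.

    Candidate windows start at successive low-q points; each window extends
    to the largest index keeping q Rg <= ``qrg_max`` (found by fixed-point
    iteration of the fitted Rg).  A window is admissible when the fit has a
    significantly negative slope (|t| >= ``t_min``) and its Rg agrees with
    the neighbouring candidate's within ``stability``.  The longest
    admissible window wins; ties go to the lowest q_min.
    """
    n = len(curve)
    candidates: list[GuinierResult] = []
    # Scan window starts across the low-q third of the grid; stop once the
    # start itself is outside any plausible Guinier regime.
    for i_min in range(0, n - min_points):
        result = _self_consistent_window(curve, i_min, qrg_max, min_points)
        if result is None:
            if candidates and curve.q[i_min] * candidates[-1].Rg > qrg_max:
                break
            continue
        if result.qRg_max > qrg_max * 1.01:
            continue
        t_stat = abs(-(result.Rg ** 2 / 3.0)) / max(
            (2.0 * result.Rg * result.Rg_err / 3.0), 1e-300
        )
        if t_stat < t_min:
            continue
        candidates.append(result)
        if curve.q[i_min] * result.Rg > qrg_max:
            break
    if not candidates:
        raise GuinierError("no admissible Guinier window found")
    stable = []
    for k, cand in enumerate(candidates):
        neighbours = [candidates[j] for j in (k - 1, k + 1) if 0 <= j < len(candidates)]
        if not neighbours or any(
            abs(cand.Rg - nb.Rg) / nb.Rg < stability for nb in neighbours
        ):
            stable.append(cand)
    pool = stable or candidates
    pool.sort(key=lambda r: (-(r.i_max - r.i_min), r.i_min))
    return pool[0]


def _self_consistent_window(curve, i_min, qrg_max, min_points):
    """Iterate i_max until q[i_max] * Rg <= qrg_max is self-consistent."""
    n = len(curve)
    i_max = min(i_min + 3 * min_points, n - 1)
    last = None
    for _ in range(30):
        if i_max - i_min + 1 < min_points:
            return None
        try:
            res = guinier_fit(curve, (i_min, i_max))
        except GuinierError:
            return None
        limit = qrg_max / res.Rg
        new_i_max = int(np.searchsorted(curve.q, limit, side="right")) - 1
        new_i_max = min(max(new_i_max, i_min + min_points - 1), n - 1)
        if new_i_max == i_max:
            return res
        if last is not None and new_i_max == last:
            # two-cycle: take the smaller window
            i_max = min(i_max, new_i_max)
            try:
                return guinier_fit(curve, (i_min, i_max))
            except GuinierError:
                return None
        last = i_max
        i_max = new_i_max
    return res


# ---------------------------------------------------------------------------
# Porod analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PorodResult:
    """Porod volume and invariant with the fitted flat background removed."""

    Vp: float
    Vp_err: float
    porod_constant: float       # C in I ~ B + C q^-4 over the high-q band
    flat_background: float      # fitted B, removed before integrating
    invariant_Q: float
    extrapolated_below: float   # fraction of Q from the q < q_min extension
    extrapolated_above: float   # fraction of Q from the q > q_max tail

    def summary(self) -> str:
        return (
            f"Porod: Vp = {self.Vp:.4g} +/- {self.Vp_err:.2g} nm^3, "
            f"Q = {self.invariant_Q:.4g}, B = {self.flat_background:.4g}, "
            f"extrapolated fractions {self.extrapolated_below:.3f} (low) / "
            f"{self.extrapolated_above:.3f} (high)"
        )


def porod_volume(
    curve: ScatteringCurve,
    guinier: GuinierResult,
    highq_band: BandSpec | None = None,
) -> PorodResult:
    """Porod volume Vp = 2 pi^2 I0 / Q with background removal.

    A flat background B is fitted so that q^4 (I - B) is flat over the
    high-q band (least squares of I on q^-4; default band 3.5 nm^-1 to the
    end of the grid): subtraction residuals at high q appear as a small
    constant, which would otherwise make the invariant diverge.  The
    invariant integrates q^2 (I - B) over the grid, extended by the Guinier
    law below q_min and by the fitted Porod tail C q^-4 above q_max.
    """
    q = curve.q
    if highq_band is None:
        highq_band = BandSpec(3.5, float(q[-1]), "porod")
    mask = highq_band.mask(q)
    if mask.sum() < 5:
        raise ValueError("high-q band holds fewer than 5 points")
    # least squares I = B + C q^-4 on the band, with B constrained so the
    # background can never exceed the measured signal level (over-
    # flattening) and C to be non-negative.  The upper bound on B is the
    # minimum of binned band means rather than the pointwise minimum, which
    # a single noisy point would otherwise drag to zero.
    from scipy.optimize import lsq_linear

    x = q[mask] ** -4.0
    y = curve.I[mask]
    n_bins = int(np.clip(mask.sum() // 10, 4, 10))
    bin_mins = [chunk.mean() for chunk in np.array_split(y, n_bins)]
    b_upper = max(float(min(bin_mins)), 1e-300)
    A = np.column_stack([np.ones_like(x), x])
    sol = lsq_linear(A, y, bounds=([0.0, 0.0], [b_upper, np.inf]))
    B, C = float(sol.x[0]), float(sol.x[1])
    resid = y - A @ sol.x
    dof = max(mask.sum() - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    B_err, C_err = math.sqrt(max(cov[0, 0], 0)), math.sqrt(max(cov[1, 1], 0))

    core = float(np.trapezoid(q ** 2 * (curve.I - B), q))
    # analytic Guinier extension below q_min:
    qs = np.linspace(0.0, q[0], 200)
    low = float(np.trapezoid(qs ** 2 * guinier.I0 * np.exp(-(qs * guinier.Rg) ** 2 / 3.0), qs))
    high = C / q[-1]  # integral of q^2 * C q^-4 from q_max to infinity
    Q = core + low + high
    if Q <= 0:
        raise ValueError(f"non-positive Porod invariant Q = {Q:.4g}")
    Vp = 2.0 * math.pi ** 2 * guinier.I0 / Q
    # first-order error: I0 uncertainty plus the B and C uncertainties in Q
    dQ_dB = -float(np.trapezoid(q ** 2, q))
    Q_err = math.sqrt((dQ_dB * B_err) ** 2 + (C_err / q[-1]) ** 2)
    Vp_err = Vp * math.sqrt((guinier.I0_err / guinier.I0) ** 2 + (Q_err / Q) ** 2)
    return PorodResult(
        Vp=Vp, Vp_err=Vp_err, porod_constant=C, flat_background=B,
        invariant_Q=Q,
        extrapolated_below=low / Q, extrapolated_above=high / Q,
    )


def mass_from_porod(Vp: float) -> float:
    """Protein mass (kDa) from the Porod volume: Vp / 1.7 nm^3 kDa^-1."""
    if Vp <= 0:
        raise ValueError("Porod volume must be positive")
    return Vp / POROD_VOLUME_PER_KDA


# ---------------------------------------------------------------------------
# Volume of correlation
# ---------------------------------------------------------------------------

def mass_from_vc(
    curve: ScatteringCurve,
    guinier: GuinierResult,
    q_cut: float = 3.0,
    plateau_tol: float = 1e-3,
) -> tuple[float, dict]:
    """Mass (kDa) from the volume of correlation Vc = I0 / integral q I dq.

    The integral runs in Angstrom units (the convention of the empirical
    constant) up to ``q_cut`` nm^-1 (0.3 A^-1, the standard upper limit of
    the correlated-volume analysis).  The mass in Da is QR / 0.1231 with
    QR = Vc^2 / Rg in A^3 (Rg in Angstrom); it is returned in kDa.  The
    estimate is concentration-independent: rescaling I rescales I0 and the
    integral together.  If the cumulative integral is still growing faster
    than ``plateau_tol`` per point at the cap (no plateau, e.g. an
    uncorrected flat background) the value is flagged as unconverged in the
    info dict but still returned.
    """
    q_nm = curve.q
    within = q_nm <= q_cut
    if within.sum() < 10:
        raise ValueError("fewer than 10 points below the Vc integration cap")
    qa = q_nm[within] / 10.0      # nm^-1 -> A^-1
    I = curve.I[within]
    integral = float(np.trapezoid(qa * I, qa))
    if integral <= 0:
        raise ValueError("non-positive integral of q I; cannot form Vc")
    # convergence: relative growth per point near the cap
    k = max(2, within.sum() // 20)
    tail = float(np.trapezoid(qa[-k:] * I[-k:], qa[-k:]))
    converged = bool(tail / integral / k < plateau_tol)
    Vc = guinier.I0 / integral                     # A^2
    Rg_A = guinier.Rg * 10.0
    QR = Vc ** 2 / Rg_A                            # A^3
    mass = QR / VC_MASS_CONSTANT / 1000.0          # Da -> kDa
    info = {
        "Vc_A2": Vc,
        "QR_A3": QR,
        "q_stop_nm": float(q_nm[within][-1]),
        "converged": converged,
    }
    return mass, info


def concentration_from_forward(I0: float, mass_kda: float) -> float:
    """Concentration (mg/ml) from calibrated forward scattering: c = I0 / M.

    On the absolute scale in use, 1 a.u. = 8.03e-4 cm^-1
    (:data:`iecsaxs.core.AU_TO_INV_CM` converts).
    """
    if mass_kda <= 0:
        raise ValueError("molar mass must be positive")
    return I0 / mass_kda


# ---------------------------------------------------------------------------
# CorMap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CormapResult:
    """Longest same-sign run of pointwise differences and its exact p-value."""

    n_points: int
    longest_run: int
    p_value: float
    adjusted_p: float | None = None
    identical: bool = False

    def summary(self) -> str:
        adj = f", adjusted p = {self.adjusted_p:.4g}" if self.adjusted_p is not None else ""
        tag = " (identical curves)" if self.identical else ""
        return (
            f"CorMap: n = {self.n_points}, longest run C = {self.longest_run}, "
            f"p = {self.p_value:.4g}{adj}{tag}"
        )


def _count_runs_at_most(n: int, m: int) -> int:
    """Number of length-n binary sequences whose longest run is <= m.

    A sequence is a choice of first symbol times a composition of n into
    run lengths; restricting runs to <= m restricts the parts.  Exact
    integer arithmetic throughout.
    """
    if m <= 0:
        return 0
    if m >= n:
        return 2 ** n
    comp = [0] * (n + 1)
    comp[0] = 1
    for k in range(1, n + 1):
        comp[k] = sum(comp[k - j] for j in range(1, min(m, k) + 1))
    return 2 * comp[n]


def longest_run_pvalue(n: int, c: int) -> float:
    """P(longest run >= c) over all 2^n fair-coin sign sequences, exact."""
    if not 1 <= c <= n:
        raise ValueError(f"need 1 <= C <= n, got C={c}, n={n}")
    favourable = 2 ** n - _count_runs_at_most(n, c - 1)
    return favourable / 2 ** n


def cormap_compare(
    a: ScatteringCurve,
    b: ScatteringCurve,
    q_range: tuple[float, float] | None = None,
) -> CormapResult:
    """Correlation-map test between two curves on a shared grid.

    The statistic is the longest run of identical sign among the pointwise
    differences a - b; under the null of pure noise each sign is a fair
    coin, and the p-value is computed exactly by the run-counting
    recurrence.  Exact zeros carry no sign information and break runs; two
    identical curves short-circuit to C = n, p = 1 with a flag.
    """
    if not grids_equal(a.q, b.q):
        raise ValueError("curves are on different q grids")
    mask = np.ones(len(a.q), dtype=bool)
    if q_range is not None:
        mask = (a.q >= q_range[0]) & (a.q <= q_range[1])
    d = a.I[mask] - b.I[mask]
    n = len(d)
    if n < 10:
        raise ValueError(f"need at least 10 points in the comparison range, got {n}")
    signs = np.sign(d)
    if np.all(signs == 0):
        return CormapResult(n_points=n, longest_run=n, p_value=1.0, identical=True)
    longest = run = 0
    prev = 0.0
    for s in signs:
        if s != 0 and s == prev:
            run += 1
        elif s != 0:
            run = 1
        else:
            run = 0
        prev = s
        longest = max(longest, run)
    return CormapResult(n_points=n, longest_run=longest,
                        p_value=longest_run_pvalue(n, longest))


def adjusted_pvalues(results, method: str = "bonferroni") -> list[CormapResult]:
    """Multiple-comparison adjustment across a set of CorMap results.

    Bonferroni by default (adjusted p = min(1, p * k)); the method is a
    documented, swappable choice.
    """
    results = list(results)
    if len(results) == 0:
        raise ValueError("empty result list")
    k = len(results)
    if method == "bonferroni":
        return [
            CormapResult(
                n_points=r.n_points, longest_run=r.longest_run,
                p_value=r.p_value, adjusted_p=min(1.0, r.p_value * k),
                identical=r.identical,
            )
            for r in results
        ]
    raise ValueError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# Stable-region selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StableRegionResult:
    """Contiguous frame range statistically identical to the reference frame."""

    start: int | None
    stop: int | None
    reference: int
    alpha: float
    table: pd.DataFrame = field(repr=False)

    @property
    def empty(self) -> bool:
        return self.start is None

    @property
    def n_frames(self) -> int:
        return 0 if self.empty else self.stop - self.start

    def summary(self) -> str:
        if self.empty:
            return (
                f"stable region: EMPTY (no frame passes CorMap alpha={self.alpha} "
                f"and ratio tolerance against frame {self.reference})"
            )
        return (
            f"stable region: frames [{self.start}, {self.stop}) "
            f"({self.n_frames} frames) around reference {self.reference}"
        )


def stable_region(
    series: FrameSeries,
    reference: int | None = None,
    alpha: float = 0.01,
    q_range: tuple[float, float] = (0.11, 2.5),
    ratio_tol: float | None = None,
    low: BandSpec = LOW_BAND,
    mid: BandSpec = MID_BAND,
) -> StableRegionResult:
    """Select the frames of a subtracted peak suitable for averaging.

    Every frame is scaled to the reference frame (least-squares factor over
    ``q_range``, removing the concentration difference) and compared with a
    CorMap test; p-values are Bonferroni-adjusted across all frames tested.
    A frame passes when its adjusted p exceeds ``alpha`` and its low/mid
    ratio agrees with the reference frame's within a tolerance band: by
    default five times the propagated per-frame ratio uncertainty, or a
    fixed width when ``ratio_tol`` is given.  The result is the largest
    contiguous passing range containing the reference.
    """
    first = series.first_frame_index
    low_tr = series.band_trace(low)
    mid_tr = series.band_trace(mid)
    if reference is None:
        reference = int(first + np.argmax(low_tr))
    ref_row = int(reference) - first
    qmask = (series.q >= q_range[0]) & (series.q <= q_range[1])
    ref_I = series.I[ref_row]

    raw: list[CormapResult] = []
    for row in range(series.n_frames):
        I = series.I[row]
        denom = float((I[qmask] ** 2).sum())
        scale = float((ref_I[qmask] * I[qmask]).sum()) / denom if denom > 0 else 1.0
        scaled = ScatteringCurve(series.q, I * scale, series.sigma[row] * abs(scale))
        raw.append(cormap_compare(
            scaled, ScatteringCurve(series.q, ref_I, series.sigma[ref_row]),
            q_range,
        ))
    adjusted = adjusted_pvalues(raw)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mid_tr != 0, low_tr / mid_tr, np.nan)
        low_sem = series.band_sem_trace(low)
        mid_sem = series.band_sem_trace(mid)
        ratio_sem = np.abs(ratio) * np.sqrt(
            np.where(low_tr != 0, (low_sem / low_tr) ** 2, 0.0)
            + np.where(mid_tr != 0, (mid_sem / mid_tr) ** 2, np.inf)
        )
    ref_ratio = ratio[ref_row]
    pass_cormap = np.array([r.adjusted_p > alpha for r in adjusted])
    with np.errstate(invalid="ignore"):
        if ratio_tol is None:
            # default: each frame's ratio must agree with the reference
            # within 5 sigma of its own propagated uncertainty -- frames
            # with little mid-band signal carry wide error bars and are
            # gated by the CorMap test instead
            band = 5.0 * np.sqrt(ratio_sem ** 2 + ratio_sem[ref_row] ** 2)
        else:
            band = float(ratio_tol) * np.ones_like(ratio)
        pass_ratio = np.abs(ratio - ref_ratio) <= band
    pass_ratio &= np.isfinite(ratio)
    passing = pass_cormap & pass_ratio

    table = pd.DataFrame({
        "frame": series.frame_numbers,
        "longest_run": [r.longest_run for r in adjusted],
        "p_value": [r.p_value for r in adjusted],
        "adjusted_p": [r.adjusted_p for r in adjusted],
        "ratio": ratio,
        "pass_cormap": pass_cormap,
        "pass_ratio": pass_ratio,
    })

    if not passing[ref_row]:
        return StableRegionResult(None, None, int(reference), alpha, table)
    lo = hi = ref_row
    while lo > 0 and passing[lo - 1]:
        lo -= 1
    while hi < series.n_frames - 1 and passing[hi + 1]:
        hi += 1
    return StableRegionResult(first + lo, first + hi + 1, int(reference), alpha, table)


# ---------------------------------------------------------------------------
# Per-frame parameter traces
# ---------------------------------------------------------------------------

def per_frame_parameters(
    series: FrameSeries,
    roi: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Guinier and mass traces across a subtracted peak.

    Returns a table of (frame, I0, Rg, mass_vc, concentration); frames where
    the Guinier or Vc analysis fails are kept with missing values rather
    than dropped, so the trace stays aligned with the chromatogram.
    """
    if roi is None:
        frames = series.frame_numbers
    else:
        frames = np.arange(int(roi[0]), int(roi[1]))
    rows = []
    for N in frames:
        rec = {"frame": int(N), "I0": np.nan, "Rg": np.nan,
               "mass_vc": np.nan, "concentration": np.nan}
        try:
            curve = series.frame(int(N))
            g = auto_guinier(curve)
            rec["I0"] = g.I0
            rec["Rg"] = g.Rg
            mass, _ = mass_from_vc(curve, g)
            rec["mass_vc"] = mass
            rec["concentration"] = concentration_from_forward(g.I0, mass)
        except (GuinierError, ValueError):
            pass
        rows.append(rec)
    return pd.DataFrame(rows)
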