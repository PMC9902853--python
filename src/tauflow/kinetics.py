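"""Simplified reference tissue model (SRTM) core.

This module implements the kinetic layer of the package:

* the SRTM forward model, which expresses a target-region time-activity
  curve (TAC) in terms of a reference-region TAC through three parameters
  (relative delivery ``R1``, target efflux ``k2`` in 1/min, and binding
  potential ``BPND``),
* basis-function estimation of those parameters (receptor parametric
  mapping, RPM): the non-linear apparent efflux rate
  ``k2a = k2 / (1 + BPND)`` is discretised on a log-spaced grid, and for
  each grid point a two-parameter weighted linear least-squares problem is
  solved,
* the semiquantitative standardized uptake value ratio (SUVr) over a late
  scan window.

All times are in minutes and activities in kBq/mL throughout; only ratios
of activities matter downstream.

Numerics: measured TACs are treated as piecewise-linear in time (frame
values attached to frame midpoints, zero at injection).  Convolutions
with exponential kernels, their values at arbitrary times and their
frame averages are then available in closed form — the recursion for
``y' = f - k y`` is integrated segment by segment, and frame averages
use the exact identity ``∫y = (∫f - Δy) / k``.  No FFT, no quadrature
error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "SRTMParams",
    "SRTMFit",
    "BasisSet",
    "srtm_model_tac",
    "make_basis",
    "fit_rpm",
    "compute_suvr",
    "dvr_from_bp",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Timing of a dynamic PET acquisition.

    Parameters
    ----------
    frame_start
        Start time of each frame in minutes, strictly increasing.
    frame_duration
        Duration of each frame in minutes, all positive.  Frames must not
        overlap; gaps between consecutive frames are allowed.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.shape != start.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if start.size < 1:
            raise ValueError("schedule needs at least one frame")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = start + dur
        if np.any(start[1:] < ends[:-1] - 1e-9):
            idx = int(np.argmax(start[1:] < ends[:-1] - 1e-9))
            raise ValueError(f"frames overlap at frame index {idx + 1}")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_start + self.frame_duration / 2.0

    @property
    def total_end(self) -> float:
        return float(self.frame_end[-1])


@dataclass(frozen=True)
class TimeActivityCurve:
    """Framewise activity concentration in a region (kBq/mL)."""

    schedule: FrameSchedule
    activity: np.ndarray

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.shape != (self.schedule.n_frames,):
            raise ValueError("activity length must equal number of frames")
        if not np.all(np.isfinite(act)):
            raise ValueError("activity values must be finite")

    @property
    def has_negative(self) -> bool:
        """True when noise has pushed any frame below zero (not clipped)."""
        return bool(np.any(self.activity < 0))


@dataclass(frozen=True)
class SRTMParams:
    """SRTM parameter triple for one region.

    ``R1`` is the target-to-reference delivery ratio (unitless, proxy for
    relative cerebral blood flow), ``k2`` the target efflux rate (1/min)
    and ``BPND`` the nondisplaceable binding potential (unitless).
    """

    R1: float
    k2: float
    BPND: float

    def __post_init__(self) -> None:
        if not (self.R1 > 0 and np.isfinite(self.R1)):
            raise ValueError("R1 must be positive")
        if not (self.k2 > 0 and np.isfinite(self.k2)):
            raise ValueError("k2 must be positive")
        if not (self.BPND >= 0 and np.isfinite(self.BPND)):
            raise ValueError("BPND must be non-negative")

    @property
    def DVR(self) -> float:
        return self.BPND + 1.0

    @property
    def k2a(self) -> float:
        """Apparent efflux rate k2 / (1 + BPND) in 1/min."""
        return self.k2 / (1.0 + self.BPND)


@dataclass(frozen=True)
class SRTMFit:
    """Result of a basis-function (RPM) fit.

    Unlike :class:`SRTMParams`, fitted values are kept as plain floats so
    that noise-induced negative ``BPND`` estimates survive unclipped (a
    clipped estimator would bias cohort means).
    """

    R1: float
    k2: float
    BPND: float
    wrss: float
    basis_index: int
    converged_on_boundary: bool

    @property
    def DVR(self) -> float:
        return self.BPND + 1.0


@dataclass(frozen=True)
class BasisSet:
    """Precomputed RPM basis functions for one reference TAC.

    Carries the reference's piecewise-linear knot representation so the
    fit can polish the discrete grid selection with a continuous 1-D
    search (basis curves at arbitrary ``k2a`` come from the same closed
    form).
    """

    k2a_grid: np.ndarray
    basis_curves: np.ndarray  # shape (n_basis, n_frames)
    ref_frames: np.ndarray = field(repr=False)
    knots_x: np.ndarray = field(repr=False, default=None)
    knots_f: np.ndarray = field(repr=False, default=None)
    schedule: FrameSchedule | None = field(default=None, repr=False)

    def basis_curve_at(self, k2a: float) -> np.ndarray:
        """Frame-averaged ``C_R ⊗ exp(-k2a t)`` at an arbitrary rate."""
        return exp_conv_frame_avg(self.knots_x, self.knots_f, k2a, self.schedule)


# ---------------------------------------------------------------------------
# closed-form convolution machinery


def fine_grid(end: float, fine_dt: float) -> np.ndarray:
    """Uniform sampling grid [0, end] with step ``fine_dt``."""
    if fine_dt <= 0:
        raise ValueError("fine_dt must be positive")
    n = int(np.ceil(end / fine_dt - 1e-9))
    return np.arange(n + 1) * fine_dt


def tac_knots(tac: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear knot representation of a measured TAC.

    Frame values sit at frame midpoints, the curve is anchored at zero
    activity at injection, and held constant from the last midpoint to
    the end of the last frame.
    """
    mid = tac.schedule.midpoints
    xp = np.concatenate(([0.0], mid, [tac.schedule.total_end]))
    fp = np.concatenate(([0.0], tac.activity, [tac.activity[-1]]))
    return xp, fp


def _conv_knot_values(xp: np.ndarray, fp: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """``y(x_i)`` for ``y' = f - rate*y``, ``y(0) = 0``, f piecewise linear.

    Exact per segment.  Returns shape (n_rates, n_knots).  Long uniform
    grids take an IIR-filter fast path.
    """
    h = np.diff(xp)
    n_seg = h.size
    if n_seg > 64 and np.allclose(h, h[0], rtol=1e-9, atol=1e-12):
        dt = h[0]
        y = np.empty((rates.size, xp.size))
        for i, k in enumerate(rates):
            e = np.exp(-k * dt)
            i0 = (1.0 - e) / k
            i1 = (dt - i0) / k
            b1, b0 = i1 / dt, i0 - i1 / dt
            yi = lfilter([b1, b0], [1.0, -e], fp)
            # lfilter assumes y0 = b1*f0; the true initial condition is 0
            yi -= b1 * fp[0] * e ** np.arange(xp.size)
            y[i] = yi
        return y
    E = np.exp(-np.outer(rates, h))
    I0 = (1.0 - E) / rates[:, None]
    I1 = (h[None, :] - I0) / rates[:, None]
    A = I0 - I1 / h[None, :]
    B = I1 / h[None, :]
    if rates.size == 1:
        # plain-float recursion: ~100x faster than numpy scalars here
        e, a, b, f = E[0].tolist(), A[0].tolist(), B[0].tolist(), fp.tolist()
        y = [0.0] * xp.size
        acc = 0.0
        for i in range(n_seg):
            acc = acc * e[i] + f[i] * a[i] + f[i + 1] * b[i]
            y[i + 1] = acc
        return np.array([y])
    y = np.zeros((rates.size, xp.size))
    for i in range(n_seg):
        y[:, i + 1] = y[:, i] * E[:, i] + fp[i] * A[:, i] + fp[i + 1] * B[:, i]
    return y


def _conv_eval(
    xp: np.ndarray,
    fp: np.ndarray,
    rates: np.ndarray,
    y_knots: np.ndarray,
    t: np.ndarray,
) -> np.ndarray:
    """Evaluate the convolution at arbitrary times ``t`` in [0, xp[-1]]."""
    h = np.diff(xp)
    idx = np.clip(np.searchsorted(xp, t, side="right") - 1, 0, xp.size - 2)
    s = t - xp[idx]
    e = np.exp(-np.outer(rates, s))
    i0 = (1.0 - e) / rates[:, None]
    i1 = (s[None, :] - i0) / rates[:, None]
    hseg = h[idx][None, :]
    return (
        y_knots[:, idx] * e
        + fp[idx][None, :] * (i0 - i1 / hseg)
        + fp[idx + 1][None, :] * (i1 / hseg)
    )


def _pl_integral(xp: np.ndarray, fp: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact ``∫_0^t f`` for piecewise-linear f, t within [0, xp[-1]]."""
    h = np.diff(xp)
    cum = np.concatenate(([0.0], np.cumsum((fp[:-1] + fp[1:]) / 2.0 * h)))
    idx = np.clip(np.searchsorted(xp, t, side="right") - 1, 0, xp.size - 2)
    s = t - xp[idx]
    slope = (fp[idx + 1] - fp[idx]) / h[idx]
    return cum[idx] + fp[idx] * s + 0.5 * slope * s * s


def exp_conv_frame_avg(
    xp: np.ndarray,
    fp: np.ndarray,
    rates: float | np.ndarray,
    schedule: FrameSchedule,
) -> np.ndarray:
    """Exact frame averages of ``f ⊗ exp(-rate t)``.

    Uses ``∫_a^b y = (∫_a^b f - y(b) + y(a)) / rate``, so the result is
    closed-form for the piecewise-linear input — no discretisation step
    enters.  Returns shape (n_rates, n_frames), or (n_frames,) for a
    scalar rate.
    """
    scalar = np.isscalar(rates)
    rates_arr = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates_arr <= 0):
        raise ValueError("rates must be positive")
    if schedule.total_end > xp[-1] + 1e-9:
        raise ValueError("knot range does not cover the frame schedule")
    y_knots = _conv_knot_values(xp, fp, rates_arr)
    ya = _conv_eval(xp, fp, rates_arr, y_knots, schedule.frame_start)
    yb = _conv_eval(xp, fp, rates_arr, y_knots, schedule.frame_end)
    f_int = _pl_integral(xp, fp, schedule.frame_end) - _pl_integral(
        xp, fp, schedule.frame_start
    )
    out = (f_int[None, :] - yb + ya) / (rates_arr[:, None] * schedule.frame_duration)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# operations


def srtm_model_tac(
    params: SRTMParams,
    ref: TimeActivityCurve,
    fine_dt: float = 0.05,
) -> TimeActivityCurve:
    """Generate a target TAC from a reference TAC under the SRTM.

    Evaluates, frame-averaged onto the reference's schedule,

        C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * [C_R ⊗ exp(-k2a t)](t)

    with ``k2a = k2 / (1 + BPND)``.  The frame average of the first term
    is exactly R1 times the measured frame values; the convolution term
    is evaluated in closed form for the piecewise-linear reference
    interpolant, so the result carries no discretisation error
    (``fine_dt`` is validated for interface compatibility but no longer
    limits accuracy).  Deterministic.
    """
    if fine_dt <= 0:
        raise ValueError("fine_dt must be positive")
    if ref.schedule.n_frames < 2:
        raise ValueError("reference TAC needs at least 2 frames")
    xp, fp = tac_knots(ref)
    k2a = params.k2a
    conv = exp_conv_frame_avg(xp, fp, k2a, ref.schedule)
    ct = params.R1 * ref.activity + (params.k2 - params.R1 * k2a) * conv
    return TimeActivityCurve(ref.schedule, ct)


def make_basis(
    ref: TimeActivityCurve,
    k2a_min: float = 0.006,
    k2a_max: float = 0.6,
    n_basis: int = 64,
    fine_dt: float = 0.05,
) -> BasisSet:
    """Build the RPM basis: frame-averaged ``C_R ⊗ exp(-k2a t)`` curves
    over a log-spaced grid of apparent efflux rates."""
    if not (0 < k2a_min < k2a_max):
        raise ValueError("require 0 < k2a_min < k2a_max")
    if n_basis < 2:
        raise ValueError("n_basis must be at least 2")
    if fine_dt <= 0:
        raise ValueError("fine_dt must be positive")
    grid = np.geomspace(k2a_min, k2a_max, n_basis)
    xp, fp = tac_knots(ref)
    curves = exp_conv_frame_avg(xp, fp, grid, ref.schedule)
    return BasisSet(
        k2a_grid=grid,
        basis_curves=curves,
        ref_frames=ref.activity,
        knots_x=xp,
        knots_f=fp,
        schedule=ref.schedule,
    )


_BASIS_MAP_CACHE: dict[tuple, np.ndarray] = {}


def _basis_linear_maps(schedule: FrameSchedule, k2a_grid: np.ndarray) -> np.ndarray:
    """Matrices M_j with ``basis_j = M_j @ ref_frames``.

    Each basis curve is a linear function of the reference frame values
    (knot construction, convolution and frame averaging are all linear),
    which is what makes a moment-based errors-in-variables correction of
    the fit exact.  Cached per (schedule, grid).
    """
    key = (
        schedule.frame_start.tobytes(),
        schedule.frame_duration.tobytes(),
        k2a_grid.tobytes(),
    )
    maps = _BASIS_MAP_CACHE.get(key)
    if maps is None:
        n = schedule.n_frames
        maps = np.empty((k2a_grid.size, n, n))
        for col in range(n):
            e = np.zeros(n)
            e[col] = 1.0
            xp, fp = tac_knots(TimeActivityCurve(schedule, e))
            maps[:, :, col] = exp_conv_frame_avg(xp, fp, k2a_grid, schedule)
        _BASIS_MAP_CACHE[key] = maps
    return maps


def _wls_two_param(
    r: np.ndarray,
    b: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    corr: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[float, float, float]:
    """Closed-form weighted LS for ``y ≈ θ1 r + θ2 b``; returns (θ1, θ2, wrss).

    ``corr`` holds the errors-in-variables moment corrections to subtract
    from (S11, S12, S22) when the regressors carry known noise.
    """
    s11 = float(np.sum(w * r * r)) - corr[0]
    s12 = float(np.sum(w * r * b)) - corr[1]
    s22 = float(np.sum(w * b * b)) - corr[2]
    c1 = float(np.sum(w * r * y))
    c2 = float(np.sum(w * b * y))
    det = s11 * s22 - s12 * s12
    if det <= 1e-12 * max(abs(s11), 1.0) * max(abs(s22), 1.0):
        return np.nan, np.nan, np.inf
    th1 = (s22 * c1 - s12 * c2) / det
    th2 = (s11 * c2 - s12 * c1) / det
    wrss = (
        float(np.sum(w * y * y))
        - 2.0 * (th1 * c1 + th2 * c2)
        + th1 * th1 * s11
        + 2.0 * th1 * th2 * s12
        + th2 * th2 * s22
    )
    return th1, th2, wrss


def fit_rpm(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    basis: BasisSet,
    weights: np.ndarray | None = None,
    refine: bool = True,
    ref_noise_sd: np.ndarray | None = None,
) -> SRTMFit:
    """Basis-function SRTM fit (receptor parametric mapping).

    For each ``k2a`` on the basis grid the weighted linear problem
    ``C_T ≈ θ1 C_R + θ2 B(k2a)`` is solved in closed form; the grid point
    with minimal weighted residual sum of squares is selected and mapped
    back to ``R1 = θ1``, ``k2 = θ2 + R1 k2a``, ``BPND = k2 / k2a - 1``.

    With ``refine=True`` (default) the discrete selection is polished by a
    bounded search over ``log k2a`` between the two neighbouring grid
    points, removing grid-quantisation bias from the parameter estimates.

    ``ref_noise_sd``, when given (per-frame noise SD of the reference
    TAC), switches on a moment-based errors-in-variables correction:
    both design columns are linear in the noisy reference, so their known
    noise second moments are subtracted from the normal equations.  This
    removes the attenuation bias in R1 that plain least squares incurs
    when the reference itself is noisy.

    Weights default to uniform.  A fit that lands on the first or last
    grid point is flagged via ``converged_on_boundary``.
    """
    if target.schedule.n_frames != ref.schedule.n_frames or not np.allclose(
        target.schedule.frame_start, ref.schedule.frame_start
    ):
        raise ValueError("target and reference must share the frame schedule")
    y = target.activity
    r = ref.activity
    n = y.size
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights length must equal number of frames")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(w > 0):
            raise ValueError("weights must not be all zero")

    B = basis.basis_curves
    grid = basis.k2a_grid
    sig2 = None
    corr11 = 0.0
    corr12 = np.zeros(grid.size)
    corr22 = np.zeros(grid.size)
    if ref_noise_sd is not None:
        sig2 = np.asarray(ref_noise_sd, dtype=float) ** 2
        if sig2.shape != (n,):
            raise ValueError("ref_noise_sd length must equal number of frames")
        maps = _basis_linear_maps(basis.schedule, grid)
        corr11 = float(np.sum(w * sig2))
        # c12: sum_i w_i M_j[i,i] sig2_i ; c22: sum_ik w_k M_j[k,i]^2 sig2_i
        corr12 = np.einsum("i,jii,i->j", w, maps, sig2)
        corr22 = np.einsum("k,jki,jki,i->j", w, maps, maps, sig2)

    s11 = float(np.sum(w * r * r)) - corr11
    s12 = B @ (w * r) - corr12
    s22 = np.sum(w * B * B, axis=1) - corr22
    c1 = float(np.sum(w * r * y))
    c2 = B @ (w * y)
    det = s11 * s22 - s12**2
    sst = float(np.sum(w * y * y))

    ok = det > 1e-12 * max(abs(s11), 1.0) * np.maximum(np.abs(s22), 1.0)
    if not np.any(ok):
        raise ValueError("design matrix is rank-deficient at every basis point")
    with np.errstate(divide="ignore", invalid="ignore"):
        th1 = (s22 * c1 - s12 * c2) / det
        th2 = (s11 * c2 - s12 * c1) / det
        wrss = (
            sst
            - 2.0 * (th1 * c1 + th2 * c2)
            + th1**2 * s11
            + 2.0 * th1 * th2 * s12
            + th2**2 * s22
        )
    wrss = np.where(ok, wrss, np.inf)
    j = int(np.argmin(wrss))
    k2a = float(grid[j])
    best = (th1[j], th2[j], float(wrss[j]), k2a)
    on_boundary = j == 0 or j == grid.size - 1

    if refine and not on_boundary and basis.schedule is not None:

        def corr_at(k2a_val: float) -> tuple[float, float, float]:
            if sig2 is None:
                return (0.0, 0.0, 0.0)
            # log-linear interpolation of the smooth correction terms
            lg = np.log(grid)
            x = np.log(k2a_val)
            return (
                corr11,
                float(np.interp(x, lg, corr12)),
                float(np.interp(x, lg, corr22)),
            )

        from scipy.optimize import minimize_scalar

        def objective(log_k2a: float) -> float:
            k2a_val = float(np.exp(log_k2a))
            b = basis.basis_curve_at(k2a_val)
            return _wls_two_param(r, b, y, w, corr_at(k2a_val))[2]

        lo = np.log(grid[j - 1])
        hi = np.log(grid[j + 1])
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-4})
        if res.fun < best[2]:
            k2a_r = float(np.exp(res.x))
            t1, t2, ws = _wls_two_param(
                r, basis.basis_curve_at(k2a_r), y, w, corr_at(k2a_r)
            )
            if np.isfinite(ws):
                best = (t1, t2, ws, k2a_r)

    th1_b, th2_b, wrss_b, k2a_b = best
    r1 = float(th1_b)
    k2 = float(th2_b + th1_b * k2a_b)
    bp = k2 / k2a_b - 1.0
    return SRTMFit(
        R1=r1,
        k2=k2,
        BPND=bp,
        wrss=float(max(wrss_b, 0.0)),
        basis_index=j,
        converged_on_boundary=on_boundary,
    )


def compute_suvr(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    window_start: float = 80.0,
    window_end: float = 100.0,
) -> float:
    """SUVr: duration-weighted mean target over reference activity within
    ``[window_start, window_end)``.

    Frames partially overlapping the window contribute in proportion to
    their overlap, which makes the value independent of where frame
    boundaries fall relative to the window edges.
    """
    if window_end <= window_start:
        raise ValueError("window_end must exceed window_start")
    sched = target.schedule
    overlap = np.minimum(sched.frame_end, window_end) - np.maximum(
        sched.frame_start, window_start
    )
    overlap = np.clip(overlap, 0.0, None)
    if overlap.sum() < (window_end - window_start) - 1e-6:
        raise ValueError("SUVr window is not fully covered by the frame schedule")
    num = float(np.sum(overlap * target.activity))
    den = float(np.sum(overlap * ref.activity))
    if den == 0:
        raise ValueError("reference activity integrates to zero over the window")
    return num / den


def dvr_from_bp(bp: float) -> float:
    """Distribution volume ratio DVR = BPND + 1.

    Small negative fitted binding potentials (a noise artefact) are passed
    through with a warning rather than clipped.
    """
    if bp < 0:
        warnings.warn(
            f"negative fitted BPND ({bp:.4g}) passed through to DVR", stacklevel=2
        )
    return bp + 1.0
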