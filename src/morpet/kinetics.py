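"""Simplified reference tissue model (SRTM) kinetics for dynamic PET.

The SRTM expresses a target-tissue time-activity curve (TAC) in terms of a
reference-region TAC with negligible specific binding::

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * [C_R (*) exp(-k2a * t)](t)

with ``k2a = k2 / (1 + BP_ND)`` the apparent efflux rate.  ``R1`` is the
target/reference delivery ratio, ``k2`` the tissue efflux rate (1/min) and
``BP_ND`` the non-displaceable binding potential, the quantity of interest.

Model curves are evaluated on a 1-second uniform grid and then averaged over
each acquisition frame, so that early 15-second frames are resolved at
sub-frame resolution.  The continuous reference curve is reconstructed from
the measured frame values by a mean-preserving piecewise-linear rule: frame
boundary values are chosen (anchored at zero activity at time zero) so that
every frame's average reproduces the measured value exactly, which keeps the
forward model an identity when R1 = 1 and BP_ND = 0.

Two estimators are provided: a basis-function fit (grid over ``k2a`` with the
two linear coefficients solved in closed form, followed by a local 1-D
refinement of ``k2a``) and a three-parameter nonlinear least-squares fit used
as an independent cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import optimize, signal
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "SRTMParams",
    "SRTMFit",
    "SUVCurve",
    "FitError",
    "default_schedule",
    "srtm_forward",
    "fit_srtm_basis",
    "fit_srtm_nls",
    "suv_curve",
    "suv_auc",
    "DEFAULT_K2A_GRID",
]

SEC_PER_MIN = 60.0
#: default k2a basis grid, 1/min: log-spaced, spans carfentanil-like kinetics
DEFAULT_K2A_GRID = np.geomspace(0.006, 1.0, 128)
#: fine evaluation grid step, seconds
FINE_DT_S = 1.0


class FitError(RuntimeError):
    """Raised when an SRTM fit cannot be completed; may carry the last iterate."""

    def __init__(self, message: str, last_params: "SRTMParams | None" = None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping PET frame timing grid (seconds)."""

    frame_starts: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.frame_starts, dtype=float)
        durs = np.asarray(self.frame_durations, dtype=float)
        if starts.ndim != 1 or starts.shape != durs.shape or starts.size == 0:
            raise ValueError("frame_starts and frame_durations must be equal-length 1-D")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be strictly positive")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)

    @classmethod
    def from_durations(cls, durations: Sequence[float], t0: float = 0.0) -> "FrameSchedule":
        durs = np.asarray(durations, dtype=float)
        starts = t0 + np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @classmethod
    def from_json(cls, path) -> "FrameSchedule":
        """Read a schedule stored as a JSON list of [start, duration] pairs."""
        with open(path) as fh:
            pairs = json.load(fh)
        pairs = np.asarray(pairs, dtype=float)
        return cls(pairs[:, 0], pairs[:, 1])

    def to_json(self, path) -> None:
        pairs = [[float(s), float(d)] for s, d in zip(self.frame_starts, self.frame_durations)]
        with open(path, "w") as fh:
            json.dump(pairs, fh)

    @property
    def n_frames(self) -> int:
        return self.frame_starts.size

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    @property
    def frame_mids(self) -> np.ndarray:
        return self.frame_starts + 0.5 * self.frame_durations

    @property
    def total_duration(self) -> float:
        return float(self.frame_ends[-1] - self.frame_starts[0])


def default_schedule() -> FrameSchedule:
    """The packaged 90-min, 26-frame acquisition schedule.

    8 x 15 s, 3 x 60 s, 5 x 120 s, 5 x 300 s, 5 x 600 s; 5400 s in total.
    """
    ref = resources.files("morpet.data").joinpath("schedule_26frame.json")
    pairs = np.asarray(json.loads(ref.read_text()), dtype=float)
    return FrameSchedule(pairs[:, 0], pairs[:, 1])


@dataclass
class TimeActivityCurve:
    """Per-frame activity concentration (kBq/mL) for one region of one subject."""

    schedule: FrameSchedule
    values: np.ndarray
    region_id: str = ""
    subject_id: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"values length {vals.size} != frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("TAC values must be finite")
        self.values = vals


@dataclass
class SRTMParams:
    """SRTM parameters: delivery ratio R1, efflux k2 (1/min), binding potential BP_ND."""

    r1: float
    k2: float
    bp_nd: float

    @property
    def k2a(self) -> float:
        """Apparent efflux rate k2 / (1 + BP_ND), 1/min."""
        return self.k2 / (1.0 + self.bp_nd)

    def validate(self) -> None:
        if not self.r1 > 0:
            raise ValueError(f"R1 must be positive, got {self.r1}")
        if not self.k2 > 0:
            raise ValueError(f"k2 must be positive, got {self.k2}")
        if not self.bp_nd > -1.0:
            raise ValueError(f"BP_ND must exceed -1 (got {self.bp_nd}); k2a would be <= 0")


@dataclass
class SRTMFit:
    params: SRTMParams
    fitted_curve: TimeActivityCurve
    weighted_rss: float
    k2a_grid_index: int | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class SUVCurve:
    """Standardised uptake values per frame: concentration / (dose / body weight)."""

    schedule: FrameSchedule
    suv_values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.suv_values, dtype=float)
        if vals.shape != (self.schedule.n_frames,):
            raise ValueError("suv_values length must equal frame count")
        self.suv_values = vals


# ---------------------------------------------------------------------------
# fine-grid evaluation machinery


def _fine_times(schedule: FrameSchedule, dt: float = FINE_DT_S) -> np.ndarray:
    t0 = float(schedule.frame_starts[0])
    t1 = float(schedule.frame_ends[-1])
    n = int(round((t1 - t0) / dt))
    return t0 + dt * np.arange(n + 1)


def _interp_ref(ref: TimeActivityCurve, t_fine: np.ndarray) -> np.ndarray:
    """Mean-preserving piecewise-linear reconstruction of the reference curve.

    Frame-boundary values b satisfy (b[i] + b[i+1]) / 2 = v[i] with b[0] = 0
    (pre-injection), so the reconstruction's average over each frame equals
    the measured frame value exactly.
    """
    v = ref.values
    b_tail = signal.lfilter([2.0], [1.0, 1.0], v)  # b[i+1] = 2 v[i] - b[i]
    bounds_t = np.concatenate([ref.schedule.frame_starts, [ref.schedule.frame_ends[-1]]])
    bounds_v = np.concatenate([[0.0], b_tail])
    return np.interp(t_fine, bounds_t, bounds_v)


def _exp_conv(c_fine: np.ndarray, k2a_per_min: float, dt_s: float) -> np.ndarray:
    """[c (*) exp(-k2a t)](t) on the fine grid, exact for piecewise-linear c.

    Time is carried in minutes so the result multiplies rate constants in
    1/min directly.  Uses the recursive update
    y[i] = E*y[i-1] + segment integral, implemented as an IIR filter.
    """
    dt = dt_s / SEC_PER_MIN
    k = k2a_per_min
    E = np.exp(-k * dt)
    a0 = (1.0 - E) / k
    a1 = (dt - a0) / k
    c0 = c_fine[:-1]
    slope = (c_fine[1:] - c_fine[:-1]) / dt
    seg = a0 * c0 + a1 * slope
    y_tail = signal.lfilter([1.0], [1.0, -E], seg)
    return np.concatenate([[0.0], y_tail])


def _frame_average(curve_fine: np.ndarray, t_fine: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    cum = cumulative_trapezoid(curve_fine, t_fine, initial=0.0)
    lo = np.interp(schedule.frame_starts, t_fine, cum)
    hi = np.interp(schedule.frame_ends, t_fine, cum)
    return (hi - lo) / schedule.frame_durations


def _basis_curve(cr_fine: np.ndarray, t_fine: np.ndarray, schedule: FrameSchedule,
                 k2a: float) -> np.ndarray:
    return _frame_average(_exp_conv(cr_fine, k2a, t_fine[1] - t_fine[0]), t_fine, schedule)


# ---------------------------------------------------------------------------
# forward model


def srtm_forward(params: SRTMParams, ref: TimeActivityCurve, dt: float = FINE_DT_S) -> TimeActivityCurve:
    """Frame-averaged SRTM model curve for the given parameters and reference TAC."""
    params.validate()
    sched = ref.schedule
    t_fine = _fine_times(sched, dt)
    cr = _interp_ref(ref, t_fine)
    conv = _exp_conv(cr, params.k2a, dt)
    ct_fine = params.r1 * cr + (params.k2 - params.r1 * params.k2a) * conv
    vals = _frame_average(ct_fine, t_fine, sched)
    return TimeActivityCurve(sched, vals, region_id="srtm_model", subject_id=ref.subject_id)


# ---------------------------------------------------------------------------
# basis-function estimation


def _check_pair(target: TimeActivityCurve, ref: TimeActivityCurve) -> None:
    if target.schedule.n_frames != ref.schedule.n_frames or not (
        np.allclose(target.schedule.frame_starts, ref.schedule.frame_starts)
        and np.allclose(target.schedule.frame_durations, ref.schedule.frame_durations)
    ):
        raise ValueError("target and reference TACs must share a frame schedule")
    if np.max(np.abs(ref.values)) == 0.0:
        raise ValueError("degenerate reference TAC (all zeros)")


def _wls_two_param(x1: np.ndarray, x2: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted LS for y ~ t1*x1 + t2*x2. Returns (t1, t2, rss)."""
    s11 = np.dot(w * x1, x1)
    s12 = np.dot(w * x1, x2)
    s22 = np.dot(w * x2, x2)
    b1 = np.dot(w * x1, y)
    b2 = np.dot(w * x2, y)
    det = s11 * s22 - s12 * s12
    if det <= 0:
        return np.nan, np.nan, np.inf
    t1 = (s22 * b1 - s12 * b2) / det
    t2 = (s11 * b2 - s12 * b1) / det
    rss = np.dot(w * y, y) - t1 * b1 - t2 * b2
    return t1, t2, max(rss, 0.0)


class BasisFitter:
    """Basis-function SRTM fitter bound to one reference TAC.

    Precomputes the frame-averaged convolution basis over the ``k2a`` grid so
    that many target regions of the same subject can be fitted cheaply.  For
    each candidate ``k2a`` the model is linear in ``(R1, k2 - R1*k2a)``; the
    weighted least-squares solution is found in closed form, the grid point
    with minimal weighted residual sum of squares is selected, then ``k2a``
    is refined by bounded 1-D minimisation between the neighbouring grid
    points.  ``BP_ND = k2/k2a - 1``.

    Weights default to frame durations.  A best fit at a grid boundary is
    flagged (``"k2a_at_grid_boundary"``), as is a negative fitted BP_ND.
    """

    def __init__(self, ref: TimeActivityCurve, k2a_grid: np.ndarray | None = None,
                 weights: np.ndarray | None = None):
        if np.max(np.abs(ref.values)) == 0.0:
            raise ValueError("degenerate reference TAC (all zeros)")
        grid = DEFAULT_K2A_GRID if k2a_grid is None else np.asarray(k2a_grid, dtype=float)
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("k2a grid must be non-empty and strictly positive")
        self.ref = ref
        self.grid = grid
        sched = ref.schedule
        self.schedule = sched
        self.weights = sched.frame_durations if weights is None else np.asarray(weights, float)
        self._t_fine = _fine_times(sched)
        self._cr_fine = _interp_ref(ref, self._t_fine)
        self.x1 = _frame_average(self._cr_fine, self._t_fine, sched)
        self.basis = np.stack([
            _basis_curve(self._cr_fine, self._t_fine, sched, k2a) for k2a in grid
        ])

    def _basis_at(self, k2a: float) -> np.ndarray:
        return _basis_curve(self._cr_fine, self._t_fine, self.schedule, k2a)

    def fit(self, target: TimeActivityCurve, refine: bool = True) -> SRTMFit:
        _check_pair(target, self.ref)
        sched, w, x1, y = self.schedule, self.weights, self.x1, target.values
        rss = np.array([_wls_two_param(x1, b, y, w)[2] for b in self.basis])
        best = int(np.argmin(rss))
        flags: list[str] = []
        if best in (0, self.grid.size - 1):
            flags.append("k2a_at_grid_boundary")

        def profile_rss(log_k2a: float) -> float:
            return _wls_two_param(x1, self._basis_at(np.exp(log_k2a)), y, w)[2]

        k2a_hat = float(self.grid[best])
        if refine and 0 < best < self.grid.size - 1:
            res = optimize.minimize_scalar(
                profile_rss,
                bounds=(np.log(self.grid[best - 1]), np.log(self.grid[best + 1])),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if res.fun <= rss[best]:
                k2a_hat = float(np.exp(res.x))

        b = self._basis_at(k2a_hat)
        t1, t2, r = _wls_two_param(x1, b, y, w)
        k2 = t2 + t1 * k2a_hat
        bp = k2 / k2a_hat - 1.0
        if bp < 0:
            flags.append("negative_bpnd")
        params = SRTMParams(r1=float(t1), k2=float(k2), bp_nd=float(bp))
        fitted = TimeActivityCurve(sched, t1 * x1 + t2 * b, region_id=target.region_id,
                                   subject_id=target.subject_id)
        return SRTMFit(params=params, fitted_curve=fitted, weighted_rss=float(r),
                       k2a_grid_index=best, flags=flags)


def fit_srtm_basis(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    k2a_grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    refine: bool = True,
) -> SRTMFit:
    """Basis-function SRTM fit of one target TAC.  See :class:`BasisFitter`."""
    return BasisFitter(ref, k2a_grid=k2a_grid, weights=weights).fit(target, refine=refine)


def fit_srtm_nls(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    init: SRTMParams | None = None,
    weights: np.ndarray | None = None,
) -> SRTMFit:
    """Three-parameter weighted nonlinear least-squares SRTM fit.

    Independent of the basis-function path; intended as a cross-check.
    Raises :class:`FitError` (carrying the last iterate) on non-convergence
    and ``ValueError`` on a degenerate all-zero target.
    """
    _check_pair(target, ref)
    if np.max(np.abs(target.values)) == 0.0:
        raise ValueError("degenerate target TAC (all zeros); BP_ND undefined")
    sched = target.schedule
    w = sched.frame_durations if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    if init is None:
        init = SRTMParams(r1=1.0, k2=0.1, bp_nd=1.0)
    init.validate()

    t_fine = _fine_times(sched)
    cr_fine = _interp_ref(ref, t_fine)
    dt = t_fine[1] - t_fine[0]
    y = target.values

    def model(p):
        r1, k2, bp = p
        k2a = k2 / (1.0 + bp)
        conv = _frame_average(_exp_conv(cr_fine, k2a, dt), t_fine, sched)
        cr_frames = _frame_average(cr_fine, t_fine, sched)
        return r1 * cr_frames + (k2 - r1 * k2a) * conv

    def resid(p):
        return sw * (model(p) - y)

    x0 = np.array([init.r1, init.k2, init.bp_nd])
    res = optimize.least_squares(
        resid, x0, bounds=([1e-6, 1e-6, -0.999], [20.0, 20.0, 60.0]), xtol=1e-12, ftol=1e-12
    )
    params = SRTMParams(r1=float(res.x[0]), k2=float(res.x[1]), bp_nd=float(res.x[2]))
    if not res.success:
        raise FitError(f"SRTM NLS did not converge: {res.message}", last_params=params)
    fitted = TimeActivityCurve(sched, model(res.x), region_id=target.region_id,
                               subject_id=target.subject_id)
    flags = ["negative_bpnd"] if params.bp_nd < 0 else []
    return SRTMFit(params=params, fitted_curve=fitted, weighted_rss=float(np.sum(res.fun**2)),
                   k2a_grid_index=None, flags=flags)


# ---------------------------------------------------------------------------
# SUV utilities (reference-region validity check)


def suv_curve(tac: TimeActivityCurve, injected_dose_mbq: float, body_weight_kg: float) -> SUVCurve:
    """SUV per frame: activity concentration normalised by injected dose per body weight.

    With tissue density ~1 g/mL the unit conversions cancel and
    SUV = C[kBq/mL] * weight[kg] / dose[MBq].
    """
    if injected_dose_mbq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    return SUVCurve(tac.schedule, tac.values * body_weight_kg / injected_dose_mbq)


def suv_auc(
    tac: TimeActivityCurve,
    injected_dose_mbq: float,
    body_weight_kg: float,
    window_min: tuple[float, float] = (10.0, 90.0),
) -> float:
    """Area under the SUV curve over a time window (result in SUV*min).

    Frames are treated as piecewise-constant; frames partially inside the
    window are pro-rated.  The default 10-90 min window is the standard
    late-uptake check of reference-region validity.
    """
    suv = suv_curve(tac, injected_dose_mbq, body_weight_kg)
    sched = tac.schedule
    lo, hi = (60.0 * window_min[0], 60.0 * window_min[1])
    if lo < sched.frame_starts[0] - 1e-9 or hi > sched.frame_ends[-1] + 1e-9:
        raise ValueError("window must lie within the frame schedule span")
    if hi <= lo:
        raise ValueError("window must have positive length")
    overlap = np.clip(np.minimum(sched.frame_ends, hi) - np.maximum(sched.frame_starts, lo),
                      0.0, None)
    return float(np.dot(suv.suv_values, overlap) / SEC_PER_MIN)
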