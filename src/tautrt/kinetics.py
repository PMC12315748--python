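"""Outcome measures for dynamic tau PET: SUV/SUVR on a late window, SRTM
forward simulation and basis-function fitting (R1, k2, BP), and MRTM2 (DVR).

Reference-tissue notation: R1 = K1_target / K1_reference (relative delivery),
k2 the target efflux rate (1/min), BP the binding potential, and
k2a = k2 / (1 + BP) the apparent efflux rate. The SRTM solution is

    C_T(t) = R1 C_R(t) + (k2 - R1 k2a) [C_R * exp(-k2a t)](t)

and under the usual equal-nondisplaceable-volume assumption the reference
efflux implied by SRTM parameters is k2' = k2 / R1. MRTM2 regresses

    C_T(T) = g1 [ Int_0^T C_R + C_R(T)/k2' ] + g2 Int_0^T C_T,   DVR = -g1/g2

over frames with midpoint >= t*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .tacs import ScanMeta, TimeActivityCurve, cumulative_integral, frames_in_window

__all__ = [
    "SuvValue",
    "SrtmParams",
    "Mrtm2Fit",
    "suv",
    "suv_window",
    "suvr",
    "srtm_forward",
    "srtm_fit",
    "mrtm2_fit",
]


@dataclass(frozen=True)
class SuvValue:
    """Standardized uptake value (g/mL) over a time window."""

    value: float
    window: tuple[float, float]
    pvc_applied: bool = False


@dataclass(frozen=True)
class SrtmParams:
    """SRTM parameters; k2a = k2/(1+BP) is derived."""

    r1: float
    k2: float
    bp: float

    def __post_init__(self) -> None:
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.bp <= -1:
            raise ValueError("BP must exceed -1")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp)


@dataclass(frozen=True)
class Mrtm2Fit:
    dvr: float
    gamma1: float
    gamma2: float
    t_star: float
    k2_prime: float
    n_frames_used: int
    residual_rms: float


def suv(mean_concentration_kbq_ml: float, meta: ScanMeta, *, window=(90.0, 110.0),
        pvc_applied: bool = False) -> SuvValue:
    """SUV (g/mL) = concentration / (injected dose per body weight).

    With dose in kBq and weight in g the normalizer is dose_MBq / weight_kg
    in kBq/g, so e.g. 1.5 kBq/mL at 185 MBq / 74 kg gives 0.6 g/mL.
    """
    factor = meta.injected_dose_mbq / meta.body_weight_kg  # kBq/g
    return SuvValue(float(mean_concentration_kbq_ml) / factor, tuple(window), pvc_applied)


def suv_window(tac: TimeActivityCurve, meta: ScanMeta, t0: float = 90.0,
               t1: float = 110.0, *, pvc_applied: bool = False) -> SuvValue:
    """SUV from the unweighted mean of the frames fully inside [t0, t1]."""
    idx = frames_in_window(tac.schedule, t0, t1)
    return suv(float(np.mean(tac.values[idx])), meta, window=(t0, t1), pvc_applied=pvc_applied)


def suvr(target: SuvValue, reference: SuvValue) -> float:
    """Target-to-reference SUV ratio; windows and PVC status must match."""
    if target.window != reference.window:
        raise ValueError(f"window mismatch: {target.window} vs {reference.window}")
    if target.pvc_applied != reference.pvc_applied:
        raise ValueError("cannot mix PVC and non-PVC SUVs in one ratio")
    if reference.value <= 0:
        raise ValueError("reference SUV must be positive")
    return target.value / reference.value


# ---------------------------------------------------------------------------
# Exponential convolution of a frame-averaged TAC.
# ---------------------------------------------------------------------------

def _exp1m(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) computed stably."""
    return -np.expm1(-x)


def _conv_exp_frame_avg(tac: TimeActivityCurve, lambdas: np.ndarray) -> np.ndarray:
    """Frame averages of X(t) = Int_0^t C_R(s) exp(-lambda (t-s)) ds.

    C_R is taken as piecewise constant on the frames (the frame-average
    convention), extended as a constant before the first frame start, and as
    the midpoint-interpolation line across acquisition gaps. Exact
    closed-form exponential updates are used for each segment, so the result
    has no grid discretization error.

    Returns an array of shape (len(lambdas), n_frames).
    """
    lam = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if np.any(lam <= 0):
        raise ValueError("convolution rates must be positive")
    sched = tac.schedule
    v = tac.values
    n = sched.n_frames
    X = np.zeros_like(lam)
    avgs = np.empty((lam.size, n))

    def const_step(X, c, d, record=False):
        x = lam * d
        E = np.exp(-x)
        phi = _exp1m(x)  # 1 - E
        X_new = X * E + c * phi / lam
        if record:
            psi = phi / x  # (1-E)/(lam d)
            avg = X * psi + (c / lam) * (1.0 - psi)
            return X_new, avg
        return X_new, None

    def linear_step(X, a, b, d):
        # forcing c(tau) = a + b tau on [0, d]
        x = lam * d
        E = np.exp(-x)
        phi = _exp1m(x)
        small = x < 1e-6
        with np.errstate(divide="ignore", invalid="ignore"):
            ramp = d / lam - phi / lam**2  # Int_0^d s exp(-lam(d-s)) ds
        ramp = np.where(small, d * d * (0.5 - x / 6.0), ramp)
        return X * E + a * phi / lam + b * ramp

    # pre-scan: constant extension of the first frame value
    if sched.starts[0] > 1e-12:
        X, _ = const_step(X, v[0], sched.starts[0])

    for i in range(n):
        X, avg = const_step(X, v[i], sched.durations[i], record=True)
        avgs[:, i] = avg
        if i + 1 < n:
            gap = sched.starts[i + 1] - sched.ends[i]
            if gap > 1e-9:
                m0, m1 = sched.midpoints[i], sched.midpoints[i + 1]
                slope = (v[i + 1] - v[i]) / (m1 - m0)
                a = v[i] + slope * (sched.ends[i] - m0)
                X = linear_step(X, a, slope, gap)
    return avgs


def srtm_forward(ref: TimeActivityCurve, params: SrtmParams) -> TimeActivityCurve:
    """Simulate a target TAC from a reference TAC under SRTM.

    Frame values honor the frame-average convention exactly: the R1*C_R term
    reproduces the reference frame values, and the convolution term is frame
    averaged in closed form.
    """
    k2a = params.k2a
    beta = params.k2 - params.r1 * k2a
    conv = _conv_exp_frame_avg(ref, np.array([k2a]))[0]
    values = params.r1 * ref.values + beta * conv
    return TimeActivityCurve(ref.schedule, values, region=f"srtm({ref.region})")


_DEFAULT_K2A_GRID = np.logspace(np.log10(1e-3), np.log10(1.0), 256)


def srtm_fit(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    k2a_grid: np.ndarray | None = None,
    weights: str | np.ndarray = "duration",
) -> tuple[SrtmParams, dict]:
    """Basis-function SRTM fit.

    For each apparent efflux rate k2a on a fixed log-spaced grid the model is
    linear in (R1, beta) with beta = k2 - R1 k2a; the weighted least-squares
    subproblem is solved in closed form and the grid point minimizing the
    weighted residual sum of squares is refined by bounded 1-D minimization.
    Frame durations are the default weights (count-statistics proxy).

    Returns (SrtmParams, diagnostics). Diagnostics flag a best k2a at the
    grid boundary and ridge-flat (unidentifiable k2) fits.
    """
    if target.schedule is not ref.schedule and not (
        np.array_equal(target.schedule.starts, ref.schedule.starts)
        and np.array_equal(target.schedule.ends, ref.schedule.ends)
    ):
        raise ValueError("target and reference TACs must share one schedule")
    if not np.any(ref.values != 0):
        raise ValueError("reference TAC is identically zero")
    if not np.any(target.values != 0):
        raise ValueError("degenerate fit: target TAC is identically zero")

    grid = _DEFAULT_K2A_GRID if k2a_grid is None else np.asarray(k2a_grid, dtype=float)
    sched = target.schedule
    if isinstance(weights, str):
        if weights == "duration":
            w = sched.durations.copy()
        elif weights == "uniform":
            w = np.ones(sched.n_frames)
        else:
            raise ValueError(f"unknown weight scheme {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)

    y = target.values
    x1 = ref.values
    B = _conv_exp_frame_avg(ref, grid)  # (m, n)

    s11 = float(np.sum(w * x1 * x1))
    syy = float(np.sum(w * y * y))
    b1 = float(np.sum(w * x1 * y))
    s12 = B @ (w * x1)
    s22 = np.sum(w * B * B, axis=1)
    b2 = B @ (w * y)
    det = s11 * s22 - s12**2
    ok = det > 1e-12 * max(s11, 1.0) * np.maximum(s22, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_g = (b1 * s22 - s12 * b2) / det
        beta_g = (s11 * b2 - s12 * b1) / det
    rss = syy - (r1_g * b1 + beta_g * b2)
    rss = np.where(ok, rss, np.inf)

    i_best = int(np.argmin(rss))

    def objective(k2a: float) -> float:
        Bv = _conv_exp_frame_avg(ref, np.array([k2a]))[0]
        a12 = float(np.sum(w * x1 * Bv))
        a22 = float(np.sum(w * Bv * Bv))
        bb2 = float(np.sum(w * Bv * y))
        d = s11 * a22 - a12 * a12
        if d <= 0:
            return np.inf
        r1 = (b1 * a22 - a12 * bb2) / d
        beta = (s11 * bb2 - a12 * b1) / d
        return syy - (r1 * b1 + beta * bb2)

    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, grid.size - 1)]
    if hi > lo:
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        k2a_best = float(res.x) if res.fun <= rss[i_best] else float(grid[i_best])
    else:
        k2a_best = float(grid[i_best])

    Bv = _conv_exp_frame_avg(ref, np.array([k2a_best]))[0]
    a12 = float(np.sum(w * x1 * Bv))
    a22 = float(np.sum(w * Bv * Bv))
    bb2 = float(np.sum(w * Bv * y))
    d = s11 * a22 - a12 * a12
    r1 = (b1 * a22 - a12 * bb2) / d
    beta = (s11 * bb2 - a12 * b1) / d
    k2 = beta + r1 * k2a_best
    final_rss = syy - (r1 * b1 + beta * bb2)

    finite = rss[np.isfinite(rss)]
    ridge_flat = bool(finite.size and (finite.max() - finite.min()) <= 1e-10 * max(syy, 1e-300))
    k2_unidentifiable = ridge_flat or abs(beta) <= 1e-8 * max(abs(r1) * s11**0.5, 1e-300)
    diagnostics = {
        "rss": float(max(final_rss, 0.0)),
        "k2a": k2a_best,
        "boundary": i_best in (0, grid.size - 1),
        "k2_unidentifiable": bool(k2_unidentifiable),
    }
    if k2_unidentifiable:
        # BP = k2/k2a - 1 = beta/(r1 k2a); ridge-flat fits pin it at 0.
        bp = 0.0
        k2 = r1 * k2a_best
    else:
        bp = k2 / k2a_best - 1.0
    params = SrtmParams(r1=float(r1), k2=float(max(k2, 1e-12)), bp=float(max(bp, -1 + 1e-12)))
    return params, diagnostics


def mrtm2_fit(
    target: TimeActivityCurve,
    ref: TimeActivityCurve,
    t_star: float = 30.0,
    k2_prime: float = 0.04,
) -> Mrtm2Fit:
    """MRTM2 multilinear fit of DVR with fixed reference efflux k2'.

    Frames with midpoint >= t_star enter a duration-weighted linear
    regression of C_T(T) on [Int C_R + C_R(T)/k2'] and Int C_T; DVR is the
    negative coefficient ratio -g1/g2.
    """
    if k2_prime <= 0:
        raise ValueError("k2_prime must be positive")
    sched = target.schedule
    mid = sched.midpoints
    sel = np.flatnonzero(mid >= t_star)
    if sel.size < 3:
        raise ValueError(f"need >= 3 frames with midpoint >= t* = {t_star} min, got {sel.size}")

    int_ref = np.asarray(cumulative_integral(ref, mid[sel]))
    int_tgt = np.asarray(cumulative_integral(target, mid[sel]))
    x1 = int_ref + ref.values[sel] / k2_prime
    x2 = int_tgt
    y = target.values[sel]
    w = sched.durations[sel]

    s11 = np.sum(w * x1 * x1)
    s12 = np.sum(w * x1 * x2)
    s22 = np.sum(w * x2 * x2)
    b1 = np.sum(w * x1 * y)
    b2 = np.sum(w * x2 * y)
    det = s11 * s22 - s12 * s12
    scale = max(s11 * s22, 1e-300)
    if det <= 1e-12 * scale:
        raise ValueError("singular MRTM2 design matrix (collinear regressors)")
    g1 = (b1 * s22 - s12 * b2) / det
    g2 = (s11 * b2 - s12 * b1) / det
    resid = y - g1 * x1 - g2 * x2
    if g2 == 0:
        raise ValueError("degenerate MRTM2 fit: zero integral coefficient")
    dvr = -g1 / g2
    return Mrtm2Fit(
        dvr=float(dvr),
        gamma1=float(g1),
        gamma2=float(g2),
        t_star=float(t_star),
        k2_prime=float(k2_prime),
        n_frames_used=int(sel.size),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
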