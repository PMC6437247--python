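"""Input-function conditioning: metabolite, delay, and dispersion correction.

The arterial input function (AIF) driving tissue uptake is the parent
(unmetabolized) tracer concentration in plasma, Cp.  What PET measures in a
large vessel is the whole-blood curve Cb, which includes labelled
metabolites (mainly carbonate).  The split is modelled with an exponential
parent-fraction decay,

    Cp(t) = Cb(t) * exp(-rate * (t - onset))   for t >= onset (t in minutes),
    Cm(t) = Cb(t) - Cp(t),

with literature constants rate = 0.104 /min and onset = 0.48 min.  The
bolus also arrives at the tissue-adjacent vessel later (delay) and smeared
(dispersion, convolution with a normalized kernel (1/tau) exp(-t/tau)); both
the blood curve and the AIF are corrected with one shared (delay, tau).

An analytic tri-exponential bolus model (the standard analytic AIF form in
dynamic PET) is provided to smooth measured curves and to generate
synthetic ones:

    Cp(t) = (A1 (t-t0) - A2 - A3) e^{-l1 (t-t0)}
            + A2 e^{-l2 (t-t0)} + A3 e^{-l3 (t-t0)}    for t >= t0, else 0,

with t in minutes and l1 > l2 > l3 >= 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .tac import SampledCurve

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteCorrectionParams",
    "InputFunctionSet",
    "AnalyticInputParams",
    "metabolite_correct",
    "estimate_delay",
    "apply_delay",
    "apply_dispersion",
    "fit_dispersion",
    "fit_analytic_input",
    "fit_analytic_blood",
    "eval_analytic_input",
]


class InputFunctionError(ValueError):
    """Raised for invalid correction parameters or degenerate curves."""


@dataclass(frozen=True)
class MetaboliteCorrectionParams:
    """Exponential parent-fraction model: rate (1/min) and onset (min)."""

    rate: float = 0.104
    onset: float = 0.48

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise InputFunctionError("metabolite rate must be >= 0")
        if self.onset < 0:
            raise InputFunctionError("metabolite onset must be >= 0")


@dataclass
class InputFunctionSet:
    """Consistent whole-blood / parent / metabolite triple on one 1-s grid.

    Cb = whole blood (all 11C species), Cp = parent acetate (the AIF),
    Cm = metabolites; Cm == Cb - Cp pointwise.  delay_s and tau_s record the
    delay/dispersion state already applied.
    """

    Cb: SampledCurve
    Cp: SampledCurve
    Cm: SampledCurve
    delay_s: float = 0.0
    tau_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Cb.t.shape == self.Cp.t.shape == self.Cm.t.shape):
            raise InputFunctionError("Cb, Cp, Cm must share one grid")
        if not np.allclose(self.Cm.y, self.Cb.y - self.Cp.y, atol=1e-8):
            raise InputFunctionError("Cm must equal Cb - Cp")

    @property
    def t(self) -> np.ndarray:
        return self.Cb.t


def metabolite_correct(
    Cb: SampledCurve, params: MetaboliteCorrectionParams | None = None
) -> tuple[SampledCurve, SampledCurve]:
    """Split a whole-blood curve into parent (Cp) and metabolite (Cm) curves.

    Before the onset time no correction applies (the parent fraction is 1).
    Negative Cm values (possible on noisy input) are clipped to 0 with a
    logged count, and Cp adjusted to preserve Cm = Cb - Cp.
    """
    params = params or MetaboliteCorrectionParams()
    t_min = Cb.t / 60.0
    frac = np.ones_like(t_min)
    late = t_min >= params.onset
    frac[late] = np.exp(-params.rate * (t_min[late] - params.onset))
    cp = Cb.y * frac
    cm = Cb.y - cp
    n_neg = int(np.sum(cm < 0))
    if n_neg:
        logger.info("metabolite_correct: clipped %d negative Cm values to 0", n_neg)
        cm = np.clip(cm, 0.0, None)
        cp = Cb.y - cm
    return Cb.copy_with(cp), Cb.copy_with(cm)


def _max_slope_time(curve: SampledCurve, window_s: float) -> float:
    """Time of maximum first-difference slope of a 3-point-smoothed curve."""
    n = int(min(window_s, curve.end)) + 1
    y = curve.y[:n]
    smooth = np.convolve(y, np.ones(3) / 3.0, mode="same")
    # drop the border samples where the moving average is truncated
    slopes = np.diff(smooth[1:-1])
    if slopes.size == 0 or np.max(slopes) <= 0:
        raise InputFunctionError("no rising edge found (flat curve)")
    return float(np.argmax(slopes) + 1)


def estimate_delay(reference: SampledCurve, local: SampledCurve, window_s: float = 120.0) -> float:
    """Bolus-arrival delay (s) of `local` relative to `reference`.

    Compares the times of maximum initial slope (first differences of a
    3-point moving-average smoothed curve) within the first `window_s`
    seconds.  Positive means the local curve lags.
    """
    return _max_slope_time(local, window_s) - _max_slope_time(reference, window_s)


def apply_delay(curve: SampledCurve, delay_s: float) -> SampledCurve:
    """Translate a curve by `delay_s` seconds on the grid, zero-filling the edge."""
    shift = int(round(delay_s))
    if abs(shift) >= curve.t.size:
        raise InputFunctionError("|delay| must be smaller than the scan duration")
    y = np.zeros_like(curve.y)
    if shift >= 0:
        y[shift:] = curve.y[: curve.y.size - shift]
    else:
        y[:shift] = curve.y[-shift:]
    return curve.copy_with(y)


def apply_dispersion(curve: SampledCurve, tau_s: float) -> SampledCurve:
    """Convolve with the normalized dispersion kernel (1/tau) exp(-t/tau).

    tau_s = 0 is the delta-kernel limit and returns the input unchanged.
    The discrete kernel is renormalized to unit sum so total area is
    preserved.
    """
    if tau_s < 0:
        raise InputFunctionError("dispersion tau must be >= 0")
    if tau_s == 0:
        return curve.copy_with(curve.y.copy())
    # cell-integrated kernel: k[j] = integral of (1/tau) e^(-s/tau) over the
    # 1-s cell centred on j, so a unit step maps to 1 - e^(-(t+1/2)/tau)
    n_k = min(int(np.ceil(30.0 * tau_s)) + 1, curve.t.size)
    edges = np.arange(n_k + 1, dtype=float) - 0.5
    edges[0] = 0.0
    cdf = 1.0 - np.exp(-edges / tau_s)
    kernel = np.diff(cdf)
    kernel /= kernel.sum()
    y = np.convolve(curve.y, kernel)[: curve.y.size]
    return curve.copy_with(y)


def fit_dispersion(
    reference: SampledCurve, local: SampledCurve, window_s: float = 120.0
) -> float:
    """Dispersion constant tau (s) mapping `reference` onto `local`.

    Minimizes the sum of squared differences over t < window_s between the
    dispersed reference and the (already delay-corrected) local curve.
    Grid search on [0, 60] s at 1-s steps, then bounded scalar refinement.
    """
    n = int(min(window_s, reference.end)) + 1

    def sse(tau: float) -> float:
        d = apply_dispersion(reference, tau).y[:n] - local.y[:n]
        return float(d @ d)

    taus = np.arange(0.0, 60.5, 1.0)
    losses = np.array([sse(tau) for tau in taus])
    best = int(np.argmin(losses))
    if np.allclose(losses, losses[0]):
        warnings.warn("fit_dispersion: flat objective; returning tau = 0", stacklevel=2)
        return 0.0
    lo = taus[max(best - 1, 0)]
    hi = taus[min(best + 1, taus.size - 1)]
    if lo == hi:
        return float(taus[best])
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3})
    return float(res.x) if res.fun <= losses[best] else float(taus[best])


# ------------------------------------------------- analytic input model


@dataclass(frozen=True)
class AnalyticInputParams:
    """Tri-exponential bolus parameters; times in minutes, rates per minute."""

    t0: float
    A1: float
    A2: float
    A3: float
    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 > self.l3 >= 0):
            raise InputFunctionError("rates must satisfy l1 > l2 > l3 >= 0")

    def __call__(self, t_s: np.ndarray) -> np.ndarray:
        return eval_analytic_input(self, t_s)


def eval_analytic_input(params: AnalyticInputParams, t_s: np.ndarray) -> np.ndarray:
    """Evaluate the tri-exponential bolus model on a grid of seconds."""
    t = np.asarray(t_s, dtype=float) / 60.0 - params.t0
    y = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    y[pos] = (
        (params.A1 * tp - params.A2 - params.A3) * np.exp(-params.l1 * tp)
        + params.A2 * np.exp(-params.l2 * tp)
        + params.A3 * np.exp(-params.l3 * tp)
    )
    return y


def fit_analytic_blood(blood, mc: MetaboliteCorrectionParams | None = None) -> AnalyticInputParams:
    """Fit the analytic parent model to a *framed* whole-blood TAC.

    The forward model is Cp_analytic(t) scaled up by the inverse parent
    fraction (so it predicts whole blood), frame-averaged onto the TAC's
    schedule; residuals are taken against the measured frame values.  This
    undoes the frame-averaging distortion that a pointwise fit to the
    interpolated curve cannot.
    """
    from .tac import SampledCurve, TimeActivityCurve, frame_average, grid_1s, total_duration

    if not isinstance(blood, TimeActivityCurve):
        raise TypeError("fit_analytic_blood expects a framed TimeActivityCurve")
    mc = mc or MetaboliteCorrectionParams()
    t = grid_1s(total_duration(blood.schedule))
    t_min = t / 60.0
    inflation = np.ones_like(t_min)
    late = t_min >= mc.onset
    inflation[late] = np.exp(mc.rate * (t_min[late] - mc.onset))

    from .tac import resample_1s

    # start from the pointwise fit of the interpolated parent curve
    cp0, _ = metabolite_correct(resample_1s(blood), mc)
    start = fit_analytic_input(cp0)

    y_obs = blood.values

    def framed_model(x: np.ndarray) -> np.ndarray:
        t0, a1, a2, a3, l1, l2, l3 = x
        tt = t_min - t0
        cp = np.zeros_like(tt)
        pos = tt > 0
        tp = tt[pos]
        cp[pos] = (
            (a1 * tp - a2 - a3) * np.exp(-l1 * tp)
            + a2 * np.exp(-l2 * tp)
            + a3 * np.exp(-l3 * tp)
        )
        return frame_average(SampledCurve(t, cp * inflation), blood.schedule).values

    def resid(x: np.ndarray) -> np.ndarray:
        return framed_model(x) - y_obs

    x0 = _pack(start)
    lo = [0.0, 0.0, 0.0, 0.0, 1e-3, 1e-4, 0.0]
    hi = [max(x0[0] * 2, 0.02), np.inf, np.inf, np.inf, 100.0, 10.0, 1.0]
    sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
                        max_nfev=2000)
    t0, a1, a2, a3, l1, l2, l3 = sol.x
    if l3 > l2:
        l2, l3, a2, a3 = l3, l2, a3, a2
    if not (l1 > l2 > l3 >= 0):
        raise InputFitError("degenerate rate ordering in framed blood fit", start)
    return AnalyticInputParams(t0, a1, a2, a3, l1, l2, l3)


class InputFitError(RuntimeError):
    """Analytic input fit failed; carries the best attempt found."""

    def __init__(self, msg: str, best: AnalyticInputParams | None = None):
        super().__init__(msg)
        self.best = best


def _pack(p: AnalyticInputParams) -> np.ndarray:
    return np.array([p.t0, p.A1, p.A2, p.A3, p.l1, p.l2, p.l3])


def fit_analytic_input(curve: SampledCurve) -> AnalyticInputParams:
    """Least-squares fit of the tri-exponential bolus model to a curve.

    Multi-start over a small set of rate initializations; raises
    :class:`InputFitError` (carrying the best attempt) if no start converges
    to a meaningful fit.
    """
    y = curve.y
    if np.max(np.abs(y)) <= 0:
        raise InputFitError("cannot fit the analytic input model to an all-zero curve")
    peak_i = int(np.argmax(y))
    peak_t_min = curve.t[peak_i] / 60.0
    amp = float(y[peak_i])

    def resid(x: np.ndarray) -> np.ndarray:
        t0, a1, a2, a3, l1, l2, l3 = x
        t = curve.t / 60.0 - t0
        out = np.zeros_like(t)
        pos = t > 0
        tp = t[pos]
        out[pos] = (
            (a1 * tp - a2 - a3) * np.exp(-l1 * tp)
            + a2 * np.exp(-l2 * tp)
            + a3 * np.exp(-l3 * tp)
        )
        return out - y

    lo = [0.0, 0.0, 0.0, 0.0, 1e-3, 1e-4, 0.0]
    hi = [max(peak_t_min, 0.02), np.inf, np.inf, np.inf, 100.0, 10.0, 1.0]
    starts = []
    for l1 in (3.0, 6.0):
        for l3 in (0.05, 0.15):
            starts.append(
                np.array(
                    [
                        max(peak_t_min - 1.0 / l1, 1e-3),
                        amp * l1 * np.e,
                        0.1 * amp,
                        0.1 * amp,
                        l1,
                        0.5,
                        l3,
                    ]
                )
            )
    best_res, best_x = np.inf, None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=2000)
        except Exception:
            continue
        if sol.cost < best_res:
            best_res, best_x = sol.cost, sol.x
    if best_x is None:
        raise InputFitError("analytic input fit did not converge from any start")
    t0, a1, a2, a3, l1, l2, l3 = best_x
    # the slow terms are symmetric under exchange; canonicalize l2 > l3
    if l3 > l2:
        l2, l3, a2, a3 = l3, l2, a3, a2
    if not (l1 > l2 > l3 >= 0):
        raise InputFitError("degenerate rate ordering in analytic input fit")
    params = AnalyticInputParams(t0, a1, a2, a3, l1, l2, l3)
    rel = np.sqrt(2 * best_res) / np.linalg.norm(y)
    if rel > 0.5:
        raise InputFitError(f"analytic input fit poor (relative misfit {rel:.2f})", params)
    return params
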