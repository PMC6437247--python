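"""Bank of compartmental models for [11C]-acetate kinetics in brown fat.

Ten linear compartment models (#1-#10) describe the fate of the tracer:
plasma parent acetate (Cp) enters one to three tissue compartments through
the flow constant K1 (mL/g/min); first-order rate constants k2..k5 (1/min)
move label between compartments, out to blood, or trap it irreversibly.
Models #8-#10 add a compartment fed by the circulating-metabolite curve Cm.
The measured PET signal mixes tissue and blood:

    Ctot(t) = (1 - vb) * sum_i Ci(t) + vb * Cb(t),

with vb the fractional blood volume and Cb the whole-blood curve (parent
plus metabolites).  For the four-compartment models (#5-#7) the entry and
exit rates of the oxidative compartment are tied to one shared constant;
the tie is implemented by parameter sharing, so only free parameters are
exposed.

Model topologies (compartment wiring):

  #1  Cp -K1-> C1 -k2-> out                                (1T, irreversible)
  #2  Cp -K1-> C1 -k2-> out;  C1 <k3/k4> C2                (2T, reversible store)
  #3  Cp -K1-> C1 -k2-> C2 -k3-> out                       (2T, series chain)
  #4  Cp -K1-> C1 -k2-> out;  C1 -k3-> C2 (trap)           (2T, irreversible store)
  #5  Cp <K1/k2> C1; C1 -k3-> C3 -k3-> out; C1 <k4/k5> C2  (3T, tied oxidation)
  #6  #5 with the storage return removed (C1 -k4-> C2 trap)
  #7  Cp -K1-> C1; C1 -k3-> C2 (trap); C1 -k2-> C3 -k2-> out
  #8  #1 plus Cm -k3-> C2 (irreversible metabolite uptake)
  #9  #1 plus Cm -k3-> C2 -k4-> out (reversible metabolite)
  #10 #4 plus Cm -k4-> C3 -k5-> out

The wiring of #3, #6, #8 and #9 admits more than one plausible encoding;
the choices above are this package's documented defaults, kept declarative
so alternates can be swapped.

Simulation integrates the linear ODE system with a classic 4th-order
Runge-Kutta scheme at a fixed 0.5-s step on the 1-s grid.  Because the
system is linear, one RK4 step is an affine map C -> R C + f; R and the
forcing weights are precomputed from the transfer matrix, so the time loop
is a cheap linear scan (numba-compiled when available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .input_function import InputFunctionSet
from .tac import SampledCurve, TimeActivityCurve

KineticParams = Dict[str, float]

__all__ = [
    "ModelSpec",
    "KineticParams",
    "CompartmentCurves",
    "MonoexpResult",
    "PatlakResult",
    "MODEL_IDS",
    "get_model_spec",
    "simulate_tissue",
    "total_signal",
    "monoexp_index",
    "patlak",
    "PARAM_BOUNDS",
]

# Hard parameter bounds shared by all models (units: K1 mL/g/min, k 1/min,
# vb dimensionless).
PARAM_BOUNDS: Dict[str, tuple] = {"K1": (0.0, 5.0), "vb": (0.0, 1.0)}


def param_bounds(name: str) -> tuple:
    return PARAM_BOUNDS.get(name, (0.0, 10.0))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative topology of one compartment model.

    ``inflows`` are (param, source, target) with source "Cp" or "Cm";
    ``transfers`` are (param, from_compartment, to_compartment) with
    ``to_compartment=None`` meaning elimination to blood.  A parameter name
    appearing in several rules is a tied rate sharing one free symbol.
    """

    id: int
    n_tissue: int
    params: tuple
    inflows: tuple
    transfers: tuple
    description: str = ""

    def __post_init__(self) -> None:
        used = {p for p, _, _ in self.inflows} | {p for p, _, _ in self.transfers}
        declared = set(self.params) - {"vb"}
        if used != declared:
            raise ValueError(f"model #{self.id}: template params {used} != declared {declared}")

    @property
    def free_params(self) -> tuple:
        """Free parameter names in fit order (tied rates appear once)."""
        return self.params

    def validate_params(self, params: KineticParams) -> None:
        missing = [p for p in self.params if p not in params]
        if missing:
            raise ValueError(f"model #{self.id}: missing parameters {missing}")
        for name in self.params:
            lo, hi = param_bounds(name)
            val = params[name]
            if not (lo <= val <= hi):
                raise ValueError(f"model #{self.id}: {name}={val} outside [{lo}, {hi}]")

    def system(self, params: KineticParams) -> tuple:
        """Transfer matrix A (1/min) and forcing vectors (bp, bm) for Cp/Cm."""
        self.validate_params(params)
        n = self.n_tissue
        A = np.zeros((n, n))
        bp = np.zeros(n)
        bm = np.zeros(n)
        for name, src, tgt in self.inflows:
            (bp if src == "Cp" else bm)[tgt] += params[name]
        for name, i, j in self.transfers:
            A[i, i] -= params[name]
            if j is not None:
                A[j, i] += params[name]
        return A, bp, bm

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "n_tissue": self.n_tissue,
            "params": list(self.params),
            "inflows": [list(x) for x in self.inflows],
            "transfers": [list(x) for x in self.transfers],
            "description": self.description,
        }


_BANK: Dict[int, ModelSpec] = {
    1: ModelSpec(1, 1, ("K1", "k2", "vb"),
                 (("K1", "Cp", 0),),
                 (("k2", 0, None),),
                 "one-tissue irreversible: uptake and oxidative clearance"),
    2: ModelSpec(2, 2, ("K1", "k2", "k3", "k4", "vb"),
                 (("K1", "Cp", 0),),
                 (("k2", 0, None), ("k3", 0, 1), ("k4", 1, 0)),
                 "two-tissue with reversible storage"),
    3: ModelSpec(3, 2, ("K1", "k2", "k3", "vb"),
                 (("K1", "Cp", 0),),
                 (("k2", 0, 1), ("k3", 1, None)),
                 "two-tissue series chain"),
    4: ModelSpec(4, 2, ("K1", "k2", "k3", "vb"),
                 (("K1", "Cp", 0),),
                 (("k2", 0, None), ("k3", 0, 1)),
                 "two-tissue with irreversible storage trap"),
    5: ModelSpec(5, 3, ("K1", "k2", "k3", "k4", "k5", "vb"),
                 (("K1", "Cp", 0),),
                 (("k2", 0, None), ("k3", 0, 2), ("k3", 2, None),
                  ("k4", 0, 1), ("k5", 1, 0)),
                 "three-tissue: reversible uptake, tied oxidation, reversible storage"),
    6: ModelSpec(6, 3, ("K1", "k2", "k3", "k4", "vb"),
                 (("K1", "Cp", 0),),
                 (("k2", 0, None), ("k3", 0, 2), ("k3", 2, None),
                  ("k4", 0, 1)),
                 "three-tissue: tied oxidation, irreversible storage"),
    7: ModelSpec(7, 3, ("K1", "k2", "k3", "vb"),
                 (("K1", "Cp", 0),),
                 (("k3", 0, 1), ("k2", 0, 2), ("k2", 2, None)),
                 "three-tissue irreversible: storage trap plus tied oxidative pathway"),
    8: ModelSpec(8, 2, ("K1", "k2", "k3", "vb"),
                 (("K1", "Cp", 0), ("k3", "Cm", 1)),
                 (("k2", 0, None),),
                 "one-tissue plus irreversible metabolite uptake"),
    9: ModelSpec(9, 2, ("K1", "k2", "k3", "k4", "vb"),
                 (("K1", "Cp", 0), ("k3", "Cm", 1)),
                 (("k2", 0, None), ("k4", 1, None)),
                 "one-tissue plus reversible metabolite compartment"),
    10: ModelSpec(10, 3, ("K1", "k2", "k3", "k4", "k5", "vb"),
                  (("K1", "Cp", 0), ("k4", "Cm", 2)),
                  (("k2", 0, None), ("k3", 0, 1), ("k5", 2, None)),
                  "two-tissue irreversible-storage plus reversible metabolite compartment"),
}

MODEL_IDS = tuple(sorted(_BANK))


def get_model_spec(model_id: int) -> ModelSpec:
    """Return the fixed :class:`ModelSpec` for model id 1..10."""
    try:
        return _BANK[int(model_id)]
    except (KeyError, ValueError) as exc:
        raise KeyError(f"unknown model id {model_id!r}; valid ids are 1..10") from exc


# ------------------------------------------------------------ simulation

_RK4_STEP_S = 0.5  # integration step in seconds (two substeps per grid cell)


def _rk4_affine(A_per_s: np.ndarray, h: float) -> tuple:
    """One RK4 step of dC/dt = A C + u(t) as an affine map.

    Returns (R, W1, W2, W3) with C_next = R C + W1 u(t) + W2 u(t+h/2) + W3 u(t+h),
    extracted from the generic step by linearity.
    """
    n = A_per_s.shape[0]

    def step(C, u1, u2, u3):
        k1 = A_per_s @ C + u1
        k2 = A_per_s @ (C + 0.5 * h * k1) + u2
        k3 = A_per_s @ (C + 0.5 * h * k2) + u2
        k4 = A_per_s @ (C + h * k3) + u3
        return C + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    eye = np.eye(n)
    zero = np.zeros(n)
    R = np.column_stack([step(eye[:, j], zero, zero, zero) for j in range(n)])
    W1 = np.column_stack([step(zero, eye[:, j], zero, zero) for j in range(n)])
    W2 = np.column_stack([step(zero, zero, eye[:, j], zero) for j in range(n)])
    W3 = np.column_stack([step(zero, zero, zero, eye[:, j]) for j in range(n)])
    return R, W1, W2, W3


def _scan_py(R: np.ndarray, F: np.ndarray) -> np.ndarray:
    C = np.zeros((F.shape[0] + 1, R.shape[0]))
    for i in range(F.shape[0]):
        C[i + 1] = R @ C[i] + F[i]
    return C


try:  # optional acceleration; pure-numpy fallback is exact but slower
    from numba import njit as _njit

    _scan_jit = _njit(cache=True)(_scan_py)

    def _scan(R: np.ndarray, F: np.ndarray) -> np.ndarray:
        return _scan_jit(np.ascontiguousarray(R), np.ascontiguousarray(F))

except Exception:  # pragma: no cover - numba not installed
    _scan = _scan_py


@dataclass
class CompartmentCurves:
    """Per-compartment tissue curves and the blood-mixed total signal."""

    C: list
    Ctot: SampledCurve


def simulate_tissue(
    spec: ModelSpec, params: KineticParams, inputs: InputFunctionSet
) -> CompartmentCurves:
    """Forward-simulate tissue compartment curves and the total PET signal.

    Integrates dC/dt = A C + bp Cp(t) + bm Cm(t) from zero initial state
    with fixed-step RK4 (0.5 s) on the shared 1-s grid, then mixes in the
    blood-volume term to produce Ctot.
    """
    A, bp, bm = spec.system(params)
    t = inputs.t
    n_grid = t.size
    # quarter-second input samples so each 0.5-s RK4 step sees t, t+h/2, t+h
    t_fine = np.arange(0.0, t[-1] + 0.125, 0.25)
    s = np.interp(t_fine, t, inputs.Cp.y)
    m = np.interp(t_fine, t, inputs.Cm.y) if np.any(bm) else None

    h_min = _RK4_STEP_S / 60.0  # rates are per minute
    R, W1, W2, W3 = _rk4_affine(A, h_min)
    n_steps = 2 * (n_grid - 1)
    idx = 2 * np.arange(n_steps)
    F = (
        np.outer(s[idx], W1 @ bp)
        + np.outer(s[idx + 1], W2 @ bp)
        + np.outer(s[idx + 2], W3 @ bp)
    )
    if m is not None:
        F += (
            np.outer(m[idx], W1 @ bm)
            + np.outer(m[idx + 1], W2 @ bm)
            + np.outer(m[idx + 2], W3 @ bm)
        )
    traj = _scan(R, F)[::2]  # back onto the 1-s grid
    curves = [SampledCurve(t.copy(), traj[:, j].copy()) for j in range(spec.n_tissue)]
    ctot = total_signal(curves, params["vb"], inputs.Cb)
    return CompartmentCurves(curves, ctot)


def total_signal(curves: Sequence[SampledCurve], vb: float, Cb: SampledCurve) -> SampledCurve:
    """Blood-volume mixture Ctot = (1 - vb) * sum_i Ci + vb * Cb."""
    if not (0.0 <= vb <= 1.0):
        raise ValueError(f"vb={vb} outside [0, 1]")
    tissue = np.sum([c.y for c in curves], axis=0)
    if np.shape(tissue) != Cb.y.shape:
        raise ValueError("compartment curves and Cb must share one grid")
    return Cb.copy_with((1.0 - vb) * tissue + vb * Cb.y)


# ----------------------------------------------- monoexponential index


@dataclass
class MonoexpResult:
    """Monoexponential washout fit: A * exp(-Kmono * t), t in minutes."""

    Kmono: float
    amplitude: float
    r2: float
    window: tuple


def monoexp_index(tac: TimeActivityCurve, window: tuple = (1.5, 5.0)) -> MonoexpResult:
    """Oxidative index from a monoexponential fit to the early washout.

    Fits A * exp(-Kmono * t) to the frame values whose mid-times fall in
    ``window`` (minutes; default 1.5-5 min, the early clearance phase).
    """
    t_min = tac.schedule.mid_times / 60.0
    mask = (t_min >= window[0]) & (t_min <= window[1])
    if int(mask.sum()) < 3:
        raise ValueError(f"monoexp window {window} contains fewer than 3 frames")
    tw, yw = t_min[mask], tac.values[mask]

    if np.ptp(yw) == 0:  # constant data: exact fit with zero decay
        return MonoexpResult(0.0, float(yw[0]), 1.0, tuple(window))

    # log-linear start when possible, else a flat start
    if np.all(yw > 0):
        slope, intercept = np.polyfit(tw, np.log(yw), 1)
        x0 = np.array([np.exp(intercept), max(-slope, 0.0)])
    else:
        x0 = np.array([max(np.max(yw), 1e-3), 0.1])

    def resid(x):
        return x[0] * np.exp(-x[1] * tw) - yw

    sol = least_squares(resid, x0, bounds=([0.0, 0.0], [np.inf, 20.0]), method="trf")
    amp, k = sol.x
    rss = float(2 * sol.cost)
    tss = float(np.sum((yw - yw.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
    return MonoexpResult(float(k), float(amp), r2, tuple(window))


# ------------------------------------------------------- Patlak analysis


@dataclass
class PatlakResult:
    """Patlak linearization: slope Ki (irreversible uptake), intercept, t_star."""

    Ki: float
    intercept: float
    t_star: float
    r2: float


def patlak(tissue: SampledCurve, Cp: SampledCurve, t_star: float = 10.0) -> PatlakResult:
    """Patlak graphical analysis of irreversible uptake.

    Regresses tissue/Cp on the 'stretched time' integral(Cp)/Cp (minutes)
    for t >= t_star (minutes).  A positive late-time slope indicates an
    irreversible (trapping) component; its units are mL/g/min under unit
    tissue density.
    """
    if tissue.t.shape != Cp.t.shape:
        raise ValueError("tissue and Cp must share one grid")
    t_min = Cp.t / 60.0
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (Cp.y[1:] + Cp.y[:-1]) * np.diff(t_min))])
    eps = 1e-3 * np.max(Cp.y)
    mask = (t_min >= t_star) & (Cp.y > eps)
    if int(mask.sum()) < 3:
        raise ValueError("too few usable points past t_star for Patlak regression")
    x = cum[mask] / Cp.y[mask]
    y = tissue.y[mask] / Cp.y[mask]
    if np.ptp(x) <= 0:
        raise ValueError("degenerate Patlak abscissa (no spread)")
    fit = stats.linregress(x, y)
    return PatlakResult(float(fit.slope), float(fit.intercept), float(t_star), float(fit.rvalue**2))
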