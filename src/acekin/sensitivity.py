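"""Sensitivity functions and identifiability (parameter-correlation) analysis.

The relative sensitivity of the model TAC to a kinetic parameter k_i is

    Sens_ki(t) = (dTAC(t) / TAC(t)) / (dk_i / k_i),

evaluated here by central finite differences at a +/-1% parameter step.
Time-integrated pairwise products form the sensitivity matrix

    SM_ij = integral_0^T Sens_ki(tau) Sens_kj(tau) dtau,

whose normalized inverse gives parameter correlation coefficients in
[-1, 1].  Pairs with |corr| >= 0.7 are considered strongly correlated and
hence not separately identifiable.  Tied rates are perturbed as the single
free symbol used in fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .input_function import InputFunctionSet
from .models import KineticParams, ModelSpec, simulate_tissue

__all__ = [
    "SensitivityCurves",
    "SensitivityMatrix",
    "sensitivity_curves",
    "sensitivity_matrix",
    "correlation_matrix",
    "flag_strong",
]

TAC_FLOOR = 1e-6  # SUV floor below which the relative sensitivity is undefined


@dataclass
class SensitivityCurves:
    """Relative sensitivity functions per parameter on the 1-s grid."""

    t: np.ndarray
    curves: Dict[str, np.ndarray]
    perturbation: float
    start_index: int
    flagged_zero: List[str] = field(default_factory=list)

    @property
    def start_time(self) -> float:
        return float(self.t[self.start_index])


def sensitivity_curves(
    spec: ModelSpec,
    params: KineticParams,
    inputs: InputFunctionSet,
    step: float = 0.01,
) -> SensitivityCurves:
    """Central-difference relative sensitivity of Ctot to each free parameter.

    Evaluation starts at the first grid point where the reference TAC
    exceeds a small floor (the pre-bolus TAC is zero and the ratio is
    undefined there).  Parameters equal to zero cannot be perturbed
    relatively and are flagged instead.
    """
    if step <= 0:
        raise ValueError("perturbation step must be > 0")
    ref = simulate_tissue(spec, params, inputs).Ctot.y
    above = np.nonzero(ref > TAC_FLOOR)[0]
    if above.size == 0:
        raise ValueError("reference TAC never exceeds the floor; nothing to evaluate")
    i0 = int(above[0])

    curves: Dict[str, np.ndarray] = {}
    flagged: List[str] = []
    for name in spec.free_params:
        val = params[name]
        if val == 0:
            flagged.append(name)
            continue
        up = dict(params, **{name: val * (1 + step)})
        dn = dict(params, **{name: val * (1 - step)})
        tac_up = simulate_tissue(spec, up, inputs).Ctot.y
        tac_dn = simulate_tissue(spec, dn, inputs).Ctot.y
        sens = np.zeros_like(ref)
        sens[i0:] = (tac_up[i0:] - tac_dn[i0:]) / (2.0 * step * ref[i0:])
        curves[name] = sens
    return SensitivityCurves(inputs.t, curves, step, i0, flagged)


@dataclass
class SensitivityMatrix:
    """Time-integrated sensitivity matrix and derived correlation structure."""

    params: Tuple[str, ...]
    SM: np.ndarray
    T_min: float
    corr: np.ndarray
    condition_number: float


def sensitivity_matrix(curves: SensitivityCurves, T: float = 30.0) -> SensitivityMatrix:
    """Integrate pairwise sensitivity products over [start_time, T] (minutes).

    The result is symmetric positive semidefinite by construction (Gram
    matrix of the sensitivity functions under the trapezoidal inner
    product).
    """
    t_min = curves.t / 60.0
    if T > t_min[-1] + 1e-9:
        raise ValueError(f"T={T} min is beyond the grid end ({t_min[-1]:.2f} min)")
    names = tuple(curves.curves)
    mask = (np.arange(t_min.size) >= curves.start_index) & (t_min <= T)
    tt = t_min[mask]
    S = np.stack([curves.curves[n][mask] for n in names])
    # trapezoidal Gram matrix: weight each sample by its trapezoid share
    w = np.zeros_like(tt)
    dt = np.diff(tt)
    w[:-1] += 0.5 * dt
    w[1:] += 0.5 * dt
    SM = (S * w) @ S.T
    SM = 0.5 * (SM + SM.T)
    corr, cond = _invert_normalize(SM)
    return SensitivityMatrix(names, SM, float(T), corr, cond)


def _invert_normalize(SM: np.ndarray) -> Tuple[np.ndarray, float]:
    cond = float(np.linalg.cond(SM))
    try:
        if cond > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
        inv = np.linalg.inv(SM)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"sensitivity matrix near-singular (cond={cond:.3g}); using pseudo-inverse",
            stacklevel=3,
        )
        inv = np.linalg.pinv(SM)
    d = np.sqrt(np.abs(np.diag(inv)))
    d[d == 0] = 1.0
    corr = inv / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0), cond


def correlation_matrix(sm: SensitivityMatrix) -> np.ndarray:
    """Parameter correlation coefficients: normalized inverse of SM."""
    return sm.corr


def flag_strong(
    corr: np.ndarray, params: Tuple[str, ...] = (), threshold: float = 0.7
) -> List[Tuple]:
    """Off-diagonal pairs with |corr| >= threshold, sorted by magnitude.

    Returns (name_i, name_j, corr_ij) tuples (index pairs if no names are
    given).
    """
    corr = np.asarray(corr)
    n = corr.shape[0]
    labels = params if params else tuple(range(n))
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr[i, j]) >= threshold:
                pairs.append((labels[i], labels[j], float(corr[i, j])))
    pairs.sort(key=lambda p: abs(p[2]), reverse=True)
    return pairs
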