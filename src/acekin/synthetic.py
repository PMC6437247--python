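"""Synthetic study data: cohort AIF presets and model-generated subjects.

Four cohort/condition presets emulate the study populations (younger and
older subjects, warm and cold conditions).  Each preset carries an analytic
tri-exponential parent-plasma curve whose amplitude is calibrated so the
whole-blood area under the curve over 30 min matches the cohort anchor
(39 / 49 / 51 / 63 SUV*min); the cold presets peak earlier with a slower
terminal washout, mirroring the measured blood curves.

The whole-blood curve is constructed by *inverting* the metabolite
correction — Cb = Cp * exp(+rate (t - onset)) past the onset — so that
applying the correction to a synthetic Cb recovers Cp exactly.  Tissue
curves are generated by the compartment models from ground-truth
parameters: model #7 uses the reference set (K1=0.07 mL/g/min, k2=0.30,
k3=0.14 min^-1, vb=0.10), model #4 its reference set (k2=0.14, k3=0.05);
truths for the remaining models are documented extrapolations sharing
K1=0.07 and vb=0.10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .input_function import (
    AnalyticInputParams,
    InputFunctionSet,
    MetaboliteCorrectionParams,
    apply_delay,
    apply_dispersion,
    eval_analytic_input,
)
from .models import KineticParams, get_model_spec, simulate_tissue
from .simulate import NoiseModel, generate_noise
from .tac import (
    FrameSchedule,
    SampledCurve,
    TimeActivityCurve,
    auc,
    default_schedule,
    frame_average,
    grid_1s,
    total_duration,
    write_tac,
)

__all__ = [
    "CohortPreset",
    "SyntheticSubject",
    "PRESETS",
    "TRUTH",
    "get_preset",
    "make_aif",
    "make_subject",
    "perturb_aif",
    "write_subject",
]

# Ground-truth kinetic parameters per model.  Models #7 and #4 use the
# reference simulation sets; the rest are extrapolations with the same uptake
# and blood volume, rates chosen once for comparable noiseless TAC peaks.
TRUTH: Dict[int, KineticParams] = {
    1: {"K1": 0.07, "k2": 0.14, "vb": 0.10},
    2: {"K1": 0.07, "k2": 0.14, "k3": 0.05, "k4": 0.02, "vb": 0.10},
    3: {"K1": 0.07, "k2": 0.30, "k3": 0.05, "vb": 0.10},
    4: {"K1": 0.07, "k2": 0.14, "k3": 0.05, "vb": 0.10},
    5: {"K1": 0.07, "k2": 0.10, "k3": 0.30, "k4": 0.05, "k5": 0.02, "vb": 0.10},
    6: {"K1": 0.07, "k2": 0.10, "k3": 0.30, "k4": 0.05, "vb": 0.10},
    7: {"K1": 0.07, "k2": 0.30, "k3": 0.14, "vb": 0.10},
    8: {"K1": 0.07, "k2": 0.14, "k3": 0.01, "vb": 0.10},
    9: {"K1": 0.07, "k2": 0.14, "k3": 0.01, "k4": 0.05, "vb": 0.10},
    10: {"K1": 0.07, "k2": 0.14, "k3": 0.05, "k4": 0.01, "k5": 0.05, "vb": 0.10},
}


@dataclass(frozen=True)
class CohortPreset:
    """Cohort/condition AIF shape, blood-AUC anchor, and injected delay state."""

    name: str
    aif_params: AnalyticInputParams
    target_auc: float  # SUV*min over 30 min, whole blood
    truth: Dict[int, KineticParams] = field(default_factory=lambda: TRUTH)
    delay_s: float = 4.0
    tau_s: float = 10.0


# Shape parameters chosen so the cold presets peak earlier (smaller t0,
# faster peak decay) with slower terminal washout, and amplitudes are later
# calibrated to the cohort blood-AUC anchors.
PRESETS: Dict[str, CohortPreset] = {
    "YS_warm": CohortPreset(
        "YS_warm", AnalyticInputParams(0.55, 200.0, 4.0, 1.2, 4.0, 0.50, 0.22), 39.0
    ),
    "YS_cold": CohortPreset(
        "YS_cold", AnalyticInputParams(0.40, 260.0, 4.5, 1.0, 5.0, 0.45, 0.20), 49.0
    ),
    "OS_warm": CohortPreset(
        "OS_warm", AnalyticInputParams(0.55, 210.0, 4.2, 1.2, 3.8, 0.50, 0.22), 51.0
    ),
    "OS_cold": CohortPreset(
        "OS_cold", AnalyticInputParams(0.42, 260.0, 4.5, 1.1, 4.8, 0.45, 0.20), 63.0
    ),
}


def get_preset(name: str) -> CohortPreset:
    try:
        return PRESETS[name]
    except KeyError as exc:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from exc


def _blood_from_parent(cp: np.ndarray, t_s: np.ndarray, mc: MetaboliteCorrectionParams) -> np.ndarray:
    """Invert the metabolite correction: Cb such that correcting Cb yields Cp."""
    t_min = t_s / 60.0
    factor = np.ones_like(t_min)
    late = t_min >= mc.onset
    factor[late] = np.exp(mc.rate * (t_min[late] - mc.onset))
    return cp * factor


def make_aif(
    preset: CohortPreset,
    total_s: Optional[float] = None,
    inject: bool = False,
    mc: Optional[MetaboliteCorrectionParams] = None,
) -> InputFunctionSet:
    """Build a metabolite-consistent input-function set for a preset.

    The analytic parent curve is evaluated on the 1-s grid, the whole-blood
    curve derived by inverting the metabolite correction, and both scaled so
    the 30-min whole-blood AUC hits the preset anchor.  With ``inject=True``
    the preset's delay and dispersion are applied to all three curves
    (emulating the tissue-adjacent vessel before correction).
    """
    mc = mc or MetaboliteCorrectionParams()
    total_s = total_s if total_s is not None else total_duration(default_schedule())
    t = grid_1s(total_s)
    cp = eval_analytic_input(preset.aif_params, t)
    cb = _blood_from_parent(cp, t, mc)
    raw_auc = auc(SampledCurve(t, cb), 0.0, min(total_s, 1800.0))
    scale = preset.target_auc / raw_auc
    cp *= scale
    cb *= scale
    delay_s = tau_s = 0.0
    if inject:
        cp_c = apply_dispersion(apply_delay(SampledCurve(t, cp), preset.delay_s), preset.tau_s)
        cb_c = apply_dispersion(apply_delay(SampledCurve(t, cb), preset.delay_s), preset.tau_s)
        cp, cb = cp_c.y, cb_c.y
        delay_s, tau_s = preset.delay_s, preset.tau_s
    ifs = InputFunctionSet(
        Cb=SampledCurve(t, cb),
        Cp=SampledCurve(t, cp),
        Cm=SampledCurve(t, cb - cp),
        delay_s=delay_s,
        tau_s=tau_s,
    )
    # carry the calibrated analytic parameters for later perturbation
    p = preset.aif_params
    ifs.analytic_params = AnalyticInputParams(
        p.t0, p.A1 * scale, p.A2 * scale, p.A3 * scale, p.l1, p.l2, p.l3
    )
    return ifs


@dataclass
class SyntheticSubject:
    """One synthetic subject: inputs, noiseless tissue TAC, noisy replicates."""

    inputs: InputFunctionSet
    tissue_noiseless: TimeActivityCurve
    tissue_noisy: list
    provenance: dict


def make_subject(
    preset: CohortPreset,
    model_id: int,
    noise: Optional[NoiseModel] = None,
    schedule: Optional[FrameSchedule] = None,
) -> SyntheticSubject:
    """Generate a synthetic subject from a preset and a generating model.

    The tissue curve is the model's Ctot at the preset truth, frame-averaged
    onto the schedule; noisy replicates add rows of the fixed noise bank.
    """
    if model_id not in preset.truth:
        raise KeyError(f"preset {preset.name} has no truth for model #{model_id}")
    schedule = schedule or default_schedule()
    noise = noise or NoiseModel(n_realizations=0)
    inputs = make_aif(preset, total_duration(schedule))
    spec = get_model_spec(model_id)
    truth = preset.truth[model_id]
    ctot = simulate_tissue(spec, truth, inputs).Ctot
    noiseless = frame_average(ctot, schedule, label=f"{preset.name}-model{model_id}")
    table = generate_noise(schedule, noise)
    noisy = [
        TimeActivityCurve(schedule, noiseless.values + row, label=f"{noiseless.label}-r{i}")
        for i, row in enumerate(table)
    ]
    prov = {
        "preset": preset.name,
        "model_id": model_id,
        "truth": dict(truth),
        "seed": noise.seed,
        "n_realizations": noise.n_realizations,
        "sd_ref": noise.sd_ref,
    }
    return SyntheticSubject(inputs, noiseless, noisy, prov)


def perturb_aif(
    base: InputFunctionSet,
    scale: float = 1.0,
    jitter_seed: Optional[int] = None,
    max_rate_jitter: float = 0.2,
    mc: Optional[MetaboliteCorrectionParams] = None,
) -> InputFunctionSet:
    """Amplitude-scaled, rate-warped variant of an input-function set.

    ``scale`` multiplies all three curves (AUC scales linearly).  With a
    ``jitter_seed`` and analytic parameters attached to ``base``, the
    exponential rates are additionally warped by up to +/-``max_rate_jitter``
    (relative) and the blood/metabolite curves re-derived consistently.
    With no jitter the operation is exact pointwise scaling.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    params = getattr(base, "analytic_params", None)
    if jitter_seed is None or params is None:
        out = InputFunctionSet(
            Cb=base.Cb.copy_with(base.Cb.y * scale),
            Cp=base.Cp.copy_with(base.Cp.y * scale),
            Cm=base.Cm.copy_with(base.Cm.y * scale),
            delay_s=base.delay_s,
            tau_s=base.tau_s,
        )
        if params is not None:
            out.analytic_params = AnalyticInputParams(
                params.t0, params.A1 * scale, params.A2 * scale, params.A3 * scale,
                params.l1, params.l2, params.l3,
            )
        return out
    mc = mc or MetaboliteCorrectionParams()
    rng = np.random.default_rng(jitter_seed)
    factors = 1.0 + max_rate_jitter * rng.uniform(-1.0, 1.0, size=3)
    l1, l2, l3 = params.l1 * factors[0], params.l2 * factors[1], params.l3 * factors[2]
    # keep the ordering invariant of the analytic form
    l1, l2, l3 = sorted([l1, l2, l3], reverse=True)
    warped = AnalyticInputParams(
        params.t0, params.A1 * scale, params.A2 * scale, params.A3 * scale, l1, l2, l3
    )
    t = base.t
    cp = eval_analytic_input(warped, t)
    cb = _blood_from_parent(cp, t, mc)
    out = InputFunctionSet(
        Cb=SampledCurve(t.copy(), cb),
        Cp=SampledCurve(t.copy(), cp),
        Cm=SampledCurve(t.copy(), cb - cp),
        delay_s=base.delay_s,
        tau_s=base.tau_s,
    )
    out.analytic_params = warped
    return out


def write_subject(subject: SyntheticSubject, outdir) -> None:
    """Write a subject directory: inputs, tissue curves, provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ifs = subject.inputs
    header = "t_s,cb_suv,cp_suv,cm_suv\n"
    with open(outdir / "inputs.csv", "w") as fh:
        fh.write(header)
        for i in range(ifs.t.size):
            fh.write(f"{ifs.t[i]:g},{ifs.Cb.y[i]:.8g},{ifs.Cp.y[i]:.8g},{ifs.Cm.y[i]:.8g}\n")
    write_tac(subject.tissue_noiseless, outdir / "tissue_noiseless.csv")
    for i, tac in enumerate(subject.tissue_noisy):
        write_tac(tac, outdir / f"tissue_noisy_{i}.csv")
    blood = TimeActivityCurve(
        subject.tissue_noiseless.schedule,
        frame_average(ifs.Cb, subject.tissue_noiseless.schedule).values,
        label="blood",
    )
    write_tac(blood, outdir / "blood.csv")
    sidecar = dict(subject.provenance)
    sidecar.update({"delay_s": ifs.delay_s, "tau_s": ifs.tau_s})
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
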