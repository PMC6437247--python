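# acekin

Compartmental kinetic modelling of [¹¹C]-acetate dynamic PET in brown
adipose tissue (BAT).

[¹¹C]-acetate PET is used to quantify oxidative metabolism: once taken up
and converted to acetyl-CoA, the label is either oxidised in the TCA cycle
(leaving the tissue as [¹¹C]-CO₂) or stored in lipids. In BAT the balance
between these pathways shifts with cold activation, and the field has
lacked a systematic answer to which kinetic model quantifies that shift
reliably. `acekin` is a toolkit for exactly that question: it implements a
bank of ten candidate compartment models, the input-function conditioning
they require, nonlinear least-squares fitting with AIC comparison, a
Monte-Carlo stability/accuracy/precision study, and sensitivity /
identifiability analysis — all exercisable end to end on synthetic cohort
data that emulate the measured curves.

It is intended for researchers in PET pharmacokinetics who want to rerun,
probe, or extend the model-selection analysis without access to the
original human data.

## The models

Each model is a linear ODE system driven by the metabolite-corrected
arterial input function C_p (and, for models #8–#10, the metabolite curve
C_m), e.g. for the reversible two-tissue model (#2):

    dC₁/dt = K₁·C_p(t) − (k₂+k₃)·C₁(t) + k₄·C₂(t)
    dC₂/dt = k₃·C₁(t) − k₄·C₂(t)

with the measured PET signal mixing tissue and whole blood C_b:

    C_tot(t) = (1 − v_b)·ΣᵢCᵢ(t) + v_b·C_b(t)

K₁ (mL/g/min) is the flow constant, k₂..k₅ (min⁻¹) first-order transfer
rates, v_b the fractional blood volume. The four-compartment models
(#5–#7) tie the oxidative compartment's entry and exit rates to one shared
constant. The whole-blood curve is split into parent and metabolites with
an exponential parent-fraction model, C_p = C_b·e^(−0.104(t−0.48)) for
t ≥ 0.48 min, and corrected for delay (maximum-initial-slope comparison)
and dispersion (convolution with (1/τ)e^(−t/τ)) between the aortic arch
and the BAT-adjacent vessel. Model comparison uses AIC = N·ln(RSS/N) +
2(P+1); identifiability uses the normalized inverse of the time-integrated
sensitivity matrix SM_ij = ∫ Sens_i(τ)Sens_j(τ)dτ with |corr| ≥ 0.7
flagged as strong.

## Worked example

Fit the four-compartment irreversible model (#7) to a synthetic
younger-subject cold-condition TAC generated from its own ground truth:

```python
import acekin as ak

preset = ak.get_preset("YS_cold")
subject = ak.make_subject(preset, model_id=7)
spec = ak.get_model_spec(7)
result = ak.fit_model(spec, subject.tissue_noiseless, subject.inputs)
print("fitted parameters:", {k: round(v, 4) for k, v in result.params.items()})
print("RSS = %.3g   R2 = %.4f" % (result.rss, result.r2))

mono = ak.monoexp_index(subject.tissue_noiseless)
print("Kmono = %.3f 1/min (R2 = %.2f)" % (mono.Kmono, mono.r2))

from acekin.sensitivity import sensitivity_curves, sensitivity_matrix, flag_strong
sens = sensitivity_curves(spec, preset.truth[7], subject.inputs)
sm = sensitivity_matrix(sens)
print("strong correlations:",
      [(a, b, round(c, 2)) for a, b, c in flag_strong(sm.corr, sm.params)])
```

prints

```
fitted parameters: {'K1': 0.07, 'k2': 0.3, 'k3': 0.14, 'vb': 0.1}
RSS = 1.07e-24   R2 = 1.0000
Kmono = 0.036 1/min (R2 = 0.94)
strong correlations: [('K1', 'k2', 0.86)]
```

The fit recovers the generating truth (K₁ = 0.07 mL/g/min, k₂ = 0.30,
k₃ = 0.14 min⁻¹, v_b = 0.10) exactly on the noiseless curve — the
model-stability criterion. The monoexponential oxidative index K_mono,
computed over the 1.5–5 min washout window, is much smaller than k₂
because the early washout is dominated by the vascular signal, and the
flagged (K₁, k₂) pair shows uptake and oxidation are not separately
identifiable from a single TAC.

The same pipeline is scriptable from the shell:

```bash
acekin generate --models 7 --presets YS_cold --n-realizations 10 --seed 7 --out subjects/
acekin fit --tac subjects/YS_cold/model7/tissue_noiseless.csv \
           --blood subjects/YS_cold/model7/blood.csv --model 7 \
           --no-delay-dispersion --out fit.json
acekin evaluate --models 1,4,7 --presets YS_warm,YS_cold --seed 1 --out study/
```

## Layout

| module | contents |
| --- | --- |
| `acekin.tac` | frame schedules, TAC containers, CSV I/O, 1-s resampling, AUC |
| `acekin.input_function` | metabolite / delay / dispersion correction, analytic bolus model |
| `acekin.models` | model bank #1–#10, ODE simulation, monoexponential index, Patlak |
| `acekin.fitting` | trust-region least squares, R², AIC |
| `acekin.simulate` | noise generator, stability / accuracy / COV, AIF variability |
| `acekin.sensitivity` | sensitivity curves and matrix, correlation flags |
| `acekin.synthetic` | cohort presets, subject generation, AIF perturbation |
| `acekin.cli` | `acekin` command-line entry points |

See `docs/methods.md` for the modelling assumptions, the synthetic-data
design, and numerical choices.
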