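# guancest

Quantification of the **guanidine CEST effect at 2 ppm** from CW-CEST
Z-spectra: closed-form physics models, a Bloch-McConnell simulator,
classical fitting baselines, a partially-synthetic training-data
generator, and a small regression network with gradient-based selection
of informative saturation offsets.

## The problem

Chemical exchange saturation transfer (CEST) MRI detects dilute solute
protons by saturating them off-resonance and measuring the resulting
loss of water signal (the Z-spectrum, S/S0 versus offset Δω in ppm).
The guanidinium protons of creatine and protein arginine resonate
≈ 2 ppm from water, and their exchange rate is pH-sensitive — in
ischemic stroke the guanidine CEST effect rises in the acidified lesion,
giving hyperintense contrast where amide proton transfer (APT, 3.5 ppm)
signals fade. Quantifying the 2 ppm effect is hard: it sits on strong
direct water saturation, a broad fast-exchanging amine background
(≈ 3 ppm, shifted toward water by exchange coalescence), and the
semi-solid magnetization-transfer (MT) baseline.

The effect of one pool is expressed as its exchange-dependent relaxation
rate in the rotating frame,

    R_ex(Δω) = f_s·k_sw·ω1² / (ω1² + (R_2s + k_sw)·k_sw
                                + (Δω − Δ)²·k_sw/(R_2s + k_sw)),

and a Z-spectrum is the inverse summation

    Z(Δω) = R_1obs·cos²θ / (R_eff + Σ_i R_ex,i·dilution_i).

The **AREX** metric inverts this: AREX = (S0/S_lab − S0/S_ref)·R_1obs·(1+f_m)
recovers R_ex of the pool that differs between label and reference.

The estimator at the package's core is a dense network
(input → 512 → 64 → 64 → 16 → 2, ReLU) that maps an R1obs-normalized
Z-spectrum to the amplitude *A* and width *W* of the guanidine AREX
peak. It is trained on **partially synthetic** spectra: guanidine, amide
and NOE components are simulated from the closed form while the
hard-to-model amine and MT backgrounds are *measured* line shapes,
extracted from mean Z-spectra by a six-pool Lorentzian fit plus a masked
cubic fit (mfit-poly), and rescaled per sample. Gradient attribution on
a trained network (mean |∂output/∂input| per offset, mean threshold)
then prunes the 69-offset protocol to the informative subset, cutting
scan time ≈ 70% (490 s → ≈ 140 s).

## Worked example

```python
import numpy as np
from guancest.bmc import default_tissue, simulate_zspectrum, ground_truth_guanidine
from guancest.physics import AcquisitionScheme
from guancest import fitting
from guancest.partial_synth import peak_amplitude_width

scheme = AcquisitionScheme.default_7t()   # 69 offsets, B1 = 1 uT, 5 s CW, TR 7 s
tissue = default_tissue()                 # 7-pool rat-brain surrogate
z = simulate_zspectrum(tissue, scheme, b0_shift_ppm=0.05)
zc = fitting.estimate_and_correct_b0(z)
print(f"estimated B0 shift : {fitting.estimate_b0_shift(z):+.3f} ppm")

truth = ground_truth_guanidine(tissue, scheme)
a, w = peak_amplitude_width(truth)
print(f"ground truth       : A = {100*a:.2f} %s^-1, W = {w:.2f} ppm")

plof = fitting.plof_fit(zc, scheme=scheme)
print(f"PLOF at 2 ppm      : {100*plof.values[np.isclose(plof.offsets_ppm, 2.0)][0]:.2f} %s^-1")

f6 = fitting.lorentzian_multipool_fit(zc, "6pool")
ag = fitting.quantify_from_fit(zc, f6, "amines_guan")
print(f"6-pool amines/guan : {100*ag.values[np.isclose(ag.offsets_ppm, 2.0)][0]:.2f} %s^-1")
print(f"3-point APT        : {100*fitting.apt_three_point(zc):.2f} %s^-1")
```

prints

```
estimated B0 shift : +0.052 ppm
ground truth       : A = 13.37 %s^-1, W = 0.48 ppm
PLOF at 2 ppm      : 12.02 %s^-1
6-pool amines/guan : 20.33 %s^-1
3-point APT        : 4.55 %s^-1
```

The B0 estimator recovers the injected 0.05 ppm shift; the exact
guanidine ground truth (AREX of simulations with and without the
guanidine pool) peaks at 13.4 %s⁻¹; PLOF lands close to it while the
six-pool fit overestimates badly because its combined amines/guanidine
pool includes the broad amine background — the failure mode the learned
estimator is designed to avoid.

A command-line surface wraps the same functions:
`guancest simulate | fit | synth | train | select-offsets | predict |
evaluate | fixtures` (see `guancest --help`).

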