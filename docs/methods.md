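# Methods

## Signal model

All rate algebra runs in rad/s and s⁻¹; offsets are stored in ppm with a
fixed 300 Hz/ppm conversion (7 T proton; the printed offset pair
13.33 ppm ↔ 4000 Hz is consistent with this). ω1 = γ·B1 with
γ = 2π·42.5764 rad s⁻¹ μT⁻¹. AREX values are kept in s⁻¹ internally and
multiplied by 100 only for display (%s⁻¹).

A dilute pool's CEST effect is the Lorentzian exchange-dependent
relaxation rate R_ex(Δω) (amplitude f_s·k_sw·ω1²/(ω1² + (R_2s+k_sw)k_sw)
at the pool shift). Z-spectra are assembled by inverse summation:
water relaxation R_eff = R1obs·cos²θ + R2w·sin²θ plus the diluted solute
terms (factor 1/(1 + r_MT·f_m)) plus r_MT times the MT term. At the
singular point ω1 = Δω = 0 we define cos²θ = 1 (no saturation field ⇒
longitudinal magnetization). The composite observed longitudinal rate is
R1obs = (R1w + r_MT·f_m·R1M)/(1 + r_MT·f_m).

**Finite saturation.** The steady-state inverse summation is exact only
as t_sat → ∞. Because the acquisition (and its numerical simulation)
uses 5 s of CW saturation, the training-data generator applies the
monoexponential approach to steady state, Z(t) = Z_ss + (1 − Z_ss)·
e^(−R_1ρ·t) with R_1ρ the full denominator. This halves the deviation
from the Bloch-McConnell signal (≈ 2% → < 1% away from water). The
steady-state form remains the default of `synthesize_zspectrum`, for
which the AREX round trip is an exact algebraic identity (tested to
1e-10).

AREX is singular wherever a signal reaches zero (inside the water dip,
where Z → 0 and cos²θ → 0); quantification functions therefore return
spectra restricted to offsets where both label and reference signals are
strictly positive, and reconstructed AREX spectra omit |Δω| < 0.3 ppm.
The evaluation window (1.5–2.5 ppm) never touches these regions.

## Bloch-McConnell simulator

Seven pools: water, amide (3.5 ppm), amine (3 ppm), guanidine (2 ppm),
NOE (−1.6), NOE (−3.5), and a semi-solid MT pool carried as a full
three-component exchanging pool with very short T2 (Lorentzian line
shape; a super-Lorentzian would be a further refinement and is out of
scope). CW irradiation makes the generator time-invariant, so the 5 s
evolution is the exact matrix exponential of the (3N+1)-dimensional
augmented system — no ODE stiffness issues despite R2m ≈ 10⁵ s⁻¹ — at
< 10 ms per 70-offset spectrum. S0 is the same simulation at the 333 ppm
control offset. Ground truth for a pool is the AREX of otherwise
identical simulations with and without it, without B0/B1 perturbations.

The shipped sampling ranges (`guancest/data/*.yaml`) are
literature-typical rat-brain 7 T values: T1w 1.4–2.2 s, T2w 30–60 ms,
f_m 0.05–0.15, guanidine f_s 2·10⁻⁴–2·10⁻³ with k_sw 50–500 s⁻¹
(slow-intermediate, pH-sensitive regime), fast amine exchange
1000–6000 s⁻¹, B0 ±0.1 ppm, B1 scale 0.9–1.1, Gaussian noise σ = 0.01
on Z. The fully-synthetic comparison arm uses deliberately broader
intervals. Every value is overridable; all shipped tests and the
acceptance study run against these defaults.

## Classical estimators

* **B0 correction**: spline argmin of Z within ±1 ppm; resampling onto
  the nominal grid by cubic interpolation.
* **Multi-pool Lorentzian fits** (6- and 7-pool) of 1−Z, bounded
  trust-region least squares (tolerances 1e-9, ≤ 2000 evaluations),
  fixed starting values, no random restarts; boundary-hitting parameters
  are reported for QC. AREX of a pool uses the measured Z as label and
  the reconstruction without that pool as reference.
* **PLOF**: Z inside 0.8–5 ppm modeled as R1obs·cos²θ/(R_eff + L_guan +
  cubic background), guanidine center 2 ± 0.1 ppm, width 0.3–1.5 ppm,
  water R2 free.
* **Polynomial reference**: cubic fit of Z over 1–1.5 ∪ 2.5–3 ppm as
  S_ref over 1–3 ppm.
* **mfit-poly / Δpoly**: cubic in (Δω − 3 ppm) fitted to the six-pool
  amines/guanidine AREX over 1–1.5 ∪ 2.5–5 ppm isolates the amine
  background; Δpoly is the subtraction (can be negative where the cubic
  overshoots).
* **Three-point APT**: S_lab = Z(3.5 ppm), S_ref = arithmetic mean of
  Z(3) and Z(4 ppm).

Fit starting values and bounds are this package's own surrogates, chosen
to reproduce the qualitative behaviors of the methods (broad
amines/guanidine pool in the 6-pool model versus a narrow guanidine pool
in the 7-pool model); they are config-overridable.

## Measured components and partially synthetic data

Components are extracted from **mean** Z-spectra (ROI-mean analogue;
averaging n spectra suppresses noise by √n and conditions the fits —
single noisy spectra gave component line shapes of draw-dependent
quality). The MT component is R1obs·L_MT/(1−L_MT) from the fitted MT
Lorentzian; the amine component is the mfit-poly cubic inside 1–5 ppm,
continued outside that range by the bounded inversion form
R1obs·(1+f_m)·L_ag/(1−L_ag) of the fitted amines/guanidine Lorentzian
(an extrapolated cubic diverges; near-water inaccuracy is tolerated
because R_eff dominates there). Fidelity on defaults: Pearson r between
the fitted MT line shape and the true pools' mean analytic R_ex over
1.5–5 ppm ≈ 0.9999.

Each training sample draws guanidine/amide/NOE pool parameters and water
relaxation from the ranges, scaling factors r_amines, r_MT ∈ [0.5, 1.5]
for the measured components, a B0 shift (realized by evaluating all
components on the shifted grid — no interpolation error for the
simulated terms) and a B1 scale (applied to ω1 of the simulated terms
and to the water terms; the measured line shapes' amplitude response to
B1 is subsumed by the r factors). Gaussian noise σ = 0.01 is added to Z.
Targets come from the noiseless, unshifted label/reference pair with and
without the guanidine pool, evaluated densely (0.005 ppm) over
0.5–3.5 ppm: A is the AREX value at 2 ppm, W the FWHM found by walking
outward to the half-maximum crossings (window edges cap pathological
widths; a vanishing peak keeps a well-defined fallback width). With
several component sources, samples alternate between them so per-source
subsets are equally sized.

## Network and training

Dense 512–64–64–16 ReLU stack with a linear 2-unit output (48,306
parameters for 19 inputs; 73,906 for 69), Huber loss (δ = 1), Adam at
1e-3, batch 64, ≈ 25–40 epochs with early stopping (patience 5–8 on a
10% validation split), all in NumPy — the model is desk-scale and an
explicit backward pass keeps training CPU-deterministic under a fixed
seed and yields exact input gradients for attribution.

Two normalizations matter and are stored in the checkpoint:

* **Targets** are z-scored during training. A (≈ 10 %s⁻¹ scale) and W
  (≈ 0.5 ppm) differ by ~20×; under a shared Huber loss the width
  residuals otherwise contribute almost no gradient and the width output
  does not train.
* **Inputs** (Z/R1obs) are centered and scaled per offset inside the
  model. Raw Z-spectra are all-positive and strongly correlated across a
  dataset; fed uncentered they can push entire ReLU layers into the dead
  region within the first epoch (constant output, zero input gradient).
  This is an affine reparametrization of the first layer; attribution
  gradients are mapped back to the raw inputs by the chain rule.

Predictions are pure functions of the input and frozen weights; the
guanidine spectrum is reconstructed as a Lorentzian at 2 ppm with the
predicted (A, W).

## Offset selection and robustness

Attribution: g_i = mean over training samples of Σ_k |∂y_k/∂x_i| (the
two outputs' absolute gradients summed per input before averaging),
computed on the tissue-mimicking reference training set. Offsets with
g_i strictly above mean(g) are retained (constant g is rejected as
degenerate). On defaults this keeps ≈ 18–21 of 69 offsets concentrated
near the amines/guanidine band, the water resonance and the MT wings,
a ≈ 70% scan-time reduction; the retrained reduced model's test MAE is
within a few percent of the full model's.

Monte-Carlo robustness: per noise level σ ∈ {0.005, 0.0067, 0.01, 0.02}
the network is trained at that σ and tested on 1000 noisy replicates of
a noiseless simulated base spectrum; CoV = std(A)/mean(A), with the
reduced model's std first divided by √(t_full/t_reduced) to express SNR
per unit scan time. RNG is seeded per σ.

## Evaluation conventions

Spectral accuracy is the mean |prediction − ground truth| over
1.5–2.5 ppm, computed on a dense 0.01 ppm comparison grid after spline
resampling (so estimates living on different grids are comparable) and
reported in %s⁻¹. Group comparisons use the two-sided Wilcoxon rank-sum
test (exact null for small tie-free samples; all-tied data reports
p = 1); associations use Spearman rank correlation (constant input
reported as NaN).

## Validation study and problem sizes

`guancest.workflows.run_validation_study` chains everything; every
random draw derives from one master seed via `SeedSequence` spawning.
Default sizes — 2 × 100 simulated voxels averaged into the two
component sources, 12,000 partially-synthetic training samples, 400
tissue-mimicking reference-training samples, 200 test samples, 1000
Monte-Carlo replicates per σ — complete in a few minutes on one CPU and
were chosen as the smallest sizes at which the study's comparisons are
stable across seeds.

## What the synthetic testbed does and does not show

The tissue-mimicking simulator provides exact ground truth, which no
in-vivo measurement can, and the package's quantitative claims (method
ordering, selection stability, noise robustness) are made against it.
It does not emulate: super-Lorentzian MT line shapes, pulsed or
non-steady-state saturation, spatial structure/partial-volume effects,
B0 inhomogeneity beyond a bulk shift, or unmodeled pools (aromatic
NOEs, multiple amines). Under the shipped surrogate ranges the mean
guanidine amplitude is ≈ 11 %s⁻¹ and the exact-(A, W) Lorentzian
reconstruction itself has a ≈ 0.9 %s⁻¹ floor against the simulated
ground truth (cos²θ skew plus pool cross-talk), so absolute MAEs scale
accordingly; the discriminating result is the ordering — learned
estimator < PLOF ≪ six-pool fit — together with the ≈ 4× six-pool/ML
separation, which is stable across seeds.

## Known limitations

* The amine background of a single measured-component source cannot span
  the full width diversity of fast-exchanging amine pools; generalization
  error of the learned estimator is dominated by this shape mismatch.
* The 7-pool fit's guanidine/amine separation is poorly identifiable at
  B1 = 1 μT and inherits large errors (as does Δpoly's subtraction).
* AREX-based quantities are undefined near the water resonance; all
  comparisons exclude it.
* In-vivo training targets (voxelwise fits on real animals) are
  supported as a procedure on simulated proxies only.
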