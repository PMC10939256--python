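# Methods

`cestarex` implements a complete quantification chain for chemical exchange
saturation transfer (CEST) MRI of brain neurometabolites — glutamate
(amine protons, 3.0 ppm), phosphocreatine and creatine (guanidinium
protons, 2.64 and 2.0 ppm) — together with the synthetic data generators
used to validate it. This note documents the models, the parameters that
matter, the numerical choices, and what the validation suite does and does
not demonstrate.

## Bloch-McConnell simulator

Each proton pool contributes three magnetization components in the frame
rotating at the saturation frequency. For pool *i* with chemical shift
δᵢ (ppm), fraction fᵢ, exchange rate kᵢ (solute→water, s⁻¹) and relaxation
rates R1ᵢ, R2ᵢ, CW irradiation of amplitude ω₁ = γB₁ at offset Δω couples
(Mxᵢ, Myᵢ, Mzᵢ) through precession at Δωᵢ = (Δω − δᵢ)·γB₀·10⁻⁶, relaxation
toward fᵢ, and two-site exchange with water only (solute–solute exchange
neglected; reverse rate fᵢ·kᵢ by mass balance). The resulting affine system
dM/dt = A·M + b is solved in closed form,

    M(t) = M∞ + exp(A·t)·(M0 − M∞),   A·M∞ + b = 0,

with an adaptive ODE fallback if A is numerically singular. Every pool,
including the semisolid MT pool, is propagated with these full Lorentzian
three-component dynamics; no super-Lorentzian lineshape is used, which keeps
a single consistent propagator and matches the Lorentzian fitting model
downstream. The semisolid pool's 9.1 μs T2 makes its direct-saturation
profile very broad, which is the dominant qualitative feature that matters
here; super-Lorentzian wings would change detailed far-offset behavior.

Each offset is simulated single-shot from thermal equilibrium. With the
repetition times used (5–8 s) against tissue T1 ≤ 2.2 s, steady-state
cycling over TR would change Z by under 2%, and the shipped protocols do not
resolve that difference.

**Pool library.** The multi-pool brain model (water; glutamate amine 3.0
ppm; PCr 2.64; Cr 2.0; amide 3.5; relayed NOE −3.5 and −1.6 ppm; semisolid
MT, symmetric at 0 ppm or asymmetric at −2.3 ppm) ships as an editable YAML
file (`data/pools.yaml`). The values are literature-plausible 9.4 T
defaults — e.g. fast amine exchange ≈ 5500 s⁻¹, Cr guanidinium ≈ 810 s⁻¹,
PCr ≈ 140 s⁻¹, MT fraction 0.07 — chosen once as working configuration, not
as measured ground truth; every validation below uses these defaults.

## Acquisition protocols

Two CEST protocols are emulated: a high-power glutamate-weighted one
(B₁ = 5.9 μT, 1000 ms CW block pulse, 57 offsets over ±8 ppm) and a
low-power creatine-weighted one (B₁ = 1.47 μT, 3500 ms, piecewise
asymmetric offset list whose printed interval boundaries enumerate to 87
offsets, denser downfield where the solute lines sit). The exact 57-offset
spacing is not published; a uniform grid is the default. Field mapping uses
a WASSR sweep (81 offsets, ±1 ppm, 0.05 μT, 1000 ms), a 30°/60° double-angle
image pair, and a variable-TR series (TR ∈ {0.25, 0.5, 1, 1.5, 2, 3.5, 5,
8} s). The reference image is taken at −300 ppm.

## Field mapping

* **B0 (WASSR).** The per-voxel water frequency is the argmin of a cubic
  spline through the WASSR spectrum, evaluated on a 0.001 ppm grid. Minima
  at the sampled boundary mask the voxel out. The maximum-symmetry WASSR
  algorithm is not used; for the symmetric low-power dips generated here the
  two coincide.
* **B1 (double angle).** θ = arccos(S₂α/(2Sα)); the ratio θ/α_nominal is the
  B1 scale. The arccos argument is clamped to [−1, 1] and clamped voxels are
  flagged rather than erroring; non-positive Sα masks the voxel.
* **T1 (variable TR).** Two-parameter saturation recovery
  S(TR) = S₀(1 − e^(−TR/T1)), bounded least squares with T1 ∈ [0.05, 10] s.
  TE decay is constant across the series and absorbed into S₀. Voxels whose
  fit hits a bound or fails to converge are flagged and removed. Whether the
  original acquisition used an inversion preparation is not documented;
  saturation recovery is assumed.

Voxels failing any field-map fit are removed from the common analysis mask
(intersection semantics).

## Z-spectrum background model

The normalized Z-spectrum is modelled as Z(Δω) = 1 − Σᵢ Aᵢ/(1 +
4((Δω−Δωᵢ)/σᵢ)²), σ = FWHM in ppm. The high-power spectra use a 3-component
background (water direct saturation, NOE at −3.5 ppm, symmetric MT); the
low-power spectra a 4-component one (water, NOE −3.5, NOE −1.6, asymmetric
MT at −2 ppm). Starting values and bounds ship verbatim in
`data/lorentzian_defaults.yaml` (water A ∈ [0.02, 1] sv 0.9, σ ∈ [0.3, 10]
sv 1.4, center ∈ [−1, 1] sv 0, and so on). The constant is fixed at 1, not a
free baseline.

The solver is bounded trust-region-reflective nonlinear least squares,
ftol = xtol = 1e−10, at most 2000 evaluations, deterministic start from the
shipped values. gtol is set to 1e−12, tighter than the scipy default,
because the 0.001-amplitude NOE −1.6 component otherwise stops polishing at
the gradient plateau on clean data. A σ floor of 1e−6 keeps the dip defined
where a shipped lower bound is exactly 0. Fitted points are sorted by
offset, so results are invariant to the ordering of the input stack.

**Exclusion windows.** Solute resonances are not fitted components; offsets
in a configurable window (default 1.8–3.8 ppm) are omitted from the
objective so the background is not dragged by the peaks being quantified.
The default covers all four solute lines (2.0, 2.64, 3.0, 3.5 ppm) with
≈0.3 ppm margin. A wider band (e.g. 1.6–4.0 ppm) was measured on null
phantoms to leave a larger unconstrained interpolation gap at 5.9 μT,
roughly 0.006 s⁻¹ of spurious Glu-AREX against ≈0.001 s⁻¹ for the default.

**Fixed analysis support.** Offsets within 0.5 ppm of the nominal grid edges
are dropped from every voxel's fit and AREX evaluation. The margin exceeds
the ±0.4 ppm WASSR search range, so the fitted support is identical for
every voxel regardless of its B0 shift. Without this, the 3-component fit is
sensitive enough to its edge samples that losing one offset to B0 resampling
changes Glu-AREX by ≈4%; with it, a uniform 0.2 ppm shift corrected by WASSR
reproduces the unshifted Glu- and Cr-AREX to ≈0.1%.

## AREX quantification

With Z_fit the fitted background (all fitted components included — water DS,
MT and NOE — so the asymmetry step is not re-contaminated by the fitted NOE
at −3.5/−1.6 ppm; the include-set is configurable):

    R(Δω)    = 1/Z(Δω) − 1/Z_fit(Δω)          (inverse subtraction)
    AREX(Δω) = (R(+Δω) − R(−Δω)) / T1          (s⁻¹)

Z values at or below 1e−6 are clipped before inversion. On the asymmetric
low-power grid the −Δω counterpart is obtained by monotone cubic (PCHIP)
interpolation over the negative branch; positive offsets whose mirror falls
outside the sampled range are dropped. Metabolite read-outs take the sampled
offset nearest the target when within 0.05 ppm, else linear interpolation
between the bracketing samples. Glu is read from the high-power pipeline at
3.0 ppm; PCr (2.64 ppm) and Cr (2.0 ppm) from the low-power pipeline. B1 is
corrected to first order by dividing by the actual/nominal ratio, clamped to
[0.5, 1.5] (clamped voxels flagged) to avoid noise blow-up.

## Synthetic phantom and study generation

The phantom is a single 2D slice: an elliptical "brain" of parenchyma with a
hippocampus-like ROI blob, one pool system per tissue class, smooth
deterministic B0 (Gaussian blob, ≤ 0.4 ppm) and B1 (multiplicative,
0.8–1.2) fields, and Rician noise realized as the magnitude of a complex
Gaussian perturbation. A voxel with B0 shift b sees every nominal offset at
(offset − b), i.e. its water resonates at +b ppm — the same convention WASSR
estimates and the corrector consumes. Simulated Z-values are cached with the
field values quantized to 0.002 ppm (B0) and 0.005 (B1 ratio), both well
below the respective estimation precision; nominal offsets are never
quantized. Transgenic-like phantoms lower the Glu/Cr pool fractions in the
ROI class; the direction matches the reported group effect, the magnitude is
configuration.

ROI tables for the statistics stage are Gaussian draws per group and
measure. The shipped effect sizes reconstruct the reported group structure —
WT − transgenic mean differences of 0.06/0.01/0.01 s⁻¹ for Glu/PCr/Cr AREX
with Cohen's d −1.31/−1.78/−1.08, a +35 ms qT1 shift (d 0.59), n = 10 per
group — with ROI volume and water linewidth as covariate distributions.

**What the generator does not emulate:** anatomy and registration, readout
and k-space effects, shaped or pulsed saturation, motion, partial volume,
spatially correlated noise, and any pH/temperature modulation of exchange.
Passing tests therefore demonstrate the correctness and self-consistency of
the processing chain under the stated forward model, not its accuracy on
acquired animal data.

## Group statistics

Two-group comparisons are ordinary least squares of the measure on a group
indicator plus covariates; the group coefficient's two-sided t test is the
reported comparison (it reduces exactly to the pooled two-sample t test with
no covariates). The reported mean difference is WT − transgenic (adjusted);
Cohen's d standardizes transgenic − WT by the pooled SD, uncorrected (not
Hedges' g), so the two deliberately carry opposite signs, matching the
published tables. The d confidence interval inverts the noncentral-t
distribution (brentq on the ncp, NaN-robust far in the tails), with a
normal-approximation fallback if bracketing fails. All measures analyzed
together form one Benjamini-Hochberg FDR family, as in a single results
table. Partial correlations residualize both variables on the covariates by
OLS and test the residual Pearson r on n − 2 − k degrees of freedom;
covariates default to the same adjustment variables as the group tables
(ROI volume for CEST measures, water linewidth for MRS) and are
configurable.

## Validation experiments and problem sizes

`scripts/acceptance.py --seed <s> --out <json>` recomputes, from scratch:
matrix-exponential vs adaptive-ODE agreement over 100 random pool/protocol
draws; the single-pool CW steady state against the rotating-frame formula
R1cos²θ/(R1cos²θ + R2sin²θ) at 50 offsets (long T2 and t_sat ≫ T1 so the
formula's ω_eff ≫ R2 regime holds); noise-free and SNR-100 recovery of the
shipped Lorentzian starting values over 500 voxels per model (the noisy
figure is the pooled median relative amplitude error over components with
A ≥ 0.02); WASSR recovery of 1000 uniform shifts in ±0.4 ppm at SNR 50;
double-angle on noiseless sinusoids; T1 recovery at 1% noise over 500
replicates; end-to-end Glu-AREX monotonicity over five Glu-fraction levels
and the zero-solute null on 10×10 noise-free phantoms; the 9×8 B1 × duration
contrast sweep; and the statistics layer (BH-FDR vs its step-up definition
on 1000 vectors, GLM vs pooled t, mean Cohen's d over 2000 replicates at
true d = −1.3). Phantom grids of 10×10 and these replicate counts keep the
whole script around three minutes on one CPU while leaving every
statistical check comfortably powered.

## Known limitations

* At 5.9 μT the deeply saturated, flat-bottomed spectrum is not a sum of
  Lorentzians; the 3-component background fit carries a systematic residual.
  With mobile background pools (NOEs) present, the residual asymmetry
  reaches ≈0.04 s⁻¹ at 3 ppm — an inherent property of Lorentzian-difference
  background removal at high power, present in the original analysis as
  well. The zero-solute null (water + MT) is clean (≲0.001 s⁻¹).
* The PCr line (≈0.16 ppm FWHM at the shipped exchange rate) is sampled at
  only 0.1–0.125 ppm on the printed low-power grid. Monotone-cubic
  resampling of a 0.2 ppm B0 shift therefore injects a few 10⁻⁴ of z-error
  at the 2.65 ppm read-out sample, so the PCr B0 round-trip reproduces to
  ≈2%, versus ≈0.1% for Glu and Cr.
* The B1 sweep's contrast definition (Z-difference with/without a pool) is
  a simulation-only construct; acquired data admits no "without-pool" arm.
* Exchange between solute pools, super-Lorentzian MT, shaped pulses and
  steady-state TR cycling are out of scope.
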