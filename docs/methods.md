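# Methods

## The thermodynamic model

A protein exists as monomer or homodimer in each of up to three well-mixed
compartments: the cytoplasm, a plasma-membrane slab of thickness *a*
(taken equal to the protein diameter, default 5 nm), and optionally an
internal-membrane slab. Within a compartment at total concentration *c*
(monomer-equivalent molar), mass action with dimer dissociation constant
K_D^dim gives

    c1 = 2c / (1 + r),   c2 = c·(8c/K)/(1 + r)²,   r = √(1 + 8c/K),

computed in these cancellation-free forms (the textbook (K/4)(r−1) form
loses all significant digits in the dilute limit). The effective chemical
potential of a compartment is ln c − ½ ln D(c) + ln K_part + const, with
D(c) = 1 + 4c/K + √(1+8c/K) and K_part the dimensionless partition
constant (1 for the cytoplasm, K_D^mem for the plasma membrane, K_D^int
for internal membranes; larger = weaker binding). The constants (RT, the
1 M reference concentration, the reference entropy) are identical across
compartments and drop out of the equilibrium condition, which reduces to
equality of partition-weighted **reduced activities**

    a(c) = c / √D(c),     a(c_c) = K_D^mem · a(c_m) = K_D^int · a(c_n).

### Closed-form solution

D factorises exactly: D(c) = (1 + √(1+8c/K))² / 2. Hence

    a(c) = √2·c / (1 + √(1+8c/K)),     c = √2·a + 4a²/K   (exact inverse),

and substituting the inverse into the conservation law
c_tot = c_c + a(ψc_m + φc_n) yields a single quadratic in the cytoplasmic
activity A:

    β A² + γ A = c_tot,
    γ = √2 (1 + aψ/K_mem + aφ/K_int),
    β = (4/K_dim)(1 + aψ/K_mem² + aφ/K_int²).

The equilibrium solver therefore needs no iteration; conservation,
mass-action and activity-equality invariants hold to ~1e-15 relative. An
independent nested-bisection solver (brentq on log c_c with brentq
activity inversion) lives in the test suite as the cross-check oracle.

Parameters and units: concentrations molar; *a* in metres; ψ, φ
(surface-area to cytoplasm-volume ratios) in 1/m. Defaults: ψ = 0.174 µm⁻¹
for the whole zygote, ψ = φ = 0.087 µm⁻¹ (posterior half) for the
three-compartment and kinetic analyses; c_tot = 27 nM (wild-type
estimate); K_D^int/K_D^mem = 5 where internal membranes are modelled.
`ModelParams` accepts all of these explicitly, since published analyses
use the whole-cell ψ for cooperativity scoring but the posterior-half
value for the three-compartment model, and do not state which was used in
the data fits; we default to 0.174 µm⁻¹ except in the fig5 presets.

## Cooperativity score

α is the OLS slope of log₁₀(membrane) on log₁₀(cytoplasm) over a graded
series (base-10 throughout, unweighted). A linear binder has α = 1; if
k_on/k_off ∝ m^λ then α = 1/(1−λ), so membrane-promoted dimerisation with
√m-like stabilisation gives α = 2. For the two-state model α is bounded by
[1, 2] and, as a function of K_D^dim at fixed K_D^mem, is unimodal: both
very weak and very strong dimerisation are linear (no change of dimeric
state upon binding); the peak sits where the cytoplasm is monomeric but
the membrane slab dimeric.

The model score (`score_model`) solves equilibria over a total-protein
sweep, by default 20 log-spaced points from 27 down to 0.27 nM. Because
the score of a curved log-log relation depends on the window, the helper
`ctot_sweep_for_cc_range` constructs the sweep from a target cytoplasmic
range; the fitted wild-type constants give α ≈ 1.8 over the observed
1–11 nM cytoplasmic window and ≈ 1.6 over the full two-decade depletion
sweep.

Bootstrap: embryos resampled with replacement, 10,000 replicates by
default (tests use hundreds for speed), percentile 2.5/97.5 bounds, seed
mandatory. Degenerate resamples (zero cytoplasmic variance in log space)
are skipped and counted.

## Rundown fitting

Raw arbitrary-unit datasets are normalised by a single factor anchoring
the reference subset's mean cytoplasmic signal to an absolute estimate
(10.4 nM for wild-type polarized zygotes); the membrane channel is
additionally divided by *a* to convert calibrated per-area signal to slab
molarity. This division-by-*a* convention is a documented choice — the
mapping between calibrated membrane units and slab concentration is not
uniquely pinned down by the measurement chain — and the recovery tests
rely only on internally consistent synthetic data.

Because both channels are measured, prediction needs only the activity
equality: c_m(c_c) = inverse-activity(a(c_c)/K_D^mem), closed form as
above. The joint fit minimises summed squared residuals of log₁₀ c_m
across genotypes with a shared K_D^mem and per-genotype K_D^dim (any of
which may be fixed, e.g. to an independently measured 358 nM), using
Nelder-Mead from 8 deterministic log-uniform starts over
K_D^dim ∈ [1 nM, 100 µM], K_D^mem ∈ [1e-5, 1]; equal-loss ties break to
the lowest K_D^dim. Residuals are taken in log space because the data
span ~2 decades. Bootstrap refits start from the full-data optimum.

Known limitation: the pairs percentile bootstrap is asymptotically
calibrated for this nonlinear fit; at n = 40 embryos per genotype its 95%
intervals cover the truth in only ~80–85% of repetitions (measured on
synthetic data), reaching nominal coverage by n ≈ 100. Point estimates at
n = 40 are nevertheless accurate to well within 25% at 10% measurement
CV. Noise on the *cytoplasm* channel additionally attenuates slope-like
quantities (errors-in-variables), which this package deliberately does
not model; coverage experiments therefore place noise on the response
channel.

## Kinetic model

Transition-state theory on the same free-energy landscape gives
concentration-dependent rates k_on = Λ̃/√D(c_c),
k_off,m = Λ̃·K_D^mem/√D(c_m), k_off,n = Λ̃·K_D^int/√D(c_n): membrane
crowding (dimerisation) lowers the off-rate. Since k_on·c_c = Λ̃·a(c_c)
and k_off,m·c_m = Λ̃·K_D^mem·a(c_m), detailed balance with the
thermodynamic equilibrium is an algebraic identity — verified to 1e-10 on
1000 random parameter draws.

Λ̃ (M/s) scales all rates and is calibrated by inverting the off-rate
expression at an observed FRAP off-rate: 0.0073 s⁻¹ at c_m = 47.6 µM,
K_D^dim = 358 nM, K_D^mem = 10^-2.43 gives Λ̃ = 46.7 M/s (printed value
46.4; the difference is rounding of 10^-2.43). Two presets are exposed —
`calibrated` (46.4) and `figure5` (4.0) — because both values appear in
published use without reconciliation; simulations default to the latter.

Symmetry breaking is modelled as a step drop of K_D^mem from 1 (no
plasma-membrane preference, e.g. before posterior clearance of inhibitory
kinase activity) to its polarized value at t = 0, starting from the
pre-step three-compartment equilibrium. ODEs (conserving total protein
exactly) are integrated with LSODA at rtol 1e-8 / atol 1e-15 M, sampled
on a log time grid, with early exit once within 1e-6 relative of the
target equilibrium; t_end defaults to 1e7 s because strong-dimer regimes
equilibrate exponentially slowly. Trajectories remain positive without
clipping in every regime exercised (initial states are interior
equilibria). Doubling Λ̃ rescales time exactly (t → t/2), which is tested
as an exact property.

Kinetic trapping: with K_D^dim far below ambient concentrations the
constitutive dimer is so stable on internal membranes that at 600 s
(≈ nuclear envelope breakdown) the internal-membrane fraction still
exceeds the plasma-membrane fraction, even though the post-step
equilibrium strongly favours the plasma membrane. `time_to_fraction`
quantifies the slowdown; it is monotone in dimer strength.

## SEC-MALS monomer–dimer model

For monomer weight W_m and dimer weight 2W_m, the weight-average MW
reduces to Mw = W_m(1 + f_d) with f_d the mass-action dimer mass
fraction, so Mw runs from W_m to 2W_m and depends on concentration only
through c/K_D^dim (exact scale collapse — K_D^dim and any concentration
scale factor are jointly unidentifiable from an Mw curve alone). W_m
defaults to 9.23474 kDa (the PAR-2 RING construct). Fits are unweighted
least squares in linear Mw space over log₁₀ K_D^dim. An optional global
`dilution_scale` maps input sample concentration to effective on-column
concentration; it defaults to fixed 1 because on-column dilution in the
published curves is unquantified, and the scale collapse means freeing it
requires external information.

## Cortex image quantification

Forward model for a straightened cortex (H = 50 cross-membrane pixels ×
L arc pixels): image[h,l] = c_cyt·s_cyt[h] + c_mem[l]·s_mem[h], with a
uniform cytoplasmic concentration per image. The profiles are initialised
to an error function (step ⊗ PSF) and a Gaussian (line ⊗ PSF), both
centred at H/2 with width 2 px, but are free to take any shape during
training. Training is two-step gradient descent on mean squared pixel
error (Adam, learning rate 0.005, convergence = relative loss change
< 1e-6 over 100 iterations): first s_cyt on cytoplasm-only images
(membrane term zero), then s_mem on polarized images with s_cyt frozen —
the along-arc membrane contrast plus the uniform-cytoplasm constraint
separates the two profiles, and training warns when that contrast is
absent. The model is bilinear, so the gradients are exact closed forms
and no autodiff framework is needed.

Scale degeneracy between profiles and concentrations is broken by fixing
the s_cyt interior plateau (mean of the 5 innermost pixels) to 1 and
max(s_mem) = 1, so concentrations read in raw intensity units.
Orientation: cross-membrane index 0 is extracellular; arc index 0 is the
anterior pole, wrapping so the posterior pole sits at L/2.

With profiles fixed, per-image quantification is linear least squares;
eliminating c_mem column-wise leaves a scalar normal equation for c_cyt,
solved exactly. A gradient-descent path is retained and agrees with the
closed form to 1e-6. Negative concentration estimates are reported, not
clipped.

Unit calibration uses an optogenetic recruitment pair: conservation of
T = C + ψcM before/after rapid membrane recruitment gives
c = (C−C′)/(ψ(M′−M)) (units of length). Polarity metrics: posterior
membrane mean over the 20% arc window centred on the posterior pole;
posterior M:C ratio; fraction at the PM = ψcM̄/(C+ψcM̄); the posterior-50%
variant; peak = best 20% circular window; and a per-pixel local M:C
profile with a circular rolling mean (default width 21 px — the smoothing
definition is a documented choice).

FRAP: the bleached-ROI series is divided by a control ROI (cancelling
drift exactly), then normalised so the designated postbleach frame
(default 1 s after bleaching, skipping the fast initial phase) is 0 and
the prebleach mean (10 frames) is 1.

## Synthetic data

Generators emulate: graded-RNAi rundown series (total protein log-uniform
over a 0.01–1 × 27 nM depletion range, 40 embryos, equilibrium forward
model, independent multiplicative lognormal noise per channel, default
CV 10%); cortex image sets (17 cytoplasm-only / 10 polarized by default,
logistic anterior-low/posterior-high membrane profiles, additive Gaussian
pixel noise, default 1% of the plateau); Mw curves; optogenetic pairs
(exactly pool-conserving); FRAP traces (single-exponential recovery,
0.0073 s⁻¹ reference rate). Noise magnitudes are not reported for the
real measurements; the defaults are chosen as plausible imaging-noise
levels so that recovery tests are meaningful. Noise is applied to
observations only; truth is returned alongside, and regeneration from the
same seed is bit-identical. Not emulated: embryo morphology, optics
beyond the profile model, RNAi biology, autofluorescence — so passing
tests demonstrate estimator correctness under the stated noise model, not
robustness to those real-data features.

## Problem sizes

Default analyses run in seconds on one CPU: equilibria are closed-form;
a 25 × 17 cooperativity landscape with 20-point sweeps is a single
vectorised evaluation; symmetry-breaking trajectories take ~50 ms each;
the end-to-end synthetic pipeline (simulate → train profiles → quantify →
score → fit) completes in under a minute at its default sizes. Test-suite
bootstrap and coverage experiments use hundreds of replicates and tens of
repetitions; the library defaults remain 10,000 replicates.
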