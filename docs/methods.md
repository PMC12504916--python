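# Methods

`p31quant` implements a resting-muscle ³¹P-MRS biomarker pipeline: synthetic
signal generation with known ground truth, 2D-CSI preprocessing, prior-knowledge
time-domain fitting, and the derivation of three biomarkers — intracellular pH,
free ionised magnesium, and the T1-corrected PDE/γ-ATP ratio — together with
fat-fraction-based staging of dystrophic muscles and cohort-level reporting.
This note records the models, the parameters that matter, and the choices made
where the design was genuinely open.

## Signal model

Every synthetic spectrum is a sum of Lorentzian-damped complex exponentials,

    s(t) = Σₖ Aₖ · exp(i(2π fₖ t + φ₀)) · exp(−π·lwₖ·t) + ε(t),

with circularly-symmetric complex Gaussian noise ε and a continuous
first-order phase ramp (degrees/ppm, pivot at the carrier) applied across the
spectrum, as produced by a receiver dead-time delay. Lineshapes are purely
Lorentzian, matching both the time-domain fitting model and the 20 Hz
Lorentzian apodisation used during preprocessing; Gaussian/Voigt broadening is
not modelled. The ppm convention is downfield-positive with PCr at 0 ppm;
1 ppm = 120.6 Hz at the default 7 T ³¹P carrier.

Default acquisition parameters: 2048 complex points at 4000 Hz bandwidth,
TR = 2 s, 45° excitation. Default resonances (shift ppm / FWHM Hz / relative
amplitude): PCr 0/10/1.0, γ-ATP −2.50/25/0.30, α-ATP −7.52/25/0.30,
β-ATP (from [Mg²⁺])/30/0.30, PDE +3.20/35/(ratio-dependent),
Pi_a (from pH)/15/0.10, Pi_b (from pH + 0.3)/15/0.02. Each ATP moiety is a
single Lorentzian; a multiplet structure is deliberately not modelled.

Two physical couplings carry the biomarkers:

* **pH → Pi shift.** The Pi resonance titrates between the H₂PO₄⁻ and
  HPO₄²⁻ limiting shifts (3.27 and 5.69 ppm from PCr, pK 6.75):
  `σ₁ = (3.27 + 5.69·r)/(1 + r)`, `r = 10^(pH − 6.75)`. The inverse map is
  `pH = 6.75 + log₁₀((3.27 − σ₁)/(σ₁ − 5.69))`, valid strictly inside
  (3.27, 5.69) ppm.
* **[Mg²⁺] → α−β ATP shift.** The observed α−β shift difference is the
  species-population-weighted mean over five ATP species (ATP, HATP, MgATP,
  MgHATP, Mg₂ATP), with populations given by formation constants and
  [H⁺] = 10^(−pH_wt). The model is strictly decreasing in [Mg²⁺], so the
  inverse is unique; it is solved by Newton iteration on the rational form
  (bisection fallback on [0, 10⁴] mM) with a cleared-denominator quadratic
  as an equivalent fast path — the two agree to better than 1e−8 mM.

The formation constants and limiting shifts are config *data*, not code.
The shipped default set (`p31quant/data/mg_atp_constants.yaml`) contains
physically representative synthetic values — free-ATP separation near
10.9 ppm, Mg-bound near 8.3 ppm, ATP predominantly Mg-complexed at resting
[Mg²⁺] — and is clearly labelled as not being a transcription of any specific
titration study. All magnesium results in the test suite are round-trip or
oracle checks that hold for any admissible constants set. The same applies to
the 7 T metabolite T1 table used for saturation correction
(`data/t1_31p_7t.yaml`): representative order-of-magnitude values (PCr and
PDE long, ATP short), source-tagged, replaceable. Because the generator
applies the same steady-state saturation weighting that the analysis removes,
round-trip results are exact for any positive T1 table.

## Two-pool Pi convention

The alkaline Pi component (Pi_b) is simulated at 20 % of the Pi_a amplitude
and one fixed step of +0.3 pH above it. These are generator conventions, not
literature claims: the real cohort's Pi_b parameters are unknown. The
weighted pH is the amplitude-weighted mean of the two pools' pH values, so
under the defaults pH_wt = pH_a + 0.05.

## Cohort generator

`make_cohort` draws per-(participant, muscle) ground truth from normal
distributions with the published baseline group medians and IQR-derived
spreads (σ = IQR/1.349), truncated to physiological ranges:

| group     | [Mg²⁺] median [IQR] mM | pH_wt | PDE/γ-ATP |
|-----------|------------------------|---------------|-----------|
| CTRL      | 0.72 [0.10]            | 7.05 [0.04]   | 0.37 [0.18] |
| BMD_pre   | 0.63 [0.16]            | 7.08 [0.05]   | 0.45 [0.33] |
| BMD_prog  | 0.62 [0.13]            | 7.07 [0.05]   | 0.46 [0.23] |

Per spectrum the generator additionally draws a zero-order phase
U(−30°, 30°), a first-order ramp U(−2, 2)°/ppm, and a single multiplicative
linewidth factor (log-normal, σ = 0.08) applied to *all* resonances — shim-
driven B₀ inhomogeneity broadens every line together. Noise is scaled so that
the PCr peak of the orthonormally-scaled magnitude spectrum divided by the
time-domain noise SD equals the SNR target (default 30).

What the generator does **not** emulate: baseline humps from immobile
phosphorus, ATP multiplet structure, B₀ inhomogeneity beyond a global width
factor, frequency drift within an acquisition, and voxel bleed from tissue
outside the nominal grid. Passing recovery tests therefore demonstrates
correctness of the estimation chain under the stated signal model, not
robustness to every artefact of real spectra.

## Preprocessing

Fixed order: Hann k-space filter → voxel reconstruction (optional half-voxel
grid shift via a k-space phase ramp) → SNR estimate and exclusion → automatic
phasing → 20 Hz Lorentzian apodisation + two-times zero-filling → PCr
referencing → alignment and averaging of multi-voxel muscles.

* **SNR** is the maximum of the orthonormal-FFT magnitude spectrum over the
  SD of the real+imaginary samples in the final 25 % of the *raw* FID. An
  orthonormal transform maps unit time-domain noise to unit spectral noise,
  so this equals the spectral peak-to-noise-floor ratio with the floor
  measured where no signal can contaminate it — the conservative choice.
  Spectra below SNR 10 are excluded (strict inequality; exactly 10 is kept).
* **Automatic phasing** minimises the ACME objective — Shannon entropy of
  the first derivative of the real part plus a scale-invariant penalty on
  negative intensity — from a coarse multi-start grid, then polishes the
  result using peak symmetry: for an isolated Lorentzian the complex
  integral over a symmetric window centred on the peak carries exactly the
  resonance phase (the dispersion part integrates out). Per-peak integral
  phases (after a local complex-affine baseline correction that removes the
  tails of distant peaks) are regressed against chemical shift on the
  circle, which settles the unwrapping branch; an iterative reweighted line
  fit down-weights anchors contaminated by overlap. The polish is accepted
  unless it worsens the ACME objective at branch scale (≥ 1.0), which marks
  a wrong unwrapping. On noiseless spectra both phase terms are recovered to
  ≲ 0.4°; under noise, residual errors of a few degrees remain and are
  absorbed by the fit's own phase parameters.
* **Referencing** translates the ppm axis so the parabolic-interpolated PCr
  maximum sits at 0 ppm. All downstream shift differences are taken between
  fitted centres (Pi − PCr, α − β), so residual referencing error cancels.
* **Alignment** shifts each spectrum by the sub-bin maximum of its
  magnitude cross-correlation with the highest-SNR member (ties → first
  index) and zero-order phases it onto that reference; members whose
  correlation maximum sits at the search-window edge are flagged
  `alignment_failure` and dropped from the mean.

## Time-domain fitting

Bounded nonlinear least squares (trust-region reflective, analytic Jacobian)
on the same Lorentzian model, fitted to the first 1024 points of the phased,
referenced, unapodised FID — all muscle resonances have fully decayed well
before that, and the trailing points carry only noise. Residuals of the
first L points are down-weighted by a quarter sine wave
w_i = sin(π(i+1)/(2L)), L = 12 by default (first point attenuated, never
zeroed), which de-emphasises broad baseline components; the broad-PDE re-fit
protocol uses L = 16 with both phase terms clamped and a freed, wide PDE
linewidth.

The default prior-knowledge file encodes, besides shift windows and
non-negative amplitudes:

* **One shared width parameter.** Every linewidth is a fixed ratio of the
  PCr width (γ/α-ATP 2.5×, β-ATP 3×, PDE 3.5×, Pi 1.5×), because shim-driven
  broadening is common-mode. This anchors the poorly-determined widths of
  weak broad peaks (PDE) to the high-SNR peaks and removes the noise-driven
  width collapse that otherwise biases weak-peak amplitudes at modest SNR.
* **Pinned PDE position.** The PDE band sits at a fixed +3.20 ppm offset
  from the fitted PCr position. Its position is not a biomarker, and leaving
  it free produces a positive selection bias in its fitted amplitude at
  SNR ≈ 30 (the fit latches onto noise-reinforced positions).
* **pH-coupled Pi_b.** The alkaline pool's position is slaved to the acid
  pool through the titration curve at +0.3 pH — the same two-pool convention
  the generator uses — leaving only its amplitude free. With a free
  separation parameter the two heavily-overlapping pools exchange amplitude
  at low SNR, biasing the weighted pH upward by more than its tolerance.

Starting values: shifts at window centres, width at the geometric mean of
its bounds, amplitudes inverted from magnitude-spectrum peak heights
(A ≈ height·(1 − e^(−π·lw·dt))), phases at zero. One jittered, seeded restart
on non-convergence; `converged` is reported honestly afterwards. A
structured-residual diagnostic flags peaks whose local residual energy
stands well above the spectrum-wide floor (this is how a broad PDE component
outside the shared-width model is detected and routed to the re-fit).

In the pipeline both phase terms float in the fit, absorbing the few-degree
residual errors of automatic phasing.

## Saturation correction

Amplitudes acquired at TR = 2 s ≪ T1 are rescaled by the steady-state factor
f = sinθ·(1−E)/(1−E·cosθ), E = exp(−TR/T1), before ratios are formed; equal
T1s cancel exactly. The corrected PDE/γ-ATP ratio is the membrane-turnover
marker.

## Staging

Fat fraction per slice is SI_fat/(SI_fat+SI_water)·100 %; per muscle, the
area-weighted mean over five slices. Muscles are staged by baseline fat
fraction: preserved (≤ 13.5 %), progressing (strictly between), end-stage
(≥ 81.5 %, excluded from biomarker analyses). The operating thresholds ship
as defaults; `derive_thresholds` re-derives them from longitudinal data as
the two roots of the lower prediction band (fit SE ⊕ residual SD) of a
progression-curve fit. The curve family follows from logistic fat-replacement
growth in time toward a 100 % ceiling: a muscle at baseline fraction x
advances to 100/(1 + e^(−k)·(100−x)/x) one follow-up interval later, so the
implied change-versus-baseline curve rises from zero at 0 %, peaks mid-range,
and returns to zero at 100 %. A plain 4-parameter logistic in baseline FF was
tried first and rejected: it is monotone, so its lower uncertainty band
almost never crosses zero twice, making threshold derivation ill-posed. The
fitted parameters are an amplitude (cohort heterogeneity), the growth rate k,
and an offset; the band is 1 SD.

## Reporting

Cohort summaries are median [IQR] per (category, metric), with quartiles by
linear interpolation between order statistics, plus pairwise Spearman rank
correlations (average ranks on ties, large-sample p-values). The pipeline
driver keeps an exclusion ledger — total, low-SNR, artefact, alignment
failure, non-convergence, end-stage — with retained + excluded = total at
every stage; per-item failures never abort a batch. Group inference (ANOVA,
mixed models) is intentionally left to standard statistical tooling on the
exported metrics table.

## Problem sizes and numerical settings

The recovery suite uses: noiseless single-spectrum round trips (machine
precision expected and achieved, ≲ 1e−6 relative); 100-replicate seeded
Monte-Carlo bias checks at SNR 30; and a 200-spectrum control cohort at
SNR 30 for end-to-end median recovery of [Mg²⁺] (±0.02 mM), weighted pH
(±0.01) and PDE/γ-ATP (±0.02). Optimiser tolerances are 1e−12 (ftol/xtol/
gtol); the magnesium inversion targets |residual| < 1e−10 ppm; the ACME
stage uses Nelder-Mead with a 30°×10°/ppm start grid. Degenerate inputs
(zero noise SD, both Pi amplitudes zero, missing PCr, constant correlation
input) raise explicit errors or QC flags rather than propagating silently.

## Known limitations

* The equilibrium-constant and T1 defaults are synthetic-representative;
  absolute magnesium values from real data require a citable constants set.
* The two-pool Pi model (fixed +0.3 pH offset, shared width) is a
  convention; cohorts whose alkaline pool behaves differently need a custom
  prior file, at the cost of the weighted-pH precision documented here.
* The shared-width prior assumes common-mode broadening; chemically
  heterogeneous width changes (e.g. selective PDE broadening) are only
  caught via the structured-residual flag and re-fit path.
* Automatic phasing is specified to ~2° on clean spectra only; noisy spectra
  rely on the fit's own phase parameters.
* CSI simulation covers k-space encoding and Hann filtering but not coil
  sensitivity profiles or through-slice effects.
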