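# Methods

## Signal model

A ³¹P spectrum is modelled on a ppm axis with phosphocreatine (PCr) at
0 ppm, axis strictly increasing, carrier at −8.3 ppm (on the NAD⁺ signal),
243 MHz spectrometer frequency (14.1 T), 12 kHz bandwidth and 4096 complex
points. Each metabolite is a spin system: one or more resonance groups, each
with a centre shift, a relative amplitude and explicit multiplet lines
(offset in Hz, weight summing to 1). A line is a unit-area pseudo-Voigt
η·L + (1−η)·G with a common nominal FWHM; η defaults to 1 (pure Lorentzian)
and is exposed per metabolite. The dispersion partner of each absorption
shape (closed form for the Lorentzian, Dawson function for the Gaussian) is
carried in the imaginary part with the sign that makes the inverse DFT of a
synthesized spectrum a forward-decaying FID, so the frequency-domain and
time-domain construction paths are exact inverses of each other — noise,
apodization and per-block drift/phase are applied in the time domain and
transformed back without approximation error between the two routes.

Basis spectra are normalized per unit concentration: a full metabolite
response integrates (real part, Hz units) to `nuclei_per_molecule × 1.0`.
A fitted amplitude therefore estimates concentration directly in the
generator's units, and reference scaling reduces to a per-nucleus signal
ratio.

The NAD⁺ signal is represented as a symmetric four-line pattern centred at
−8.30 ppm (two doublets separated by 60 Hz with a 20 Hz coupling), NADH as a
singlet at −8.13 ppm on the α-ATP (−7.60 ppm) shoulder, and UDPG as two
doublets near −9.8 and −11.5 ppm. These shift/coupling defaults, like the
rest of the spin-parameter file, are literature-style placeholders shipped
as editable JSON: every test derives its ground truth from the generator
itself, so no conclusion depends on the defaults being exactly right.

## Synthetic data

A synthetic spectrum is Σ cₘ·basisₘ plus a smooth baseline plus complex
Gaussian time-domain noise. The default concentration profile is an
illustrative mouse-brain-like set (PCr 3.3, each ATP site 2.8, NAD⁺ 0.28,
NADH 0.14 mM — redox ratio 2, total NAD 0.42 mM — with phosphoesters and a
broad membrane-phospholipid component); default linewidths put PCr at 13 Hz.
These are plausible study conditions, not measured values.

Noise is calibrated against the SNR convention *α-ATP real-part peak height
at −7.6 ppm over the real-part SD in the signal-free −20 to −25 ppm region*:
i.i.d. complex time noise of per-component SD σ_t transforms to white
frequency noise of real-part SD σ_t·√N, so σ_t = height/(SNR·√N). The
realized SNR of a replicate then matches the target in expectation (the
small positive bias from taking a windowed maximum is below the 10%
calibration tolerance the tests assert).

The baseline emulates short-T₂* background: broad Lorentzian humps with a
200 Hz minimum width enforced by the model. The default places a gentle
2500 Hz-wide hump (height 0.012, about 20% of the α-ATP peak) under the fit
region and a second hump outside it. Width matters: a much sharper hump
(≲1000 Hz over the 8 ppm fit window) cannot be represented by the low-order
background polynomial, and its estimation error rivals the broad, shallow
NAD⁺ quartet — the subtract-then-fit route then underestimates NAD⁺ at
every SNR, far in excess of the behaviour this class of fitters shows in
practice. The default was chosen so that baseline handling perturbs, but
does not dominate, NAD quantification; the harsher regime remains one
`BaselineModel` away for anyone studying baseline-driven failure modes.

Block series replicate the acquisition scheme of many short blocks: each
block is the same noiseless FID with an independent Gaussian frequency
offset (drift) and zero-order phase offset, plus independent noise scaled so
the corrected *sum* reaches the target SNR. True offsets are stored in the
series so correction accuracy is testable against ground truth.

What the generator does **not** emulate: respiration/motion artifacts,
eddy-current lineshape distortion, frequency-dependent excitation profiles,
J-evolution/strong coupling, T₁ saturation differences. Passing tests
therefore demonstrate correctness of the processing chain under ideal
pseudo-Voigt statistics, not robustness to every in vivo artifact.

## Preprocessing

Apodization multiplies the FID by exp(−π·b·t) (b = 10 Hz by default before
quantification), adding exactly b Hz of Lorentzian width; the t = 0 sample
is untouched. Drift correction aligns each block to the first usable block's
reference-peak position (sub-bin, by parabolic interpolation of the
magnitude peak, applied as time-domain modulation); zero-order phase is set
from the complex value at the aligned peak, maximizing the real-part height;
blocks whose reference peak falls below a 3×noise floor are excluded with a
warning. Linewidth is measured as interpolated half-height width with a
parabolic apex refinement (without it, the half-bin centre offset biases a
13 Hz line to ≈13.7 Hz on a 2.93 Hz grid); estimates never fall below one
grid bin.

Baseline estimation is an iteratively reweighted Legendre-polynomial fit
(order 4) with an asymmetric truncated-quadratic cost: residuals more than
4 robust SDs *above* the curve get zero weight, everything else quadratic,
so narrow positive peaks cannot pull the curve up while the smooth
background anchors it. Two numerical choices matter. First, the robust noise
scale comes from the median absolute first difference (÷√2), not from the
raw residual MAD, which background misfit inflates. Second, the default
estimation window is (−15.5, −3) ppm — the −6 to −14 ppm fit region plus
signal-free anchor stretches on both sides, excluding β-ATP: fitted only
over the fit region, the polynomial is unconstrained beneath the
α-ATP/NAD/UDPG cluster and absorbs part of the broad NAD⁺ quartet.
Iteration stops when the clipped set stabilizes (≤50 passes; a
non-converged loop warns and returns the last iterate).

## Linear-combination fitting and uncertainty

The fitter minimizes the squared real-part residual over the region of
interest with `scipy.optimize.least_squares` (trust-region reflective),
three parameters per component — amplitude ≥ 0, shift offset within
±0.1 ppm, linewidth scale within [0.5, 5] — and optionally a joint Legendre
baseline. Starting amplitudes come from non-negative linear least squares at
nominal shift and width, so a model-matched noiseless fit starts at the
exact solution and the procedure is deterministic. The linewidth-scale upper
bound of 5 (rather than a tighter 2) is deliberate: the linewidth sweep
fits data broadened by up to 30 Hz plus 10 Hz apodization against a fixed
basis, which demands scales around 2.3. Components whose nominal responses
are indistinguishable in the region (|cosine| > 0.99999) raise a singular-
design error rather than returning an arbitrary split.

CRLB% is 100·σ·√[(JᵀJ)⁻¹]ₐₐ/a with σ the −20 to −25 ppm real-part SD and J
the Jacobian at the solution — a white-Gaussian bound that the tests verify
against Monte Carlo scatter within a factor 1.5. The 30% exclusion cutoff is
inclusive (exactly 30% is retained). Reference scaling uses
cₘ = sₘ/s_ref · c_ref · n_ref/nₘ on per-molecule signal amplitudes
s = amplitude × nuclei, logged explicitly; phantom mode references 9.57 mM
internal Pi, external mode a supplied PCr concentration. Derived indices:
RR, tNAD, PME, PDE, PME/PDE and ATP as the mean of the α- and γ-ATP values;
missing inputs yield absent fields and a zero NADH makes RR a hard error.

## Monte Carlo framework

Default grids: SNR 10–100 in steps of 10 at 13 Hz PCr linewidth, and 7
linewidth conditions in +5 Hz increments at SNR 30; 100 replicates per
condition. Data spectra contain all 14 metabolites plus the baseline; the
fit uses α-ATP, NAD⁺, NADH and UDPG over −6 to −14 ppm against a fixed
basis whose widths are the nominal table plus the 10 Hz apodization, in one
of two variants — subtract-then-fit (default) or joint polynomial baseline —
as the package's two-method comparison. Replicate seeds derive from
`SeedSequence([master, condition_index, replicate_index])`, so any single
replicate reproduces in isolation and a fixed master seed makes the whole
summary bit-identical. RSD uses the sample mean in the denominator (the
ambiguous alternative, truth in the denominator, is covered by the separate
bias column); replicates with zero NADH are excluded from RR with a log
entry, and conditions with >10% fit failures are flagged.

Under the default conditions the sweep reproduces the expected orderings:
RSD falls with SNR for NAD⁺, NADH, RR and tNAD (roughly 11→4% for NAD⁺ over
SNR 30→100 at 50 replicates); NADH is less precise than NAD⁺ (half the
concentration, nearer to α-ATP); widening lines degrades NADH and RR more
than tNAD, whose anticorrelated component errors partially cancel. The
acceptance-style tests assert these orderings at 50 replicates — the printed
RSD magnitudes depend on the chosen concentrations, linewidths and baseline
and are reported, not asserted.

## Physiology

pH and free Mg²⁺ are closed forms of chemical-shift differences:
pH = 6.73 + log₁₀[(δ_Pi − 3.275)/(5.685 − δ_Pi)] with δ_Pi the positive
Pi−PCr separation in ppm (the convention consistent with the constants'
bracket), valid on (3.275, 5.685); and pMg = 4.24 −
log₁₀[(δ + 18.58)^0.42/(−15.74 − δ)^0.84], [Mg²⁺] = 10^(−pMg), for the
β-ATP−PCr difference δ on (−18.58, −15.74). Out-of-domain shifts raise
errors rather than clamping — a clamped value would fabricate physiology.
Both relations are strictly monotone on their domains (property-tested), and
the identities pH(midpoint) = pKa and pMg(unit-log-argument root) = 4.24
serve as analytic anchors.

## Statistics

One-way fixed-factor ANOVA (scipy's omnibus F) with a linear-trend posttest:
a contrast L = Σcᵢȳᵢ on ordered group means with centred scores — equally
spaced by default, actual postnatal-day spacing by option, since either is a
defensible reading of a standard trend posttest — tested against the pooled
within-group mean square with a t statistic on the within-group degrees of
freedom, plus an ordinary regression slope along age. Pairwise comparisons
are pooled-variance t tests with Bonferroni adjustment
min(1, p·#pairs). Correlations are Pearson (rank correlation available),
reported as r, R² and the t-transform p, with pairwise deletion and
undefined (not zero) cells for constant columns. Groups with fewer than two
observations are an error naming the group. The linear-mixed-model covariate
check is out of scope; the API accepts covariate columns but does not model
them.

The developmental-table generator draws per-animal values around group means
chosen to emulate a maturation trajectory — NADH falling 0.194→0.043 mM with
a stable NAD⁺ pool (so the redox ratio rises ≈2→9), PME falling, PDE rising,
pH falling, free Mg²⁺ rising, with cohort sizes 10/9/8/5 — for exercising
the statistics stage against known effects.

## Problem sizes and defaults used in checks

Analytic identities run at trivial size (<1 s). Model-match recovery fits
all 14 components over the full bandwidth of one noiseless 4096-point
spectrum. The precision-ordering checks use 50 replicates per condition with
SNR {30, 100} and the 7-step linewidth grid — sizes at which the asserted
orderings exceed three joint standard errors of the RSD estimates while the
whole suite stays quick on one CPU.

## Known limitations

* Pseudo-Voigt multiplets with fixed line patterns; no density-matrix
  evolution, so field-dependent strong-coupling effects are absent.
* The subtract-then-fit route inherits the documented pathology of
  background estimation under broad shallow signals: with sharper baselines
  than the default it systematically underestimates NAD⁺, increasingly so at
  low SNR.
* CRLB assumes white Gaussian frequency-domain noise; after apodization the
  noise is mildly correlated and the bound is approximate.
* Reference scaling against PCr requires PCr in the fitted region; the
  −6 to −14 ppm regional fit therefore reports generator-unit amplitudes
  unless combined with a full-bandwidth fit.
* First-order phase, eddy currents and vendor file formats are out of scope.
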