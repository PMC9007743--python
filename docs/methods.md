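# Methods

## What the package models

Time-resolved native mass spectrometry can follow an entire signalling
cascade in one experiment when the states of interest differ in mass:
rhodopsin (rho) versus its apo-form opsin (Δ 266 Da, the retinylidene
Schiff-base shift), transducin with and without GDP (Δ 443 Da), and the PDE6
tetramer with and without cGMP (Δ 345 Da).  The package implements the
computational chain for such an experiment — per-scan text exports are
quantified into relative-abundance traces by windowed charge-state
integration, the traces are fitted with a kinetic model of the photocycle,
and downstream G-protein/PDE6 and lipid observables are extracted — plus a
synthetic instrument that stands in for the spectrometer so every stage is
testable without raw data.

## Mass conventions

Intact-protein species use **average** neutral masses; the charge carrier is
a proton at 1.00728 Da (average).  Ligand shifts are computed from molecular
formulas at import time (pyteomics): retinylidene +266.42 Da average
(+266.2034 monoisotopic, used for the lipid-region analyses where peaks are
isotope-width), GDP +443.20, cGMP +345.21, GTPγS +539.25.  The electrospray
relation is m/z = (M + z·1.00728)/z.  Lipids are treated in negative mode as
[M−H]⁻ with monoisotopic masses; PE/PC masses derive from the diacyl
elemental composition of the summed chain notation (e.g. PE 18:0/18:1 →
C41H80NO8P, 745.5622 Da).

## Quantification

For each declared species an integration window (half-width
max(2 Th, 1.2 × peak FWHM)) is laid at every charge-state position and the
intensity is integrated by trapezoid on the native grid.  Two numerical
choices matter:

* **Exact window edges.**  Window boundaries are interpolated into the grid
  before integration; otherwise the integral jitters by ~10⁻⁵ (relative)
  with the accidental alignment of window edge and grid, which is the
  difference between recovering noiseless fixtures at 10⁻⁸ and 10⁻⁵.
* **Flat background subtraction.**  The median intensity outside all windows
  is subtracted per unit width.  Spectra sit on a noise floor; integrating
  it inflates weak species (the decayed rho tail late in a run), which
  biases fitted rates upward by tens of percent at 1% noise.  With
  subtraction, abundance errors at 1% noise stay below ~0.6% absolute.

Where two species' windows overlap (unavoidable for Δ266 at high charge),
the shared intensity is split point-wise in proportion to the species' model
Gaussian profiles; the profile amplitudes are refined from the integrals
themselves over three fixed-point passes, which removes most of the bias the
unit-amplitude split has for unequal mixtures.  Ratios report a denominator
below 0.1% of the combined intensity as an absent species (inf), because
peak-tail bleed between windows ~3σ apart sits at that scale.

The zero-charge projection is a direct comb sum — score(M) = Σ_z I((M +
z·1.00728)/z) — used for mass assignment only.  It inherits the harmonic
artifacts of comb methods (a species also scores at mismatched-charge
images) and is not a Bayesian deconvolution; peak calling is a local-maximum
scan above a relative threshold.  On noiseless envelopes the mass estimate
is good to the grid step.

## Photocycle model

State vector (populations normalized to total rhodopsin at t = 0): ground
state R_c (cis-retinylidene), photoactivated R_t (trans-retinylidene,
isobaric with R_c), opsin, free all-trans-retinal, free cis-retinal, free
PE, the N-ret-PE conjugate, and a cumulative retinal-oxime sink.  Mass
action throughout; illumination I(t) is binary, built from pulse intervals,
and intensity dependence is folded into the photochemical rates (the
experiment varies exposure time, not flux).  Hydroxylamine concentration is
constant (5 mM ≫ protein).  Regeneration (cis-retinal + opsin) and
conjugation are pseudo-first-order in pooled concentrations; true
bimolecular kinetics in the membrane are not identifiable from these data.
The solver (LSODA, rtol 1e-10) splits integration at light on/off switches
so the right-hand side is smooth per sub-interval; protein and retinal
totals are conserved to <1e-8 relative.

The observables are what the spectrometer sees: mass-rho = R_c + R_t (the
photoproduct is mass-silent until hydrolysis) and opsin.

### Effective rate

`fit_effective` fits R(t) = R_inf + (R_0 − R_inf)·e^(−k·t) by weighted least
squares and reports k as the overall hydrolysis rate: under continuous light
isomerization is much faster than hydrolysis, so the observed rho decay
relaxes at the slow hydrolysis step.  Traces that are flat within noise, or
shorter than 5 points, raise an identifiability error rather than returning
a number.

### Hydroxylamine decomposition

Hydroxylamine cleaves the Schiff base of the *photoactivated* state only, so
the treated rho trace tracks R_c and decays at the isomerization rate k_iso,
while the untreated trace is R_c + R_t.  Subtracting the curves yields the
rho* population, whose balance (formation k_iso·R_c, decay k'_hyd·R_t) is
fitted for the pure hydrolysis rate.

Cleavage is fast but finite: at k_ox·[NH2OH] = 2 s⁻¹ and k_iso = 0.2 s⁻¹ the
treated condition itself carries a quasi-steady rho* of ≈10% of R_c.  Naive
subtraction therefore underestimates rho* and biases k'_hyd by ~28% — far
outside the target accuracy.  The treated decay is instead fitted as a
two-exponential a·e^(−kt) + b·e^(−μt) + c by variable projection (amplitudes
solved linearly for each (k, μ), multistart over the rate separation),
which identifies both k_iso (slow component) and the treated rho* term
−b·(e^(−kt) − e^(−μt)); the latter is added back to the subtraction.  The
R_t balance is then solved in closed form against the fitted forcing, making
the k'_hyd fit exact on noiseless data.  When the fast component is not
identifiable the fit falls back to a single exponential with zero
correction, which is the instant-cleavage limit.  Recovery through the full
spectral pipeline: <0.1% noiseless, ~1–2% median at 1% instrument noise for
both rates.

`compare_conditions` turns per-condition (rate, stderr) pairs into
fold-changes versus a control with propagated relative uncertainty and
classifies accelerator/decelerator/neutral at 2σ by default.

## Downstream cascade

The transducin/PDE6 layer is deliberately minimal: rho*-driven nucleotide
release (G_t•GDP → apo-G_t), GTP-gated dissociation into Gα•GTP + Gβγ, GTP
hydrolysis on Gα (zero for the GTPγS analogue), recombination to G_t•GDP,
1:1 Gα binding to PDE6, and hydrolysis of the single occupied cGMP site in
the activated complex.  The asymmetric stoichiometry (one Gα, at most one
cGMP per tetramer) is hard-coded to the observed complexes; 1:2 complexes
do not exist in the model.  Coupling to the photocycle is one-way (rho* is
an external drive).  Integration uses sub-stepped explicit Euler with the
sub-step bounded so no pool loses more than 20% per step — positivity
without clipping, conservation exact to rounding.

No rate constants for this layer are identifiable from the quantified
ratios alone, so cascade parameters and pools are **fixture values** chosen
to express the qualitative pattern: the GTPγS condition is strictly
single-turnover (Gα parks on PDE6), the supplementary-GTP condition has a
larger recyclable GTP pool (supplementary nucleotide on top of endogenous),
and Gα is sub-stoichiometric to PDE6 so the single-turnover condition
plateaus at an intermediate occupancy.  This reproduces the ordering
occupancy(+GTP) < occupancy(GTPγS) < occupancy(endogenous) < dark, and
GTP-dependent replenishment of G_t•GDP, without claiming quantitative rates.

## Lipid analyses

N-ret-PE identification is pure mass arithmetic: conjugate mass = PE mass +
266.2034 Da, identical for every PE (a property test).  Conjugated:free
ratios and the PC unsaturated:saturated ratio are AUC window integrals on
[M−H]⁻ peaks (window half-width: the larger of the ppm tolerance, default
10 ppm, and ±3σ of the expected peak), with the spectrum-median background
subtracted — lipid spectra are sparse, so the median is a robust floor.
Retinal cis/trans isomers of the conjugate are isobaric and not
distinguished.

## Synthetic instrument

Charge envelopes are discretized Gaussians over the declared integer
charges (mean/spread per species); each charge's peak is a unit-area
Gaussian scaled by population × envelope weight, so integrated intensity is
linear in population and noiseless quantification is exact by construction.
Additive Gaussian noise and a flat baseline are both scaled to the tallest
rendered peak; the default baseline of 5 noise SD keeps the non-negativity
clip from truncating the noise distribution (an un-truncated floor is what
the background subtraction assumes).  Optional unresolved-adduct tails move
a fraction of each peak's area to a +Δm/z satellite.  Randomness comes from
`numpy.random.default_rng(seed)` (PCG64); seeds are mandatory — requesting
noise without an RNG raises.

What the generator does **not** emulate: isotope structure, detector
saturation, m/z-dependent transmission, chemical noise with structure,
space-charge effects, peak-shape asymmetry.  Passing tests therefore
demonstrate correctness of the analysis chain under a well-behaved
instrument model, not robustness to every artifact of real spectra.

## Study conditions and problem sizes

Defaults are chosen once as the package's study conditions: dark-adapted
composition 73% rho / 27% opsin; k_iso = 0.2 s⁻¹, k'_hyd = 0.02 s⁻¹ for the
decomposition experiments (k'_hyd = 0.00385 s⁻¹ = ln2/180 in the shipped
default config, putting the half-conversion on the minutes scale);
k_ox·[NH2OH] = 2 s⁻¹; instrument noise 1% of the tallest peak; scans every
2 s over 0–120 s for the fast decomposition runs and every 20 s over
0–1200 s for the slow conversion run; 50 random draws for quantification
accuracy, 20 for zero-charge accuracy, 20–50 noise seeds for recovery
medians.  Fixture masses (rho 39 965 Da, G_t 85 kDa, PDE6 215 kDa) are
order-of-magnitude placeholders that put envelopes in the m/z 4000–8000
window; all are configurable.

## Known limitations

* The effective single-exponential rate is a presentation-level summary; it
  approximates the slow hydrolysis step and is biased when regeneration or
  strong early transients are present (use the decomposition then).
* The overlap split assumes symmetric peaks of similar width; heavily
  interleaved envelopes (window separation ≲ 1 FWHM) should be avoided by
  choosing charge ranges, as the PDE6 fixtures do.
* Zero-charge harmonics can out-score the true mass if the assumed charge
  range is badly wrong.
* Meta-rhodopsin substates, phosphorylation kinetics, arrestin termination
  and channel closure are out of scope; temperature and pH dependence of
  rates are not modelled.
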