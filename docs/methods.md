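# Methods

This note documents the models implemented in `thtbind`, the assumptions
behind them, the synthetic-data generator that defines the package's study
conditions, and the numerical choices that a maintainer would want spelled
out.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Equilibrium microdialysis and mass balance

The device has two chambers of equal volume separated by a membrane that
passes the dye freely and retains fibrils.  At equilibrium the free-dye
concentration C_f is identical in both chambers, so with C₀ the total dye
loaded (expressed per chamber volume) the bound concentration is

    C_b = C₀ − 2·C_f .

Assumptions: equal chamber volumes (a `volume_ratio` manifest override
generalizes `bound_conc` to asymmetric devices), no dye adsorption to the
membrane, and full equilibration.  `BindingPoint` enforces the balance to
1 nM at construction; the synthetic generator satisfies it to root-finder
precision (~10⁻²⁰ M, checked by `mass_balance_residuals`).

C_f is read from the reference chamber's 412 nm absorbance with
ε₄₁₂ = 31,600 M⁻¹cm⁻¹ (free-ThT extinction maximum); fibril concentrations
are monomer-equivalent molar (ε₂₈₀ = 1490 M⁻¹cm⁻¹ for the Aβ peptides).
All internal units are molar, nm and ns; manifests declare concentrations
in molar to avoid silent µM/M factors.

## Spectral preprocessing

**Scatter.** Fibril light scattering follows a power law A_sc(λ) = a·λ⁻ᵐ
(0 ≤ m ≤ 6; m ≈ 4 in the Rayleigh limit, smaller for large aggregates).
It is fitted by linear least squares in log A vs log λ over a dye-free
window, default 550–650 nm — chosen because neither free ThT (max 412 nm)
nor the red-shifted bound bands (~450–460 nm) absorb there — and
extrapolated under the dye bands.  The fit stores its regression geometry
so the *prediction* uncertainty of the extrapolated baseline (the standard
leverage formula on the log scale) can be propagated; this matters because
an extrapolation over ~150 nm amplifies window noise into a smooth
systematic error under the bands.

**Bound-dye spectrum.** D(λ) = sample − A_sc − reference on a common grid.
Negative dips within 3σ of the total pointwise uncertainty (photometric
noise, estimated as 1.4826·MAD of D over 650–700 nm, combined in quadrature
with the scatter-extrapolation sigma) are clipped to zero; a contiguous dip
deeper than 5σ spanning ≥ 10 nm raises a mispaired-chambers error.  Both
the fibril-only tail and the sample tail can serve as the scatter source —
`fit_scatter` accepts either spectrum.

**Inner filter.** The primary inner-filter correction uses the standard
cuvette-center form F_corr = F·A·ln10/(1 − 10⁻ᴬ) with A the *total*
absorbance at the 440 nm excitation wavelength (dye bands plus scatter).
The form is continuous at A = 0 and grows as A·ln10 for dense samples.
Secondary (emission re-absorption) correction is out of scope; instrument
geometry factors beyond the standard form are not modelled.

## Binding model, fitting and mode selection

The isotherm is a sum of independent Langmuir site classes,
C_b = C_p·Σ nᵢK_bᵢC_f/(1+K_bᵢC_f), with n per protein monomer.  Fits run in
(log K_b, log n) (positivity by construction) with scipy's trust-region
reflective least squares, tolerances 10⁻¹⁴ and a capped evaluation budget;
runs that exhaust the budget at those tolerances are kept as multistart
candidates.  Starting values come from the Scatchard linearization
(slope → −K_b, intercept → K_b n C_p), split into low-C_f/high-C_f halves
for two modes; 10 restarts (6 in the Monte-Carlo studies) perturb the start
by up to half a decade, with ties broken by lowest RSS then lowest leading
K_b.  Modes are reported sorted by descending K_b, and since the
association constant (M⁻¹) and the affinity (its reciprocal, M) are both in
common use, both are printed.

**Weighting.**  Unit weights are the constructor default.  The validation
studies and the pipeline use `weights="relative"` (1/C_b²), matched to the
multiplicative measurement noise of the study conditions: with unit weights
the low-concentration points that carry the high-affinity mode's signal
contribute almost nothing to the objective, and two-mode detection degrades
noticeably (≈83% vs 100% detection in the package's own selection study).

**Model selection.**  Two modes are accepted only when all three hold:
AICc₂ < AICc₁ − 2 (AICc with the residual variance counted as a
parameter), the quadratic-vs-linear F-test on the Scatchard plot rejects
linearity at α = 0.05 (statsmodels OLS, `compare_f_test`), and the two-mode
optimum is not degenerate (K_b1/K_b2 ≥ 3).  The conjunction guards against
over-fitting a second class to one-mode data; the acceptance rate of the
linearity test on true one-mode data sits at its nominal 95% by
construction.  Bootstrap CIs are case-resampling percentiles (B ≥ 200,
seeded, resamples that collapse to fewer distinct C_f values than
parameters are redrawn-by-skip); coverage of the true K_b is checked in the
suite.  The upper CI bound of a nearly saturated high-affinity mode is
honestly wide — the data bound such a K_b from below but hardly from above.

A detected second mode is surfaced in the pipeline report as
`clustering_associated_second_mode`: a site class with ~100× higher binding
constant and ~100× fewer sites is the fingerprint of dye immobilized in
fibrillar clots rather than in the ordinary groove.

## Photophysics

**Anisotropy.** r = (I_VV − G·I_HV)/(I_VV + 2G·I_HV), G = I_VH/I_HH;
invariant under common intensity scaling.

**Quantum yield.** Relative method against an ATTO-425-like standard
(q_ref = 0.9, spectrally similar to ThT): q = q_ref·(S/S_ref)·(A_ref/A)
with S inner-filter-corrected emission integrals (trapezoid over ≥ 455 nm,
excitation at 440 nm) and A absorbances at 440 nm.  For bound dye, A comes
from the difference spectrum and S from sample−reference emission.  Same
solvent throughout, so no refractive-index term.  q > 1.05 raises (the
upstream decomposition must be wrong); q ∈ (1, 1.05] clips with a warning.

**Lifetimes.** Iterative reconvolution: M(t) = IRF(t−δ) ⊛ Σ αᵢe^(−t/τᵢ)
as a discrete convolution on the recorded (uniform) bin grid, with a fitted
sub-bin IRF shift δ (linear interpolation of the IRF), Poisson weights
σ² = max(counts, 1), and the same trust-region optimizer.  The fit window
starts just before the IRF rise (first bin above 10⁻³ of the IRF peak):
empty pre-trigger bins carry no information and would deflate the reduced
χ².  Reported diagnostics: reduced χ² (warning above 2; values near 1 are
expected at proper weighting), AICc on the χ² surrogate for choosing the
component count, and both amplitude-weighted (Σατ/Σα, the default) and
intensity-weighted (Σατ²/Σατ) mean lifetimes, since conventions differ and
the intensity-weighted mean is always the larger.

## Denaturation series

GdnHCl concentrations are verified by refractive-index increment with the
standard calibration polynomial c = 57.147·Δn + 38.68·Δn² − 91.60·Δn³
(valid to ≈6 M); the inverse is solved by bracketed root finding.

Free-ThT emission itself rises ≈3-fold between 0 and 6 M GdnHCl, so the
bound-dye profile must be built from per-concentration microdialysis pairs:
bound_F(c) = IFC(sample emission) − IFC(reference emission), each corrected
with its own chamber's A(440), normalized to the 0 M point.  The dye-only
enhancement curve e(c) (normalized to e(0) = 1, monotone PCHIP; isotonic
regression first if the raw curve decreases beyond noise) is carried in the
series for reporting and for workflows where reference spectra exist only
at 0 M.

**Transition analysis.** The profile is fitted with a logistic anchored at
the normalization point, F(c) = b + (1−b)·g(c)/g(0) with g decreasing; the
reported c_half is the logistic midpoint.  The early-decay flag refits the
*main* transition with the interior of the early window (0 < c ≤ 1 M)
excluded and the midpoint constrained beyond it — otherwise a fast
clot-disassembly phase is silently absorbed into sigmoid broadening — and
flags when any early point falls more than 0.25 (normalized units) below
that reference curve.  When flagged, the reported midpoint is the main
transition's.  Turbidity (apparent absorbance, default 450 nm) and RLS
(excitation = emission) are normalized to 0 M; per-sample normalization
throughout.  Thermodynamic m-value/ΔG extraction is deliberately out of
scope: the data are degradation profiles, not reversible two-state
unfolding curves.

## Fibril-fragment bookkeeping

Fragments are stacks: `layers × symmetry` subunits (C3 × 12 = 36 for the
Aβ40 model derived from the brain-seeded 2M4J polymorph; C2 × 12 = 24 for
the Aβ42 model from 2NAO).  Formal charges use integer fixed-pKa rules —
Arg/Lys/N-terminus +1, Asp/Glu/C-terminus −1, His neutral at pH 7.4
(protonated below pH 6) — giving −3 per Aβ subunit at pH 7.4 and hence
−108/−72 per fragment.  The printed totals are integer multiples of the
subunit charge, which is why the integer rule set is the default; a
Henderson–Hasselbalch fractional mode exists behind a flag for pH values
off the plateaus.  Strand annotations are the deposited structures' printed
β-regions (three for 2M4J-like, five for 2NAO-like), validated against the
peptide length.  No coordinates are built or parsed; `source_structure` is
metadata.

## The synthetic-data generator and its study conditions

`GeneratorTruth` defaults define the baseline experiment:

| parameter | default | rationale |
|---|---|---|
| binding modes | K_b = 10⁴ M⁻¹, n = 0.05 | ordinary groove mode, affinity ~10⁻⁴ M |
| two-mode variant | + K_b = 10⁶ M⁻¹, n = 5×10⁻⁴ | clustering contrasts: 100× up in K_b, 100× down in n |
| C_p | 1.15×10⁻⁴ M | 0.5 mg/mL of a ~4.3 kDa peptide |
| C₀ series | 12 points, log-spaced 2–80 µM | titration around the ~32 µM working point |
| free band | log-normal, peak 412 nm, ε 31,600 | free-ThT absorption |
| bound bands | 450 nm (mode 1); 460 nm, broader (mode 2) | red shift on binding; superposed bands broaden the two-mode spectrum |
| scatter | a = 2.5×10⁸, m = 3.5 | ~0.06–0.18 A across the dye region |
| spectral noise | σ = 2×10⁻⁴ A | scan-averaged double-beam instrument |
| decay | τ = 2.0 ns (2-exp variant 0.5/3.0 ns, α 0.7/0.3), Gaussian IRF σ = 0.15 ns centred at 2 ns, 1024 bins over 12.8 ns | typical bound-ThT TCSPC settings |
| quantum yields | bound 0.44, free 10⁻⁴, standard 0.9 | molecular-rotor contrast |
| denaturation | logistic collapse, c_half = 2.0 M, width 0.4 M; free-dye enhancement linear to 3× at 6 M; 0–6 M in 0.5 M steps, 3% noise on the bound signal | observed degradation and enhancement scales |
| two-phase variant | fast phase: midpoint 0.3 M, width 0.1 M, fraction 0.6 | a dramatic sub-molar clot collapse; clot sites carry a disproportionate share of fluorescence because of their higher quantum yield |

Band shapes are log-normal in wavelength (mildly asymmetric, like real dye
bands).  Decay expectations use the analytic exponentially-modified-Gaussian
convolution (`scipy.stats.exponnorm`), against which the reconvolution
fitter's independent discrete convolution is tested; histograms are Poisson
draws, as are the IRF counts.  All randomness flows from one recorded seed
(written into every manifest); regeneration is bit-identical, and the
pipeline is a pure function of (inputs, config, seed).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: wavelength-dependent instrument response and
baseline drift, correlated (non-white) spectral noise, membrane adsorption
or incomplete dialysis equilibration, fibril sedimentation during
acquisition, dye photobleaching, IRF afterpulsing/colour shift, and any
kinetics (all models here are equilibrium or steady-state).  End-to-end
recovery of a *weak* second mode from spectra alone is also noise-limited
in a way the direct-concentration studies are not: with photometric noise
σ = 2×10⁻⁴ the mode-2 signal (≲6×10⁻⁸ M of bound dye) is near the
detection floor of C_b = C₀ − 2C_f, which is why the selection studies
inject noise at the concentration level, emulating replicate-averaged
concentration estimates.

## Problem sizes

The validation studies run at the sizes the package documents: 200 seeds
for one-mode recovery, 100 per truth for mode selection, 50 (1-exp) and 25
(2-exp) for lifetimes, 50 per scenario for denaturation, 200 random
equilibria for the mass-balance check.  The full suite runs in about a
minute; `scripts/acceptance.py` in about half a minute.

## Known limitations

* Only 1- or 2-mode isotherms are fitted (3+ classes are not identifiable
  from 12-point titrations); no cooperative (Hill) models.
* The bootstrap treats titration points as exchangeable cases; it does not
  model the shared C_f error induced by a common extinction coefficient.
* The decay model has no baseline/afterglow term and fits a single curve
  (no global linked-τ analysis).
* The early-decay flag is a deviation detector, not a fitted two-phase
  mechanistic model — the underlying process is interpreted, not
  parameterized.
* The refractive-index calibration coefficients are a literature standard
  shipped as config; instruments should be checked against their own
  calibration.
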