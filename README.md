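# thtbind

Quantitative analysis of thioflavin-T (ThT) binding to amyloid fibrils from
equilibrium-microdialysis spectroscopy.

ThT is the standard fluorescent probe for amyloid: it is a molecular rotor
whose quantum yield jumps by orders of magnitude when intramolecular
twisting is blocked on binding to the cross-β groove of a fibril.  Measuring
*how* it binds — how many classes of sites, with what association constants
and stoichiometries — is confounded by the fact that any stained sample is
an equilibrium mixture of free and bound dye.  Equilibrium microdialysis
resolves this: two chambers separated by a dye-permeable, fibril-impermeable
membrane equilibrate so that the reference chamber holds only free dye at
concentration C_f, and the fibril chamber holds the same C_f plus the bound
dye.  With total loaded dye C₀, mass balance over the two equal chambers
gives

    C_b = C₀ − 2·C_f ,

and the bound-dye absorption spectrum is the sample−reference difference
after removing the fibrils' power-law light scattering A_sc(λ) = a·λ⁻ᵐ.

Binding is modelled as independent site classes ("modes"), each with an
association constant K_b (M⁻¹) and n sites per protein monomer:

    C_b(C_f) = C_p · Σᵢ nᵢ K_bᵢ C_f / (1 + K_bᵢ C_f) .

The Scatchard transform C_b/C_f vs C_b is affine for one mode (slope −K_b,
abscissa intercept n·C_p); curvature signals a second site class, which for
Aβ-type fibrils is the signature of dye trapped in fibrillar clots.  The
package fits one- and two-mode models by trust-region least squares in
(log K_b, log n), selects the mode count with a corrected-AIC margin plus an
F-test of Scatchard linearity, and reports bootstrap confidence intervals.

Around that core it implements the full workflow:

* `thtbind.spectra` — plain-text spectrum/decay/manifest I/O with validation
* `thtbind.preprocess` — scatter fitting and subtraction, bound-dye
  difference spectra, primary inner-filter correction
  F_corr = F·A·ln10/(1−10⁻ᴬ)
* `thtbind.binding` — `BindingIsotherm` model → `BindingResults`
  (Scatchard, fits, AICc, bootstrap CIs, `summary()`)
* `thtbind.photophysics` — anisotropy r = (I_VV−G·I_HV)/(I_VV+2G·I_HV),
  relative quantum yield against an ATTO-425 standard (q_ref = 0.9), and
  TCSPC lifetimes by iterative reconvolution (`DecayModel` → `DecayResults`)
* `thtbind.denaturation` — GdnHCl series: refractive-index→molarity
  calibration, free-dye-enhancement correction (≈3× at 6 M), logistic
  transition midpoints and a two-phase early-decay flag
* `thtbind.fibril` — fibril-fragment composition and formal-charge
  bookkeeping (Aβ40 36-mer: −108; Aβ42 24-mer: −72 at pH 7.4)
* `thtbind.simulate` — a fully seeded synthetic-data generator for every
  input the pipeline consumes
* `thtbind.studies` — reproducible Monte-Carlo validation studies

## Worked example

Fit a simulated clustering-fibril titration (two binding modes, 2% relative
noise on C_b) and let the package decide the mode count:

```python
from thtbind import BindingIsotherm, select_model
from thtbind.simulate import GeneratorTruth
from thtbind.studies import noisy_binding_series

truth = GeneratorTruth.two_mode()          # Kb = 1e4 & 1e6 M^-1, n = 0.05 & 5e-4
points = noisy_binding_series(truth, seed=42, noise=0.02)
model = BindingIsotherm(points, weights="relative")
fit1, fit2 = model.fit(n_modes=1, seed=42), model.fit(n_modes=2, seed=42)
sel = select_model(fit1, fit2)
print(sel.results.bootstrap_ci(B=500, seed=42).summary())
```

```
Multi-site Langmuir fit: 2 mode(s), 12 points, Cp = 0.000115 M
RSS = 0.00321844   AICc = -78.69
 mode Kb (M^-1) affinity 1/Kb (M) n (sites/monomer)            Kb 95% CI            n 95% CI
    1  9.63e+05         1.038e-06         0.0005494  [2.5e+05, 8.42e+14] [0.000237, 0.00159]
    2      8080         0.0001238           0.05947 [2.52e+03, 1.16e+04]     [0.0453, 0.178]
```

The high-affinity, low-abundance mode 1 (affinity ~10⁻⁶ M, n ~ 5×10⁻⁴) is
the clustering-associated site class; mode 2 (affinity ~10⁻⁴ M, n ~ 0.06)
is the ordinary groove-binding mode shared by both fibril types.  The
selection evidence for this dataset was ΔAICc = 25.6 in favour of two modes
with Scatchard linearity rejected at p = 0.004, so two modes are reported.
The wide upper bootstrap bound on K_b of the scarce mode is typical: its
Langmuir term is nearly saturated over the measured range, so the data
bound it well from below but weakly from above.

A full run (simulate → preprocess → fit → photophysics → denaturation) is
one call — `run_pipeline(RunConfig(seed=1))` — or, from a shell,

```sh
tht run --seed 1 --report report.json
tht simulate out_tree --seed 3          # write a synthetic directory tree
tht fit-binding out_tree                # analyze it
tht fragment --peptide Abeta42          # composition/charge bookkeeping
```

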