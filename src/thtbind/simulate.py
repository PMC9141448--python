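"""Synthetic-data generator: every input the analysis pipeline consumes.

The generator emulates the equilibrium-microdialysis experiment from known
ground truth so that each stage of the pipeline has an oracle:

* paired-chamber absorption spectra with a free thioflavin-T band peaking at
  412 nm (ε = 31,600 M⁻¹cm⁻¹), red-shifted bound-dye bands (one per binding
  mode; the second-mode band sits further to the red and is broader, which
  reproduces the broadened bound spectrum seen for clustering fibrils),
  power-law fibril scattering ``a·λ⁻ᵐ`` and i.i.d. Gaussian spectral noise;
* TCSPC decay histograms as Poisson samples of an exponential mixture
  convolved with a Gaussian IRF (the noiseless expectation is the analytic
  exponentially-modified-Gaussian form);
* GdnHCl denaturation series whose bound fraction follows a logistic
  collapse (optionally two-phase) and whose free-dye emission is enhanced
  ~3-fold between 0 and 6 M.

Band shapes are log-normal in wavelength — mildly asymmetric, like real dye
bands.  All randomness flows from one recorded seed; regeneration is
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import exponnorm

from .binding import BindingMode, isotherm, EPSILON_THT_412
from .preprocess import inner_filter_correct
from .spectra import (DecayCurve, ExperimentManifest, Spectrum,
                      write_spectrum, write_decay, write_manifest)

__all__ = [
    "Band", "GeneratorTruth", "DialysisPoint", "DenaturationSim",
    "solve_equilibrium", "simulate_dialysis_series", "simulate_decay",
    "expected_decay", "simulate_denaturation", "simulate_qy_standard",
    "write_simulated_tree",
]


def lognormal_band(wavelength_nm, peak_nm: float, width: float) -> np.ndarray:
    """Unit-peak log-normal band shape, maximum at ``peak_nm``."""
    lam = np.asarray(wavelength_nm, dtype=float)
    return np.exp(-np.log(lam / peak_nm) ** 2 / (2.0 * width ** 2))


@dataclass(frozen=True)
class Band:
    """A log-normal spectral band with a molar peak amplitude."""

    peak_nm: float
    width: float          # dimensionless log-wavelength width
    peak_epsilon: float   # M^-1 cm^-1 (absorption) or brightness (emission)

    def absorbance(self, wavelength_nm, conc_M: float,
                   path_cm: float = 1.0) -> np.ndarray:
        return (self.peak_epsilon * conc_M * path_cm
                * lognormal_band(wavelength_nm, self.peak_nm, self.width))


def _default_c0_series() -> tuple[float, ...]:
    # 12 loaded-dye concentrations log-spaced around the ~32 uM working point
    return tuple(np.geomspace(2e-6, 8e-5, 12))


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground truth for all simulations.

    Defaults describe the baseline experiment: one binding mode with
    association constant 10⁴ M⁻¹ (affinity ~10⁻⁴ M) and n = 0.05 sites per
    monomer, fibrils at 1.15×10⁻⁴ M monomer equivalent (0.5 mg/mL of a
    ~4.3 kDa peptide), twelve loaded-dye concentrations log-spaced over
    2–80 µM around the ~32 µM working point.
    """

    modes: tuple[BindingMode, ...] = (BindingMode(Kb=1e4, n=0.05),)
    Cp_M: float = 1.15e-4
    C0_series_M: tuple[float, ...] = field(default_factory=_default_c0_series)
    path_length_cm: float = 1.0

    free_band: Band = Band(412.0, 0.045, EPSILON_THT_412)
    bound_bands: tuple[Band, ...] = (Band(450.0, 0.050, 36000.0),)
    free_emission: Band = Band(490.0, 0.050, 1.0)
    bound_emission: Band = Band(482.0, 0.050, 1.0)
    scatter_amplitude: float = 2.5e8   # absorbance * nm^m
    scatter_exponent: float = 3.5
    noise_sigma: float = 2e-4          # absorbance units (scan-averaged)
    grid_nm: tuple[float, float, float] = (300.0, 700.0, 1.0)

    qy_bound: float = 0.44
    qy_free: float = 1e-4
    qy_ref: float = 0.9                # ATTO-425-like standard
    a_ref_440: float = 0.05
    emission_scale: float = 1e4        # instrument factor k in S = k*q*A(440)

    decay_components: tuple[tuple[float, float], ...] = ((1.0, 2.0),)
    irf_center_ns: float = 2.0
    irf_sigma_ns: float = 0.15

    denat_c_half_M: float = 2.0
    denat_width_M: float = 0.4
    denat_two_phase: bool = False
    denat_fast_c_half_M: float = 0.3   # clot-disassembly phase
    denat_fast_width_M: float = 0.1
    denat_fast_fraction: float = 0.6
    denat_conc_M: tuple[float, ...] = tuple(np.arange(0.0, 6.01, 0.5))
    denat_noise_frac: float = 0.03
    enhancement_at_6M: float = 3.0     # free-dye emission gain at 6 M GdnHCl

    seed: int = 0

    @classmethod
    def two_mode(cls, **kwargs) -> "GeneratorTruth":
        """Clustering-fibril scenario: second mode with a 100-fold higher
        binding constant and a 100-fold lower number of sites, with a
        red-shifted, broader absorption band."""
        defaults = dict(
            modes=(BindingMode(Kb=1e4, n=0.05), BindingMode(Kb=1e6, n=5e-4)),
            bound_bands=(Band(450.0, 0.050, 36000.0),
                         Band(460.0, 0.080, 42000.0)),
            decay_components=((0.7, 0.5), (0.3, 3.0)),
        )
        defaults.update(kwargs)
        return cls(**defaults)

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi, step = self.grid_nm
        return np.arange(lo, hi + step / 2, step)


def solve_equilibrium(c0: float, cp: float, modes) -> tuple[float, float]:
    """Free/bound concentrations from the mass-balance root.

    Solves ``C0 − 2·Cf − Cb(Cf) = 0`` with the additive Langmuir isotherm;
    the left side is strictly decreasing in Cf, so the root in
    ``[0, C0/2]`` is unique.  Solved by bracketed root-finding to 1e-12
    relative; returns ``(Cf, Cb)`` with ``Cb = C0 − 2·Cf``.
    """
    if c0 < 0 or cp < 0:
        raise ValueError("concentrations must be non-negative")
    modes = tuple(modes)
    if c0 == 0 or not modes or cp == 0:
        return c0 / 2.0, 0.0

    def balance(cf):
        return c0 - 2.0 * cf - isotherm(cf, cp, modes)

    if balance(c0 / 2.0) >= 0:
        return c0 / 2.0, 0.0
    cf = brentq(balance, 0.0, c0 / 2.0, xtol=1e-30 * c0 + 1e-300, rtol=8.9e-16)
    return float(cf), float(c0 - 2.0 * cf)


@dataclass(frozen=True)
class DialysisPoint:
    """One simulated microdialysis pair (iterable as ref, sample, manifest)."""

    reference: Spectrum
    sample: Spectrum
    manifest: ExperimentManifest
    reference_emission: Spectrum | None = None
    sample_emission: Spectrum | None = None

    def __iter__(self):
        return iter((self.reference, self.sample, self.manifest))


def _mode_wise_cb(cf: float, cp: float, modes) -> np.ndarray:
    """Partition the bound concentration by each mode's own Langmuir term."""
    out = np.array([cp * m.n * m.Kb * cf / (1.0 + m.Kb * cf) for m in modes])
    return out


def simulate_dialysis_series(truth: GeneratorTruth, include_emission: bool = False,
                             rng: np.random.Generator | None = None,
                             ) -> list[DialysisPoint]:
    """Simulate the paired-chamber absorption spectra of a titration.

    For each loaded concentration the equilibrium is solved, the reference
    chamber gets the free band scaled to C_f, and the sample chamber adds the
    per-mode bound bands plus the power-law scatter; both receive i.i.d.
    Gaussian noise.  With ``include_emission`` the matching emission pair is
    generated as well (free + bound emission bands, inner-filter attenuated).
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    lam = truth.wavelengths
    l_cm = truth.path_length_cm
    points = []
    for i, c0 in enumerate(truth.C0_series_M):
        cf, cb = solve_equilibrium(c0, truth.Cp_M, truth.modes)
        cb_modes = _mode_wise_cb(cf, truth.Cp_M, truth.modes)
        # renormalize the partition so the parts sum to the mass-balance Cb
        if cb_modes.sum() > 0:
            cb_modes = cb_modes * (cb / cb_modes.sum())
        a_ref = truth.free_band.absorbance(lam, cf, l_cm)
        a_sample = a_ref.copy()
        for band, cbi in zip(truth.bound_bands, cb_modes):
            a_sample = a_sample + band.absorbance(lam, cbi, l_cm)
        a_sample = a_sample + truth.scatter_amplitude * lam ** (-truth.scatter_exponent)
        if truth.noise_sigma > 0:
            a_ref = a_ref + rng.normal(0.0, truth.noise_sigma, lam.size)
            a_sample = a_sample + rng.normal(0.0, truth.noise_sigma, lam.size)
        manifest = ExperimentManifest(C0_M=float(c0), Cp_M=truth.Cp_M,
                                      path_length_cm=l_cm,
                                      id=f"sim-{i:02d}", seed=truth.seed)
        ref_em = sam_em = None
        if include_emission:
            ref_em, sam_em = _emission_pair(truth, lam, cf, float(cb_modes.sum()),
                                            rng)
        points.append(DialysisPoint(
            reference=Spectrum(lam, a_ref, "absorption", l_cm),
            sample=Spectrum(lam, a_sample, "absorption", l_cm),
            manifest=manifest,
            reference_emission=ref_em, sample_emission=sam_em))
    return points


def _emission_pair(truth: GeneratorTruth, lam: np.ndarray, cf: float, cb: float,
                   rng: np.random.Generator, enhancement: float = 1.0,
                   scatter_scale: float = 1.0, bound_scale: float = 1.0,
                   ) -> tuple[Spectrum, Spectrum]:
    """Emission spectra of the two chambers, inner-filter attenuated.

    The ideal emission integral follows ``S = k · q · A(440)``; the observed
    spectrum is the ideal one divided by the inner-filter factor of its own
    chamber's total absorbance at the 440 nm excitation.
    """
    l_cm = truth.path_length_cm
    a_free_440 = float(truth.free_band.absorbance(440.0, cf, l_cm))
    a_bound_440 = float(sum(b.absorbance(440.0, 1.0, l_cm) for b in truth.bound_bands)
                        / len(truth.bound_bands) * cb)
    scatter_440 = scatter_scale * truth.scatter_amplitude * 440.0 ** (-truth.scatter_exponent)

    shape_free = lognormal_band(lam, truth.free_emission.peak_nm,
                                truth.free_emission.width)
    shape_bound = lognormal_band(lam, truth.bound_emission.peak_nm,
                                 truth.bound_emission.width)
    # emission integrals are quoted over the >= 455 nm analysis window
    # (excitation at 440 nm), so band shapes are normalized there
    window = lam >= 455.0
    norm_free = np.trapezoid(shape_free[window], lam[window])
    norm_bound = np.trapezoid(shape_bound[window], lam[window])

    s_free = truth.emission_scale * truth.qy_free * enhancement * a_free_440
    s_bound = truth.emission_scale * truth.qy_bound * a_bound_440 * bound_scale

    def attenuate(spec_vals, a_total):
        factor = inner_filter_correct(1.0, a_total)
        return spec_vals / factor

    ref_vals = attenuate(s_free * shape_free / norm_free, a_free_440)
    sam_vals = attenuate(s_free * shape_free / norm_free
                         + s_bound * shape_bound / norm_bound,
                         a_free_440 + a_bound_440 + scatter_440)
    em_noise = truth.noise_sigma * truth.emission_scale * 1e-3
    if em_noise > 0:
        ref_vals = ref_vals + rng.normal(0.0, em_noise, lam.size)
        sam_vals = sam_vals + rng.normal(0.0, em_noise, lam.size)
    return (Spectrum(lam, ref_vals, "emission", l_cm),
            Spectrum(lam, sam_vals, "emission", l_cm))


def simulate_qy_standard(truth: GeneratorTruth) -> tuple[float, float]:
    """Observed emission integral and A(440) of the quantum-yield standard."""
    s_ideal = truth.emission_scale * truth.qy_ref * truth.a_ref_440
    s_obs = s_ideal / inner_filter_correct(1.0, truth.a_ref_440)
    return float(s_obs), truth.a_ref_440


# ---------------------------------------------------------------------------
# decay


def expected_decay(truth: GeneratorTruth, time_ns: np.ndarray,
                   peak_counts: float = 1e4) -> np.ndarray:
    """Noiseless expected counts: analytic Gaussian-IRF ⊛ exponential mixture.

    Each component is the exponentially-modified-Gaussian density
    ``τ·ExpNorm(t; K=τ/σ, loc=μ, σ)`` weighted by its amplitude fraction;
    the mixture is scaled to the requested peak.
    """
    t = np.asarray(time_ns, dtype=float)
    model = np.zeros_like(t)
    for frac, tau in truth.decay_components:
        k = tau / truth.irf_sigma_ns
        model += frac * tau * exponnorm.pdf(t, k, loc=truth.irf_center_ns,
                                            scale=truth.irf_sigma_ns)
    return model * (peak_counts / model.max())


def simulate_decay(truth: GeneratorTruth, peak_counts: float = 1e4,
                   t_max_ns: float = 12.8, n_bins: int = 1024,
                   irf_peak_counts: float = 1e5, poisson: bool = True,
                   rng: np.random.Generator | None = None) -> DecayCurve:
    """Simulate a TCSPC histogram with its instrument response function.

    Expected counts come from :func:`expected_decay`; with ``poisson`` both
    the decay and the IRF are Poisson-sampled, otherwise the rounded
    expectations are returned (the infinite-count limit).
    """
    rng = np.random.default_rng(truth.seed + 1) if rng is None else rng
    t = np.arange(n_bins) * (t_max_ns / n_bins)
    expected = expected_decay(truth, t, peak_counts)
    irf_shape = np.exp(-(t - truth.irf_center_ns) ** 2
                       / (2.0 * truth.irf_sigma_ns ** 2))
    irf_expected = irf_peak_counts * irf_shape
    if poisson:
        counts = rng.poisson(expected).astype(float)
        irf_counts = rng.poisson(irf_expected).astype(float)
    else:
        counts = np.round(expected)
        irf_counts = np.round(irf_expected)
    return DecayCurve(t, counts, irf_counts)


# ---------------------------------------------------------------------------
# denaturation


def bound_fraction_truth(truth: GeneratorTruth, conc_M) -> np.ndarray:
    """Ground-truth bound fraction vs GdnHCl, normalized to 1 at 0 M."""
    c = np.asarray(conc_M, dtype=float)

    def logistic(cc, half, width):
        return 1.0 / (1.0 + np.exp((cc - half) / width))

    slow = logistic(c, truth.denat_c_half_M, truth.denat_width_M)
    slow0 = logistic(0.0, truth.denat_c_half_M, truth.denat_width_M)
    if not truth.denat_two_phase:
        return slow / slow0
    fast = logistic(c, truth.denat_fast_c_half_M, truth.denat_fast_width_M)
    fast0 = logistic(0.0, truth.denat_fast_c_half_M, truth.denat_fast_width_M)
    w = truth.denat_fast_fraction
    return ((1.0 - w) * slow / slow0 + w * fast / fast0)


def enhancement_truth(truth: GeneratorTruth, conc_M) -> np.ndarray:
    """Ground-truth free-dye enhancement, linear from 1 to e(6 M)."""
    c = np.asarray(conc_M, dtype=float)
    return 1.0 + (truth.enhancement_at_6M - 1.0) * c / 6.0


@dataclass(frozen=True)
class DenaturationSim:
    """Simulated denaturation inputs: microdialysis pairs per GdnHCl level
    plus the dye-only enhancement titration."""

    points: tuple
    free_curve_conc_M: np.ndarray
    free_curve_intensity: np.ndarray


def simulate_denaturation(truth: GeneratorTruth,
                          rng: np.random.Generator | None = None,
                          ) -> DenaturationSim:
    """Per-concentration microdialysis pairs with a logistic bound-fraction
    collapse and denaturant-enhanced free-dye emission.

    The bound concentration at each level is ``Cb(0)·φ(c)`` with φ the
    (optionally two-phase) collapse; the free concentration follows from the
    mass balance, so every generated pair conserves dye exactly.
    """
    from .denaturation import DenaturationPoint  # local import: avoid cycle

    rng = np.random.default_rng(truth.seed + 2) if rng is None else rng
    lam = truth.wavelengths
    l_cm = truth.path_length_cm
    c0 = float(np.median(truth.C0_series_M))
    cf0, cb0 = solve_equilibrium(c0, truth.Cp_M, truth.modes)
    phi = bound_fraction_truth(truth, truth.denat_conc_M)
    enh = enhancement_truth(truth, truth.denat_conc_M)

    points = []
    for c, p, e in zip(truth.denat_conc_M, phi, enh):
        cb = cb0 * p
        cf = (c0 - cb) / 2.0
        # measurement noise acts multiplicatively on the bound-dye signal,
        # relative to the 0 M level so the noise floor does not vanish with phi
        bound_scale = 1.0
        if truth.denat_noise_frac > 0 and p > 0:
            bound_scale = 1.0 + rng.normal(0.0, truth.denat_noise_frac) / p
        ref_em, sam_em = _emission_pair(truth, lam, cf, cb, rng,
                                        enhancement=e, scatter_scale=p,
                                        bound_scale=bound_scale)
        a_ref = truth.free_band.absorbance(lam, cf, l_cm)
        a_sam = a_ref + sum(b.absorbance(lam, cb / len(truth.bound_bands), l_cm)
                            for b in truth.bound_bands)
        a_sam = a_sam + p * truth.scatter_amplitude * lam ** (-truth.scatter_exponent)
        if truth.noise_sigma > 0:
            a_ref = a_ref + rng.normal(0.0, truth.noise_sigma, lam.size)
            a_sam = a_sam + rng.normal(0.0, truth.noise_sigma, lam.size)
        manifest = ExperimentManifest(C0_M=c0, Cp_M=truth.Cp_M,
                                      path_length_cm=l_cm, gdnhcl_M=float(c),
                                      id=f"denat-{c:.2f}M", seed=truth.seed)
        points.append(DenaturationPoint(
            manifest=manifest,
            sample_emission=sam_em, reference_emission=ref_em,
            sample_absorption=Spectrum(lam, a_sam, "absorption", l_cm),
            reference_absorption=Spectrum(lam, a_ref, "absorption", l_cm)))

    free_c = np.asarray(truth.denat_conc_M, dtype=float)
    free_i = enhancement_truth(truth, free_c)
    if truth.denat_noise_frac > 0:
        free_i = free_i * (1.0 + rng.normal(0.0, truth.denat_noise_frac / 3.0,
                                            free_c.size))
        free_i[0] = 1.0  # the normalization point is measured with the series
    return DenaturationSim(points=tuple(points), free_curve_conc_M=free_c,
                           free_curve_intensity=free_i)


# ---------------------------------------------------------------------------
# on-disk tree


def write_simulated_tree(truth: GeneratorTruth, outdir) -> Path:
    """Write a ready-to-analyze directory: spectra CSVs, manifests, decay,
    denaturation series and the ground truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    series = simulate_dialysis_series(truth, include_emission=True)
    for i, pt in enumerate(series):
        write_spectrum(pt.reference, out / f"ref_{i:02d}.csv")
        write_spectrum(pt.sample, out / f"sample_{i:02d}.csv")
        write_spectrum(pt.reference_emission, out / f"ref_em_{i:02d}.csv")
        write_spectrum(pt.sample_emission, out / f"sample_em_{i:02d}.csv")
        write_manifest(pt.manifest, out / f"manifest_{i:02d}.yaml")
    write_decay(simulate_decay(truth), out / "decay.csv")
    denat = simulate_denaturation(truth)
    ddir = out / "denaturation"
    ddir.mkdir(exist_ok=True)
    for j, pt in enumerate(denat.points):
        write_spectrum(pt.sample_emission, ddir / f"sample_em_{j:02d}.csv")
        write_spectrum(pt.reference_emission, ddir / f"ref_em_{j:02d}.csv")
        write_spectrum(pt.sample_absorption, ddir / f"sample_abs_{j:02d}.csv")
        write_spectrum(pt.reference_absorption, ddir / f"ref_abs_{j:02d}.csv")
        write_manifest(pt.manifest, ddir / f"manifest_{j:02d}.yaml")
    np.savetxt(ddir / "free_dye_curve.csv",
               np.column_stack([denat.free_curve_conc_M,
                                denat.free_curve_intensity]),
               delimiter=",", header="gdnhcl_M,intensity", comments="")
    truth_dict = asdict(truth)
    truth_dict["modes"] = [{"Kb": m.Kb, "n": m.n} for m in truth.modes]
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_dict, fh, indent=1, default=float)
    return out
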