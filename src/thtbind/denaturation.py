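"""Guanidine-hydrochloride denaturation series for amyloid fibrils.

Fibril degradation is tracked by turbidity, Rayleigh light scattering (RLS)
and, most sensitively, the fluorescence of fibril-bound thioflavin T.  Two
effects must be untangled at each denaturant level: the bound-dye signal
falls as fibrils depolymerize, while the free-dye emission *rises* with
GdnHCl (roughly threefold between 0 and 6 M) because the denaturant
viscosifies/structures the solvent around the rotor.  Per-concentration
microdialysis pairs plus the measured free-dye enhancement curve let the
bound-only profile be isolated; its midpoint comes from a logistic fit, and
an early collapse below the fitted sigmoid within the first molar of
denaturant flags a two-phase process (clot disassembly preceding fibril
depolymerization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, least_squares
from sklearn.isotonic import IsotonicRegression

from .preprocess import inner_filter_correct
from .photophysics import emission_integral
from .spectra import Spectrum, ExperimentManifest

__all__ = [
    "NOZAKI_COEFFS", "gdnhcl_from_ri", "ri_from_gdnhcl",
    "FreeDyeEnhancement", "free_dye_enhancement",
    "DenaturationPoint", "DenaturationSeries", "bound_fluorescence_profile",
    "transition_points", "TransitionResults", "NoTransitionError",
]

#: Nozaki-type calibration polynomial mapping the refractive-index increment
#: Δn (relative to buffer) to GdnHCl molarity:
#:     c = 57.147·Δn + 38.68·Δn² − 91.60·Δn³
#: Standard calibration for GdnHCl stock verification; valid to ≈6 M
#: (Δn ≈ 0.1).
NOZAKI_COEFFS = (57.147, 38.68, -91.60)

_DELTA_N_MAX = 0.1006  # Δn at ~6.05 M; upper edge of the calibration


def gdnhcl_from_ri(delta_n: float) -> float:
    """GdnHCl molarity from the refractive-index increment Δn.

    Monotone on the calibration range [0, ~0.1]; raises beyond it.
    """
    if delta_n < 0:
        raise ValueError("refractive-index increment must be non-negative")
    if delta_n > _DELTA_N_MAX:
        raise ValueError(
            f"delta_n = {delta_n:.4f} above the calibration range "
            f"(max {_DELTA_N_MAX}, ~6 M)")
    c1, c2, c3 = NOZAKI_COEFFS
    return c1 * delta_n + c2 * delta_n ** 2 + c3 * delta_n ** 3


def ri_from_gdnhcl(conc_M: float) -> float:
    """Inverse calibration: Δn producing a given molarity (bracketed root)."""
    if conc_M < 0:
        raise ValueError("concentration must be non-negative")
    if conc_M == 0:
        return 0.0
    c_max = gdnhcl_from_ri(_DELTA_N_MAX)
    if conc_M > c_max:
        raise ValueError(f"{conc_M} M above the calibration range ({c_max:.2f} M)")
    return brentq(lambda dn: gdnhcl_from_ri(dn) - conc_M, 0.0, _DELTA_N_MAX,
                  xtol=1e-12)


# ---------------------------------------------------------------------------
# free-dye enhancement


@dataclass(frozen=True)
class FreeDyeEnhancement:
    """Monotone interpolant e(c) of free-dye emission versus GdnHCl, e(0)=1."""

    conc_M: np.ndarray
    enhancement: np.ndarray
    _interp: PchipInterpolator = field(repr=False, compare=False)

    def __call__(self, conc_M) -> np.ndarray | float:
        c = np.asarray(conc_M, dtype=float)
        if np.any(c < self.conc_M[0]) or np.any(c > self.conc_M[-1]):
            raise ValueError("concentration outside the measured enhancement range")
        out = self._interp(c)
        return float(out) if np.isscalar(conc_M) else out


def free_dye_enhancement(conc_M, intensity, noise_rtol: float = 0.02
                         ) -> FreeDyeEnhancement:
    """Build the free-dye enhancement curve e(c) from a dye-only titration.

    The curve is normalized to the mandatory c = 0 point.  Decreases larger
    than ``noise_rtol`` (relative) trigger a warning and isotonic regression
    before the monotone PCHIP interpolation, so the result is always
    non-decreasing.
    """
    c = np.asarray(conc_M, dtype=float)
    f = np.asarray(intensity, dtype=float)
    if c.size != f.size or c.size < 2:
        raise ValueError("need matching concentration/intensity arrays (>= 2 points)")
    order = np.argsort(c)
    c, f = c[order], f[order]
    if c[0] != 0:
        raise ValueError("enhancement curve must include a c = 0 point")
    if np.any(np.diff(c) <= 0):
        raise ValueError("duplicate GdnHCl concentrations")
    if np.any(f <= 0):
        raise ValueError("intensities must be positive")
    e = f / f[0]
    drops = -np.minimum(np.diff(e), 0.0)
    if np.any(drops > noise_rtol * np.maximum(e[:-1], 1e-12)):
        warnings.warn("free-dye enhancement curve is non-monotone beyond "
                      "noise; applying isotonic regression", stacklevel=2)
        e = IsotonicRegression(increasing=True).fit_transform(c, e)
        e = e / e[0]
    else:
        e = np.maximum.accumulate(e)  # iron out sub-noise dips
    return FreeDyeEnhancement(conc_M=c, enhancement=e,
                              _interp=PchipInterpolator(c, e))


# ---------------------------------------------------------------------------
# bound-dye profile


@dataclass(frozen=True)
class DenaturationPoint:
    """One denaturant level: paired microdialysis emission/absorption spectra."""

    manifest: ExperimentManifest
    sample_emission: Spectrum
    reference_emission: Spectrum
    sample_absorption: Spectrum | None = None
    reference_absorption: Spectrum | None = None

    @property
    def gdnhcl_M(self) -> float:
        return self.manifest.gdnhcl_M


@dataclass(frozen=True)
class DenaturationSeries:
    """Per-concentration normalized observables of a GdnHCl titration."""

    gdnhcl_M: np.ndarray
    bound_F: np.ndarray            # bound-dye fluorescence, normalized to c=0
    turbidity: np.ndarray | None   # apparent absorbance, normalized to c=0
    rls: np.ndarray | None         # Rayleigh scattering, normalized to c=0
    free_enhancement: np.ndarray   # e(c) evaluated at the series points

    def to_frame(self) -> pd.DataFrame:
        data = {"gdnhcl_M": self.gdnhcl_M, "bound_F": self.bound_F,
                "free_enhancement": self.free_enhancement}
        if self.turbidity is not None:
            data["turbidity"] = self.turbidity
        if self.rls is not None:
            data["rls"] = self.rls
        return pd.DataFrame(data)


def bound_fluorescence_profile(points, enhancement: FreeDyeEnhancement,
                               excitation_nm: float = 440.0,
                               turbidity_nm: float = 450.0,
                               ) -> DenaturationSeries:
    """Bound-dye fluorescence versus GdnHCl from per-point microdialysis pairs.

    At each concentration the reference chamber holds only free dye at the
    equilibrium C_f, already subject to the denaturant enhancement e(c), so

        bound_F(c) = IFC(sample emission) − IFC(reference emission),

    both integrals inner-filter corrected with the absorbance of their own
    chamber at the excitation wavelength (when absorption spectra are
    available).  The profile and turbidity are normalized to the c = 0 point.
    """
    pts = sorted(points, key=lambda p: p.gdnhcl_M)
    if not pts:
        raise ValueError("empty denaturation series")
    if pts[0].gdnhcl_M != 0:
        raise ValueError("series must include a 0 M point for normalization")
    conc, bound, turb = [], [], []
    for p in pts:
        if p.sample_emission is None or p.reference_emission is None:
            raise ValueError(
                f"missing microdialysis pair at {p.gdnhcl_M} M GdnHCl")
        a_s = (p.sample_absorption.value_at(excitation_nm)
               if p.sample_absorption is not None else 0.0)
        a_r = (p.reference_absorption.value_at(excitation_nm)
               if p.reference_absorption is not None else 0.0)
        s_sample = inner_filter_correct(emission_integral(p.sample_emission), a_s)
        s_ref = inner_filter_correct(emission_integral(p.reference_emission), a_r)
        conc.append(p.gdnhcl_M)
        bound.append(s_sample - s_ref)
        if p.sample_absorption is not None:
            turb.append(p.sample_absorption.value_at(turbidity_nm))
    conc_arr = np.asarray(conc)
    bound_arr = np.asarray(bound)
    if bound_arr[0] <= 0:
        raise ValueError("no bound-dye signal at 0 M; cannot normalize")
    bound_arr = bound_arr / bound_arr[0]
    turb_arr = None
    if len(turb) == len(pts) and turb[0] > 0:
        turb_arr = np.asarray(turb) / turb[0]
    e_vals = np.asarray([enhancement(min(c, enhancement.conc_M[-1])) for c in conc_arr])
    return DenaturationSeries(gdnhcl_M=conc_arr, bound_F=bound_arr,
                              turbidity=turb_arr, rls=None,
                              free_enhancement=e_vals)


# ---------------------------------------------------------------------------
# transition analysis


class NoTransitionError(ValueError):
    """The profile shows no decrease across the denaturant range."""


@dataclass(frozen=True)
class TransitionResults:
    """Logistic-fit summary of a denaturation profile."""

    c_half_M: float            # midpoint of the logistic collapse
    width_M: float             # logistic width parameter
    baseline: float            # fitted post-transition level
    amplitude: float           # fitted pre-transition level minus baseline
    early_decay_flag: bool     # collapse below the sigmoid within the first 1 M
    residual_rms: float

    def predict(self, conc_M) -> np.ndarray:
        c = np.asarray(conc_M, dtype=float)
        g = 1.0 / (1.0 + np.exp((c - self.c_half_M) / self.width_M))
        g0 = 1.0 / (1.0 + np.exp(-self.c_half_M / self.width_M))
        return self.baseline + self.amplitude * g / g0

    def to_dict(self) -> dict:
        return {"c_half_M": self.c_half_M, "width_M": self.width_M,
                "early_decay_flag": self.early_decay_flag,
                "baseline": self.baseline, "amplitude": self.amplitude,
                "residual_rms": self.residual_rms}


def transition_points(series: DenaturationSeries,
                      early_window_M: float = 1.0,
                      early_drop: float = 0.25) -> TransitionResults:
    """Locate the denaturation midpoint by a decreasing logistic fit.

    Fits ``F(c) = b + A / (1 + exp((c − c_half)/w))`` to the normalized
    bound-dye profile and reports the midpoint ``c_half``.
    ``early_decay_flag`` is set when any observed point within the first
    ``early_window_M`` molar falls more than ``early_drop`` (in normalized
    units) below the fitted sigmoid — the signature of a fast clot-disassembly
    phase preceding fibril depolymerization.
    """
    c = np.asarray(series.gdnhcl_M, dtype=float)
    f = np.asarray(series.bound_F, dtype=float)
    if c.size < 6:
        raise ValueError("need at least 6 points spanning the transition")
    if f[-1] >= 0.8 * f[0]:
        raise NoTransitionError(
            "profile does not decrease across the range "
            f"(F({c[-1]} M) = {f[-1]:.3g} vs F(0) = {f[0]:.3g})")

    # The profile is normalized to the 0 M point, so the sigmoid is anchored
    # there: F(c) = b + (1-b) * g(c)/g(0) with g the decreasing logistic.
    # The fit excludes the interior of the early window (0 < c <= 1 M by
    # default): a fast clot-disassembly phase there would otherwise be
    # absorbed by sigmoid broadening instead of showing up as a deviation.
    def model(theta, conc):
        b, c_half, logw = theta
        w = np.exp(logw)
        g = 1.0 / (1.0 + np.exp((conc - c_half) / w))
        g0 = 1.0 / (1.0 + np.exp(-c_half / w))
        return b + (1.0 - b) * g / g0

    half_guess = float(np.interp(0.5 * (f[0] + f[-1]), f[::-1], c[::-1]))
    x0 = np.array([min(max(f[-1], -0.1), 0.4), half_guess, np.log(0.3)])
    bounds = ([-0.2, c[0] + 1e-6, np.log(1e-2)],
              [0.5, c[-1], np.log(c[-1] - c[0] + 1e-9)])

    def fit_on(mask, c_half_min=None):
        lo = list(bounds[0])
        start = x0.copy()
        if c_half_min is not None:
            lo[1] = c_half_min
            start[1] = max(start[1], c_half_min + 0.1)
        return least_squares(lambda th: model(th, c[mask]) - f[mask], start,
                             method="trf", bounds=(lo, bounds[1]))

    # midpoint: best single-sigmoid description of the whole profile
    sol = fit_on(np.ones_like(c, dtype=bool))
    b, c_half, logw = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))

    # early-decay flag: the main transition is refitted with the interior of
    # the early window excluded, so a fast clot-disassembly phase cannot be
    # absorbed into sigmoid broadening; early points are then compared
    # against that reference curve
    early = (c <= early_window_M) & (c > 0)
    flag = False
    keep = ~early
    if early.any() and keep.sum() >= 4:
        # the main depolymerization transition lies beyond the early window
        # by definition, so the reference midpoint is constrained there
        ref = fit_on(keep, c_half_min=early_window_M)
        fitted_ref = model(ref.x, c)
        flag = bool(np.any(f[early] < fitted_ref[early] - early_drop))
        if flag:
            # with a clot phase present, the main transition's parameters
            # are the meaningful ones
            b, c_half, logw = ref.x
            rms = float(np.sqrt(np.mean(ref.fun ** 2)))
    return TransitionResults(c_half_M=float(c_half), width_M=float(np.exp(logw)),
                             baseline=float(b), amplitude=float(1.0 - b),
                             early_decay_flag=flag, residual_rms=rms)
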