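"""Scatter correction, inner-filter correction and bound-dye spectrum extraction.

Amyloid fibrils scatter light with a smooth power-law wavelength dependence,
``A_sc(λ) = a·λ⁻ᵐ``.  Fitting that tail in a window where neither free
(412 nm) nor red-shifted bound thioflavin T absorbs lets the fibril
contribution be extrapolated under the dye bands and removed.  The bound-dye
absorption spectrum is then the difference between the scatter-corrected
sample chamber and the reference chamber of the microdialysis pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

__all__ = [
    "ScatterFit", "ChamberPairError", "fit_scatter", "subtract_scatter",
    "bound_dye_spectrum", "inner_filter_correct", "estimate_noise_sigma",
]

#: default window for the scatter power-law fit: free ThT (max 412 nm) and the
#: red-shifted bound bands (~450-460 nm) are both negligible here
DEFAULT_SCATTER_WINDOW = (550.0, 650.0)

#: dye-free region used for the robust noise estimate of difference spectra
DEFAULT_NOISE_WINDOW = (650.0, 700.0)


class ChamberPairError(ValueError):
    """Sample/reference spectra are inconsistent (e.g. mispaired chambers)."""


@dataclass(frozen=True)
class ScatterFit:
    """Power-law scattering baseline ``A_sc(λ) = amplitude · λ**(-exponent)``.

    The trailing fields record the log-log regression geometry so that the
    systematic uncertainty of extrapolating the baseline under the dye bands
    can be propagated (:meth:`prediction_sigma`).
    """

    amplitude: float          # absorbance · nm^exponent
    exponent: float           # dimensionless, 0 (flat) .. ~4 (Rayleigh)
    window_nm: tuple[float, float]
    residual_rms: float
    log_rms: float = 0.0          # residual std of the log-log fit
    log_x_mean: float = 0.0       # mean of log(lambda) over the window
    log_x_ssq: float = 1.0        # centered sum of squares of log(lambda)
    n_points: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("scatter amplitude must be non-negative")
        if not (0.0 <= self.exponent <= 6.0):
            raise ValueError(f"scatter exponent {self.exponent} outside [0, 6]")

    def __call__(self, wavelengths_nm) -> np.ndarray:
        lam = np.asarray(wavelengths_nm, dtype=float)
        return self.amplitude * lam ** (-self.exponent)

    def prediction_sigma(self, wavelengths_nm) -> np.ndarray:
        """Absolute 1-sigma uncertainty of the extrapolated baseline.

        Standard linear-regression prediction error of the log-log fit,
        scaled by the baseline itself; grows with the leverage of the
        extrapolation distance from the fit window.
        """
        lam = np.asarray(wavelengths_nm, dtype=float)
        if self.n_points < 3 or self.amplitude == 0:
            return np.zeros_like(lam)
        x = np.log(lam)
        lever = np.sqrt(1.0 / self.n_points
                        + (x - self.log_x_mean) ** 2 / self.log_x_ssq)
        return self(lam) * self.log_rms * lever


#: identity scatter fit (no correction)
NO_SCATTER = ScatterFit(0.0, 0.0, (0.0, 0.0), 0.0)


def fit_scatter(spectrum: Spectrum,
                window_nm: tuple[float, float] = DEFAULT_SCATTER_WINDOW) -> ScatterFit:
    """Fit ``A = a·λ⁻ᵐ`` to the dye-free tail by log-log least squares.

    Requires at least five points inside the window, all strictly positive
    (the fit is linear in ``log A`` vs ``log λ``).
    """
    lo, hi = window_nm
    wl = spectrum.wavelengths
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 5:
        raise ValueError(
            f"scatter window [{lo}, {hi}] nm contains only {int(mask.sum())} "
            "points; need at least 5")
    a_vals = spectrum.values[mask]
    if np.any(a_vals <= 0):
        raise ValueError(
            "non-positive absorbance inside the scatter window; cannot "
            "log-transform (is the window inside the dye bands?)")
    x = np.log(wl[mask])
    y = np.log(a_vals)
    slope, intercept = np.polyfit(x, y, 1)
    m = -slope
    # clamp tiny numerically-negative exponents from flat baselines
    if -1e-9 < m < 0:
        m = 0.0
    a = float(np.exp(intercept))
    resid = a_vals - a * wl[mask] ** (-m)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    log_resid = y - (intercept + slope * x)
    dof = max(x.size - 2, 1)
    return ScatterFit(a, float(m), (float(lo), float(hi)), rms,
                      log_rms=float(np.sqrt(np.sum(log_resid ** 2) / dof)),
                      log_x_mean=float(x.mean()),
                      log_x_ssq=float(np.sum((x - x.mean()) ** 2)),
                      n_points=int(x.size))


def subtract_scatter(spectrum: Spectrum, fit: ScatterFit) -> Spectrum:
    """Remove the fitted scattering baseline (negative results are allowed
    here; downstream consumers decide how to treat them)."""
    return spectrum.with_values(spectrum.values - fit(spectrum.wavelengths))


def estimate_noise_sigma(spectrum: Spectrum,
                         window_nm: tuple[float, float] = DEFAULT_NOISE_WINDOW) -> float:
    """Robust noise scale: 1.4826·MAD of the values in a dye-free window.

    Falls back to the full spectrum when the window has fewer than 5 points.
    """
    lo, hi = window_nm
    wl = spectrum.wavelengths
    mask = (wl >= lo) & (wl <= hi)
    vals = spectrum.values[mask] if mask.sum() >= 5 else spectrum.values
    mad = np.median(np.abs(vals - np.median(vals)))
    return float(1.4826 * mad)


def bound_dye_spectrum(sample: Spectrum, reference: Spectrum, fit: ScatterFit,
                       noise_sigma: float | None = None,
                       clip_sigma: float = 3.0,
                       fail_sigma: float = 5.0,
                       fail_span_nm: float = 10.0) -> Spectrum:
    """Bound-dye difference spectrum ``D = sample − scatter − reference``.

    Both spectra must be absorption mode, share the wavelength grid and path
    length.  Negative dips within ``clip_sigma`` of the noise scale are
    clipped to zero; a contiguous dip deeper than ``fail_sigma``·σ spanning at
    least ``fail_span_nm`` signals mispaired chambers and raises
    :class:`ChamberPairError`.
    """
    if sample.mode != "absorption" or reference.mode != "absorption":
        raise ValueError("bound_dye_spectrum needs absorption-mode spectra")
    if sample.wavelengths.shape != reference.wavelengths.shape or \
            not np.allclose(sample.wavelengths, reference.wavelengths):
        raise ValueError("sample and reference must share one wavelength grid "
                         "(resample_to_grid first)")
    if not np.isclose(sample.path_length_cm, reference.path_length_cm):
        raise ValueError("sample and reference path lengths differ")

    diff = sample.values - fit(sample.wavelengths) - reference.values
    d = sample.with_values(diff)
    sigma = estimate_noise_sigma(d) if noise_sigma is None else float(noise_sigma)
    # total pointwise uncertainty: photometric noise plus the systematic
    # uncertainty of extrapolating the scatter baseline under the dye bands
    sigma_tot = np.hypot(sigma, fit.prediction_sigma(sample.wavelengths))

    if np.any(sigma_tot > 0):
        deep = diff < -fail_sigma * sigma_tot
        span = _longest_true_span_nm(sample.wavelengths, deep)
        if span >= fail_span_nm:
            raise ChamberPairError(
                "reference exceeds sample by more than "
                f"{fail_sigma}x noise (sigma={sigma:.3g}) over a {span:.0f} nm "
                "span - chambers appear mispaired")
        clipped = np.where((diff < 0) & (diff >= -clip_sigma * sigma_tot), 0.0, diff)
        n_strong = int(np.sum(clipped < 0))
        if n_strong:
            warnings.warn(
                f"{n_strong} points more than {clip_sigma} sigma below zero "
                "left unclipped in bound-dye spectrum", stacklevel=2)
        diff = clipped
    else:
        diff = np.where(diff < 0, 0.0, diff)
    return sample.with_values(diff)


def _longest_true_span_nm(wl: np.ndarray, mask: np.ndarray) -> float:
    """Length in nm of the longest contiguous run of True in ``mask``."""
    best = 0.0
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            best = max(best, wl[i - 1] - wl[start])
            start = None
    if start is not None:
        best = max(best, wl[-1] - wl[start])
    return float(best)


def inner_filter_correct(f_obs, a_ex):
    """Primary inner-filter correction for excitation attenuation.

    ``F_corr = F_obs · A·ln10 / (1 − 10⁻ᴬ)`` with ``A`` the total absorbance
    at the excitation wavelength; continuous limit ``F_corr → F_obs`` as
    ``A → 0``.  Accepts scalars or arrays; the correction factor is ≥ 1 and
    grows like ``A·ln10`` for optically dense samples.
    """
    a = np.asarray(a_ex, dtype=float)
    if np.any(a < 0):
        raise ValueError("absorbance at the excitation wavelength must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(a > 0, a * np.log(10.0) / (1.0 - 10.0 ** (-a)), 1.0)
    out = np.asarray(f_obs, dtype=float) * factor
    if np.isscalar(f_obs) and np.isscalar(a_ex):
        return float(out)
    return out
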