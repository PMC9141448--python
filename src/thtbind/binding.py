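"""Multi-site Langmuir analysis of thioflavin-T binding to amyloid fibrils.

The microdialysis device has two equal chambers separated by a membrane the
dye crosses freely and fibrils cannot.  At equilibrium the free dye
concentration C_f is the same in both, so with total loaded dye C0 the bound
concentration follows from mass balance over both chambers,

    C_b = C0 − 2·C_f .

Binding is described by a sum of independent site classes ("modes"), each
with an association constant K_b (M⁻¹) and a stoichiometry n of sites per
protein monomer:

    C_b(C_f) = C_p · Σ_i  n_i · K_bi · C_f / (1 + K_bi · C_f) .

For a single mode the Scatchard transform C_b/C_f vs C_b is affine with slope
−K_b and abscissa intercept n·C_p; curvature of the Scatchard plot is the
classic signature of a second site class.  :class:`BindingIsotherm` fits the
isotherm by trust-region least squares in (log K_b, log n) with multistart
restarts seeded from the Scatchard linearization; :func:`select_model`
chooses between one and two modes using a corrected-AIC margin combined with
a quadratic-vs-linear F-test of the Scatchard plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

__all__ = [
    "BindingMode", "BindingPoint", "BindingIsotherm", "BindingResults",
    "LinearityTest", "ModelSelection", "MassBalanceError",
    "free_conc", "bound_conc", "isotherm", "scatchard", "linearity_test",
    "select_model",
]

#: molar extinction coefficient of free thioflavin T at its 412 nm maximum
EPSILON_THT_412 = 31600.0  # M^-1 cm^-1

#: degeneracy threshold: a two-mode optimum with Kb1/Kb2 below this is
#: effectively a single site class
DEGENERACY_RATIO = 3.0


class MassBalanceError(ValueError):
    """Free-dye concentration incompatible with the loaded amount."""


@dataclass(frozen=True)
class BindingMode:
    """One class of equivalent binding sites."""

    Kb: float  # association constant, M^-1
    n: float   # sites per protein monomer

    def __post_init__(self):
        if not self.Kb > 0:
            raise ValueError(f"Kb must be positive, got {self.Kb}")
        if not self.n > 0:
            raise ValueError(f"n must be positive, got {self.n}")

    @property
    def affinity_M(self) -> float:
        """Dissociation constant 1/Kb, in molar."""
        return 1.0 / self.Kb


@dataclass(frozen=True)
class BindingPoint:
    """One titration point: free/bound dye at one loaded concentration."""

    Cf: float  # M, free dye
    Cb: float  # M, bound dye
    C0: float  # M, total loaded dye
    Cp: float  # M, fibril concentration (monomer equivalent)

    def __post_init__(self):
        if self.Cf < 0 or self.Cb < 0:
            raise ValueError("concentrations must be non-negative")
        if not self.Cp > 0:
            raise ValueError("Cp must be positive")
        resid = self.C0 - 2.0 * self.Cf - self.Cb
        if abs(resid) > 1e-9:
            raise MassBalanceError(
                f"C0 = 2*Cf + Cb violated by {resid:.3e} M (tolerance 1e-9 M)")

    @property
    def mass_balance_residual(self) -> float:
        return self.C0 - 2.0 * self.Cf - self.Cb


def free_conc(a412: float, epsilon: float = EPSILON_THT_412,
              path_length_cm: float = 1.0) -> float:
    """Free-dye concentration from the 412 nm absorbance (Beer-Lambert)."""
    if a412 < 0:
        raise ValueError("absorbance must be non-negative")
    if not epsilon > 0 or not path_length_cm > 0:
        raise ValueError("extinction coefficient and path length must be positive")
    return a412 / (epsilon * path_length_cm)


def bound_conc(c0: float, cf: float, rtol: float = 1e-6,
               volume_ratio: float = 1.0) -> float:
    """Bound-dye concentration by two-chamber mass balance, ``C0 − 2·Cf``.

    ``volume_ratio`` (sample/reference chamber volume) generalizes to
    asymmetric devices: ``Cb = C0/v − (1 + 1/v)·Cf`` reduces to the symmetric
    form at ``v = 1``.  A free concentration exceeding ``C0/2`` beyond
    ``rtol`` is physically impossible and raises :class:`MassBalanceError`.
    """
    if not c0 > 0:
        raise ValueError("C0 must be positive")
    if cf < 0:
        raise ValueError("Cf must be non-negative")
    v = volume_ratio
    cb = c0 / v - (1.0 + 1.0 / v) * cf
    if cb < -rtol * c0:
        raise MassBalanceError(
            f"2*Cf = {2 * cf:.3e} M exceeds C0 = {c0:.3e} M beyond tolerance")
    return max(cb, 0.0)


def isotherm(cf, cp: float, modes) -> np.ndarray | float:
    """Bound concentration of the additive multi-site Langmuir model."""
    cf_arr = np.asarray(cf, dtype=float)
    cb = np.zeros_like(cf_arr)
    for mode in modes:
        kc = mode.Kb * cf_arr
        cb = cb + cp * mode.n * kc / (1.0 + kc)
    if np.isscalar(cf):
        return float(cb)
    return cb


def scatchard(points) -> tuple[np.ndarray, np.ndarray]:
    """Scatchard coordinates ``(x, y) = (Cb, Cb/Cf)``; Cf = 0 points dropped."""
    pts = [p for p in points]
    kept = [p for p in pts if p.Cf > 0]
    if len(kept) < len(pts):
        warnings.warn(f"{len(pts) - len(kept)} points with Cf = 0 excluded "
                      "from the Scatchard plot", stacklevel=2)
    x = np.array([p.Cb for p in kept])
    y = np.array([p.Cb / p.Cf for p in kept])
    return x, y


@dataclass(frozen=True)
class LinearityTest:
    """F-test of a quadratic against a linear Scatchard regression."""

    linear: bool
    curvature_stat: float  # F statistic for the quadratic term
    p: float


def linearity_test(x, y, alpha: float = 0.05) -> LinearityTest:
    """Test Scatchard linearity: quadratic-vs-linear extra-sum-of-squares F.

    ``linear=True`` iff the quadratic term is not significant at ``alpha``.
    A linear plot is the single-binding-mode signature; curvature indicates
    at least two site classes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 6:
        raise ValueError(f"linearity test needs at least 6 points, got {x.size}")
    xs = x / np.max(np.abs(x))  # scale for conditioning
    lin = sm.OLS(y, sm.add_constant(xs)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([xs, xs ** 2]))).fit()
    fstat, pval, _ = quad.compare_f_test(lin)
    if not np.isfinite(pval):  # exactly collinear / zero-residual edge cases
        fstat, pval = 0.0, 1.0
    return LinearityTest(linear=bool(pval >= alpha),
                         curvature_stat=float(fstat), p=float(pval))


# ---------------------------------------------------------------------------
# model / results


class BindingIsotherm:
    """Multi-site Langmuir binding model for a microdialysis titration.

    Parameters
    ----------
    points : sequence of BindingPoint
        Titration points; all must share one fibril concentration Cp.
    weights : array-like, optional
        Per-point weights for the residuals (default unit weights; pass
        ``1/Cb**2``-style arrays for relative weighting).

    Examples
    --------
    >>> model = BindingIsotherm(points)
    >>> res = model.fit(n_modes=1)
    >>> res2 = model.fit(n_modes=2)
    >>> chosen = select_model(res, res2).results
    """

    def __init__(self, points, weights=None):
        points = list(points)
        if not points:
            raise ValueError("no binding points")
        cps = {p.Cp for p in points}
        if max(cps) - min(cps) > 1e-12 * max(cps):
            raise ValueError("all points must share one fibril concentration Cp")
        self.points = points
        self.Cp = points[0].Cp
        self.Cf = np.array([p.Cf for p in points])
        self.Cb = np.array([p.Cb for p in points])
        if weights is None:
            self.weights = np.ones_like(self.Cb)
        elif isinstance(weights, str):
            if weights != "relative":
                raise ValueError("weights must be an array, None or 'relative'")
            # 1/Cb^2: matched to multiplicative (constant relative) noise
            self.weights = 1.0 / np.maximum(self.Cb, 1e-300) ** 2
        else:
            self.weights = np.asarray(weights, dtype=float)
            if self.weights.shape != self.Cb.shape:
                raise ValueError("weights length must match number of points")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, cf="Cf_M", cb="Cb_M",
                       c0="C0_M", cp="Cp_M", weights=None) -> "BindingIsotherm":
        pts = [BindingPoint(row[cf], row[cb], row[c0], row[cp])
               for _, row in df.iterrows()]
        return cls(pts, weights=weights)

    @classmethod
    def from_concentrations(cls, cf, cb, cp, c0=None, weights=None) -> "BindingIsotherm":
        """Build from raw arrays; C0 defaults to the mass-balance value."""
        cf = np.asarray(cf, dtype=float)
        cb = np.asarray(cb, dtype=float)
        c0 = 2 * cf + cb if c0 is None else np.asarray(c0, dtype=float)
        pts = [BindingPoint(f, b, t, cp) for f, b, t in zip(cf, cb, c0)]
        return cls(pts, weights=weights)

    # -- fitting ------------------------------------------------------------

    def _residuals(self, log_params: np.ndarray) -> np.ndarray:
        # clip keeps exp() finite if the optimizer wanders; the optimum of
        # any identifiable fit is far inside the clipped box
        modes = _modes_from_log(np.clip(log_params, -80.0, 80.0))
        return np.sqrt(self.weights) * (isotherm(self.Cf, self.Cp, modes) - self.Cb)

    def _scatchard_start(self, n_modes: int) -> np.ndarray:
        """Starting values from the Scatchard linearization.

        One mode: straight-line fit, slope −Kb, intercept Kb·n·Cp.  Two
        modes: separate lines through the low-Cf and high-Cf halves (the
        high-affinity class dominates the steep low-Cf limb).
        """
        x, y = scatchard(self.points)
        order = np.argsort(self.Cf[self.Cf > 0])
        x, y = x[order], y[order]

        def line_to_mode(xs, ys) -> tuple[float, float]:
            slope, intercept = np.polyfit(xs, ys, 1)
            kb = max(-slope, 1e-12)
            n = max(intercept / (kb * self.Cp), 1e-12)
            return kb, n

        if n_modes == 1:
            kb, n = line_to_mode(x, y)
            return np.log(np.array([kb, n]))
        half = max(len(x) // 2, 2)
        kb_hi, n_hi = line_to_mode(x[:half], y[:half])   # low-Cf limb
        kb_lo, n_lo = line_to_mode(x[-half:], y[-half:])  # high-Cf limb
        if kb_hi <= kb_lo:  # curvature too weak to split; impose a spread
            kb_hi, kb_lo = kb_lo * 50.0, kb_lo
            n_hi = max(n_lo / 50.0, 1e-12)
        return np.log(np.array([kb_lo, n_lo, kb_hi, n_hi]))

    def fit(self, n_modes: int = 1, n_restarts: int = 10,
            seed: int = 0) -> "BindingResults":
        """Fit the isotherm with ``n_modes`` site classes.

        Positivity is enforced by optimizing (log Kb, log n); ``n_restarts``
        multistart restarts perturb the Scatchard-seeded start by up to half
        a decade, and ties are broken by lowest RSS then lowest leading Kb.
        """
        if n_modes not in (1, 2):
            raise ValueError("n_modes must be 1 or 2")
        n_par = 2 * n_modes
        if len(self.points) < 2 * n_par:
            raise ValueError(
                f"need at least {2 * n_par} points for a {n_modes}-mode fit, "
                f"got {len(self.points)}")
        rng = np.random.default_rng(seed)
        x0 = self._scatchard_start(n_modes)
        best = None
        for trial in range(n_restarts + 1):
            start = x0 if trial == 0 else x0 + rng.uniform(-0.5, 0.5, n_par) * np.log(10)
            try:
                sol = least_squares(self._residuals, start, method="trf",
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                    max_nfev=500 * n_par)
            except Exception:
                continue
            # a run that exhausts its evaluation budget at these tolerances
            # is still a valid candidate; the multistart picks the best RSS
            if not (sol.success or sol.status == 0):
                continue
            rss = float(np.sum(sol.fun ** 2))
            if not np.isfinite(rss):
                continue
            kb1 = float(np.exp(sol.x[0]))
            if best is None or rss < best[0] * (1 - 1e-10) or \
                    (abs(rss - best[0]) <= 1e-10 * max(best[0], 1e-300) and kb1 < best[1]):
                best = (rss, kb1, sol)
        if best is None:
            raise RuntimeError(
                f"{n_modes}-mode fit failed to converge after "
                f"{n_restarts + 1} starts")
        rss, _, sol = best
        modes = _modes_from_log(np.clip(sol.x, -80.0, 80.0))
        modes = sorted(modes, key=lambda m: -m.Kb)
        degenerate = False
        if n_modes == 2:
            ratio = modes[0].Kb / modes[1].Kb
            degenerate = ratio < DEGENERACY_RATIO
            if degenerate:
                warnings.warn(
                    f"two-mode fit is degenerate (Kb1/Kb2 = {ratio:.2f} < "
                    f"{DEGENERACY_RATIO}); the data support a single mode",
                    stacklevel=2)
        return BindingResults(model=self, modes=tuple(modes), rss=rss,
                              degenerate=degenerate)


def _modes_from_log(log_params: np.ndarray) -> list[BindingMode]:
    p = np.exp(np.asarray(log_params, dtype=float))
    return [BindingMode(Kb=p[2 * i], n=p[2 * i + 1]) for i in range(p.size // 2)]


def _aicc(rss: float, n_obs: int, n_par: int) -> float:
    """Corrected AIC for Gaussian residuals (variance counted as a parameter)."""
    k = n_par + 1
    rss = max(rss, 1e-300)
    aic = n_obs * np.log(rss / n_obs) + 2 * k
    denom = n_obs - k - 1
    if denom <= 0:
        return float("inf")
    return float(aic + 2 * k * (k + 1) / denom)


@dataclass(frozen=True)
class BindingResults:
    """Fitted binding parameters with diagnostics.

    Attributes
    ----------
    modes : tuple of BindingMode, sorted by descending Kb
    rss : weighted residual sum of squares
    degenerate : True when a two-mode optimum collapsed (Kb1/Kb2 < 3)
    """

    model: BindingIsotherm
    modes: tuple[BindingMode, ...]
    rss: float
    degenerate: bool = False
    conf_int: dict | None = field(default=None, compare=False)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def aicc(self) -> float:
        return _aicc(self.rss, len(self.model.points), 2 * self.n_modes)

    def predict(self, cf) -> np.ndarray | float:
        return isotherm(cf, self.model.Cp, self.modes)

    def bootstrap_ci(self, B: int = 500, seed: int = 0, level: float = 0.95,
                     ) -> "BindingResults":
        """Case-resampling bootstrap percentile CIs for every Kb and n.

        Returns a copy of the results with ``conf_int`` populated as
        ``{"Kb_1": (lo, hi), "n_1": (lo, hi), ...}``.  Reproducible under a
        fixed seed.
        """
        if B < 200:
            raise ValueError("use at least B = 200 bootstrap replicates")
        pts = self.model.points
        if len(pts) < 2 * (2 * self.n_modes):
            raise ValueError("too few points to bootstrap this model")
        rng = np.random.default_rng(seed)
        x_hat = np.log(np.concatenate([[m.Kb, m.n] for m in self.modes]))
        draws = []
        idx = np.arange(len(pts))
        for _ in range(B):
            take = rng.choice(idx, size=len(pts), replace=True)
            if np.unique(self.model.Cf[take]).size < 2 * self.n_modes:
                continue  # degenerate resample cannot constrain the fit
            sub = BindingIsotherm([pts[i] for i in take],
                                  weights=self.model.weights[take])
            try:
                sol = least_squares(sub._residuals, x_hat, method="trf",
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            if sol.success:
                modes = sorted(_modes_from_log(sol.x), key=lambda m: -m.Kb)
                draws.append([v for m in modes for v in (m.Kb, m.n)])
        if len(draws) < B // 2:
            raise RuntimeError("bootstrap failed on most resamples")
        draws_arr = np.array(draws)
        q = 100 * np.array([(1 - level) / 2, 1 - (1 - level) / 2])
        ci = {}
        names = [f"{nm}_{i + 1}" for i in range(self.n_modes) for nm in ("Kb", "n")]
        for j, name in enumerate(names):
            lo, hi = np.percentile(draws_arr[:, j], q)
            ci[name] = (float(lo), float(hi))
        return dataclasses_replace_ci(self, ci)

    def summary(self) -> str:
        """Plain-text parameter table in the statsmodels spirit."""
        rows = []
        for i, m in enumerate(self.modes, start=1):
            row = {"mode": i, "Kb (M^-1)": f"{m.Kb:.4g}",
                   "affinity 1/Kb (M)": f"{m.affinity_M:.4g}",
                   "n (sites/monomer)": f"{m.n:.4g}"}
            if self.conf_int:
                lo, hi = self.conf_int[f"Kb_{i}"]
                row["Kb 95% CI"] = f"[{lo:.3g}, {hi:.3g}]"
                lo, hi = self.conf_int[f"n_{i}"]
                row["n 95% CI"] = f"[{lo:.3g}, {hi:.3g}]"
            rows.append(row)
        table = pd.DataFrame(rows).to_string(index=False)
        head = (f"Multi-site Langmuir fit: {self.n_modes} mode(s), "
                f"{len(self.model.points)} points, Cp = {self.model.Cp:.4g} M\n"
                f"RSS = {self.rss:.6g}   AICc = {self.aicc:.4g}"
                + ("   [degenerate]" if self.degenerate else ""))
        return head + "\n" + table

    def to_dict(self) -> dict:
        out = {"n_modes": self.n_modes, "rss": self.rss, "aicc": self.aicc,
               "degenerate": self.degenerate,
               "modes": [{"Kb_M_inv": m.Kb, "affinity_M": m.affinity_M, "n": m.n}
                         for m in self.modes]}
        if self.conf_int:
            out["conf_int"] = {k: list(v) for k, v in self.conf_int.items()}
        return out

    def plot_scatchard(self, ax=None):
        """Scatchard plot of the data with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = scatchard(self.model.points)
        ax.plot(x, y, "o", label="data")
        cf_grid = np.linspace(self.model.Cf.min(), self.model.Cf.max(), 200)
        cb_grid = np.asarray(self.predict(cf_grid))
        ax.plot(cb_grid, cb_grid / cf_grid, "-",
                label=f"{self.n_modes}-mode fit")
        ax.set_xlabel("$C_b$ (M)")
        ax.set_ylabel("$C_b/C_f$")
        ax.legend()
        return ax


def dataclasses_replace_ci(res: BindingResults, ci: dict) -> BindingResults:
    return BindingResults(model=res.model, modes=res.modes, rss=res.rss,
                          degenerate=res.degenerate, conf_int=ci)


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of the one-vs-two binding-mode decision."""

    results: BindingResults
    n_modes: int
    evidence: dict


def select_model(fit1: BindingResults, fit2: BindingResults,
                 aicc_margin: float = 2.0, alpha: float = 0.05) -> ModelSelection:
    """Choose between one- and two-mode fits of the same titration.

    The two-mode model is adopted only when (a) its AICc beats the one-mode
    AICc by more than ``aicc_margin``, (b) the Scatchard plot rejects
    linearity at ``alpha``, and (c) the two-mode optimum is not degenerate.
    This conjunction guards against overfitting a second site class to
    single-mode data.
    """
    if fit1.model is not fit2.model and fit1.model.points != fit2.model.points:
        raise ValueError("fits must come from identical points")
    x, y = scatchard(fit1.model.points)
    lin = linearity_test(x, y, alpha=alpha)
    delta = fit1.aicc - fit2.aicc
    two = (delta > aicc_margin) and (not lin.linear) and (not fit2.degenerate)
    chosen = fit2 if two else fit1
    evidence = {"aicc_1": fit1.aicc, "aicc_2": fit2.aicc,
                "delta_aicc": float(delta), "aicc_margin": aicc_margin,
                "scatchard_linear": bool(lin.linear), "linearity_p": lin.p,
                "fit2_degenerate": bool(fit2.degenerate)}
    return ModelSelection(results=chosen, n_modes=chosen.n_modes, evidence=evidence)
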