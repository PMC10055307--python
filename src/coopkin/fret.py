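"""Tight-binding (Morrison) fluorescence titration model.

When the enzyme concentration is comparable to the dissociation constant
(here 10 nM enzyme probing nanomolar inhibitors by tryptophan->ligand FRET),
ligand depletion makes the hyperbolic binding isotherm invalid and the bound
fraction follows the quadratic (Morrison) form

    F = F0 + A * ([I] + Et + Kd - sqrt(([I] + Et + Kd)^2 - 4 Et [I])) / (2 Et)

Fits hold Et fixed at the pipetted value by default. A diagnostic guards
against the stoichiometric-titration regime where the curve degenerates to
a step function and Kd is no longer resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConfigurationError, ConvergenceError


@dataclass
class FretCurve:
    """A fluorescence titration: ligand concentrations (M) vs signal (a.u.)."""

    ligand_conc: np.ndarray
    fluorescence: np.ndarray
    enzyme_total: float = 10e-9

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.ligand_conc.shape != self.fluorescence.shape:
            raise ConfigurationError("concentration and signal lengths differ")
        if np.any(self.ligand_conc < 0):
            raise ConfigurationError("concentrations must be >= 0")
        if self.enzyme_total <= 0:
            raise ConfigurationError("enzyme concentration must be > 0")


@dataclass
class MorrisonFit:
    f0: float
    amplitude: float
    kd: float
    f0_se: float
    amplitude_se: float
    kd_se: float
    et: float
    residuals: np.ndarray
    tight_binding_warning: bool = False


def morrison_model(
    conc, f0: float, amplitude: float, et: float, kd: float
) -> np.ndarray:
    """Quadratic bound-fraction fluorescence model; vectorized over conc."""
    if et <= 0:
        raise ConfigurationError("Et must be > 0")
    if kd < 0:
        raise ConfigurationError("Kd must be >= 0")
    i = np.asarray(conc, dtype=float)
    b = i + et + kd
    disc = np.maximum(b * b - 4.0 * et * i, 0.0)  # guard roundoff
    bound = (b - np.sqrt(disc)) / (2.0 * et)
    return f0 + amplitude * bound


def fit_morrison(curve: FretCurve, fix_et: bool = True) -> MorrisonFit:
    """Least-squares Morrison fit of (F0, A, Kd), Et fixed by default.

    Standard errors come from the covariance of the fit. Requires at least
    5 points spanning both sides of Et. Setting ``fix_et=False`` co-fits Et
    for sensitivity analysis.
    """
    i, f = curve.ligand_conc, curve.fluorescence
    et = curve.enzyme_total
    if len(i) < 5:
        raise ConfigurationError("need at least 5 titration points")
    if not i.min() < et < i.max():
        import warnings

        warnings.warn(
            "titration points do not span the enzyme concentration; "
            "the depletion regime is unconstrained",
            stacklevel=2,
        )
    f0_0 = float(f[np.argmin(i)])
    a0 = float(f.max() - f.min()) or 1.0
    kd0 = max(float(np.median(i)), et / 10.0)

    try:
        if fix_et:
            popt, pcov = curve_fit(
                lambda x, f0, a, kd: morrison_model(x, f0, a, et, kd),
                i,
                f,
                p0=[f0_0, a0, kd0],
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
                ftol=1e-15,
                xtol=1e-15,
                gtol=1e-15,
            )
            et_fit = et
        else:
            popt, pcov = curve_fit(
                lambda x, f0, a, et_, kd: morrison_model(x, f0, a, et_, kd),
                i,
                f,
                p0=[f0_0, a0, et, kd0],
                bounds=(
                    [-np.inf, -np.inf, et / 100.0, 0.0],
                    [np.inf, np.inf, et * 100.0, np.inf],
                ),
                maxfev=20000,
                ftol=1e-15,
                xtol=1e-15,
                gtol=1e-15,
            )
            et_fit = float(popt[2])
            popt = np.array([popt[0], popt[1], popt[3]])
            pcov = pcov[np.ix_([0, 1, 3], [0, 1, 3])]
    except RuntimeError as exc:
        raise ConvergenceError(f"Morrison fit did not converge: {exc}") from exc

    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    resid = f - morrison_model(i, popt[0], popt[1], et_fit, popt[2])
    warn = bool(popt[2] < 1e-15 or popt[2] <= et_fit / 100.0)
    if warn:
        import warnings

        warnings.warn(
            "fitted Kd at or near zero: tight-binding regime, "
            "Kd below Et is not resolvable",
            stacklevel=2,
        )
    return MorrisonFit(
        f0=float(popt[0]),
        amplitude=float(popt[1]),
        kd=float(popt[2]),
        f0_se=float(se[0]),
        amplitude_se=float(se[1]),
        kd_se=float(se[2]),
        et=et_fit,
        residuals=resid,
        tight_binding_warning=warn,
    )


def step_function_diagnostic(
    fit: MorrisonFit,
    conc: np.ndarray,
    noise_level: float | None = None,
    threshold: float = 3.0,
) -> str:
    """Flag fits indistinguishable from a stoichiometric step function.

    Curves are re-simulated at Kd/10 and Kd/100 on the experimental
    concentration grid; if a tighter curve differs from the fitted one by
    less than ``threshold`` times the noise level (RMS of the residuals by
    default), the titration only counts molecules and the fitted Kd is an
    upper bound, not a measurement. The factor-of-3 threshold asks for a
    clearly-above-noise separation, not bare statistical visibility.

    Returns "resolvable" or "titration-limited".
    """
    conc = np.asarray(conc, dtype=float)
    if noise_level is None:
        noise_level = float(np.sqrt(np.mean(fit.residuals**2)))
        if noise_level == 0:
            noise_level = 1e-3 * abs(fit.amplitude)
    ref = morrison_model(conc, fit.f0, fit.amplitude, fit.et, fit.kd)
    for factor in (10.0, 100.0):
        alt = morrison_model(conc, fit.f0, fit.amplitude, fit.et, fit.kd / factor)
        rms = float(np.sqrt(np.mean((alt - ref) ** 2)))
        if rms < threshold * noise_level:
            return "titration-limited"
    return "resolvable"
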