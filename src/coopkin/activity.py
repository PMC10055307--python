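"""Kinase-activity readouts, inhibition-curve fitting and synergy grids.

Observed rates come from a coupled NADH-depletion assay (A340 slope) and
are fitted to an empirical four-parameter logistic (4PL). The mechanistic
counterpart predicts fractional activity from a conformational-ensemble
scheme: only conformations with nonzero catalytic weight and a drug-free
orthosteric site turn over. The headline combination metric is the dose of
orthosteric drug needed for 10% residual activity and its fold-reduction
as the allosteric co-drug is raised across a checkerboard grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq, curve_fit

from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateModelError,
    UnreachableInhibitionError,
)
from .linkage import DoubleDrugScheme, LigandProfile, species_fractions


@dataclass
class DoseResponseRecord:
    """Inhibitor concentrations (M) vs observed rates (1/s), with metadata."""

    inhibitor_conc: np.ndarray
    k_obs: np.ndarray
    enzyme: str = ""
    co_inhibitor_conc: float = 0.0

    def __post_init__(self) -> None:
        self.inhibitor_conc = np.asarray(self.inhibitor_conc, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.inhibitor_conc.shape != self.k_obs.shape:
            raise ConfigurationError("concentration and rate lengths differ")
        if np.any(self.k_obs < 0):
            raise ConfigurationError("rates must be >= 0")
        if len(self.inhibitor_conc) < 6 or 0.0 not in self.inhibitor_conc:
            raise ConfigurationError(
                "need >= 6 concentrations including an uninhibited (0) point"
            )


@dataclass
class FourPLFit:
    """Four-parameter logistic fit: y = bottom + (top-bottom)/(1+(x/IC50)^h)."""

    top: float
    bottom: float
    ic50: float
    hill: float
    covariance: np.ndarray
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ConfigurationError("IC50 must be > 0")
        if self.bottom > self.top:
            raise ConfigurationError("bottom must not exceed top")

    def predict(self, conc) -> np.ndarray:
        return four_pl(np.asarray(conc, dtype=float),
                       self.top, self.bottom, self.ic50, self.hill)

    @property
    def param_se(self) -> dict[str, float]:
        se = np.sqrt(np.maximum(np.diag(self.covariance), 0.0))
        return dict(zip(("top", "bottom", "log10_ic50", "hill"), se))


@dataclass
class SynergyGrid:
    """Checkerboard of activities with per-row 10%-residual doses."""

    ortho_concs: np.ndarray
    allo_concs: np.ndarray
    activity: np.ndarray  # shape (n_allo, n_ortho)
    dose_10pct: np.ndarray  # per allo level; NaN = not achievable
    fold_reduction: np.ndarray  # dose_10pct[0] / dose_10pct

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, ca in enumerate(self.allo_concs):
            for j, co in enumerate(self.ortho_concs):
                rows.append(
                    {"allo_conc": ca, "ortho_conc": co,
                     "activity": self.activity[i, j]}
                )
        return pd.DataFrame(rows)


def kobs_from_absorbance(
    time: np.ndarray,
    a340: np.ndarray,
    enzyme_total: float,
    epsilon: float = 6220.0,
    path: float = 1.0,
) -> tuple[float, float]:
    """Observed rate from an NADH-depletion A340 trace.

    k_obs = -slope / (epsilon * path * [E]); default epsilon is NADH at
    340 nm (6220 /M/cm). Returns (k_obs, R^2); warns below R^2 = 0.98 where
    the trace has left the linear regime.
    """
    time = np.asarray(time, dtype=float)
    a340 = np.asarray(a340, dtype=float)
    if len(time) < 10:
        raise ConfigurationError("need at least 10 time points in the linear regime")
    if enzyme_total <= 0:
        raise ConfigurationError("enzyme concentration must be > 0")
    fit = stats.linregress(time, a340)
    kobs = -fit.slope / (epsilon * path * enzyme_total)
    r2 = float(fit.rvalue**2)
    if np.ptp(a340) > 0 and r2 < 0.98:
        warnings.warn(f"A340 trace nonlinear (R^2 = {r2:.3f})", stacklevel=2)
    return float(kobs), r2


def predicted_activity(
    scheme: DoubleDrugScheme,
    ortho_conc: float,
    allo_conc: float,
    atp: tuple[LigandProfile, float] | None = None,
) -> float:
    """Fractional activity at given free inhibitor concentrations.

    activity = sum_s cw_s * fraction(state s, orthosteric drug-free),
    normalized to the uninhibited (apo, or ATP-only) value. ATP optionally
    enters as a state-selective orthosteric competitor whose complexes
    remain catalytically productive — it only shifts the ensemble and
    competes the drug out of the active site.
    """
    cw = scheme.catalytic_weights()
    if not np.any(cw > 0):
        raise DegenerateModelError("all catalytic weights are zero")

    def raw(fo: float, fa: float) -> float:
        if atp is None:
            pop = species_fractions(scheme, fo, fa)
            return float(np.sum(cw * pop.ortho_free_site_fractions()))
        atp_prof, atp_free = atp
        states = scheme.ensemble.states
        w = np.asarray(scheme.ensemble.weights)
        xo = _factor(scheme.ortho, states, fo)
        xa = _factor(scheme.allo, states, fa)
        xt = _factor(atp_prof, states, atp_free)
        c = scheme.couplings()
        # orthosteric site: empty | drug | ATP; allosteric: empty | drug
        z_state = (1.0 + xo + xt) * (1.0 + xa) + (c - 1.0) * xo * xa
        active = (1.0 + xt) * (1.0 + xa)  # drug-free orthosteric site
        z = np.sum(w * z_state)
        return float(np.sum(cw * w * active) / z)

    denom = raw(0.0, 0.0)
    if denom == 0:
        raise DegenerateModelError("uninhibited activity is zero")
    return raw(ortho_conc, allo_conc) / denom


def _factor(lig: LigandProfile, states, free: float) -> np.ndarray:
    kd = lig.kd_array(states)
    out = np.zeros_like(kd)
    fin = np.isfinite(kd)
    out[fin] = free / kd[fin]
    return out


def four_pl(x, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic; exact at x = 0 (returns top)."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, top)
    nz = x > 0
    out[nz] = bottom + (top - bottom) / (1.0 + (x[nz] / ic50) ** hill)
    return out


def fit_4pl(record: DoseResponseRecord) -> FourPLFit:
    """Least-squares 4PL fit on log-dose; zero-dose points anchor the top."""
    x, y = record.inhibitor_conc, record.k_obs
    pos = x[x > 0]
    if len(pos) < 4:
        raise ConfigurationError("need at least 4 nonzero doses")
    top0 = float(np.mean(y[x == 0])) or float(y.max())
    bot0 = float(y[np.argmax(x)])
    ic50_0 = float(np.exp(np.median(np.log(pos))))

    def model(xx, top, bottom, log10_ic50, hill):
        return four_pl(xx, top, bottom, 10.0**log10_ic50, hill)

    try:
        popt, pcov = curve_fit(
            model,
            x,
            y,
            p0=[top0, bot0, math.log10(ic50_0), 1.0],
            bounds=([0.0, 0.0, -15.0, 0.1], [np.inf, np.inf, 2.0, 10.0]),
            maxfev=20000,
            ftol=1e-15,
            xtol=1e-15,
            gtol=1e-15,
        )
    except RuntimeError as exc:
        raise ConvergenceError(f"4PL fit did not converge: {exc}") from exc
    top, bottom, l_ic50, hill = popt
    fit = FourPLFit(
        top=float(top),
        bottom=float(min(bottom, top)),
        ic50=float(10.0**l_ic50),
        hill=float(hill),
        covariance=pcov,
        residuals=y - model(x, *popt),
    )
    if bottom > 0.2 * top and y[np.argmax(x)] > bottom + 0.1 * (top - bottom):
        warnings.warn("inhibition plateau not clearly reached; wide CI on "
                      "bottom/IC50", stacklevel=2)
    return fit


def dose_for_residual_activity(
    fit_or_model: FourPLFit | Callable[[float], float],
    residual: float = 0.10,
    bracket: tuple[float, float] = (1e-15, 1.0),
) -> float:
    """Dose giving ``residual`` x the uninhibited rate.

    For a 4PL fit the inversion is closed-form relative to the curve's own
    top; a callable model (dose -> fractional activity, already normalized
    to 1 at zero dose) is inverted by bracketed root-finding. Raises
    UnreachableInhibitionError when the curve's floor lies above the target.
    """
    if not 0.0 < residual < 1.0:
        raise ValueError("residual must be in (0, 1)")
    if isinstance(fit_or_model, FourPLFit):
        f = fit_or_model
        target = residual * f.top
        if target <= f.bottom:
            raise UnreachableInhibitionError(
                f"floor {f.bottom / f.top:.2f} of the curve exceeds the "
                f"requested residual {residual}"
            )
        if target >= f.top:
            raise ValueError("residual must lie below the uninhibited rate")
        ratio = (f.top - f.bottom) / (target - f.bottom) - 1.0
        return float(f.ic50 * ratio ** (1.0 / f.hill))
    model = fit_or_model
    lo, hi = bracket
    if model(hi) > residual:
        # expand until the target is bracketed or declared unreachable
        for _ in range(60):
            hi *= 10.0
            if model(hi) <= residual:
                break
        else:
            raise UnreachableInhibitionError(
                f"activity floor {model(hi):.3f} above residual {residual}"
            )
    return float(brentq(lambda d: model(d) - residual, lo, hi,
                        xtol=1e-300, rtol=8.9e-16, maxiter=200))


def jackknife_se(
    data: Sequence, statistic: Callable[[Sequence], float]
) -> float:
    """Leave-one-out jackknife standard error of a fitted statistic.

    SE = sqrt((n-1)/n * sum_i (theta_(i) - theta_bar)^2). Failed replicate
    refits are dropped with a warning and the effective n reported.
    """
    data = list(data)
    n = len(data)
    if n < 4:
        raise ConfigurationError("jackknife needs at least 4 data points")
    thetas = []
    for i in range(n):
        subset = data[:i] + data[i + 1 :]
        try:
            thetas.append(float(statistic(subset)))
        except Exception as exc:  # noqa: BLE001 — refit failures are data-driven
            warnings.warn(
                f"leave-one-out refit {i} failed ({exc}); effective n reduced",
                stacklevel=2,
            )
    m = len(thetas)
    if m < 2:
        raise ConvergenceError("too few successful jackknife replicates")
    t = np.asarray(thetas)
    return float(np.sqrt((m - 1) / m * np.sum((t - t.mean()) ** 2)))


def synergy_grid(
    source: DoubleDrugScheme | np.ndarray,
    ortho_concs: Sequence[float],
    allo_concs: Sequence[float],
    residual: float = 0.10,
) -> SynergyGrid:
    """Fill a checkerboard of activities and extract per-row dose-reduction.

    ``source`` is either a scheme (predicted activities) or a pre-measured
    activity matrix of shape (n_allo, n_ortho) normalized to the [0, 0]
    corner. For each allosteric level the orthosteric dose reaching the
    residual-activity threshold is computed; unreachable rows are recorded
    as NaN rather than raised.
    """
    oc = np.asarray(ortho_concs, dtype=float)
    ac = np.asarray(allo_concs, dtype=float)
    if np.any(np.diff(oc) <= 0) or np.any(np.diff(ac) <= 0):
        raise ConfigurationError("concentration grids must be strictly increasing")
    if oc[0] != 0 or ac[0] != 0:
        raise ConfigurationError("grids must include the zero row/column")

    if isinstance(source, DoubleDrugScheme):
        act = np.array(
            [[predicted_activity(source, o, a) for o in oc] for a in ac]
        )

        def row_dose(a: float) -> float:
            apo = predicted_activity(source, 0.0, a)
            try:
                return dose_for_residual_activity(
                    lambda d: predicted_activity(source, d, a) / apo, residual
                )
            except UnreachableInhibitionError:
                return math.nan

        doses = np.array([row_dose(a) for a in ac])
    else:
        act = np.asarray(source, dtype=float)
        if act.shape != (len(ac), len(oc)):
            raise ConfigurationError("activity matrix shape mismatch")
        doses = np.array([_interp_dose(oc, act[i] / act[i, 0], residual)
                          for i in range(len(ac))])
    fold = doses[0] / doses
    return SynergyGrid(
        ortho_concs=oc, allo_concs=ac, activity=act,
        dose_10pct=doses, fold_reduction=fold,
    )


def _interp_dose(conc: np.ndarray, activity: np.ndarray, residual: float) -> float:
    """Log-linear interpolation of the dose reaching the residual threshold."""
    if activity.min() > residual:
        return math.nan
    for j in range(1, len(conc)):
        if activity[j] <= residual:
            lo, hi = max(conc[j - 1], conc[1] / 100.0), conc[j]
            a0, a1 = activity[j - 1], activity[j]
            if a0 == a1:
                return float(hi)
            t = (a0 - residual) / (a0 - a1)
            return float(10 ** (np.log10(lo) + t * (np.log10(hi) - np.log10(lo))))
    return math.nan
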