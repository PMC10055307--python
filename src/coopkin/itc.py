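"""Isothermal titration calorimetry: forward simulation and fitting.

Supports the two analysis modes used for apparent-affinity measurement on
double-drugged kinases:

* direct (independent-sites) titrations, fitted for (Kd, dH, n),
* competitive-replacement titrations, where a tight binder B is titrated
  into enzyme pre-loaded with a weak competitor A at the same site, which
  extends the measurable affinity range: B's apparent Kd is inflated to
  ``Kd_B (1 + [A]_free/Kd_A)`` and stays in the fittable c-value window.

The forward model uses the "overflow" displaced-volume convention: each
injection of volume dV into a cell of volume V0 scales every pre-existing
cell concentration by (1 - dV/V0) before the syringe material is added.
Injection heats are V0 * sum_complexes dH * (net complex formed in the cell
during the injection). The first injection of an experiment is discarded
before fitting, mirroring standard instrument practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import ConfigurationError, ConvergenceError
from .linkage import ALLOSTERIC, ORTHOSTERIC, DoubleDrugScheme, solve_free_concentrations

#: two-sided 68.3% (1 sigma) z-score used for fit confidence intervals
Z_1SIGMA = 1.0


@dataclass
class TitrationExperiment:
    """One ITC run: cell composition, syringe, injection schedule, heats.

    All volumes in liters, concentrations molar, heats joules. The first
    cell species is the titrand (enzyme).
    """

    cell_volume: float
    cell_species: list[tuple[str, float]]
    syringe_species: tuple[str, float]
    injections: list[tuple[float, float]]  # (volume L, observed heat J)
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.cell_volume <= 0:
            raise ConfigurationError("cell volume must be > 0")
        if any(v <= 0 for v, _ in self.injections):
            raise ConfigurationError("injection volumes must be > 0")
        if any(c <= 0 for _, c in self.cell_species) or self.syringe_species[1] <= 0:
            raise ConfigurationError("concentrations must be > 0")

    @classmethod
    def design(
        cls,
        cell_volume: float,
        cell_species: Sequence[tuple[str, float]],
        syringe_species: tuple[str, float],
        injection_volumes: Sequence[float],
        temperature: float = 298.15,
    ) -> "TitrationExperiment":
        """Build an experiment with the heats left blank (for simulation)."""
        return cls(
            cell_volume=cell_volume,
            cell_species=list(cell_species),
            syringe_species=tuple(syringe_species),
            injections=[(v, 0.0) for v in injection_volumes],
            temperature=temperature,
        )

    @property
    def volumes(self) -> np.ndarray:
        return np.array([v for v, _ in self.injections])

    @property
    def heats(self) -> np.ndarray:
        return np.array([q for _, q in self.injections])

    def with_heats(self, heats: Sequence[float]) -> "TitrationExperiment":
        if len(heats) != len(self.injections):
            raise ConfigurationError("one heat per injection required")
        return TitrationExperiment(
            cell_volume=self.cell_volume,
            cell_species=list(self.cell_species),
            syringe_species=self.syringe_species,
            injections=[(v, float(q)) for (v, _), q in zip(self.injections, heats)],
            temperature=self.temperature,
        )


@dataclass
class BindingFitResult:
    """Point estimates, 68.3% confidence intervals and residuals of an ITC fit."""

    kd: float
    kd_ci: tuple[float, float]
    dh: float  # kJ/mol
    dh_se: float
    n_sites: float
    n_se: float
    residuals: np.ndarray
    model: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ConfigurationError("fitted Kd must be > 0")
        lo, hi = self.kd_ci
        if not (lo <= self.kd <= hi):
            raise ConfigurationError("confidence interval must bracket the estimate")


# ---------------------------------------------------------------------------
# equilibrium solvers
# ---------------------------------------------------------------------------

def single_site_complex(et: float, lt: float, kd: float) -> float:
    """[EL] for one site via the stable root of the binding quadratic."""
    b = et + lt + kd
    disc = max(b * b - 4.0 * et * lt, 0.0)
    return 0.5 * (b - math.sqrt(disc))


def competitive_complexes(
    et: float, at: float, bt: float, ka: float, kb: float
) -> tuple[float, float, float]:
    """Exact equilibrium for two ligands A, B competing for one site.

    Returns (free E, [EA], [EB]) from the physical root of the cubic in free
    enzyme (trigonometric closed form); degenerate single-ligand cases fall
    back to the quadratic.
    """
    if at == 0 and bt == 0:
        return et, 0.0, 0.0
    if bt == 0:
        ea = single_site_complex(et, at, ka)
        return et - ea, ea, 0.0
    if at == 0:
        eb = single_site_complex(et, bt, kb)
        return et - eb, 0.0, eb
    a = ka + kb + at + bt - et
    b = kb * (at - et) + ka * (bt - et) + ka * kb
    c = -ka * kb * et
    q = a * a - 3.0 * b
    theta = math.acos(
        min(1.0, max(-1.0, (-2.0 * a**3 + 9.0 * a * b - 27.0 * c) / (2.0 * q**1.5)))
    )
    fe = -a / 3.0 + (2.0 / 3.0) * math.sqrt(q) * math.cos(theta / 3.0)
    fe = min(max(fe, 0.0), et)
    # the trigonometric root cancels catastrophically when fe << |a|;
    # polish on the well-conditioned monotone mass-balance residual
    for _ in range(50):
        ra, rb = ka + fe, kb + fe
        g = fe * (1.0 + at / ra + bt / rb) - et
        dg = 1.0 + at * ka / ra**2 + bt * kb / rb**2
        step = g / dg
        fe_new = min(max(fe - step, 0.0), et)
        if abs(fe_new - fe) <= 1e-15 * fe_new:
            fe = fe_new
            break
        fe = fe_new
    ea = at * fe / (ka + fe)
    eb = bt * fe / (kb + fe)
    return fe, ea, eb


def competitive_complexes_bisection(
    et: float, at: float, bt: float, ka: float, kb: float
) -> tuple[float, float, float]:
    """Bracketed-bisection oracle for the same equilibrium (slow, robust)."""

    def resid(fe: float) -> float:
        return fe * (1.0 + at / (ka + fe) + bt / (kb + fe)) - et

    if et == 0:
        return 0.0, 0.0, 0.0
    fe = brentq(resid, 0.0, et, xtol=1e-300, rtol=8.9e-16, maxiter=500)
    return fe, at * fe / (ka + fe), bt * fe / (kb + fe)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def _titrate_totals(experiment: TitrationExperiment):
    """Yield per-injection total concentrations in the cell after the
    overflow dilution and syringe addition."""
    v0 = experiment.cell_volume
    totals = {name: conc for name, conc in experiment.cell_species}
    syr_name, syr_conc = experiment.syringe_species
    totals.setdefault(syr_name, 0.0)
    out = []
    for dv, _ in experiment.injections:
        d = 1.0 - dv / v0
        totals = {k: v * d for k, v in totals.items()}
        totals[syr_name] += syr_conc * dv / v0
        out.append(dict(totals))
    return out


def _heats_from_complexes(
    experiment: TitrationExperiment,
    complexes: Callable[[dict], dict[str, float]],
    dh_kj: dict[str, float],
) -> np.ndarray:
    """Generic injection-heat bookkeeping given a totals -> complexes map."""
    v0 = experiment.cell_volume
    totals0 = dict(experiment.cell_species)
    totals0.setdefault(experiment.syringe_species[0], 0.0)
    prev = complexes(totals0)
    heats = []
    for totals, (dv, _) in zip(_titrate_totals(experiment), experiment.injections):
        cur = complexes(totals)
        q = 0.0
        for name, conc in cur.items():
            dconc = conc - prev[name] * (1.0 - dv / v0)
            q += dh_kj[name] * 1000.0 * dconc * v0  # kJ/mol -> J
        heats.append(q)
        prev = cur
    return np.array(heats)


def simulate_direct(
    experiment: TitrationExperiment, kd: float, dh: float, n: float = 1.0
) -> np.ndarray:
    """Heats (J) per injection for a single-site independent model.

    The stoichiometry factor n scales the competent titrand concentration;
    titrand is the first cell species, titrant the syringe species.
    """
    enzyme = experiment.cell_species[0][0]
    ligand = experiment.syringe_species[0]

    def cx(totals: dict) -> dict[str, float]:
        return {"EL": single_site_complex(n * totals[enzyme], totals[ligand], kd)}

    return _heats_from_complexes(experiment, cx, {"EL": dh})


def simulate_displacement(
    experiment: TitrationExperiment,
    kd_b: float,
    dh_b: float,
    kd_a: float,
    dh_a: float,
    n: float = 1.0,
) -> np.ndarray:
    """Heats (J) for a competitive-replacement titration.

    Cell holds enzyme (first species) pre-loaded with weak ligand A (second
    species); tight ligand B is in the syringe. Injection heats combine B
    binding and A displacement. With [A] = 0 this reduces exactly to the
    direct model.
    """
    if len(experiment.cell_species) < 2:
        raise ConfigurationError(
            "displacement experiment needs enzyme + competitor in the cell"
        )
    enzyme = experiment.cell_species[0][0]
    lig_a = experiment.cell_species[1][0]
    lig_b = experiment.syringe_species[0]

    def cx(totals: dict) -> dict[str, float]:
        _, ea, eb = competitive_complexes(
            n * totals[enzyme], totals[lig_a], totals[lig_b], kd_a, kd_b
        )
        return {"EA": ea, "EB": eb}

    return _heats_from_complexes(experiment, cx, {"EA": dh_a, "EB": dh_b})


def simulate_scheme(
    experiment: TitrationExperiment, scheme: DoubleDrugScheme
) -> np.ndarray:
    """Heats (J) for a two-site ensemble scheme with per-state enthalpies.

    Cell/syringe species whose names match the scheme's ligands are routed
    to their sites; every populated bound species must carry an enthalpy.
    """
    enzyme = experiment.cell_species[0][0]
    names = {scheme.ortho.name: ORTHOSTERIC, scheme.allo.name: ALLOSTERIC}
    for lig in (scheme.ortho, scheme.allo):
        if lig.dh_per_state is None:
            raise ConfigurationError(
                f"ligand {lig.name!r} carries no enthalpies; cannot simulate heats"
            )

    states = scheme.ensemble.states
    dho = scheme.ortho.dh_array(states)
    dha = scheme.allo.dh_array(states)

    def cx(totals: dict) -> dict[str, float]:
        tot_o = sum(v for k, v in totals.items() if names.get(k) == ORTHOSTERIC)
        tot_a = sum(v for k, v in totals.items() if names.get(k) == ALLOSTERIC)
        pop = solve_free_concentrations(scheme, totals[enzyme], tot_o, tot_a)
        out: dict[str, float] = {}
        for i, s in enumerate(states):
            out[f"{s}:ortho"] = totals[enzyme] * (
                pop.fractions[i, 1] + pop.fractions[i, 3]
            )
            out[f"{s}:allo"] = totals[enzyme] * (
                pop.fractions[i, 2] + pop.fractions[i, 3]
            )
        return out

    dh_map = {f"{s}:ortho": dho[i] for i, s in enumerate(states)}
    dh_map |= {f"{s}:allo": dha[i] for i, s in enumerate(states)}
    return _heats_from_complexes(experiment, cx, dh_map)


def simulate_titration(experiment: TitrationExperiment, model, **params) -> np.ndarray:
    """Dispatching front-end: model is 'direct', 'displacement' or a scheme."""
    if isinstance(model, DoubleDrugScheme):
        return simulate_scheme(experiment, model)
    if model == "direct":
        return simulate_direct(experiment, **params)
    if model == "displacement":
        return simulate_displacement(experiment, **params)
    raise ConfigurationError(f"unknown titration model {model!r}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_ls(
    predict: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    x0: np.ndarray,
    bounds,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least squares with asymptotic parameter SEs from the Jacobian."""
    res = least_squares(
        lambda p: predict(p) - y,
        x0,
        bounds=bounds,
        ftol=1e-15,
        xtol=1e-15,
        gtol=1e-15,
        max_nfev=5000,
    )
    if not res.success:
        raise ConvergenceError(f"ITC fit did not converge: {res.message}")
    m, p = len(y), len(x0)
    dof = max(m - p, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return res.x, se, res.fun


def _multistart_kd0(cell0: float) -> list[float]:
    return [cell0 * f for f in (1e-3, 1e-2, 0.1, 1.0, 10.0)]


def fit_direct(
    experiment: TitrationExperiment,
    n_fixed: float | None = None,
    discard_first: bool = True,
) -> BindingFitResult:
    """Fit a direct single-site titration for (Kd, dH, n).

    Fitting is done on log10(Kd); the first injection is excluded from the
    objective (its heat never enters the fit). A c-value below 1 triggers a
    warning that Kd is poorly constrained.
    """
    y_all = experiment.heats
    skip = 1 if discard_first else 0
    if len(y_all) - skip < 6:
        raise ConfigurationError("need at least 6 retained injections")
    y = y_all[skip:]
    cell0 = experiment.cell_species[0][1]
    v0 = experiment.cell_volume
    dh0 = float(np.sum(y_all)) / (cell0 * v0 * 1000.0)
    if dh0 == 0:
        dh0 = -1.0

    def make_predict(fixed_n):
        def predict(p):
            kd = 10.0 ** p[0]
            dh = p[1]
            n = fixed_n if fixed_n is not None else p[2]
            return simulate_direct(experiment, kd, dh, n)[skip:]

        return predict

    predict = make_predict(n_fixed)
    best = None
    for kd0 in _multistart_kd0(cell0):
        x0 = [math.log10(kd0), dh0] + ([] if n_fixed is not None else [1.0])
        lo = [-15.0, -1e4] + ([] if n_fixed is not None else [0.05])
        hi = [2.0, 1e4] + ([] if n_fixed is not None else [20.0])
        try:
            x, se, resid = _fit_ls(predict, y, np.array(x0), (lo, hi))
        except ConvergenceError:
            continue
        cost = float(np.sum(resid**2))
        if best is None or cost < best[0]:
            best = (cost, x, se, resid)
    if best is None:
        raise ConvergenceError("direct ITC fit failed from every start")
    _, x, se, resid = best
    kd = 10.0 ** x[0]
    # 68.3% CI on Kd from the SE of log10(Kd)
    kd_ci = (kd * 10.0 ** (-Z_1SIGMA * se[0]), kd * 10.0 ** (Z_1SIGMA * se[0]))
    n_val = n_fixed if n_fixed is not None else float(x[2])
    n_se = 0.0 if n_fixed is not None else float(se[2])
    if cell0 / kd < 1.0:
        warnings.warn(
            f"c-value {cell0 / kd:.2g} < 1: Kd is poorly constrained",
            stacklevel=2,
        )
    return BindingFitResult(
        kd=kd,
        kd_ci=kd_ci,
        dh=float(x[1]),
        dh_se=float(se[1]),
        n_sites=n_val,
        n_se=n_se,
        residuals=resid,
        model="direct",
    )


def fit_displacement(
    experiment: TitrationExperiment,
    kd_a: float,
    dh_a: float,
    n_fixed: float | None = 1.0,
    discard_first: bool = True,
) -> BindingFitResult:
    """Fit a competitive-replacement titration for the tight ligand B.

    The weak competitor's (Kd_A, dH_A) come from a prior direct fit and are
    held fixed. Stoichiometry defaults to n = 1 (weakly identifiable here).
    Warns when B is not tight relative to A's apparent affinity, i.e. when
    the replacement design adds nothing.
    """
    y_all = experiment.heats
    skip = 1 if discard_first else 0
    y = y_all[skip:]
    cell0 = experiment.cell_species[0][1]
    a0 = experiment.cell_species[1][1]

    def predict(p):
        kd_b = 10.0 ** p[0]
        dh_b = p[1]
        n = n_fixed if n_fixed is not None else p[2]
        return simulate_displacement(experiment, kd_b, dh_b, kd_a, dh_a, n)[skip:]

    best = None
    for kd0 in _multistart_kd0(cell0):
        x0 = [math.log10(kd0), -40.0] + ([] if n_fixed is not None else [1.0])
        lo = [-15.0, -1e4] + ([] if n_fixed is not None else [0.05])
        hi = [2.0, 1e4] + ([] if n_fixed is not None else [20.0])
        try:
            x, se, resid = _fit_ls(predict, y, np.array(x0), (lo, hi))
        except ConvergenceError:
            continue
        cost = float(np.sum(resid**2))
        if best is None or cost < best[0]:
            best = (cost, x, se, resid)
    if best is None:
        raise ConvergenceError("displacement ITC fit failed from every start")
    _, x, se, resid = best
    kd_b = 10.0 ** x[0]
    kd_ci = (kd_b * 10.0 ** (-Z_1SIGMA * se[0]), kd_b * 10.0 ** (Z_1SIGMA * se[0]))
    if kd_b > kd_a * (1.0 + a0 / kd_a) / 10.0:
        warnings.warn(
            "titrant is not tight relative to the competitor's apparent "
            "affinity; displacement design poorly conditioned",
            stacklevel=2,
        )
    return BindingFitResult(
        kd=kd_b,
        kd_ci=kd_ci,
        dh=float(x[1]),
        dh_se=float(se[1]),
        n_sites=n_fixed if n_fixed is not None else float(x[2]),
        n_se=0.0 if n_fixed is not None else float(se[2]),
        residuals=resid,
        model="displacement",
    )


def ddh_report(fits: Sequence[BindingFitResult], labels: Sequence[str] | None = None):
    """Pairwise binding-enthalpy differences with quadrature-propagated errors.

    Returns a DataFrame with one row per ordered pair (i < j):
    ddh = dH_j - dH_i, se = sqrt(se_i^2 + se_j^2).
    """
    import pandas as pd

    if len(fits) < 2:
        raise ConfigurationError("need at least two fits to compare enthalpies")
    if labels is None:
        labels = [f.label or f"fit{i}" for i, f in enumerate(fits)]
    rows = []
    for i in range(len(fits)):
        for j in range(i + 1, len(fits)):
            rows.append(
                {
                    "first": labels[i],
                    "second": labels[j],
                    "ddh_kj_per_mol": fits[j].dh - fits[i].dh,
                    "se_kj_per_mol": math.hypot(fits[i].dh_se, fits[j].dh_se),
                }
            )
    return pd.DataFrame(rows)
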