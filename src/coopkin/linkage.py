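"""Conformational-selection thermodynamic linkage model.

A kinase is modeled as an equilibrium ensemble of conformations (e.g.
active/inactive for Aurora A, open/closing-competent/closed for Abl), each
carrying a relative statistical weight. Ligands bind with state-selective
dissociation constants to one of two non-overlapping sites (orthosteric or
allosteric). Because both ligands read out the same conformational
equilibrium, occupancy at one site shifts the ensemble and thereby the
apparent affinity at the other site: cooperativity without direct contact.

The central quantities are

* the apparent dissociation constant of a state-selective ligand on an
  ensemble, ``1/K_app = sum_s f_s / Kd_s`` (population-weighted association),
* the cooperativity factor ``alpha = K_app(apo) / K_app(partner saturated)``,
  with ``alpha > 1`` positive (partner tightens the probe) and ``alpha < 1``
  negative, identical for either probe by thermodynamic cycle closure,
* the shift-only ceiling ``(1 + K_eq)/K_eq`` on positive cooperativity for a
  probe exclusive to the minor state: once the ensemble is fully shifted
  there is nothing left to gain.

State-exclusive binding is expressed as ``Kd = +inf`` on the excluded state
and handled symbolically (the Boltzmann factor for that species is exactly
zero); saturation is the analytic free-ligand -> infinity limit, never a
large float.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import (
    CannotSaturateError,
    ConfigurationError,
    ConvergenceError,
    InfeasibleCooperativityError,
    UndefinedAffinityError,
)

ORTHOSTERIC = "orthosteric"
ALLOSTERIC = "allosteric"

#: occupancy classes of the two-site lattice
OCCUPANCIES = ("apo", "ortho", "allo", "both")

Site = Literal["orthosteric", "allosteric"]
ProbeKind = Literal["active-exclusive", "inactive-exclusive"]


@dataclass(frozen=True)
class ConformationalEnsemble:
    """Named conformational states with relative statistical weights.

    Weights are normalized so the first state with nonzero weight is 1.
    For a two-state ensemble ``keq`` recovers the scalar equilibrium
    constant weight(state 1)/weight(state 0) — with the ("active",
    "inactive") convention this is [inactive]/[active].
    """

    states: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ConfigurationError("an ensemble needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ConfigurationError("state labels must be unique")
        if len(self.weights) != len(self.states):
            raise ConfigurationError("one weight per state required")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ConfigurationError("weights must be finite and >= 0")
        if not np.any(w > 0):
            raise ConfigurationError("at least one weight must be positive")
        ref = w[w > 0][0]
        object.__setattr__(self, "weights", tuple(w / ref))
        object.__setattr__(self, "states", tuple(self.states))

    @classmethod
    def two_state(
        cls, keq: float, states: Sequence[str] = ("active", "inactive")
    ) -> "ConformationalEnsemble":
        """Build a two-state ensemble from K_eq = [state 1]/[state 0]."""
        if keq < 0:
            raise ConfigurationError("K_eq must be >= 0")
        return cls(states=tuple(states), weights=(1.0, keq))

    @property
    def keq(self) -> float:
        """Two-state equilibrium constant [state 1]/[state 0]."""
        if len(self.states) != 2:
            raise ConfigurationError("keq is defined for two-state ensembles only")
        if self.weights[0] == 0:
            return math.inf
        return self.weights[1] / self.weights[0]

    def fractions(self) -> np.ndarray:
        """State populations of the ligand-free ensemble."""
        w = np.asarray(self.weights)
        return w / w.sum()

    def fraction(self, state: str) -> float:
        return float(self.fractions()[self.states.index(state)])


@dataclass(frozen=True)
class LigandProfile:
    """One ligand at one site: per-state Kd (molar) and optional binding enthalpy.

    ``kd_per_state[s] = +inf`` means the ligand does not bind conformation
    ``s`` at all. Enthalpies are in kJ/mol and only needed for calorimetric
    simulation.
    """

    name: str
    site: Site
    kd_per_state: Mapping[str, float]
    dh_per_state: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.site not in (ORTHOSTERIC, ALLOSTERIC):
            raise ConfigurationError(f"unknown site {self.site!r}")
        kds = dict(self.kd_per_state)
        for s, kd in kds.items():
            if not (kd > 0):  # catches NaN and non-positive
                raise ConfigurationError(f"Kd for state {s!r} must be > 0 (got {kd})")
        if not any(math.isfinite(kd) for kd in kds.values()):
            raise UndefinedAffinityError(
                f"ligand {self.name!r} binds no state (all Kd infinite)"
            )
        object.__setattr__(self, "kd_per_state", kds)
        if self.dh_per_state is not None:
            object.__setattr__(self, "dh_per_state", dict(self.dh_per_state))

    def kd_array(self, states: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.kd_per_state[s] for s in states], dtype=float)
        except KeyError as exc:
            raise ConfigurationError(
                f"ligand {self.name!r} has no Kd for state {exc.args[0]!r}"
            ) from exc

    def dh_array(self, states: Sequence[str]) -> np.ndarray:
        if self.dh_per_state is None:
            raise ConfigurationError(f"ligand {self.name!r} carries no enthalpies")
        return np.array([self.dh_per_state.get(s, 0.0) for s in states], dtype=float)


@dataclass(frozen=True)
class DoubleDrugScheme:
    """Ensemble + orthosteric ligand + allosteric ligand: the 2-site lattice.

    ``catalytic_weight_per_state`` is the intrinsic activity of each
    conformation when the orthosteric site is drug-free (1 = fully active).
    ``coupling_per_state`` is an optional direct ternary interaction factor
    multiplying the statistical weight of the doubly-bound species in that
    state (1 = pure conformational linkage; > 1 means extra affinity in the
    ternary complex beyond what the equilibrium shift provides).
    """

    ensemble: ConformationalEnsemble
    ortho: LigandProfile
    allo: LigandProfile
    catalytic_weight_per_state: Mapping[str, float] = field(default_factory=dict)
    coupling_per_state: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ortho.site != ORTHOSTERIC or self.allo.site != ALLOSTERIC:
            raise ConfigurationError(
                "scheme requires one orthosteric and one allosteric ligand"
            )
        for lig in (self.ortho, self.allo):
            lig.kd_array(self.ensemble.states)  # validates state labels
        cw = {s: float(self.catalytic_weight_per_state.get(s, 0.0))
              for s in self.ensemble.states}
        for s, v in cw.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"catalytic weight for {s!r} outside [0,1]")
        cp = {s: float(self.coupling_per_state.get(s, 1.0))
              for s in self.ensemble.states}
        for s, v in cp.items():
            if not v > 0:
                raise ConfigurationError(f"coupling factor for {s!r} must be > 0")
        object.__setattr__(self, "catalytic_weight_per_state", cw)
        object.__setattr__(self, "coupling_per_state", cp)

    def catalytic_weights(self) -> np.ndarray:
        return np.array(
            [self.catalytic_weight_per_state[s] for s in self.ensemble.states]
        )

    def couplings(self) -> np.ndarray:
        return np.array([self.coupling_per_state[s] for s in self.ensemble.states])


@dataclass(frozen=True)
class SpeciesPopulation:
    """Molar fractions of every (conformation, occupancy) enzyme species."""

    states: tuple[str, ...]
    #: fractions[i, j]: state i, occupancy OCCUPANCIES[j]
    fractions: np.ndarray
    free_ortho: float
    free_allo: float

    def fraction(self, state: str, occupancy: str) -> float:
        return float(
            self.fractions[self.states.index(state), OCCUPANCIES.index(occupancy)]
        )

    def state_fractions(self) -> np.ndarray:
        return self.fractions.sum(axis=1)

    def bound_fraction(self, site: Site) -> float:
        """Fraction of enzyme with the given site occupied."""
        if site == ORTHOSTERIC:
            cols = [1, 3]
        else:
            cols = [2, 3]
        return float(self.fractions[:, cols].sum())

    def ortho_free_site_fractions(self) -> np.ndarray:
        """Per-state fraction with the orthosteric site empty (apo + allo-only)."""
        return self.fractions[:, [0, 2]].sum(axis=1)


def _binding_factor(kd: np.ndarray, free: float) -> np.ndarray:
    """Per-state Boltzmann factor free/Kd with Kd=+inf handled as exactly 0."""
    out = np.zeros_like(kd)
    finite = np.isfinite(kd)
    out[finite] = free / kd[finite]
    return out


def species_fractions(
    scheme: DoubleDrugScheme, free_ortho: float, free_allo: float
) -> SpeciesPopulation:
    """Equilibrium species fractions at given *free* ligand concentrations.

    The statistical weight of species (state s, occupancy o) is
    ``w_s * (free_O/Kd_O,s)^[O bound] * (free_A/Kd_A,s)^[A bound] * c_s^[both]``
    and fractions are these weights over the grand partition function.
    """
    if free_ortho < 0 or free_allo < 0:
        raise ValueError("free concentrations must be >= 0")
    states = scheme.ensemble.states
    w = np.asarray(scheme.ensemble.weights)
    xo = _binding_factor(scheme.ortho.kd_array(states), free_ortho)
    xa = _binding_factor(scheme.allo.kd_array(states), free_allo)
    c = scheme.couplings()
    lattice = np.stack([w, w * xo, w * xa, w * xo * xa * c], axis=1)
    z = lattice.sum()
    return SpeciesPopulation(
        states=states,
        fractions=lattice / z,
        free_ortho=float(free_ortho),
        free_allo=float(free_allo),
    )


def _shift_factors(ligand: LigandProfile, states: Sequence[str], free: float) -> np.ndarray:
    """Weight rescaling (1 + free/Kd_s); free=inf is the analytic limit 1/Kd_s
    (up to the overall normalization) with excluded states dropping to 0."""
    kd = ligand.kd_array(states)
    if math.isinf(free):
        out = np.zeros_like(kd)
        finite = np.isfinite(kd)
        out[finite] = 1.0 / kd[finite]
        return out
    return 1.0 + _binding_factor(kd, free)


def apparent_kd(
    ensemble: ConformationalEnsemble,
    ligand: LigandProfile,
    background: tuple[LigandProfile, float] | None = None,
) -> float:
    """Apparent dissociation constant of a state-selective ligand.

    ``1/K_app = sum_s f_s / Kd_s`` over the populations ``f_s`` of the
    ligand-free ensemble; a background ligand at the other site first
    rescales the weights by ``(1 + free_bg/Kd_bg,s)`` (``free_bg = inf``
    takes the saturation limit analytically).
    """
    w = np.asarray(ensemble.weights)
    if background is not None:
        bg, free_bg = background
        if bg.site == ligand.site:
            raise ConfigurationError("background ligand must occupy the other site")
        w = w * _shift_factors(bg, ensemble.states, free_bg)
        if not np.any(w > 0):
            raise CannotSaturateError(
                f"background ligand {bg.name!r} binds no populated state"
            )
    f = w / w.sum()
    kd = ligand.kd_array(ensemble.states)
    inv = np.sum(f[np.isfinite(kd)] / kd[np.isfinite(kd)])
    if inv == 0:
        raise UndefinedAffinityError(
            f"ligand {ligand.name!r} binds no populated state"
        )
    return float(1.0 / inv)


def shifted_ensemble(
    ensemble: ConformationalEnsemble, ligand: LigandProfile, free: float
) -> ConformationalEnsemble:
    """Ensemble re-weighted by ligand occupancy: w'_s = w_s (1 + free/Kd_s).

    At saturation (``free = math.inf``) a two-state K_eq becomes K_eq * s
    with s = Kd(state 0)/Kd(state 1), the selectivity of the ligand.
    """
    if free < 0:
        raise ValueError("free concentration must be >= 0")
    w = np.asarray(ensemble.weights) * _shift_factors(ligand, ensemble.states, free)
    if not np.any(w > 0):
        raise CannotSaturateError(
            f"ligand {ligand.name!r} binds no state; saturated ensemble is empty"
        )
    return ConformationalEnsemble(states=ensemble.states, weights=tuple(w))


def cooperativity_factor(scheme: DoubleDrugScheme, probe: str = "allo") -> float:
    """Fold-change alpha = K_app(probe, apo) / K_app(probe, partner saturated).

    alpha > 1: the partner tightens the probe (positive cooperativity);
    alpha < 1: weakening. By closure of the thermodynamic cycle the value is
    identical for probe="ortho" and probe="allo".
    """
    if probe == "ortho":
        probe_lig, partner = scheme.ortho, scheme.allo
    elif probe == "allo":
        probe_lig, partner = scheme.allo, scheme.ortho
    else:
        raise ValueError("probe must be 'ortho' or 'allo'")
    states = scheme.ensemble.states
    k_apo = apparent_kd(scheme.ensemble, probe_lig)

    # partner-saturated weights: w_s / Kd_partner,s (excluded states vanish)
    w_sat = np.asarray(scheme.ensemble.weights) * _shift_factors(
        partner, states, math.inf
    )
    if not np.any(w_sat > 0):
        raise CannotSaturateError(f"partner {partner.name!r} binds no populated state")
    f_sat = w_sat / w_sat.sum()
    # on a partner-bound enzyme the probe's effective Kd is Kd_s / c_s
    kd = probe_lig.kd_array(states)
    c = scheme.couplings()
    finite = np.isfinite(kd)
    inv_sat = np.sum(f_sat[finite] * c[finite] / kd[finite])
    if inv_sat == 0:
        return 0.0  # ternary complex inaccessible: complete negative cooperativity
    return float(k_apo * inv_sat)


def max_cooperativity_ceiling(keq: float) -> float:
    """Supremum of alpha achievable by pure equilibrium shift in two states.

    For a probe exclusive to the minor state (population K_eq/(1+K_eq) with
    the [minor]/[major] convention) and a partner infinitely selective for
    that state, alpha -> (1 + K_eq)/K_eq. Strictly decreasing in K_eq: the
    further the apo ensemble already sits in the probe's state, the less a
    partner can add.
    """
    if not keq > 0:
        raise ValueError("K_eq must be > 0")
    return (1.0 + keq) / keq


def solve_selectivity(
    alpha_observed: float, keq: float, probe_profile: ProbeKind
) -> float:
    """Invert the two-state linkage model for the partner's selectivity s.

    ``s = Kd_partner(active)/Kd_partner(inactive)`` is the fold-preference of
    the partner for the inactive state; saturation multiplies K_eq by s.
    ``alpha_observed`` is the fold magnitude: for an active-exclusive probe
    it is the observed *weakening* fold F = (1 + K_eq s)/(1 + K_eq); for an
    inactive-exclusive probe the observed *tightening* fold
    alpha = (1 + K_eq) s / (1 + K_eq s), which cannot exceed
    ``max_cooperativity_ceiling(keq)``.
    """
    if not keq > 0:
        raise ValueError("K_eq must be > 0")
    if not alpha_observed > 0:
        raise ValueError("observed fold must be > 0")
    if probe_profile == "active-exclusive":
        s = (alpha_observed * (1.0 + keq) - 1.0) / keq
        if s <= 0:
            raise InfeasibleCooperativityError(
                f"weakening fold {alpha_observed} below the feasible floor "
                f"{1.0 / (1.0 + keq):.4g} for an active-exclusive probe"
            )
        return s
    if probe_profile == "inactive-exclusive":
        denom = 1.0 + keq - alpha_observed * keq
        if denom <= 0:
            raise InfeasibleCooperativityError(
                f"tightening fold {alpha_observed} reaches or exceeds the "
                f"shift-only ceiling {max_cooperativity_ceiling(keq):.4g}; "
                "extra affinity to the partner-bound state is required"
            )
        return alpha_observed / denom
    raise ValueError("probe_profile must be 'active-exclusive' or 'inactive-exclusive'")


def solve_free_concentrations(
    scheme: DoubleDrugScheme,
    total_enzyme: float,
    total_ortho: float,
    total_allo: float,
    rtol: float = 1e-12,
    max_iter: int = 200,
) -> SpeciesPopulation:
    """Free ligand concentrations under mass balance with enzyme depletion.

    Solves the coupled conservation equations
    ``free_X + E_t * bound_fraction_X(free_O, free_A) = total_X`` for both
    ligands by nested bracketed root-finding on [0, total]; each residual is
    monotone in its own free concentration so the brackets are guaranteed.
    """
    if min(total_enzyme, total_ortho, total_allo) < 0:
        raise ValueError("totals must be >= 0")

    def free_ortho_given(fa: float) -> float:
        if total_ortho == 0:
            return 0.0
        if total_enzyme == 0:
            return total_ortho

        def g(fo: float) -> float:
            pop = species_fractions(scheme, fo, fa)
            return fo + total_enzyme * pop.bound_fraction(ORTHOSTERIC) - total_ortho

        if g(total_ortho) <= 0:
            return total_ortho
        return brentq(g, 0.0, total_ortho, xtol=1e-300, rtol=8.9e-16,
                      maxiter=max_iter)

    if total_allo == 0:
        fa_star = 0.0
    elif total_enzyme == 0:
        fa_star = total_allo
    else:

        def h(fa: float) -> float:
            fo = free_ortho_given(fa)
            pop = species_fractions(scheme, fo, fa)
            return fa + total_enzyme * pop.bound_fraction(ALLOSTERIC) - total_allo

        if h(total_allo) <= 0:
            fa_star = total_allo
        else:
            fa_star = brentq(h, 0.0, total_allo, xtol=1e-300, rtol=8.9e-16,
                             maxiter=max_iter)
    fo_star = free_ortho_given(fa_star)
    pop = species_fractions(scheme, fo_star, fa_star)

    for total, free, site in (
        (total_ortho, fo_star, ORTHOSTERIC),
        (total_allo, fa_star, ALLOSTERIC),
    ):
        if total > 0:
            resid = abs(free + total_enzyme * pop.bound_fraction(site) - total)
            if resid > 1e-8 * total:
                raise ConvergenceError(
                    f"mass balance for {site} ligand off by {resid:.3g} M "
                    f"(total {total:.3g} M)"
                )
    return pop
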