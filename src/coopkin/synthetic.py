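"""Seedable generators emulating the wet-lab instruments.

Every experiment type consumed by the fitting modules can be produced from
a ground-truth scheme: Wiseman-type ITC injection heats (additive Gaussian
noise on heats), Morrison-regime FRET curves at 10 nM enzyme, and
4PL-shaped inhibition curves and checkerboard grids (multiplicative noise
on rates, reflecting replicate scatter). Noiseless output equals the
forward models exactly; identical seeds give bit-identical output
(NumPy PCG64 generator, platform-stable).

Default designs mirror the calorimetric and assay conditions of the study
this package models: 190 uL cell, 2 uL injections, 20 uM cell / 150 uM
syringe for Aurora A monobody titrations, 10 nM enzyme for FRET, 20 nM
enzyme for activity assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .activity import DoseResponseRecord, predicted_activity
from .errors import ConfigurationError
from .fret import FretCurve
from .itc import TitrationExperiment, simulate_scheme
from .linkage import solve_free_concentrations
from .presets import GroundTruth, make_preset, preset_names  # noqa: F401 — re-export

#: default ITC design (cell volume L, injection volume L, injection count)
ITC_CELL_VOLUME = 190e-6
ITC_INJECTION_VOLUME = 2e-6
ITC_N_INJECTIONS = 25


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: kind, magnitude (fraction of signal scale), RNG seed."""

    kind: str = "additive_gaussian"
    sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "multiplicative_gaussian"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator | None = None
              ) -> np.ndarray:
        """Corrupt an array; for additive noise the scale is max |value|."""
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        if rng is None:
            rng = self.rng()
        if self.kind == "additive_gaussian":
            scale = float(np.max(np.abs(values))) or 1.0
            return values + rng.normal(0.0, self.sigma * scale, values.shape)
        return values * (1.0 + rng.normal(0.0, self.sigma, values.shape))


def gen_itc(
    truth: GroundTruth,
    noise: NoiseSpec,
    titrant: str = "allo",
    cell_enzyme: float = 20e-6,
    syringe_conc: float = 150e-6,
    background_conc: float = 0.0,
    n_injections: int = ITC_N_INJECTIONS,
    injection_volume: float = ITC_INJECTION_VOLUME,
    cell_volume: float = ITC_CELL_VOLUME,
) -> TitrationExperiment:
    """Simulate a (optionally pre-incubated) direct titration of one ligand.

    ``titrant`` selects which of the scheme's ligands is in the syringe;
    ``background_conc`` pre-loads the other ligand in the cell, emulating
    the pre-incubation experiments used to measure cooperativity.
    """
    scheme = truth.scheme
    if titrant == "allo":
        syr, bg = scheme.allo.name, scheme.ortho.name
    elif titrant == "ortho":
        syr, bg = scheme.ortho.name, scheme.allo.name
    else:
        raise ConfigurationError("titrant must be 'ortho' or 'allo'")
    cell = [("enzyme", cell_enzyme)]
    if background_conc > 0:
        cell.append((bg, background_conc))
    exp = TitrationExperiment.design(
        cell_volume=cell_volume,
        cell_species=cell,
        syringe_species=(syr, syringe_conc),
        injection_volumes=[injection_volume] * n_injections,
    )
    heats = simulate_scheme(exp, scheme)
    return exp.with_heats(noise.apply(heats))


def gen_fret(
    truth: GroundTruth,
    noise: NoiseSpec,
    concs: Sequence[float] | None = None,
    enzyme_total: float = 10e-9,
    allo_conc: float = 0.0,
    f0: float = 1.0,
    amplitude: float = 4.0,
    replicates: int = 1,
) -> list[FretCurve]:
    """Simulate FRET titrations of the orthosteric ligand at 10 nM enzyme.

    Fluorescence tracks the orthosteric-site bound fraction under full mass
    balance (ligand depletion included); ``allo_conc`` fixes a background
    allosteric drug (e.g. 200 nM asciminib). Noise is applied per replicate
    from one generator so replicate curves are independent but the call is
    deterministic given the seed.
    """
    scheme = truth.scheme
    if concs is None:
        concs = np.concatenate([[0.0], np.geomspace(0.2e-9, 2e-6, 17)])
    concs = np.asarray(concs, dtype=float)
    bound = np.empty_like(concs)
    for i, c in enumerate(concs):
        pop = solve_free_concentrations(scheme, enzyme_total, c, allo_conc)
        bound[i] = pop.bound_fraction("orthosteric")
    signal = f0 + amplitude * bound
    rng = noise.rng()
    return [
        FretCurve(
            ligand_conc=concs.copy(),
            fluorescence=noise.apply(signal, rng),
            enzyme_total=enzyme_total,
        )
        for _ in range(replicates)
    ]


def gen_dose(
    truth: GroundTruth,
    noise: NoiseSpec,
    concs: Sequence[float] | None = None,
    allo_conc: float = 0.0,
    kobs_uninhibited: float = 0.5,
    replicates: int = 1,
) -> DoseResponseRecord:
    """Simulate an orthosteric-inhibitor dose-response at fixed co-drug.

    Rates are ``k_obs = k_apo * predicted_activity``; replicate rates are
    averaged after multiplicative noise, mirroring the n = 2 mean +/- s.d.m.
    structure of plate-based assays.
    """
    scheme = truth.scheme
    if concs is None:
        concs = np.concatenate([[0.0], np.geomspace(1e-10, 1e-5, 11)])
    concs = np.asarray(concs, dtype=float)
    act = np.array([predicted_activity(scheme, c, allo_conc) for c in concs])
    rates = kobs_uninhibited * act
    rng = noise.rng()
    reps = np.stack([noise.apply(rates, rng) for _ in range(replicates)])
    return DoseResponseRecord(
        inhibitor_conc=concs,
        k_obs=np.maximum(reps.mean(axis=0), 0.0),
        enzyme=truth.name,
        co_inhibitor_conc=float(allo_conc),
    )


def gen_grid(
    truth: GroundTruth,
    noise: NoiseSpec,
    ortho_concs: Sequence[float],
    allo_concs: Sequence[float],
    kobs_uninhibited: float = 0.5,
) -> np.ndarray:
    """Simulate a checkerboard k_obs matrix, shape (n_allo, n_ortho)."""
    scheme = truth.scheme
    act = np.array(
        [
            [predicted_activity(scheme, o, a) for o in ortho_concs]
            for a in allo_concs
        ]
    )
    return np.maximum(noise.apply(kobs_uninhibited * act), 0.0)


def recovery_harness(
    truth: GroundTruth,
    generator: Callable[[GroundTruth, NoiseSpec], object],
    fitter: Callable[[object], dict[str, tuple[float, float | None]]],
    true_values: dict[str, float],
    n_seeds: int = 100,
    sigma: float = 0.01,
    kind: str = "additive_gaussian",
    base_seed: int = 12345,
    max_failure_rate: float = 0.2,
) -> dict:
    """Repeated generate -> fit cycles; per-parameter bias, RMSE, coverage.

    ``fitter`` maps the generated data to ``{param: (estimate, se_or_None)}``.
    Coverage counts nominal 95% (+/- 1.96 se) intervals containing the truth.
    Raises when more than ``max_failure_rate`` of the fits fail.
    """
    if n_seeds < 10:
        raise ConfigurationError("recovery harness needs n_seeds >= 10")
    estimates: dict[str, list[float]] = {k: [] for k in true_values}
    covered: dict[str, int] = {k: 0 for k in true_values}
    with_se: dict[str, int] = {k: 0 for k in true_values}
    failures = 0
    for i in range(n_seeds):
        spec = NoiseSpec(kind=kind, sigma=sigma, seed=base_seed + i)
        try:
            result = fitter(generator(truth, spec))
        except Exception:  # noqa: BLE001 — fit failures are the measured quantity
            failures += 1
            continue
        for k in true_values:
            est, se = result[k]
            estimates[k].append(est)
            if se is not None and se > 0:
                with_se[k] += 1
                if abs(est - true_values[k]) <= 1.96 * se:
                    covered[k] += 1
    if failures > max_failure_rate * n_seeds:
        raise ConfigurationError(
            f"fitter failed {failures}/{n_seeds} times (> {max_failure_rate:.0%})"
        )
    report: dict = {
        "preset": truth.name,
        "sigma": sigma,
        "n_seeds": n_seeds,
        "n_failures": failures,
        "parameters": {},
    }
    for k, tv in true_values.items():
        est = np.asarray(estimates[k])
        report["parameters"][k] = {
            "true": tv,
            "median": float(np.median(est)),
            "bias_rel": float((est.mean() - tv) / tv) if tv != 0 else float(est.mean()),
            "rmse_rel": float(np.sqrt(np.mean((est - tv) ** 2)) / abs(tv))
            if tv != 0
            else float(np.sqrt(np.mean(est**2))),
            "ci95_coverage": (covered[k] / with_se[k]) if with_se[k] else None,
        }
    return report
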