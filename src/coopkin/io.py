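"""File formats: scheme JSON (validated), CSV tables for every experiment.

Units at the file boundary follow the instrument conventions (uL, uJ, nM);
everything in memory is SI (L, J, M). All schemas are plain CSV/JSON so
synthetic datasets diff cleanly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .activity import DoseResponseRecord
from .errors import ConfigurationError
from .fret import FretCurve
from .itc import TitrationExperiment
from .linkage import ConformationalEnsemble, DoubleDrugScheme, LigandProfile

_INF_TOKENS = {"inf", "Infinity", "+inf", None}


class LigandModel(BaseModel):
    name: str
    site: Literal["orthosteric", "allosteric"]
    kd_per_state: dict[str, float | None]
    dh_per_state: dict[str, float] | None = None

    @field_validator("kd_per_state", mode="before")
    @classmethod
    def _parse_inf(cls, v):
        out = {}
        for k, x in v.items():
            out[k] = math.inf if x in _INF_TOKENS or x == math.inf else float(x)
        return out


class EnsembleModel(BaseModel):
    states: list[str] = Field(min_length=2)
    weights: list[float]


class SchemeModel(BaseModel):
    """JSON schema for a double-drugging scheme config."""

    ensemble: EnsembleModel
    ligands: list[LigandModel] = Field(min_length=2, max_length=2)
    catalytic_weights: dict[str, float] = Field(default_factory=dict)
    coupling: dict[str, float] = Field(default_factory=dict)


def scheme_from_model(model: SchemeModel) -> DoubleDrugScheme:
    ens = ConformationalEnsemble(
        states=tuple(model.ensemble.states), weights=tuple(model.ensemble.weights)
    )
    profiles = {
        lig.site: LigandProfile(
            name=lig.name,
            site=lig.site,
            kd_per_state={k: (math.inf if v is None else v)
                          for k, v in lig.kd_per_state.items()},
            dh_per_state=lig.dh_per_state,
        )
        for lig in model.ligands
    }
    if set(profiles) != {"orthosteric", "allosteric"}:
        raise ConfigurationError("need exactly one ligand per site")
    return DoubleDrugScheme(
        ensemble=ens,
        ortho=profiles["orthosteric"],
        allo=profiles["allosteric"],
        catalytic_weight_per_state=model.catalytic_weights,
        coupling_per_state=model.coupling,
    )


def load_scheme(path: str | Path) -> DoubleDrugScheme:
    """Read and validate a scheme config (JSON)."""
    data = json.loads(Path(path).read_text())
    return scheme_from_model(SchemeModel.model_validate(data))


def dump_scheme(scheme: DoubleDrugScheme, path: str | Path) -> None:
    def kd_json(kd: Mapping[str, float]) -> dict:
        return {k: (None if math.isinf(v) else v) for k, v in kd.items()}

    data = {
        "ensemble": {
            "states": list(scheme.ensemble.states),
            "weights": list(scheme.ensemble.weights),
        },
        "ligands": [
            {
                "name": lig.name,
                "site": lig.site,
                "kd_per_state": kd_json(lig.kd_per_state),
                "dh_per_state": dict(lig.dh_per_state)
                if lig.dh_per_state is not None
                else None,
            }
            for lig in (scheme.ortho, scheme.allo)
        ],
        "catalytic_weights": dict(scheme.catalytic_weight_per_state),
        "coupling": dict(scheme.coupling_per_state),
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_itc_csv(experiment: TitrationExperiment, path: str | Path) -> None:
    """itc_injections.csv: injection_index, volume_uL, heat_uJ."""
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, len(experiment.injections) + 1),
            "volume_uL": experiment.volumes * 1e6,
            "heat_uJ": experiment.heats * 1e6,
        }
    )
    df.to_csv(path, index=False)


def read_itc_csv(
    path: str | Path,
    cell_volume: float,
    cell_species: Sequence[tuple[str, float]],
    syringe_species: tuple[str, float],
    temperature: float = 298.15,
) -> TitrationExperiment:
    df = pd.read_csv(path)
    required = {"injection_index", "volume_uL", "heat_uJ"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"ITC CSV needs columns {sorted(required)}")
    df = df.sort_values("injection_index")
    return TitrationExperiment(
        cell_volume=cell_volume,
        cell_species=list(cell_species),
        syringe_species=tuple(syringe_species),
        injections=[(v * 1e-6, q * 1e-6)
                    for v, q in zip(df["volume_uL"], df["heat_uJ"])],
        temperature=temperature,
    )


def write_fret_csv(curves: Sequence[FretCurve], path: str | Path) -> None:
    """fret_curve.csv: conc_nM, fluorescence_au, replicate."""
    frames = [
        pd.DataFrame(
            {
                "conc_nM": c.ligand_conc * 1e9,
                "fluorescence_au": c.fluorescence,
                "replicate": i + 1,
            }
        )
        for i, c in enumerate(curves)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fret_csv(path: str | Path, enzyme_total: float = 10e-9) -> list[FretCurve]:
    df = pd.read_csv(path)
    required = {"conc_nM", "fluorescence_au", "replicate"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"FRET CSV needs columns {sorted(required)}")
    return [
        FretCurve(
            ligand_conc=g["conc_nM"].to_numpy() * 1e-9,
            fluorescence=g["fluorescence_au"].to_numpy(),
            enzyme_total=enzyme_total,
        )
        for _, g in df.groupby("replicate")
    ]


def write_dose_csv(record: DoseResponseRecord, path: str | Path) -> None:
    """dose_response.csv: conc_nM, kobs_per_s, replicate, co_inhibitor_nM."""
    pd.DataFrame(
        {
            "conc_nM": record.inhibitor_conc * 1e9,
            "kobs_per_s": record.k_obs,
            "replicate": 1,
            "co_inhibitor_nM": record.co_inhibitor_conc * 1e9,
        }
    ).to_csv(path, index=False)


def read_dose_csv(path: str | Path) -> list[DoseResponseRecord]:
    """One record per co-inhibitor level; replicates averaged."""
    df = pd.read_csv(path)
    required = {"conc_nM", "kobs_per_s", "replicate", "co_inhibitor_nM"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"dose CSV needs columns {sorted(required)}")
    out = []
    for co, g in df.groupby("co_inhibitor_nM"):
        mean = g.groupby("conc_nM")["kobs_per_s"].mean().reset_index()
        out.append(
            DoseResponseRecord(
                inhibitor_conc=mean["conc_nM"].to_numpy() * 1e-9,
                k_obs=mean["kobs_per_s"].to_numpy(),
                co_inhibitor_conc=float(co) * 1e-9,
            )
        )
    return out


def write_grid_csv(
    kobs: np.ndarray,
    ortho_concs: Sequence[float],
    allo_concs: Sequence[float],
    path: str | Path,
) -> None:
    """grid.csv (long format): allo_conc_nM, ortho_conc_nM, kobs_per_s."""
    rows = []
    for i, a in enumerate(allo_concs):
        for j, o in enumerate(ortho_concs):
            rows.append(
                {"allo_conc_nM": a * 1e9, "ortho_conc_nM": o * 1e9,
                 "kobs_per_s": kobs[i, j]}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_grid_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (ortho_concs M, allo_concs M, kobs matrix)."""
    df = pd.read_csv(path)
    required = {"allo_conc_nM", "ortho_conc_nM", "kobs_per_s"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"grid CSV needs columns {sorted(required)}")
    pivot = df.pivot_table(
        index="allo_conc_nM", columns="ortho_conc_nM", values="kobs_per_s"
    ).sort_index().sort_index(axis=1)
    return (
        pivot.columns.to_numpy() * 1e-9,
        pivot.index.to_numpy() * 1e-9,
        pivot.to_numpy(),
    )
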