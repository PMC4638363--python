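"""Tabular and JSON input/output for the LIE workflow.

CSV dialect: comma-separated, mandatory header, '.' decimal separator,
UTF-8.  Energies are kJ/mol, distances nm, concentrations μM in files.

Energy tables carry one row per MD simulation (ligand_id, pose_id, the four
averaged interaction energies); per-residue decompositions live in a
separate long-format table keyed by (ligand_id, pose_id, residue_label).
Calibrated models round-trip through JSON.
"""

from __future__ import annotations

import json

import pandas as pd

from .lie import (
    CalibrationResult,
    LIEParameters,
    LigandEnergyProfile,
    SimulationEnergies,
)

__all__ = [
    "InputFormatError",
    "read_profiles",
    "write_energies_csv",
    "write_decomposition_csv",
    "write_observations_csv",
    "model_to_json",
    "model_from_json",
]

ENERGY_COLUMNS = [
    "ligand_id",
    "pose_id",
    "v_vdw_protein",
    "v_ele_protein",
    "v_vdw_water",
    "v_ele_water",
]
DECOMPOSITION_COLUMNS = ["ligand_id", "pose_id", "residue_label", "v_ele", "v_vdw"]
OBSERVATION_COLUMNS = ["compound_id", "dg_kjmol"]


class InputFormatError(ValueError):
    """Raised when an input table does not match the documented dialect."""


def _require_columns(frame: pd.DataFrame, columns, source) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise InputFormatError(f"{source}: missing columns {missing}")


def read_profiles(
    energies_csv,
    observations_csv=None,
    decomposition_csv=None,
) -> list[LigandEnergyProfile]:
    """Assemble ligand profiles from the energy table and optional extras.

    Row order within a ligand defines pose order (used for deterministic
    tie-breaking downstream).
    """
    energies = pd.read_csv(energies_csv, float_precision="round_trip")
    _require_columns(energies, ENERGY_COLUMNS, energies_csv)

    decomposition: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
    if decomposition_csv is not None:
        decomp = pd.read_csv(decomposition_csv, float_precision="round_trip")
        _require_columns(decomp, DECOMPOSITION_COLUMNS, decomposition_csv)
        for row in decomp.itertuples(index=False):
            key = (str(row.ligand_id), str(row.pose_id))
            decomposition.setdefault(key, {})[str(row.residue_label)] = (
                float(row.v_ele),
                float(row.v_vdw),
            )

    observations: dict[str, float] = {}
    if observations_csv is not None:
        obs = pd.read_csv(observations_csv, float_precision="round_trip")
        _require_columns(obs, OBSERVATION_COLUMNS, observations_csv)
        observations = {
            str(r.compound_id): float(r.dg_kjmol) for r in obs.itertuples(index=False)
        }

    profiles = []
    for ligand_id, group in energies.groupby("ligand_id", sort=False):
        sims = []
        for row in group.itertuples(index=False):
            key = (str(ligand_id), str(row.pose_id))
            sims.append(
                SimulationEnergies(
                    ligand_id=str(ligand_id),
                    pose_id=str(row.pose_id),
                    v_vdw_protein=float(row.v_vdw_protein),
                    v_ele_protein=float(row.v_ele_protein),
                    v_vdw_water=float(row.v_vdw_water),
                    v_ele_water=float(row.v_ele_water),
                    residue_decomposition=decomposition.get(key),
                )
            )
        profiles.append(
            LigandEnergyProfile(
                ligand_id=str(ligand_id),
                simulations=sims,
                dg_obs=observations.get(str(ligand_id)),
            )
        )
    if not profiles:
        raise InputFormatError(f"{energies_csv}: no simulation rows found")
    return profiles


def write_energies_csv(profiles, path) -> None:
    rows = [
        {
            "ligand_id": s.ligand_id,
            "pose_id": s.pose_id,
            "v_vdw_protein": s.v_vdw_protein,
            "v_ele_protein": s.v_ele_protein,
            "v_vdw_water": s.v_vdw_water,
            "v_ele_water": s.v_ele_water,
        }
        for p in profiles
        for s in p.simulations
    ]
    pd.DataFrame(rows, columns=ENERGY_COLUMNS).to_csv(path, index=False)


def write_decomposition_csv(profiles, path) -> None:
    rows = []
    for p in profiles:
        for s in p.simulations:
            if s.residue_decomposition is None:
                continue
            for label, (ele, vdw) in s.residue_decomposition.items():
                rows.append(
                    {
                        "ligand_id": s.ligand_id,
                        "pose_id": s.pose_id,
                        "residue_label": label,
                        "v_ele": ele,
                        "v_vdw": vdw,
                    }
                )
    pd.DataFrame(rows, columns=DECOMPOSITION_COLUMNS).to_csv(path, index=False)


def write_observations_csv(profiles, path) -> None:
    rows = [
        {"compound_id": p.ligand_id, "dg_kjmol": p.dg_obs}
        for p in profiles
        if p.dg_obs is not None
    ]
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def model_to_json(result: CalibrationResult, path=None) -> str:
    """Serialize a calibrated model (parameters, metrics, pose weights)."""
    weights: dict[str, dict[str, float]] = {}
    for (ligand_id, pose_id), w in result.weights.items():
        weights.setdefault(ligand_id, {})[pose_id] = w
    payload = {
        "alpha": result.parameters.alpha,
        "beta": result.parameters.beta,
        "gamma": result.parameters.gamma,
        "temperature": result.parameters.temperature,
        "max_poses": result.max_poses,
        "metrics": {
            "rmse": result.rmse,
            "r2": result.r2,
            "sdep_cv": result.sdep_cv,
            "q2": result.q2,
            "iterations": result.iterations,
            "converged": result.converged,
        },
        "sdep_table": {str(k): v for k, v in result.sdep_table.items()},
        "weights": weights,
        "dg_calc": result.dg_calc,
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as handle:
            handle.write(text + "\n")
    return text


def model_from_json(source) -> CalibrationResult:
    """Load a calibrated model written by :func:`model_to_json`."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            with open(source) as handle:
                payload = json.load(handle)
    try:
        params = LIEParameters(
            payload["alpha"], payload["beta"], payload["gamma"], payload["temperature"]
        )
        metrics = payload.get("metrics", {})
        weights = {
            (ligand, pose): w
            for ligand, poses in payload.get("weights", {}).items()
            for pose, w in poses.items()
        }
        return CalibrationResult(
            parameters=params,
            max_poses=int(payload["max_poses"]),
            weights=weights,
            dg_calc=payload.get("dg_calc", {}),
            rmse=metrics.get("rmse", float("nan")),
            r2=metrics.get("r2", float("nan")),
            iterations=metrics.get("iterations", 0),
            converged=metrics.get("converged", True),
            sdep_cv=metrics.get("sdep_cv"),
            q2=metrics.get("q2"),
            sdep_table={int(k): v for k, v in payload.get("sdep_table", {}).items()},
        )
    except KeyError as exc:
        raise InputFormatError(f"model JSON missing field {exc}") from exc
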