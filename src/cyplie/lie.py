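"""Iterative Boltzmann-weighted linear interaction energy (LIE) models.

The LIE ansatz estimates the binding free energy of a ligand from the
difference in its ensemble-averaged nonbonded interaction energies with the
surroundings between the protein-bound and the free (water) state:

    dG_i = alpha * dV_vdw_i + beta * dV_ele_i + gamma            (per pose)

For flexible targets such as cytochrome P450s a ligand samples several
binding modes; each mode is simulated separately and the per-simulation
estimates are combined with Boltzmann weights

    W_i = exp(-dG_i / RT) / sum_j exp(-dG_j / RT)

so that the ligand-level prediction is the weight-averaged interaction
energy model dG = alpha * sum_i W_i dV_vdw_i + beta * sum_i W_i dV_ele_i.
Because the weights depend on (alpha, beta) and vice versa, calibration is a
self-consistent iteration: fit the parameters by least squares with the
current weights, recompute per-pose free energies, re-rank and re-weight,
and repeat until the parameters stop moving.  The number of poses retained
per ligand (the lowest-dG ones) is itself selected by leave-one-out
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .affinity import DEFAULT_TEMPERATURE, GAS_CONSTANT_KJ

__all__ = [
    "SimulationEnergies",
    "LIEParameters",
    "LigandEnergyProfile",
    "CalibrationResult",
    "RegressionMetrics",
    "SingularFitError",
    "simulation_dg",
    "boltzmann_weights",
    "ligand_dg",
    "calibrate",
    "loo_cv",
    "select_pose_count",
    "regression_metrics",
    "pearson_r2",
]


class SingularFitError(np.linalg.LinAlgError):
    """Raised when the LIE regression design is rank deficient."""


@dataclass
class SimulationEnergies:
    """MD-averaged ligand-surroundings interaction energies for one pose.

    Energies in kJ mol^-1; ``residue_decomposition`` optionally maps a
    residue label to its ``(electrostatic, van der Waals)`` contribution.
    """

    ligand_id: str
    pose_id: str
    v_vdw_protein: float
    v_ele_protein: float
    v_vdw_water: float
    v_ele_water: float
    residue_decomposition: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        fields = (
            self.v_vdw_protein,
            self.v_ele_protein,
            self.v_vdw_water,
            self.v_ele_water,
        )
        if not all(np.isfinite(fields)):
            raise ValueError(
                f"{self.ligand_id}/{self.pose_id}: non-finite interaction energy"
            )

    @property
    def delta_vdw(self) -> float:
        """dV_vdw = <V_vdw>_protein - <V_vdw>_water."""
        return self.v_vdw_protein - self.v_vdw_water

    @property
    def delta_ele(self) -> float:
        """dV_ele = <V_ele>_protein - <V_ele>_water."""
        return self.v_ele_protein - self.v_ele_water


@dataclass
class LIEParameters:
    """Empirical LIE coefficients and the thermodynamic temperature."""

    alpha: float
    beta: float
    gamma: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")


@dataclass
class LigandEnergyProfile:
    """All simulations of one ligand plus its observed affinity (if any)."""

    ligand_id: str
    simulations: list[SimulationEnergies]
    dg_obs: float | None = None

    def __post_init__(self) -> None:
        if not self.simulations:
            raise ValueError(f"{self.ligand_id}: profile needs >= 1 simulation")
        pose_ids = [s.pose_id for s in self.simulations]
        if len(set(pose_ids)) != len(pose_ids):
            raise ValueError(f"{self.ligand_id}: duplicate pose ids")


class RegressionMetrics(NamedTuple):
    rmse: float
    r2: float
    max_abs_residual: float
    sdep: float


@dataclass
class CalibrationResult:
    """Outcome of the self-consistent LIE calibration."""

    parameters: LIEParameters
    max_poses: int
    weights: dict[tuple[str, str], float]
    dg_calc: dict[str, float]
    rmse: float
    r2: float
    iterations: int
    converged: bool
    sdep_cv: float | None = None
    q2: float | None = None
    sdep_table: dict[int, float] = field(default_factory=dict)


def simulation_dg(sim: SimulationEnergies, params: LIEParameters) -> float:
    """Per-simulation LIE free energy alpha*dV_vdw + beta*dV_ele + gamma."""
    return params.alpha * sim.delta_vdw + params.beta * sim.delta_ele + params.gamma


def boltzmann_weights(
    dgs: Sequence[float], temperature: float = DEFAULT_TEMPERATURE
) -> np.ndarray:
    """Normalized Boltzmann weights exp(-dG_i/RT) / sum_j exp(-dG_j/RT).

    Energies are molar (kJ mol^-1), so the thermal energy is R*T.  The
    minimum dG is subtracted before exponentiation to guard against
    overflow; the weights are invariant under that shift.
    """
    dgs = np.asarray(dgs, dtype=float)
    if dgs.size == 0:
        raise ValueError("boltzmann_weights needs a non-empty energy list")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    shifted = dgs - dgs.min()
    w = np.exp(-shifted / (GAS_CONSTANT_KJ * temperature))
    return w / w.sum()


def _retained_indices(dgs: np.ndarray, max_poses: int) -> np.ndarray:
    # Stable sort => ties broken by input pose order.
    order = np.argsort(dgs, kind="stable")
    return np.sort(order[: max(1, max_poses)])


def _aggregate(
    profile: LigandEnergyProfile, params: LIEParameters, max_poses: int
) -> tuple[float, float, dict[str, float]]:
    """Weighted (dV_vdw, dV_ele) sums over the retained lowest-dG poses."""
    dgs = np.array([simulation_dg(s, params) for s in profile.simulations])
    keep = _retained_indices(dgs, max_poses)
    w = boltzmann_weights(dgs[keep], params.temperature)
    x_vdw = float(sum(wi * profile.simulations[i].delta_vdw for wi, i in zip(w, keep)))
    x_ele = float(sum(wi * profile.simulations[i].delta_ele for wi, i in zip(w, keep)))
    weights = {profile.simulations[i].pose_id: float(wi) for wi, i in zip(w, keep)}
    return x_vdw, x_ele, weights


def ligand_dg(
    profile: LigandEnergyProfile, params: LIEParameters, max_poses: int
) -> tuple[float, dict[str, float]]:
    """Boltzmann-weighted ligand free energy over the lowest-dG pose set.

    Returns the weighted-sum prediction and the pose weights used.  With a
    single simulation this reduces to :func:`simulation_dg`.
    """
    if max_poses < 1:
        raise ValueError(f"max_poses must be >= 1, got {max_poses}")
    x_vdw, x_ele, weights = _aggregate(profile, params, max_poses)
    dg = params.alpha * x_vdw + params.beta * x_ele + params.gamma
    return dg, weights


def _fit_parameters(
    x_vdw: np.ndarray,
    x_ele: np.ndarray,
    y: np.ndarray,
    fit_gamma: bool,
    gamma: float,
    temperature: float,
) -> LIEParameters:
    if fit_gamma:
        design = np.column_stack([x_vdw, x_ele, np.ones_like(x_vdw)])
    else:
        design = np.column_stack([x_vdw, x_ele])
        y = y - gamma
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise SingularFitError(
            "LIE design matrix is rank deficient (dV_vdw and dV_ele columns "
            "are linearly dependent or constant)"
        )
    if fit_gamma:
        return LIEParameters(coef[0], coef[1], coef[2], temperature)
    return LIEParameters(coef[0], coef[1], gamma, temperature)


def calibrate(
    profiles: Sequence[LigandEnergyProfile],
    max_poses: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
    fit_gamma: bool = False,
    gamma: float = 0.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> CalibrationResult:
    """Self-consistent calibration of (alpha, beta[, gamma]).

    The first fit uses uniform weights over every pose of each ligand; each
    subsequent iteration re-ranks poses with the current parameters, retains
    the ``max_poses`` lowest-dG simulations per ligand, recomputes Boltzmann
    weights and refits by (unweighted) least squares of the ligand-level
    weighted sums against the observed affinities.  Iteration stops when the
    L1 change in the fitted coefficients drops below ``tol``; a revisit of a
    previously seen parameter state (oscillation) stops the iteration with
    ``converged=False``.
    """
    profiles = [p for p in profiles if p.dg_obs is not None]
    if len(profiles) < 3:
        raise ValueError("calibration needs >= 3 profiles with observed dG")
    if max_poses < 1:
        raise ValueError(f"max_poses must be >= 1, got {max_poses}")
    y = np.array([p.dg_obs for p in profiles])

    # First iteration: uniform weights over all poses.
    x_vdw = np.array([np.mean([s.delta_vdw for s in p.simulations]) for p in profiles])
    x_ele = np.array([np.mean([s.delta_ele for s in p.simulations]) for p in profiles])
    params = _fit_parameters(x_vdw, x_ele, y, fit_gamma, gamma, temperature)

    history = [(params.alpha, params.beta, params.gamma)]
    converged = False
    iterations = 1
    for iterations in range(2, max_iter + 1):
        agg = [_aggregate(p, params, max_poses) for p in profiles]
        x_vdw = np.array([a[0] for a in agg])
        x_ele = np.array([a[1] for a in agg])
        new = _fit_parameters(x_vdw, x_ele, y, fit_gamma, gamma, temperature)
        delta = (
            abs(new.alpha - params.alpha)
            + abs(new.beta - params.beta)
            + abs(new.gamma - params.gamma)
        )
        params = new
        if delta < tol:
            converged = True
            break
        state = (params.alpha, params.beta, params.gamma)
        if any(
            sum(abs(a - b) for a, b in zip(state, past)) < tol for past in history
        ):
            break  # oscillating trajectory: stop, flag as not converged
        history.append(state)

    weights: dict[tuple[str, str], float] = {}
    dg_calc: dict[str, float] = {}
    for p in profiles:
        dg, w = ligand_dg(p, params, max_poses)
        dg_calc[p.ligand_id] = dg
        for pose_id, wi in w.items():
            weights[(p.ligand_id, pose_id)] = wi
    metrics = regression_metrics(y, np.array([dg_calc[p.ligand_id] for p in profiles]))
    return CalibrationResult(
        parameters=params,
        max_poses=max_poses,
        weights=weights,
        dg_calc=dg_calc,
        rmse=metrics.rmse,
        r2=metrics.r2,
        iterations=iterations,
        converged=converged,
    )


def loo_cv(
    profiles: Sequence[LigandEnergyProfile],
    max_poses: int,
    **config,
) -> tuple[float, float, dict[str, float]]:
    """Leave-one-out cross-validation of the calibrated model.

    Each ligand is predicted from a model recalibrated on the remaining
    ligands (weights refit per fold).  Returns ``(SDEP, q2, predictions)``
    with SDEP the root-mean-square prediction error and
    ``q2 = 1 - PRESS/SS_tot``.
    """
    profiles = [p for p in profiles if p.dg_obs is not None]
    if len(profiles) < 4:
        raise ValueError("LOO-CV needs >= 4 profiles with observed dG")
    predictions: dict[str, float] = {}
    for i, held_out in enumerate(profiles):
        train = profiles[:i] + profiles[i + 1 :]
        result = calibrate(train, max_poses, **config)
        predictions[held_out.ligand_id], _ = ligand_dg(
            held_out, result.parameters, max_poses
        )
    obs = np.array([p.dg_obs for p in profiles])
    pred = np.array([predictions[p.ligand_id] for p in profiles])
    press = float(np.sum((obs - pred) ** 2))
    sdep = float(np.sqrt(press / len(obs)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    q2 = 1.0 - press / ss_tot
    return sdep, q2, predictions


def select_pose_count(
    profiles: Sequence[LigandEnergyProfile],
    candidate_counts: Sequence[int],
    **config,
) -> tuple[CalibrationResult, dict[int, float]]:
    """Pick the retained-pose count with the lowest LOO-CV SDEP.

    One model is calibrated per candidate count; ties are broken in favour
    of the smallest count.  The winning :class:`CalibrationResult` carries
    its cross-validation SDEP/q2 and the full SDEP-per-count table.
    """
    if not candidate_counts:
        raise ValueError("candidate_counts must be non-empty")
    table: dict[int, float] = {}
    results: dict[int, tuple[CalibrationResult, float]] = {}
    for count in candidate_counts:
        result = calibrate(profiles, count, **config)
        sdep, q2, _ = loo_cv(profiles, count, **config)
        result.sdep_cv = sdep
        result.q2 = q2
        table[count] = sdep
        results[count] = (result, sdep)
    best_count = min(sorted(results), key=lambda c: results[c][1])
    best = results[best_count][0]
    best.sdep_table = dict(table)
    return best, table


def regression_metrics(obs, calc) -> RegressionMetrics:
    """RMSE/SDEP (root mean squared residual), r2 and worst residual.

    ``r2`` is the coefficient of determination ``1 - SS_res/SS_tot`` about
    the mean of the observations; see :func:`pearson_r2` for the squared
    correlation alternative.
    """
    obs = np.asarray(obs, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if obs.shape != calc.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {calc.shape}")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    residuals = obs - calc
    rmse = float(np.sqrt(np.mean(residuals**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot
    return RegressionMetrics(
        rmse=rmse,
        r2=r2,
        max_abs_residual=float(np.max(np.abs(residuals))),
        sdep=rmse,
    )


def pearson_r2(obs, calc) -> float:
    """Squared Pearson correlation between observed and calculated values."""
    obs = np.asarray(obs, dtype=float)
    calc = np.asarray(calc, dtype=float)
    return float(np.corrcoef(obs, calc)[0, 1] ** 2)
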