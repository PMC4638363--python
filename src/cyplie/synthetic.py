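"""Synthetic MD-energy and pose generators for exercising the LIE workflow.

Real inputs to the workflow are ensemble-averaged interaction energies from
MD simulations and docked-pose geometries — neither of which can be
regenerated cheaply.  These generators emulate their *statistical* structure
(not their physics): per-pose energy differences drawn in the regime seen
for CYP 1A2 ligands, observations built from a known (alpha, beta) through
the same Boltzmann-weighted model the calibrator assumes, Gaussian
observation noise at the level of the experimental uncertainty, and
per-residue decompositions as random convex splits of the pose totals.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .affinity import DEFAULT_TEMPERATURE
from .lie import (
    LIEParameters,
    LigandEnergyProfile,
    SimulationEnergies,
    boltzmann_weights,
    simulation_dg,
)
from .poses import Pose

__all__ = ["GeneratorConfig", "generate_profiles", "generate_pose_geometries"]

# Residues lining the CYP 1A2 catalytic site (plus active-site water as one
# pseudo-residue), used as decomposition labels.
_SITE_RESIDUES = [
    "WAT",
    "THR118",
    "SER122",
    "THR124",
    "PHE125",
    "PHE226",
    "PHE260",
    "ASN312",
    "ASP313",
    "GLY316",
    "ALA317",
    "ASP320",
    "THR321",
    "ILE386",
    "LEU497",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic LIE dataset.

    Defaults follow the regime of the CYP 1A2 model this package targets:
    ~35 training ligands with 4-7 binding poses each, energy differences
    dV_vdw in [-60, -10] and dV_ele in [-45, +5] kJ/mol, the fitted
    coefficients alpha=0.587 / beta=0.267 as ground truth, and Gaussian
    observation noise of 3.3 kJ/mol (the estimated experimental
    uncertainty of the affinity data).
    """

    n_ligands: int = 35
    poses_per_ligand: int | tuple[int, int] = (4, 7)
    true_alpha: float = 0.587
    true_beta: float = 0.267
    true_gamma: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE
    vdw_range: tuple[float, float] = (-60.0, -10.0)
    ele_range: tuple[float, float] = (-45.0, 5.0)
    # Free-state (water) energies; the bound-state values are water + dV.
    vdw_water_range: tuple[float, float] = (-120.0, -40.0)
    ele_water_range: tuple[float, float] = (-150.0, -20.0)
    noise_sigma: float = 3.3
    n_residues: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands < 1 or self.n_residues < 1:
            raise ValueError("counts must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        lo, hi = self.pose_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid poses_per_ligand: {self.poses_per_ligand}")
        for name in ("vdw_range", "ele_range", "vdw_water_range", "ele_water_range"):
            a, b = getattr(self, name)
            if b < a:
                raise ValueError(f"invalid {name}: ({a}, {b})")

    @property
    def pose_range(self) -> tuple[int, int]:
        if isinstance(self.poses_per_ligand, int):
            return self.poses_per_ligand, self.poses_per_ligand
        return tuple(self.poses_per_ligand)

    @property
    def residue_labels(self) -> list[str]:
        labels = list(_SITE_RESIDUES)
        while len(labels) < self.n_residues:
            labels.append(f"RES{len(labels):03d}")
        return labels[: self.n_residues]


def generate_profiles(
    config: GeneratorConfig,
) -> tuple[list[LigandEnergyProfile], LIEParameters]:
    """Generate ligand energy profiles with observations from known truth.

    Per ligand: draw a pose count and per-pose (dV_vdw, dV_ele) pairs, give
    each pose a per-residue decomposition as a Dirichlet convex split of
    its dV per channel, compute per-pose free energies at the true
    parameters, Boltzmann-weight them over all poses, and add Gaussian
    noise to form ``dg_obs``.  Returns the profiles and the true
    :class:`~cyplie.lie.LIEParameters`.
    """
    rng = np.random.default_rng(config.seed)
    truth = LIEParameters(
        config.true_alpha, config.true_beta, config.true_gamma, config.temperature
    )
    lo, hi = config.pose_range
    labels = config.residue_labels
    profiles = []
    for lig_index in range(config.n_ligands):
        ligand_id = f"L{lig_index:03d}"
        n_poses = int(rng.integers(lo, hi + 1))
        sims = []
        for pose_index in range(n_poses):
            d_vdw = float(rng.uniform(*config.vdw_range))
            d_ele = float(rng.uniform(*config.ele_range))
            w_vdw = float(rng.uniform(*config.vdw_water_range))
            w_ele = float(rng.uniform(*config.ele_water_range))
            split_ele = rng.dirichlet(np.ones(config.n_residues))
            split_vdw = rng.dirichlet(np.ones(config.n_residues))
            decomposition = {
                label: (float(d_ele * se), float(d_vdw * sv))
                for label, se, sv in zip(labels, split_ele, split_vdw)
            }
            sims.append(
                SimulationEnergies(
                    ligand_id=ligand_id,
                    pose_id=f"p{pose_index}",
                    v_vdw_protein=w_vdw + d_vdw,
                    v_ele_protein=w_ele + d_ele,
                    v_vdw_water=w_vdw,
                    v_ele_water=w_ele,
                    residue_decomposition=decomposition,
                )
            )
        dgs = np.array([simulation_dg(s, truth) for s in sims])
        weights = boltzmann_weights(dgs, config.temperature)
        dg_true = (
            truth.alpha * float(np.dot(weights, [s.delta_vdw for s in sims]))
            + truth.beta * float(np.dot(weights, [s.delta_ele for s in sims]))
            + truth.gamma
        )
        dg_obs = dg_true + float(rng.normal(0.0, config.noise_sigma))
        profiles.append(LigandEnergyProfile(ligand_id, sims, dg_obs=dg_obs))
    return profiles, truth


def generate_pose_geometries(
    n_clusters: int,
    spread: float,
    separation: float,
    seed: int = 0,
    poses_per_cluster: int = 80,
    n_atoms: int = 20,
    ligand_id: str = "synthetic",
) -> tuple[list[Pose], np.ndarray]:
    """Gaussian pose clouds around distinct conformations (units: nm).

    ``n_clusters`` base conformations share a common scaffold and are
    displaced along mutually orthogonal directions in flattened-coordinate
    space, so every pair of cluster centers is at least ``separation`` nm
    apart.  Each pose perturbs every atom of its base conformation by
    isotropic Gaussian noise with standard deviation ``spread``.  The
    defaults mirror post-docking reality (a few hundred poses of a
    medium-sized ligand).  Returns the poses (cluster-interleaved order)
    and the ground-truth membership.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if separation <= 0:
        raise ValueError("separation must be positive")
    if n_clusters > 3 * n_atoms:
        raise ValueError("n_clusters cannot exceed the coordinate dimension")
    rng = np.random.default_rng(seed)
    common = rng.uniform(-0.15, 0.15, size=(n_atoms, 3))
    directions, _ = np.linalg.qr(rng.normal(size=(3 * n_atoms, n_clusters)))
    bases = [
        common + separation * directions[:, c].reshape(n_atoms, 3)
        for c in range(n_clusters)
    ]
    poses, labels = [], []
    for i in range(poses_per_cluster):
        for c in range(n_clusters):
            coords = bases[c] + rng.normal(0.0, spread, size=(n_atoms, 3))
            poses.append(
                Pose(
                    ligand_id=ligand_id,
                    pose_id=f"c{c}_r{i}",
                    heavy_atom_coords=coords,
                    atom_labels=[f"C{j}" for j in range(n_atoms)],
                )
            )
            labels.append(c)
    return poses, np.array(labels)
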