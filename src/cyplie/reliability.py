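"""Per-prediction reliability (applicability-domain) estimation for LIE models.

A calibrated LIE model is an empirical regression: a prediction for a query
compound is trustworthy only where the training set has sampled comparable
information.  Four independent analyses probe that, each yielding a binary
outlier flag:

A. *Chemical similarity* — MACCS-fingerprint Tanimoto score of the query
   against the training set, with the cutoff set to the weakest best-match
   similarity found inside the training set itself.
B. *Interaction-energy distribution* — squared Mahalanobis distance of each
   query simulation's (dV_ele, dV_vdw) pair from the training cloud,
   compared to a 95% chi-square quantile.
C/D. *Per-residue interaction profiles* — PCA models of the
   Boltzmann-weighted per-residue electrostatic (C) and van der Waals (D)
   interaction energies of the training compounds; a query is a *score*
   outlier if its variance-normalized score distance exceeds the
   chi-square-based SD_crit, and an *orthogonal* outlier if its residual
   off the retained subspace exceeds a robust median/MAD-based OD_crit.

The number of flags raised (0-4) is the reliability category; empirically
the prediction error grows with the category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lie import CalibrationResult, LigandEnergyProfile, SimulationEnergies, ligand_dg

__all__ = [
    "FingerprintProfile",
    "EnergyDistributionModel",
    "PCAOutlierModel",
    "ReliabilityReport",
    "tanimoto",
    "similarity_cutoff",
    "similarity_flag",
    "fit_energy_distribution",
    "mahalanobis_squared",
    "energy_distribution_flag",
    "weighted_residue_profile",
    "fit_pca_outlier_model",
    "pca_distances",
    "pca_flags",
    "reliability_category",
    "category_sdep",
    "run_reliability_analysis",
]

MACCS_N_BITS = 167


@dataclass(frozen=True)
class FingerprintProfile:
    """A compound's binary structural fingerprint (set of on-bit indices)."""

    compound_id: str
    bits: frozenset[int]
    n_bits: int = MACCS_N_BITS

    @classmethod
    def from_smiles(cls, compound_id: str, smiles: str) -> "FingerprintProfile":
        """MACCS-keys fingerprint of a SMILES structure."""
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"{compound_id}: SMILES does not parse: {smiles!r}")
        fp = MACCSkeys.GenMACCSKeys(mol)
        return cls(compound_id, frozenset(fp.GetOnBits()), fp.GetNumBits())


def tanimoto(a: FingerprintProfile, b: FingerprintProfile) -> float:
    """Tanimoto score |a & b| / |a | b|; 1.0 when both fingerprints are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def similarity_cutoff(training: Sequence[FingerprintProfile]) -> float:
    """Weakest best-match Tanimoto score within the training set.

    For every training compound, take its highest similarity to any *other*
    training compound; the minimum of those maxima becomes the cutoff below
    which a query counts as structurally novel.
    """
    if len(training) < 2:
        raise ValueError("similarity_cutoff needs >= 2 training compounds")
    best = []
    for i, a in enumerate(training):
        best.append(max(tanimoto(a, b) for j, b in enumerate(training) if j != i))
    return min(best)


def similarity_flag(
    query: FingerprintProfile,
    training: Sequence[FingerprintProfile],
    cutoff: float,
) -> int:
    """1 iff the query's best Tanimoto score against training is < cutoff."""
    if not 0 <= cutoff <= 1:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    best = max(tanimoto(query, t) for t in training)
    return int(best < cutoff)


@dataclass
class EnergyDistributionModel:
    """Gaussian summary of the training (dV_ele, dV_vdw) cloud."""

    center: np.ndarray
    covariance: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)


def _sim_energy_pairs(sims: Iterable[SimulationEnergies]) -> np.ndarray:
    return np.array([[s.delta_ele, s.delta_vdw] for s in sims])


def fit_energy_distribution(
    training_sims: Sequence[SimulationEnergies], dof: int = 1
) -> EnergyDistributionModel:
    """Fit center/covariance of training (dV_ele, dV_vdw) pairs.

    The outlier threshold on the *squared* Mahalanobis distance is the 95%
    chi-square quantile.  ``dof=1`` (default, 3.841) treats a deviation
    along either single energy axis as the reference; ``dof=2`` is the
    joint-bivariate alternative.
    """
    points = _sim_energy_pairs(training_sims)
    if len(points) < 3:
        raise ValueError("fit_energy_distribution needs >= 3 simulations")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 1e-10 * max(eigvals.max(), 1.0):
        raise np.linalg.LinAlgError("singular covariance: degenerate energy cloud")
    return EnergyDistributionModel(
        center=center,
        covariance=cov,
        threshold=float(stats.chi2.ppf(0.95, dof)),
    )


def mahalanobis_squared(point, model: EnergyDistributionModel) -> float:
    """Squared Mahalanobis distance of a (dV_ele, dV_vdw) pair from the center."""
    diff = np.asarray(point, dtype=float) - model.center
    return float(diff @ np.linalg.solve(model.covariance, diff))


def energy_distribution_flag(
    query_sims: Sequence[SimulationEnergies], model: EnergyDistributionModel
) -> int:
    """1 iff any query simulation exceeds the squared-distance threshold."""
    if not query_sims:
        raise ValueError("energy_distribution_flag needs >= 1 query simulation")
    d2 = [mahalanobis_squared(p, model) for p in _sim_energy_pairs(query_sims)]
    return int(max(d2) > model.threshold)


_CHANNEL_INDEX = {"ele": 0, "vdw": 1}


def weighted_residue_profile(
    sims: Sequence[SimulationEnergies],
    weights: Sequence[float],
    channel: str,
) -> pd.Series:
    """Boltzmann-weighted per-residue interaction profile of one ligand.

    Each simulation's per-residue decomposition (``channel`` 'ele' or
    'vdw') is scaled by its weight and summed, producing a single vector of
    residue contributions indexed by residue label.
    """
    if channel not in _CHANNEL_INDEX:
        raise ValueError(f"channel must be 'ele' or 'vdw', got {channel!r}")
    if len(sims) != len(weights):
        raise ValueError("weights do not align with simulations")
    total = float(np.sum(weights))
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"weights must sum to 1, got {total}")
    idx = _CHANNEL_INDEX[channel]
    reference = None
    acc: dict[str, float] = {}
    for sim, w in zip(sims, weights):
        if sim.residue_decomposition is None:
            raise ValueError(f"{sim.ligand_id}/{sim.pose_id}: no residue decomposition")
        labels = list(sim.residue_decomposition)
        if reference is None:
            reference = labels
            acc = {label: 0.0 for label in labels}
        elif set(labels) != set(reference):
            raise ValueError(
                f"{sim.ligand_id}/{sim.pose_id}: residue label set mismatch"
            )
        for label, values in sim.residue_decomposition.items():
            acc[label] += w * values[idx]
    return pd.Series(acc, index=reference, name=sims[0].ligand_id)


@dataclass
class PCAOutlierModel:
    """Centered PCA of training residue profiles with outlier cutoffs.

    ``loadings`` is the (p, a) orthonormal component matrix, ``variances``
    the per-component training variances lambda_k.  ``sd_crit`` is the
    chi-square-based score-distance cutoff sqrt(chi2_{a,0.95}) and
    ``od_crit`` the robust orthogonal-distance cutoff
    (median(OD^{2/3}) + MAD(OD^{2/3}) * z_{0.95})^{3/2}.
    """

    center: np.ndarray
    loadings: np.ndarray
    variances: np.ndarray
    sd_crit: float
    od_crit: float
    feature_labels: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _as_matrix(training_vectors) -> tuple[np.ndarray, list[str]]:
    if isinstance(training_vectors, pd.DataFrame):
        return training_vectors.to_numpy(dtype=float), list(training_vectors.columns)
    if len(training_vectors) and isinstance(training_vectors[0], pd.Series):
        frame = pd.DataFrame([v for v in training_vectors])
        return frame.to_numpy(dtype=float), list(frame.columns)
    arr = np.asarray(training_vectors, dtype=float)
    return arr, [str(i) for i in range(arr.shape[1])]


def fit_pca_outlier_model(
    training_vectors,
    variance_threshold: float = 0.05,
    transformed_median: bool = True,
    mad_scale: float = 1.0,
) -> PCAOutlierModel:
    """Fit the PCA outlier model on training per-residue profiles.

    Variables are mean-centered (not scaled); components individually
    explaining more than ``variance_threshold`` of the total variance are
    retained (at least one).  ``transformed_median=False`` switches the
    OD_crit location term from median(OD^{2/3}) to median(OD)^{2/3};
    ``mad_scale=1.4826`` applies the normal-consistency factor to the MAD.
    """
    X, labels = _as_matrix(training_vectors)
    if X.shape[0] < 3:
        raise ValueError("fit_pca_outlier_model needs >= 3 training vectors")
    center = X.mean(axis=0)
    Xc = X - center
    # SVD-based PCA; eigenvalues of the sample covariance.
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    variances = svals**2 / (X.shape[0] - 1)
    total = variances.sum()
    if total <= 0:
        raise ValueError("zero total variance in training vectors")
    ratios = variances / total
    a = max(1, int(np.sum(ratios > variance_threshold)))
    loadings = vt[:a].T
    variances = variances[:a]

    scores = Xc @ loadings
    residuals = Xc - scores @ loadings.T
    od = np.linalg.norm(residuals, axis=1)
    sd_crit = float(np.sqrt(stats.chi2.ppf(0.95, a)))
    z95 = float(stats.norm.ppf(0.95))
    t = od ** (2.0 / 3.0)
    location = float(np.median(t)) if transformed_median else float(np.median(od)) ** (2.0 / 3.0)
    mad = float(np.median(np.abs(t - np.median(t)))) * mad_scale
    od_crit = (location + mad * z95) ** 1.5
    return PCAOutlierModel(
        center=center,
        loadings=loadings,
        variances=variances,
        sd_crit=sd_crit,
        od_crit=float(od_crit),
        feature_labels=labels,
    )


def pca_distances(query_vector, model: PCAOutlierModel) -> tuple[float, float]:
    """Score distance and orthogonal distance of a query profile.

    SD = sqrt(sum_k t_k^2 / lambda_k) over retained components (scores
    normalized by training variances); OD is the Euclidean norm of the
    query's residual off the retained subspace.
    """
    if isinstance(query_vector, pd.Series):
        if model.feature_labels and list(query_vector.index) != model.feature_labels:
            query_vector = query_vector.reindex(model.feature_labels)
        query_vector = query_vector.to_numpy(dtype=float)
    q = np.asarray(query_vector, dtype=float)
    if q.shape != model.center.shape:
        raise ValueError(f"dimension mismatch: {q.shape} vs {model.center.shape}")
    centered = q - model.center
    t = model.loadings.T @ centered
    sd = float(np.sqrt(np.sum(t**2 / model.variances)))
    od = float(np.linalg.norm(centered - model.loadings @ t))
    return sd, od


def pca_flags(query_vector, model: PCAOutlierModel) -> tuple[int, int]:
    """(score_outlier, orthogonal_outlier) flags against SD_crit/OD_crit."""
    sd, od = pca_distances(query_vector, model)
    return int(sd > model.sd_crit), int(od > model.od_crit)


def reliability_category(flags: Sequence[int]) -> int:
    """Reliability category 0-4: the number of analyses flagging an outlier."""
    flags = list(flags)
    if len(flags) != 4 or any(f not in (0, 1) for f in flags):
        raise ValueError(f"expected four binary flags, got {flags}")
    return int(sum(flags))


@dataclass
class ReliabilityReport:
    """Outcome of the four-criterion analysis for one query compound."""

    compound_id: str
    flag_similarity: int
    flag_energy_distribution: int
    flag_residue_ele: int
    flag_residue_vdw: int
    category: int = None
    dg_calc: float | None = None
    dg_obs: float | None = None

    def __post_init__(self) -> None:
        expected = reliability_category(self.flags)
        if self.category is None:
            self.category = expected
        elif self.category != expected:
            raise ValueError(
                f"{self.compound_id}: category {self.category} != sum of flags"
            )

    @property
    def flags(self) -> tuple[int, int, int, int]:
        return (
            self.flag_similarity,
            self.flag_energy_distribution,
            self.flag_residue_ele,
            self.flag_residue_vdw,
        )

    @property
    def residual(self) -> float | None:
        if self.dg_obs is None or self.dg_calc is None:
            return None
        return self.dg_obs - self.dg_calc


def category_sdep(reports: Sequence) -> dict[int, tuple[int, float]]:
    """Per-category membership count and SDEP (root mean squared residual).

    Accepts :class:`ReliabilityReport` objects carrying residuals, or plain
    ``(category, residual)`` pairs.  Empty categories are omitted.
    """
    grouped: dict[int, list[float]] = {}
    for report in reports:
        if isinstance(report, ReliabilityReport):
            category, residual = report.category, report.residual
        else:
            category, residual = report
        if residual is None:
            raise ValueError("every report needs a residual")
        grouped.setdefault(int(category), []).append(float(residual))
    return {
        c: (len(r), float(np.sqrt(np.mean(np.square(r)))))
        for c, r in sorted(grouped.items())
    }


def run_reliability_analysis(
    train_profiles: Sequence[LigandEnergyProfile],
    query_profiles: Sequence[LigandEnergyProfile],
    calibration: CalibrationResult,
    train_structures: dict[str, str] | None = None,
    query_structures: dict[str, str] | None = None,
    variance_threshold: float = 0.05,
    energy_dof: int = 1,
) -> list[ReliabilityReport]:
    """Run all four analyses for a set of query compounds.

    Criterion A needs SMILES for training and query compounds; if
    structures are omitted the similarity flag is reported as 0 with the
    category computed from the remaining analyses.  Criterion B compares
    every query simulation against the simulations retained in the
    calibrated model; criteria C/D require per-residue decompositions on
    both sides.
    """
    params, max_poses = calibration.parameters, calibration.max_poses

    # A: chemical similarity
    sim_flags: dict[str, int] = {}
    if train_structures and query_structures:
        train_fps = [
            FingerprintProfile.from_smiles(cid, smi)
            for cid, smi in train_structures.items()
        ]
        cutoff = similarity_cutoff(train_fps)
        for q in query_profiles:
            fp = FingerprintProfile.from_smiles(
                q.ligand_id, query_structures[q.ligand_id]
            )
            sim_flags[q.ligand_id] = similarity_flag(fp, train_fps, cutoff)
    else:
        sim_flags = {q.ligand_id: 0 for q in query_profiles}

    # B: training simulations retained by the model vs all query simulations
    retained = [
        s
        for p in train_profiles
        for s in p.simulations
        if (p.ligand_id, s.pose_id) in calibration.weights
    ]
    energy_model = fit_energy_distribution(retained, dof=energy_dof)

    # C/D: PCA outlier models on weighted per-residue profiles
    def profile_matrix(profiles, weight_lookup):
        rows = {}
        for p in profiles:
            w = weight_lookup(p)
            sims = [s for s in p.simulations if s.pose_id in w]
            weights = [w[s.pose_id] for s in sims]
            rows[p.ligand_id] = {
                ch: weighted_residue_profile(sims, weights, ch)
                for ch in ("ele", "vdw")
            }
        return rows

    train_rows = profile_matrix(
        train_profiles,
        lambda p: {
            pose: w
            for (lig, pose), w in calibration.weights.items()
            if lig == p.ligand_id
        },
    )
    query_predictions = {
        p.ligand_id: ligand_dg(p, params, max_poses) for p in query_profiles
    }
    query_rows = profile_matrix(
        query_profiles, lambda p: query_predictions[p.ligand_id][1]
    )
    pca_models = {
        ch: fit_pca_outlier_model(
            pd.DataFrame([rows[ch] for rows in train_rows.values()]),
            variance_threshold=variance_threshold,
        )
        for ch in ("ele", "vdw")
    }

    reports = []
    for p in query_profiles:
        flag_b = energy_distribution_flag(p.simulations, energy_model)
        residue_flags = {}
        for ch in ("ele", "vdw"):
            score_out, orth_out = pca_flags(query_rows[p.ligand_id][ch], pca_models[ch])
            residue_flags[ch] = int(score_out or orth_out)
        reports.append(
            ReliabilityReport(
                compound_id=p.ligand_id,
                flag_similarity=sim_flags[p.ligand_id],
                flag_energy_distribution=flag_b,
                flag_residue_ele=residue_flags["ele"],
                flag_residue_vdw=residue_flags["vdw"],
                dg_calc=query_predictions[p.ligand_id][0],
                dg_obs=p.dg_obs,
            )
        )
    return reports
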