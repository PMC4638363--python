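"""Docked-pose clustering, active-site geometry and the reactive-group filter.

After docking, a ligand's poses are reduced to a handful of representative
binding modes: a PCA on the flattened heavy-atom coordinates (poses are
assumed pre-aligned in the protein frame), k-means in score space, and the
cluster medoids as representatives.  Both the number of PCA components and
the number of clusters grow only while each addition gains at least 5
percentage points of explained variance.

The same representative poses feed a knowledge-based filter for compounds
that are unlikely to be purely competitive, reversible binders: if a ligand
carries a substructure known to yield mechanism-based inactivation (e.g. a
furan or thiophene that CYPs bioactivate to a reactive intermediate) or
quasi-irreversible heme coordination (an accessible aromatic nitrogen lone
pair), and the reactive atom sits within 0.6 nm of the heme iron in at
least one representative pose, the compound is flagged and should be
excluded from LIE calibration (its binding is not described by a classical
force field).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "Pose",
    "ReactiveGroupRule",
    "SiteGeometry",
    "ClusterResult",
    "GeometryError",
    "site_center",
    "cluster_poses",
    "detect_reactive_groups",
    "classify_inhibition",
    "load_rules",
    "default_rules",
    "read_poses_pdb",
    "site_geometry_from_pdb",
]

#: Distance (nm) from the heme iron to the active-site center, measured
#: along the Cys-sulfur -> Fe axis.
SITE_CENTER_OFFSET_NM = 0.78

#: Radius (nm) of the sphere around the site center defining the active site.
SITE_RADIUS_NM = 1.2

#: Reactive-atom / heme-iron distance cutoff (nm) for the binder filter.
REACTIVE_DISTANCE_CUTOFF_NM = 0.6

MECHANISM_BASED = "mechanism-based"
QUASI_IRREVERSIBLE = "quasi-irreversible"
COMPETITIVE = "competitive"


class GeometryError(ValueError):
    """Raised for degenerate geometric input (e.g. coincident atoms)."""


@dataclass
class Pose:
    """One docked conformation: heavy-atom coordinates (nm) plus labels."""

    ligand_id: str
    pose_id: str
    heavy_atom_coords: np.ndarray
    atom_labels: list[str]

    def __post_init__(self) -> None:
        self.heavy_atom_coords = np.asarray(self.heavy_atom_coords, dtype=float)
        if self.heavy_atom_coords.ndim != 2 or self.heavy_atom_coords.shape[1] != 3:
            raise ValueError("heavy_atom_coords must be an (n, 3) array")
        if len(self.heavy_atom_coords) == 0:
            raise ValueError("pose needs at least one atom")
        if len(self.atom_labels) != len(self.heavy_atom_coords):
            raise ValueError("atom label / coordinate count mismatch")


@dataclass
class ReactiveGroupRule:
    """A structural alert: SMARTS pattern plus its reactive atom positions."""

    name: str
    pattern: str
    reactive_atom_indices: tuple[int, ...]
    mechanism: str

    def __post_init__(self) -> None:
        self._query = Chem.MolFromSmarts(self.pattern)
        if self._query is None:
            raise ValueError(f"rule {self.name}: SMARTS does not parse: {self.pattern}")
        n = self._query.GetNumAtoms()
        if any(i < 0 or i >= n for i in self.reactive_atom_indices):
            raise ValueError(f"rule {self.name}: reactive atom index out of range")
        if self.mechanism not in (MECHANISM_BASED, QUASI_IRREVERSIBLE):
            raise ValueError(f"rule {self.name}: unknown mechanism {self.mechanism}")

    @property
    def query(self) -> Chem.Mol:
        return self._query


@dataclass
class SiteGeometry:
    """Heme-anchored geometry of the catalytic site (all positions in nm)."""

    fe_position: np.ndarray
    sulfur_position: np.ndarray
    site_center: np.ndarray
    site_radius: float = SITE_RADIUS_NM

    def __post_init__(self) -> None:
        self.fe_position = np.asarray(self.fe_position, dtype=float)
        self.sulfur_position = np.asarray(self.sulfur_position, dtype=float)
        self.site_center = np.asarray(self.site_center, dtype=float)
        if self.site_radius <= 0:
            raise ValueError("site_radius must be positive")

    @classmethod
    def from_anchors(cls, fe, sulfur, site_radius: float = SITE_RADIUS_NM):
        return cls(fe, sulfur, site_center(fe, sulfur), site_radius)


def site_center(fe, sulfur) -> np.ndarray:
    """Active-site center: 0.78 nm from Fe along the sulfur->Fe direction.

    The Cys-thiolate coordinates the iron from the proximal face, so the
    unit vector from sulfur to iron points into the distal pocket where
    ligands bind.
    """
    fe = np.asarray(fe, dtype=float)
    sulfur = np.asarray(sulfur, dtype=float)
    axis = fe - sulfur
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise GeometryError("Fe and sulfur positions coincide")
    return fe + SITE_CENTER_OFFSET_NM * axis / norm


@dataclass
class ClusterResult:
    """Representative binding modes of one ligand."""

    medoids: list[Pose]
    labels: np.ndarray
    medoid_indices: list[int]
    n_components: int
    explained_variance: float
    scores: np.ndarray = field(repr=False, default=None)


def _select_k(
    scores: np.ndarray, total_ss: float, increment: float, random_state: int
) -> tuple[KMeans | None, float]:
    """Grow k while each added cluster explains >= `increment` more variance.

    Explained variance is the between-cluster sum of squares (computed in
    the retained score space) as a fraction of the *total* coordinate
    variance, so splitting unstructured within-mode scatter never clears
    the threshold.
    """
    n = len(scores)
    score_ss = float(np.sum((scores - scores.mean(axis=0)) ** 2))
    best = None
    explained_prev = 0.0  # k=1: no between-cluster variance
    for k in range(2, n + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit(scores)
        explained = (score_ss - km.inertia_) / total_ss
        if explained - explained_prev < increment:
            break
        best, explained_prev = km, explained
        if km.inertia_ <= 1e-12 * total_ss:
            break
    return best, explained_prev


def cluster_poses(
    poses: list[Pose],
    variance_increment: float = 0.05,
    random_state: int = 0,
) -> ClusterResult:
    """Cluster docked poses into representative binding modes.

    PCA on flattened heavy-atom coordinates retains components while each
    one adds at least ``variance_increment`` of the total coordinate
    variance; k-means on the retained scores grows the cluster count under
    the same rule on explained score variance.  Each cluster is represented
    by its medoid (the member pose closest to the centroid in score space;
    ties resolved by input order).
    """
    if not poses:
        raise ValueError("cluster_poses needs at least one pose")
    n_atoms = len(poses[0].heavy_atom_coords)
    if any(len(p.heavy_atom_coords) != n_atoms for p in poses):
        raise ValueError("inconsistent atom counts across poses")
    coords = np.stack([p.heavy_atom_coords.ravel() for p in poses])
    n = len(poses)

    total_var = float(np.sum(np.var(coords, axis=0)))
    if n == 1 or total_var < 1e-15:
        return ClusterResult(
            medoids=[poses[0]],
            labels=np.zeros(n, dtype=int),
            medoid_indices=[0],
            n_components=0,
            explained_variance=1.0,
            scores=np.zeros((n, 1)),
        )

    pca = PCA(n_components=min(n, coords.shape[1])).fit(coords)
    ratios = pca.explained_variance_ratio_
    n_components = 1
    while n_components < len(ratios) and ratios[n_components] >= variance_increment:
        n_components += 1
    scores = pca.transform(coords)[:, :n_components]

    total_ss = total_var * n
    km, explained = _select_k(scores, total_ss, variance_increment, random_state)
    if km is None:
        labels = np.zeros(n, dtype=int)
        centroids = scores.mean(axis=0, keepdims=True)
    else:
        labels = km.labels_
        centroids = km.cluster_centers_

    medoid_indices = []
    for cluster in range(centroids.shape[0]):
        members = np.flatnonzero(labels == cluster)
        dists = np.linalg.norm(scores[members] - centroids[cluster], axis=1)
        medoid_indices.append(int(members[int(np.argmin(dists))]))
    return ClusterResult(
        medoids=[poses[i] for i in medoid_indices],
        labels=labels,
        medoid_indices=medoid_indices,
        n_components=n_components,
        explained_variance=float(explained),
        scores=scores,
    )


def _as_mol(structure) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return Chem.RemoveHs(structure)
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"structure does not parse as SMILES: {structure!r}")
    return mol


def detect_reactive_groups(
    structure, rules: list[ReactiveGroupRule]
) -> list[tuple[ReactiveGroupRule, tuple[int, ...]]]:
    """All reactive-group matches with reactive atoms in molecule indexing.

    ``structure`` may be a SMILES string or an RDKit molecule.  Each hit is
    returned as ``(rule, reactive_atom_indices_in_molecule)``, one entry per
    substructure match.
    """
    mol = _as_mol(structure)
    hits = []
    for rule in rules:
        for match in mol.GetSubstructMatches(rule.query):
            reactive = tuple(match[i] for i in rule.reactive_atom_indices)
            hits.append((rule, reactive))
    return hits


def classify_inhibition(
    structure,
    poses: list[Pose],
    geometry: SiteGeometry,
    rules: list[ReactiveGroupRule] | None = None,
    distance_cutoff: float = REACTIVE_DISTANCE_CUTOFF_NM,
) -> str:
    """Label a ligand competitive / mechanism-based / quasi-irreversible.

    A ligand is non-competitive only if (a) a reactive-group rule matches
    its structure AND (b) a matched reactive atom lies within
    ``distance_cutoff`` (nm) of the heme iron in at least one representative
    pose.  Mechanism-based takes precedence when rules of both kinds
    trigger.  Pose coordinates must follow the molecule's heavy-atom order.
    """
    if rules is None:
        rules = default_rules()
    mol = _as_mol(structure)
    n_heavy = mol.GetNumAtoms()
    for pose in poses:
        if len(pose.heavy_atom_coords) != n_heavy:
            raise ValueError(
                f"{pose.ligand_id}/{pose.pose_id}: pose has "
                f"{len(pose.heavy_atom_coords)} atoms, structure has {n_heavy}"
            )
    hits = detect_reactive_groups(mol, rules)
    if not hits:
        return COMPETITIVE
    triggered = set()
    fe = geometry.fe_position
    for rule, reactive_atoms in hits:
        for pose in poses:
            d = np.linalg.norm(pose.heavy_atom_coords[list(reactive_atoms)] - fe, axis=1)
            if np.any(d < distance_cutoff):
                triggered.add(rule.mechanism)
                break
    if MECHANISM_BASED in triggered:
        return MECHANISM_BASED
    if QUASI_IRREVERSIBLE in triggered:
        return QUASI_IRREVERSIBLE
    return COMPETITIVE


def _parse_rules(text: str, source: str) -> list[ReactiveGroupRule]:
    rules = []
    for row in csv.DictReader(io.StringIO(text)):
        rules.append(
            ReactiveGroupRule(
                name=row["name"],
                pattern=row["smarts"],
                reactive_atom_indices=tuple(
                    int(i) for i in row["reactive_atoms"].split(";")
                ),
                mechanism=row["mechanism"].strip(),
            )
        )
    if not rules:
        raise ValueError(f"no rules found in {source}")
    return rules


def load_rules(path) -> list[ReactiveGroupRule]:
    """Load reactive-group rules from CSV (name, smarts, reactive_atoms, mechanism).

    ``reactive_atoms`` is a semicolon-separated list of 0-based atom
    positions within the SMARTS pattern.
    """
    with open(path, newline="") as handle:
        return _parse_rules(handle.read(), str(path))


def default_rules() -> list[ReactiveGroupRule]:
    """The built-in CYP structural-alert catalogue (user-replaceable)."""
    from importlib.resources import files

    text = files("cyplie.data").joinpath("reactive_groups.csv").read_text()
    return _parse_rules(text, "cyplie.data/reactive_groups.csv")


# ---------------------------------------------------------------------------
# PDB input (coordinates are converted from Angstrom to nm)

_ANGSTROM_TO_NM = 0.1


def read_poses_pdb(path, ligand_id: str | None = None) -> list[Pose]:
    """Read ligand poses from a (multi-MODEL) PDB file.

    Every MODEL becomes one pose; hydrogens are dropped and coordinates are
    converted to nm.  HETATM/ATOM records of the first chain/residue
    encountered are used in file order, so all models must share the same
    atom ordering (as docking output does).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("poses", str(path))
    poses = []
    for model in structure:
        coords, labels = [], []
        for atom in model.get_atoms():
            if (atom.element or "").upper() == "H":
                continue
            coords.append(atom.coord * _ANGSTROM_TO_NM)
            labels.append(atom.get_name())
        poses.append(
            Pose(
                ligand_id=ligand_id or "ligand",
                pose_id=str(model.id),
                heavy_atom_coords=np.array(coords),
                atom_labels=labels,
            )
        )
    if not poses:
        raise ValueError(f"no poses found in {path}")
    return poses


def site_geometry_from_pdb(path, site_radius: float = SITE_RADIUS_NM) -> SiteGeometry:
    """Locate the heme iron and the coordinating Cys sulfur in a protein PDB.

    Fe is looked up in HEM/HEC residues; the Cys SG atom nearest to the iron
    is taken as the coordinating thiolate.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("protein", str(path))
    fe = None
    sulfurs = []
    for atom in structure.get_atoms():
        resname = atom.get_parent().get_resname().strip()
        if resname in ("HEM", "HEC") and (atom.element or "").upper() == "FE":
            fe = atom.coord * _ANGSTROM_TO_NM
        if resname == "CYS" and atom.get_name() == "SG":
            sulfurs.append(atom.coord * _ANGSTROM_TO_NM)
    if fe is None:
        raise ValueError(f"no heme iron (HEM/HEC Fe) found in {path}")
    if not sulfurs:
        raise ValueError(f"no CYS SG atom found in {path}")
    sulfur = min(sulfurs, key=lambda s: np.linalg.norm(s - fe))
    return SiteGeometry.from_anchors(fe, sulfur, site_radius)
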