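"""Per-protomer conformational collective variables of the kinase domain.

Three metrics, each computable on a static structure or on a trajectory frame:

* **αC position** — distance between the Cα of the β7 reference residue
  (Ile582) and the Cα centroid of the three αC-helix center residues
  (Asn500, Glu501, Val502).  Below 19.6 Å the helix is "in", above it "out"
  (the KLIFS convention).  The three center atoms are all Cα carbons, so the
  unweighted centroid equals their center of mass.
* **K–E minimum distance** — minimum distance between the catalytic lysine's
  sidechain ζ-nitrogen (Lys483 NZ) and the two carboxylate oxygens of the αC
  glutamate (Glu501 OE1/OE2).  At ≤ 4.0 Å the salt bridge is counted as
  formed; a looser ≤ 4.5 Å predicate is exposed as the alternative
  sidechain-distance definition of the αC-in state.
* **DFG pseudo-dihedral** — torsion over the Cα atoms of Ile592, Gly593,
  Asp594 and Phe595, reported in [0, 360): the standard signed torsion with
  negative angles mapped to 360 + θ.  Below 140° is DFG-in, otherwise
  DFG-out.

Boundary conventions are fixed and documented: αC-in strict (< 19.6),
salt bridge inclusive (≤ 4.0), DFG-in strict (< 140).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anchors import DEFAULT_ANCHORS, DEFAULT_THRESHOLDS, AnchorMap, Thresholds
from .errors import MissingResidueError, UndefinedDihedralError
from .structure import KinaseStructure

STATE_IN = "IN"
STATE_OUT = "OUT"

#: collinearity tolerance for the torsion (|n| relative to bond lengths)
_DEGENERATE_EPS = 1e-10


# ---------------------------------------------------------------------------
# vectorized geometry cores (frames may be stacked along leading axes)
# ---------------------------------------------------------------------------

def centroid_distance(reference: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Distance from ``reference`` (..., 3) to the centroid of ``points`` (..., m, 3)."""
    centroid = np.mean(points, axis=-2)
    return np.linalg.norm(np.asarray(reference) - centroid, axis=-1)


def min_pair_distance(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Minimum pairwise distance between two atom groups (..., m, 3) and (..., n, 3)."""
    diff = np.asarray(group_a)[..., :, None, :] - np.asarray(group_b)[..., None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    return d.min(axis=(-2, -1))


def torsion_angle(p0, p1, p2, p3, check_degenerate: bool = True) -> np.ndarray:
    """Signed four-point torsion in degrees, wrapped to [0, 360).

    Standard convention: looking down the p1→p2 axis, a clockwise rotation of
    the p2→p3 bond relative to p1→p0 is positive; negative IUPAC angles map to
    360 + θ.  Collinear inner triplets make the torsion undefined and raise
    :class:`UndefinedDihedralError`.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if check_degenerate:
        scale1 = np.linalg.norm(b0, axis=-1) * np.linalg.norm(b1, axis=-1)
        scale2 = np.linalg.norm(b1, axis=-1) * np.linalg.norm(b2, axis=-1)
        bad = (np.linalg.norm(n1, axis=-1) <= _DEGENERATE_EPS * np.maximum(scale1, 1e-30)) | (
            np.linalg.norm(n2, axis=-1) <= _DEGENERATE_EPS * np.maximum(scale2, 1e-30)
        )
        if np.any(bad):
            raise UndefinedDihedralError(
                "torsion undefined: three consecutive atoms are collinear"
            )
    b1_unit = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b1_unit, axis=-1)
    theta = np.degrees(np.arctan2(y, x))
    return np.mod(theta, 360.0)


# ---------------------------------------------------------------------------
# anchor-atom index resolution
# ---------------------------------------------------------------------------

def alpha_c_atom_indices(
    structure: KinaseStructure, protomer: str, anchors: AnchorMap = DEFAULT_ANCHORS
) -> tuple[int, np.ndarray]:
    """(reference Cα index, center-residue Cα indices) for the αC metric."""
    ref = structure.residue_atom_indices(
        protomer, anchors.alpha_c_reference_residue, atom_names=["CA"]
    )[0]
    center = np.array(
        [
            structure.residue_atom_indices(protomer, rid, atom_names=["CA"])[0]
            for rid in anchors.alpha_c_center_residues
        ]
    )
    return int(ref), center


def ke_atom_indices(
    structure: KinaseStructure, protomer: str, anchors: AnchorMap = DEFAULT_ANCHORS
) -> tuple[int, np.ndarray]:
    """(Lys ζ-nitrogen index, Glu carboxylate oxygen indices) for the K–E metric."""
    nz = structure.residue_atom_indices(
        protomer, anchors.catalytic_lysine, atom_names=["NZ"]
    )[0]
    oxy = structure.residue_atom_indices(
        protomer, anchors.alpha_c_glutamate, atom_names=["OE1", "OE2"]
    )
    return int(nz), oxy


def dfg_atom_indices(
    structure: KinaseStructure, protomer: str, anchors: AnchorMap = DEFAULT_ANCHORS
) -> np.ndarray:
    """Ordered Cα indices of the four pseudo-dihedral residues."""
    return np.array(
        [
            structure.residue_atom_indices(protomer, rid, atom_names=["CA"])[0]
            for rid in anchors.dfg_dihedral_residues
        ]
    )


# ---------------------------------------------------------------------------
# public metrics
# ---------------------------------------------------------------------------

def alpha_c_position(
    structure: KinaseStructure,
    protomer: str,
    anchors: AnchorMap = DEFAULT_ANCHORS,
    coords: np.ndarray | None = None,
) -> float:
    """αC-helix position (Å) of one protomer.

    ``coords`` optionally overrides the structure's coordinates (one frame,
    same atom ordering).
    """
    ref, center = alpha_c_atom_indices(structure, protomer, anchors)
    xyz = structure.atoms.coord if coords is None else np.asarray(coords)
    return float(centroid_distance(xyz[ref], xyz[center]))


def classify_alpha_c(position: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """"IN" iff position < the αC-in cutoff (strict), else "OUT"."""
    if position < 0:
        raise ValueError("αC position must be non-negative")
    return STATE_IN if position < thresholds.alpha_c_in_cutoff else STATE_OUT


def ke_min_distance(
    structure: KinaseStructure,
    protomer: str,
    anchors: AnchorMap = DEFAULT_ANCHORS,
    coords: np.ndarray | None = None,
) -> float:
    """Minimum Lys Nζ – Glu Oε distance (Å) of one protomer."""
    nz, oxy = ke_atom_indices(structure, protomer, anchors)
    xyz = structure.atoms.coord if coords is None else np.asarray(coords)
    return float(min_pair_distance(xyz[nz][None, :], xyz[oxy]))


def is_salt_bridge(distance: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """Salt bridge formed iff distance ≤ 4.0 Å (inclusive)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance <= thresholds.salt_bridge_cutoff


def is_alpha_c_in_by_sidechain(
    distance: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Alternative αC-in definition: minimum K–E sidechain distance ≤ 4.5 Å.

    Never mixed silently with :func:`is_salt_bridge`; the two predicates use
    distinct cutoffs and are exposed under distinct names.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance <= thresholds.alpha_c_in_sidechain_cutoff


def dfg_pseudo_dihedral(
    structure: KinaseStructure,
    protomer: str,
    anchors: AnchorMap = DEFAULT_ANCHORS,
    coords: np.ndarray | None = None,
) -> float:
    """DFG pseudo-dihedral (degrees, [0, 360)) of one protomer."""
    idx = dfg_atom_indices(structure, protomer, anchors)
    xyz = structure.atoms.coord if coords is None else np.asarray(coords)
    return float(torsion_angle(xyz[idx[0]], xyz[idx[1]], xyz[idx[2]], xyz[idx[3]]))


def classify_dfg(dihedral: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """"IN" iff dihedral < 140° (strict), else "OUT"."""
    if not 0 <= dihedral < 360:
        raise ValueError("dihedral must be in [0, 360)")
    return STATE_IN if dihedral < thresholds.dfg_in_cutoff else STATE_OUT


@dataclass(frozen=True)
class MetricRecord:
    """All per-protomer conformational metrics of one structure or frame."""

    protomer: str
    alpha_c_position: float
    alpha_c_state: str
    ke_min_distance: float
    salt_bridge_formed: bool
    dfg_pseudo_dihedral: float
    dfg_state: str
    ligand_glu501_distance: float | None = None

    def as_dict(self) -> dict:
        return {
            "protomer": self.protomer,
            "alpha_c_position": self.alpha_c_position,
            "alpha_c_state": self.alpha_c_state,
            "ke_min_distance": self.ke_min_distance,
            "salt_bridge_formed": self.salt_bridge_formed,
            "dfg_pseudo_dihedral": self.dfg_pseudo_dihedral,
            "dfg_state": self.dfg_state,
            "ligand_glu501_distance": self.ligand_glu501_distance,
        }


def metric_record(
    structure: KinaseStructure,
    protomer: str,
    anchors: AnchorMap = DEFAULT_ANCHORS,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    ligand: str | None = None,
    coords: np.ndarray | None = None,
) -> MetricRecord:
    """Aggregate the three conformational metrics (and optionally the
    ligand–Glu501 distance) into one :class:`MetricRecord`."""
    pos = alpha_c_position(structure, protomer, anchors, coords)
    ke = ke_min_distance(structure, protomer, anchors, coords)
    dih = dfg_pseudo_dihedral(structure, protomer, anchors, coords)
    lig_d = None
    if ligand is not None:
        from .fingerprint import ligand_glu501_min_distance

        lig_d = ligand_glu501_min_distance(
            structure, protomer, ligand, anchors, coords=coords
        )
    return MetricRecord(
        protomer=protomer,
        alpha_c_position=pos,
        alpha_c_state=classify_alpha_c(pos, thresholds),
        ke_min_distance=ke,
        salt_bridge_formed=is_salt_bridge(ke, thresholds),
        dfg_pseudo_dihedral=dih,
        dfg_state=classify_dfg(dih, thresholds),
        ligand_glu501_distance=lig_d,
    )
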