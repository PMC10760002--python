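"""Residue-level ligand–kinase interaction fingerprints.

Interactions are detected from heavy-atom distances alone, with three types:

* ``H_DONOR`` — a ligand donor (N/O bearing a hydrogen, or flagged as donor)
  within 3.5 Å of a protein acceptor (backbone carbonyl O or acceptor-capable
  sidechain N/O).  "H_DONOR" always means *the ligand donates*.
* ``H_ACCEPTOR`` — the converse: ligand acceptor within 3.5 Å of a protein
  donor (backbone amide N or donor-capable sidechain N/O).
* ``HYDROPHOBIC`` — apolar (carbon) proximity: 4.0 Å for aromatic–aromatic
  pairs, 4.5 Å for all other apolar pairs.  Aromatic face-to-face stacking is
  deliberately folded into the hydrophobic class.

The h-bond criterion is distance-only (no donor–H–acceptor angle); an
optional angle filter exists but is off by default, since crystal-structure
hydrogens are usually absent and the donor–acceptor distance is the stated
definition.  All cutoffs are inclusive (≤).

Ligand atom typing is perceived from connectivity (bond records when present,
covalent-radius distances otherwise) and can be corrected through an override
table — mirroring the practice of manually verifying automated fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .anchors import DEFAULT_ANCHORS, DEFAULT_THRESHOLDS, AnchorMap, Thresholds
from .errors import TypingError
from .structure import KinaseStructure

HYDROPHOBIC = "HYDROPHOBIC"
H_DONOR = "H_DONOR"
H_ACCEPTOR = "H_ACCEPTOR"

# -- protein donor/acceptor/aromatic templates (standard residue chemistry) --

BACKBONE_DONOR = "N"       # amide nitrogen (absent donor H in proline)
BACKBONE_ACCEPTORS = ("O", "OXT")

SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("ND2",), "GLN": ("NE2",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"), "TRP": ("NE1",),
}
SIDECHAIN_ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
}
AROMATIC_SIDECHAIN = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: C–O bond lengths above this are taken as single bonds (hydroxyl-like)
_CARBONYL_BOND_MAX = 1.32
#: max deviation (Å) from the best-fit plane for a ring to count as aromatic
_RING_PLANARITY_TOL = 0.15


@dataclass(frozen=True)
class LigandAtomTyping:
    """Chemical roles of ligand heavy atoms, keyed by atom name."""

    donor_atoms: frozenset[str]
    acceptor_atoms: frozenset[str]
    aromatic_atoms: frozenset[str]
    heavy_atoms: frozenset[str]

    def __post_init__(self):
        if not (self.donor_atoms | self.acceptor_atoms) <= self.heavy_atoms:
            raise ValueError("donor/acceptor atoms must be heavy atoms")


@dataclass(frozen=True)
class InteractionRecord:
    residue_id: int
    residue_name: str
    interaction: str
    min_distance: float
    ligand_atom: str
    protein_atom: str


@dataclass(frozen=True)
class Fingerprint:
    """Deduplicated interaction records of one ligand with one protomer.

    At most one record per (residue, interaction type), carrying the minimum
    qualifying distance; records sorted by residue id then interaction type.
    """

    ligand_id: str
    protomer: str
    records: tuple[InteractionRecord, ...]

    def residues(self) -> tuple[int, ...]:
        return tuple(sorted({r.residue_id for r in self.records}))

    def as_table(self):
        """records as a pandas DataFrame (residues × interaction columns)."""
        import pandas as pd

        rows = [
            {
                "residue_id": r.residue_id,
                "residue_name": r.residue_name,
                "interaction": r.interaction,
                "min_distance": r.min_distance,
                "ligand_atom": r.ligand_atom,
                "protein_atom": r.protein_atom,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "residue_id", "residue_name", "interaction",
                "min_distance", "ligand_atom", "protein_atom",
            ],
        )


# ---------------------------------------------------------------------------
# ligand typing
# ---------------------------------------------------------------------------

def _ring_atoms(sub: struc.AtomArray, bonds: np.ndarray, heavy_idx: np.ndarray) -> set[int]:
    """Indices (into sub) of atoms in planar 5–7 membered heavy-atom rings."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(heavy_idx.tolist())
    hset = set(heavy_idx.tolist())
    for i, j in bonds:
        if i in hset and j in hset:
            g.add_edge(int(i), int(j))
    aromatic: set[int] = set()
    for cyc in nx.cycle_basis(g):
        if not 5 <= len(cyc) <= 7:
            continue
        if any(sub.element[i].upper() not in ("C", "N", "O", "S") for i in cyc):
            continue
        pts = sub.coord[cyc]
        centered = pts - pts.mean(axis=0)
        # smallest singular direction = ring normal; planarity from residuals
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        dev = np.abs(centered @ vt[-1])
        if dev.max() <= _RING_PLANARITY_TOL:
            aromatic.update(int(i) for i in cyc)
    return aromatic


def type_ligand_atoms(
    structure: KinaseStructure,
    ligand: str,
    overrides: dict[str, set[str]] | None = None,
) -> LigandAtomTyping:
    """Perceive donor/acceptor/aromatic roles of a ligand's heavy atoms.

    Connectivity comes from covalent-radius distance perception.  Donors are
    N/O with at least one bonded hydrogen; if the ligand carries no hydrogens
    (the usual case for crystal structures), under-coordinated N (≤ 2 heavy
    neighbours) and hydroxyl-like O (one heavy neighbour, single-bond length)
    are assumed protonated.  Acceptors are every O plus N with lone-pair
    capacity (≤ 2 heavy neighbours and no implied donor H on a saturated
    amide).  ``overrides`` maps atom names to replacement role sets drawn from
    {"donor", "acceptor", "aromatic"} (empty set = strip all roles).
    """
    idx = structure.ligand_indices(ligand)
    sub = structure.atoms[idx]
    elem = np.char.upper(sub.element.astype("U4"))
    heavy = np.flatnonzero((elem != "H") & (elem != "D"))
    if heavy.size == 0:
        raise TypingError(f"ligand {ligand!r} has no heavy atoms")
    names = sub.atom_name
    if len(set(names[heavy])) != heavy.size:
        raise TypingError(f"ligand {ligand!r} has duplicate atom names; cannot type")
    try:
        bond_list = struc.connect_via_distances(sub)
        bonds = bond_list.as_array()[:, :2]
    except Exception as exc:
        raise TypingError(
            f"could not perceive connectivity for {ligand!r}: {exc}; "
            "supply an override table"
        ) from exc

    n_atoms = len(sub)
    neighbors: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        neighbors[int(i)].append(int(j))
        neighbors[int(j)].append(int(i))

    has_any_h = bool(np.any((elem == "H") | (elem == "D")))
    aromatic_idx = _ring_atoms(sub, bonds, heavy)

    donors: set[str] = set()
    acceptors: set[str] = set()
    for i in heavy:
        e = elem[i]
        if e not in ("N", "O"):
            continue
        heavy_nb = [j for j in neighbors[i] if elem[j] not in ("H", "D")]
        h_nb = [j for j in neighbors[i] if elem[j] in ("H", "D")]
        if e == "O":
            acceptors.add(names[i])
            if h_nb:
                donors.add(names[i])
            elif not has_any_h and len(heavy_nb) == 1:
                d = np.linalg.norm(sub.coord[i] - sub.coord[heavy_nb[0]])
                if d > _CARBONYL_BOND_MAX:  # single bond ⇒ hydroxyl-like
                    donors.add(names[i])
        else:  # nitrogen
            if h_nb:
                donors.add(names[i])
            elif not has_any_h and len(heavy_nb) <= 2:
                donors.add(names[i])
            if len(heavy_nb) + len(h_nb) <= 2:
                acceptors.add(names[i])

    aromatic = {names[i] for i in aromatic_idx}
    heavy_names = set(names[heavy])

    if overrides:
        for name, roles in overrides.items():
            if name not in heavy_names:
                raise TypingError(f"override names unknown atom {name!r}")
            roles = {r.lower() for r in roles} - {"none"}
            donors.discard(name)
            acceptors.discard(name)
            aromatic.discard(name)
            if "donor" in roles:
                donors.add(name)
            if "acceptor" in roles:
                acceptors.add(name)
            if "aromatic" in roles:
                aromatic.add(name)

    return LigandAtomTyping(
        donor_atoms=frozenset(donors),
        acceptor_atoms=frozenset(acceptors),
        aromatic_atoms=frozenset(aromatic),
        heavy_atoms=frozenset(heavy_names),
    )


# ---------------------------------------------------------------------------
# protein-side role resolution
# ---------------------------------------------------------------------------

def _protein_roles(structure: KinaseStructure, protomer: str):
    """Per-atom role flags for the heavy atoms of one protomer."""
    mask = structure.protomer_mask(protomer) & structure.heavy_mask
    idx = np.flatnonzero(mask)
    atoms = structure.atoms
    names = atoms.atom_name[idx]
    resn = atoms.res_name[idx]
    elem = np.char.upper(atoms.element[idx].astype("U4"))

    donor = np.zeros(idx.size, dtype=bool)
    acceptor = np.zeros(idx.size, dtype=bool)
    aromatic = np.zeros(idx.size, dtype=bool)
    for k in range(idx.size):
        n, rn = names[k], resn[k]
        if n == BACKBONE_DONOR and rn != "PRO":
            donor[k] = True
        if n in BACKBONE_ACCEPTORS:
            acceptor[k] = True
        if n in SIDECHAIN_DONORS.get(rn, ()):
            donor[k] = True
        if n in SIDECHAIN_ACCEPTORS.get(rn, ()):
            acceptor[k] = True
        if n in AROMATIC_SIDECHAIN.get(rn, ()):
            aromatic[k] = True
    apolar = elem == "C"
    return idx, donor, acceptor, aromatic, apolar


def _dedupe_min(records: list[InteractionRecord]) -> list[InteractionRecord]:
    best: dict[tuple[int, str], InteractionRecord] = {}
    for rec in records:
        key = (rec.residue_id, rec.interaction)
        if key not in best or rec.min_distance < best[key].min_distance:
            best[key] = rec
    return [best[k] for k in sorted(best)]


def _pair_records(
    structure, protomer, ligand, coords,
    lig_names, prot_sel, interaction, cutoff_matrix,
) -> list[InteractionRecord]:
    """Generic qualifying-pair scan; cutoff_matrix gives the per-pair cutoff."""
    lig_idx_all = structure.ligand_indices(ligand)
    sub_names = structure.atoms.atom_name[lig_idx_all]
    lig_pick = np.flatnonzero(np.isin(sub_names, list(lig_names)))
    if lig_pick.size == 0 or prot_sel.size == 0:
        return []
    lig_idx = lig_idx_all[lig_pick]
    xyz = structure.atoms.coord if coords is None else np.asarray(coords)
    d = np.linalg.norm(
        xyz[lig_idx][:, None, :] - xyz[prot_sel][None, :, :], axis=-1
    )
    qual = d <= cutoff_matrix
    records = []
    atoms = structure.atoms
    for li, pi in zip(*np.nonzero(qual)):
        gi = int(prot_sel[pi])
        records.append(
            InteractionRecord(
                residue_id=int(atoms.res_id[gi]),
                residue_name=str(atoms.res_name[gi]),
                interaction=interaction,
                min_distance=float(d[li, pi]),
                ligand_atom=str(atoms.atom_name[lig_idx[li]]),
                protein_atom=str(atoms.atom_name[gi]),
            )
        )
    return _dedupe_min(records)


def detect_hbonds(
    structure: KinaseStructure,
    protomer: str,
    ligand: str,
    typing: LigandAtomTyping,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    coords: np.ndarray | None = None,
) -> list[InteractionRecord]:
    """Hydrogen bonds between a ligand and one protomer (distance criterion).

    Returns one record per (residue, direction) with the minimum qualifying
    donor–acceptor distance.  A ligand atom typed as both donor and acceptor
    facing a protein atom with the same dual capacity yields both directions.
    """
    idx, p_donor, p_acceptor, _, _ = _protein_roles(structure, protomer)
    cutoff = thresholds.hbond_cutoff
    recs = _pair_records(
        structure, protomer, ligand, coords,
        typing.donor_atoms, idx[p_acceptor], H_DONOR, cutoff,
    )
    recs += _pair_records(
        structure, protomer, ligand, coords,
        typing.acceptor_atoms, idx[p_donor], H_ACCEPTOR, cutoff,
    )
    return _dedupe_min(recs)


def detect_hydrophobic(
    structure: KinaseStructure,
    protomer: str,
    ligand: str,
    typing: LigandAtomTyping,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    coords: np.ndarray | None = None,
) -> list[InteractionRecord]:
    """Apolar contacts: aromatic–aromatic pairs ≤ 4.0 Å, other C–C pairs ≤ 4.5 Å."""
    idx, _, _, p_aromatic, p_apolar = _protein_roles(structure, protomer)
    prot_sel = idx[p_apolar | p_aromatic]
    prot_arom = p_aromatic[p_apolar | p_aromatic]

    lig_idx_all = structure.ligand_indices(ligand)
    sub_names = structure.atoms.atom_name[lig_idx_all]
    elem = np.char.upper(structure.atoms.element[lig_idx_all].astype("U4"))
    lig_apolar_names = [
        str(n) for n, e in zip(sub_names, elem)
        if e == "C" or n in typing.aromatic_atoms
    ]
    lig_arom = np.array([n in typing.aromatic_atoms for n in lig_apolar_names])
    if not lig_apolar_names:
        return []
    # per-pair cutoff: 4.0 iff both sides aromatic
    cutoff = np.where(
        lig_arom[:, None] & prot_arom[None, :],
        thresholds.hydrophobic_aromatic_cutoff,
        thresholds.hydrophobic_cutoff,
    )
    return _pair_records(
        structure, protomer, ligand, coords,
        lig_apolar_names, prot_sel, HYDROPHOBIC, cutoff,
    )


def ligand_glu501_min_distance(
    structure: KinaseStructure,
    protomer: str,
    ligand: str,
    anchors: AnchorMap = DEFAULT_ANCHORS,
    typing: LigandAtomTyping | None = None,
    coords: np.ndarray | None = None,
) -> float:
    """Minimum distance (Å) between the ligand's donor atoms and the αC
    glutamate carboxylate oxygens — the x-axis quantity of the ligand–Glu501
    density analysis."""
    if typing is None:
        typing = type_ligand_atoms(structure, ligand)
    oxy = structure.residue_atom_indices(
        protomer, anchors.alpha_c_glutamate, atom_names=["OE1", "OE2"]
    )
    lig_idx_all = structure.ligand_indices(ligand)
    names = structure.atoms.atom_name[lig_idx_all]
    donors = lig_idx_all[np.isin(names, list(typing.donor_atoms))]
    if donors.size == 0:
        return float("inf")
    xyz = structure.atoms.coord if coords is None else np.asarray(coords)
    d = np.linalg.norm(xyz[donors][:, None, :] - xyz[oxy][None, :, :], axis=-1)
    return float(d.min())


def has_glu501_hbond(
    structure: KinaseStructure,
    protomer: str,
    ligand: str,
    anchors: AnchorMap = DEFAULT_ANCHORS,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    typing: LigandAtomTyping | None = None,
    coords: np.ndarray | None = None,
) -> tuple[bool, float]:
    """Does the ligand donate an h-bond to the αC-glutamate carboxylate?

    Returns ``(formed, min_donor_carboxylate_distance)``; formed iff the
    minimum distance is ≤ the h-bond cutoff (inclusive).
    """
    d = ligand_glu501_min_distance(structure, protomer, ligand, anchors, typing, coords)
    return d <= thresholds.hbond_cutoff, d


def build_fingerprint(
    structure: KinaseStructure,
    protomer: str,
    ligand: str,
    typing: LigandAtomTyping | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    coords: np.ndarray | None = None,
) -> Fingerprint:
    """Full residue-level fingerprint: h-bond plus hydrophobic records,
    deduplicated per (residue, interaction) keeping the minimum distance."""
    if typing is None:
        typing = type_ligand_atoms(structure, ligand)
    recs = detect_hbonds(structure, protomer, ligand, typing, thresholds, coords)
    recs += detect_hydrophobic(structure, protomer, ligand, typing, thresholds, coords)
    order = {H_DONOR: 0, H_ACCEPTOR: 1, HYDROPHOBIC: 2}
    recs = sorted(_dedupe_min(recs), key=lambda r: (r.residue_id, order[r.interaction]))
    return Fingerprint(ligand_id=ligand, protomer=protomer, records=tuple(recs))
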