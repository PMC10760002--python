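"""Structure and trajectory I/O for protomer-resolved kinase analysis.

A :class:`KinaseStructure` wraps a biotite ``AtomArray`` with a mapping from
protomer labels to chains and an inventory of bound ligands.  Trajectory
ensembles are ordered coordinate frames over a fixed topology, grouped into
replicas, with an optional burn-in fraction that is excluded from every
downstream statistic.

Conventions
-----------
* Author (PDB) residue numbering is canonical; Glu501 means author id 501.
* Alternate locations are resolved to the highest-occupancy conformer
  (ties: first listed), deterministically.
* Hydrogens are retained in the atom array but flagged; every metric in this
  package operates on heavy atoms only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    ArityError,
    FormatError,
    MissingResidueError,
    ModelNotFoundError,
    TopologyMismatchError,
)

#: residue names treated as solvent/buffer/ions rather than ligands
NON_LIGAND_RESNAMES = frozenset(
    {
        "HOH", "WAT", "DOD", "H2O", "SOL",
        "NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "NI", "CD", "IOD", "BR",
        "SO4", "PO4", "GOL", "EDO", "ACT", "DMS", "PEG", "PG4", "CIT", "FMT", "NO3",
        "MPD", "TRS", "EPE", "MES", "BME", "PGE",
    }
)


def _is_hydrogen(element: np.ndarray) -> np.ndarray:
    elem = np.char.upper(element.astype("U4"))
    return (elem == "H") | (elem == "D")


def set_coordinates64(atoms: struc.AtomArray, coords: np.ndarray) -> None:
    """Install float64 coordinates on a biotite atom array.

    biotite's public ``coord`` setter downcasts to float32; geometric
    contracts here (exact synthetic scaffolds, sub-1e-6 closed loops) need
    double precision, so the array is stored directly.
    """
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if coords.shape != (atoms.array_length(), 3):
        raise ValueError(f"coordinate shape {coords.shape} does not fit atom array")
    atoms._coord = coords


@dataclass
class KinaseStructure:
    """A kinase (mono- or multimeric) structure with protomer organization.

    Parameters
    ----------
    atoms :
        biotite ``AtomArray`` carrying coordinates (Å) and annotations
        (``chain_id``, ``res_id``, ``ins_code``, ``res_name``, ``atom_name``,
        ``element``, ``hetero``).
    protomers :
        Mapping from protomer label (typically ``"A"``/``"B"``) to a tuple of
        chain ids making up that protomer.  Protomer selections cover the
        polymer (non-hetero) atoms of those chains.
    ligands :
        Mapping from ligand identifier (``"RESNAME:chain:resid"``) to the
        integer atom indices of that ligand instance.
    source :
        Provenance text (file path, PDB id, or "synthetic:...").
    """

    atoms: struc.AtomArray
    protomers: dict[str, tuple[str, ...]] = field(default_factory=dict)
    ligands: dict[str, np.ndarray] = field(default_factory=dict)
    source: str = ""
    scaffold_specs: dict | None = None  # set by the synthetic generator

    def __post_init__(self):
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("non-finite coordinates")
        seen: set[str] = set()
        for label, chains in self.protomers.items():
            if not np.any(self.protomer_mask(label)):
                raise ValueError(f"protomer {label!r} selects no atoms")
            overlap = seen.intersection(chains)
            if overlap:
                raise ValueError(f"chains {sorted(overlap)} assigned to two protomers")
            seen.update(chains)

    # -- masks and selections -------------------------------------------------

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~_is_hydrogen(self.atoms.element)

    def protomer_mask(self, label: str) -> np.ndarray:
        try:
            chains = self.protomers[label]
        except KeyError:
            raise KeyError(
                f"unknown protomer {label!r}; have {sorted(self.protomers)}"
            ) from None
        return np.isin(self.atoms.chain_id, list(chains)) & ~self.atoms.hetero

    def protomer_labels(self) -> tuple[str, ...]:
        return tuple(self.protomers)

    def ligand_indices(self, ligand: str) -> np.ndarray:
        if ligand in self.ligands:
            return self.ligands[ligand]
        # allow lookup by bare residue name, unique or per all copies
        matches = [k for k in self.ligands if k.split(":")[0] == ligand]
        if len(matches) == 1:
            return self.ligands[matches[0]]
        if len(matches) > 1:
            raise KeyError(
                f"ligand name {ligand!r} is ambiguous: {matches}; use the full id"
            )
        raise KeyError(f"no ligand {ligand!r}; have {sorted(self.ligands)}")

    def ligand_for_protomer(self, protomer: str, name: str | None = None) -> str | None:
        """Identifier of the ligand copy bound in (= sharing a chain with) a protomer."""
        chains = set(self.protomers[protomer])
        found = []
        for lig_id in self.ligands:
            resname, chain, _ = lig_id.split(":")
            if chain in chains and (name is None or resname == name):
                found.append(lig_id)
        if not found:
            return None
        return found[0]

    def residue_atom_indices(
        self,
        protomer: str,
        residue_id: int,
        atom_names=None,
        insertion_code: str = "",
        heavy_only: bool = True,
    ) -> np.ndarray:
        """Indices of (heavy) atoms of one residue in one protomer.

        Raises :class:`MissingResidueError` when the residue, or any requested
        atom of it, is not resolved — unresolved anchors must fail loudly.
        """
        mask = self.protomer_mask(protomer) & (self.atoms.res_id == residue_id)
        if insertion_code:
            mask &= self.atoms.ins_code == insertion_code
        if heavy_only:
            mask &= self.heavy_mask
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise MissingResidueError(protomer, residue_id)
        if atom_names is None:
            return idx
        names = list(atom_names)
        by_name = {self.atoms.atom_name[i]: i for i in idx}
        picked = []
        for name in names:
            if name not in by_name:
                raise MissingResidueError(
                    protomer, residue_id, detail=f"atom {name!r} missing"
                )
            picked.append(by_name[name])
        return np.asarray(picked, dtype=int)

    # -- derived views --------------------------------------------------------

    def with_coordinates(self, coords: np.ndarray) -> "KinaseStructure":
        """Same topology with replaced coordinates (used per trajectory frame)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.atoms.coord.shape:
            raise TopologyMismatchError(
                f"coordinate shape {coords.shape} != topology {self.atoms.coord.shape}"
            )
        atoms = self.atoms.copy()
        set_coordinates64(atoms, coords)
        return KinaseStructure(
            atoms=atoms,
            protomers=dict(self.protomers),
            ligands={k: v.copy() for k, v in self.ligands.items()},
            source=self.source,
            scaffold_specs=self.scaffold_specs,
        )

    def summary(self) -> dict:
        """Chains, protomers, ligands and resolved residue ranges (CLI `inspect`)."""
        out = {"source": self.source, "n_atoms": len(self.atoms)}
        chains = {}
        poly = ~self.atoms.hetero
        for ch in sorted(set(self.atoms.chain_id[poly])):
            ids = self.atoms.res_id[poly & (self.atoms.chain_id == ch)]
            chains[ch] = {"first_residue": int(ids.min()), "last_residue": int(ids.max()),
                          "n_residues": int(len(np.unique(ids)))}
        out["chains"] = chains
        out["protomers"] = {k: list(v) for k, v in self.protomers.items()}
        out["ligands"] = {k: int(v.size) for k, v in self.ligands.items()}
        return out


def select_atoms(
    structure: KinaseStructure,
    protomer: str,
    residue_id: int,
    atom_names,
    insertion_code: str = "",
) -> np.ndarray:
    """Heavy atoms of ``residue_id`` in ``protomer`` matching ``atom_names``.

    Returns atom indices in the order the names are given (deterministic and
    invariant to the file's atom ordering within the residue).
    """
    return structure.residue_atom_indices(
        protomer, residue_id, atom_names=atom_names, insertion_code=insertion_code
    )


def _infer_ligands(atoms: struc.AtomArray) -> dict[str, np.ndarray]:
    ligands: dict[str, np.ndarray] = {}
    het = atoms.hetero & ~np.isin(atoms.res_name, list(NON_LIGAND_RESNAMES))
    for i in np.flatnonzero(het):
        key = f"{atoms.res_name[i]}:{atoms.chain_id[i]}:{atoms.res_id[i]}"
        ligands.setdefault(key, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in ligands.items()}


def structure_from_atoms(
    atoms: struc.AtomArray,
    protomer_map: dict[str, tuple[str, ...]] | None = None,
    source: str = "",
) -> KinaseStructure:
    """Build a :class:`KinaseStructure`, inferring protomers and ligands.

    By default every polymer chain is its own protomer, labelled by its chain
    id; pass ``protomer_map`` for non-standard depositions (e.g. two chains
    forming one protomer).
    """
    if protomer_map is None:
        chains = sorted(set(atoms.chain_id[~atoms.hetero]))
        protomer_map = {c: (c,) for c in chains}
    if atoms.coord.dtype != np.float64:
        set_coordinates64(atoms, atoms.coord.astype(np.float64))
    return KinaseStructure(
        atoms=atoms,
        protomers={k: tuple(v) for k, v in protomer_map.items()},
        ligands=_infer_ligands(atoms),
        source=source,
    )


def read_structure(
    path,
    model_index: int | None = None,
    protomer_map: dict[str, tuple[str, ...]] | None = None,
) -> KinaseStructure:
    """Read a (single- or multi-model) PDB file into a :class:`KinaseStructure`.

    Parameters
    ----------
    path :
        PDB file path (mmCIF also accepted when the suffix is ``.cif``).
    model_index :
        1-based model to load from a multi-model file; default: first model.
    protomer_map :
        Optional override of the chain → protomer assignment.

    Alt-locs are resolved to the highest-occupancy conformer (ties broken by
    file order).  Hydrogens are kept in the atom array but excluded from all
    metric selections.
    """
    path = os.fspath(path)
    try:
        if path.lower().endswith((".cif", ".mmcif")):
            from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get

            cif = CIFFile.read(path)
            atoms = _cif_get(
                cif, model=model_index or 1, altloc="occupancy",
                extra_fields=["occupancy"],
            )
        else:
            pdb = PDBFile.read(path)
            atoms = pdb.get_structure(
                model=model_index or 1, altloc="occupancy",
                extra_fields=["occupancy"],
            )
    except (MissingResidueError, ModelNotFoundError):
        raise
    except ValueError as exc:
        if "model" in str(exc):
            raise ModelNotFoundError(str(exc)) from exc
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    except Exception as exc:  # biotite raises several parse-error types
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return structure_from_atoms(atoms, protomer_map, source=path)


def write_structure(structure: KinaseStructure, path) -> None:
    """Write a structure as PDB; coordinates round-trip at 3-decimal precision."""
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    pdb.write(os.fspath(path))


def write_multimodel(topology: KinaseStructure, coords: np.ndarray, path) -> None:
    """Write frames (n_frames, n_atoms, 3) over ``topology`` as a multi-model PDB."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[1:] != topology.atoms.coord.shape:
        raise TopologyMismatchError(
            f"frames shape {coords.shape} incompatible with topology"
        )
    stack = struc.from_template(topology.atoms, coords)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(os.fspath(path))


@dataclass
class TrajectoryEnsemble:
    """Replicated coordinate frames over a fixed topology.

    ``replicas[r]`` has shape (n_frames, n_atoms, 3) in Å.  The first
    ``floor(burn_in_fraction * n_frames)`` frames of each replica are treated
    as equilibration and excluded from analysis — the default of 0.4 mirrors
    discarding the first 2 µs of a 5 µs run and analysing the last 3 µs.
    """

    topology: KinaseStructure
    replicas: list[np.ndarray]
    burn_in_fraction: float = 0.4

    def __post_init__(self):
        if not self.replicas:
            raise ValueError("at least one replica required")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        n_atoms = len(self.topology.atoms)
        clean = []
        for r, rep in enumerate(self.replicas):
            rep = np.asarray(rep, dtype=float)
            if rep.ndim != 3 or rep.shape[1] != n_atoms or rep.shape[2] != 3:
                raise TopologyMismatchError(
                    f"replica {r}: frame shape {rep.shape} does not match "
                    f"topology with {n_atoms} atoms"
                )
            clean.append(rep)
        self.replicas = clean

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def n_discard(self, replica: int) -> int:
        return int(np.floor(self.burn_in_fraction * self.replicas[replica].shape[0]))

    def analysis_coords(self, replica: int) -> np.ndarray:
        """Post-burn-in frames of one replica."""
        return self.replicas[replica][self.n_discard(replica):]

    def n_analysis_frames(self, replica: int) -> int:
        return self.replicas[replica].shape[0] - self.n_discard(replica)

    def iter_analysis_frames(self):
        """Yield (replica_index, frame_coords) over all analysis frames."""
        for r in range(self.n_replicas):
            for frame in self.analysis_coords(r):
                yield r, frame


def read_trajectory(
    topology_path,
    frames_paths,
    burn_in_fraction: float = 0.4,
    protomer_map: dict[str, tuple[str, ...]] | None = None,
) -> TrajectoryEnsemble:
    """Load a replica ensemble: one multi-model PDB file per replica.

    Every frame file must share the topology's atom count and ordering;
    a mismatch raises :class:`TopologyMismatchError`.
    """
    topology = read_structure(topology_path, protomer_map=protomer_map)
    n_atoms = len(topology.atoms)
    replicas = []
    for path in frames_paths:
        try:
            pdb = PDBFile.read(os.fspath(path))
            coords = pdb.get_coord()  # (models, atoms, 3)
        except Exception as exc:
            raise FormatError(f"cannot parse frames file {path}: {exc}") from exc
        if coords.shape[1] != n_atoms:
            raise TopologyMismatchError(
                f"{path}: {coords.shape[1]} atoms per frame, topology has {n_atoms}"
            )
        replicas.append(np.asarray(coords, dtype=float))
    return TrajectoryEnsemble(topology, replicas, burn_in_fraction)


def fetch_structure(pdb_id: str, cache_dir) -> KinaseStructure:
    """Fetch a PDB entry from RCSB into ``cache_dir`` and read it.

    Uses the file already in the cache when present, so previously fetched
    entries work offline.
    """
    cache_dir = os.fspath(cache_dir)
    os.makedirs(cache_dir, exist_ok=True)
    local = os.path.join(cache_dir, f"{pdb_id.lower()}.pdb")
    if not os.path.exists(local):
        import biotite.database.rcsb as rcsb

        rcsb.fetch(pdb_id, "pdb", cache_dir)
        # biotite names the file <id>.pdb in the target directory
        if not os.path.exists(local):
            raise FormatError(f"fetch of {pdb_id} produced no file")
    return read_structure(local)


def require_dimer(structure: KinaseStructure) -> tuple[str, str]:
    """Return the two protomer labels, or raise :class:`ArityError`."""
    labels = structure.protomer_labels()
    if len(labels) != 2:
        raise ArityError(
            f"operation requires a dimer; structure has {len(labels)} "
            f"protomer(s): {list(labels)}"
        )
    return labels[0], labels[1]
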