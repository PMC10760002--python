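"""Synthetic kinase scaffolds and trajectories with dialled-in conformations.

The generator builds *geometric minimal models*, not physically plausible
proteins: each anchor residue carries exactly the atoms the metrics read
(Cα everywhere; Lys Nζ, Glu Oε1/Oε2, His backbone C/O), arranged in spatially
separated clusters so every metric can be set independently:

* the αC cluster realizes a requested αC position exactly (the three helix
  center Cα sit at 120° around their centroid, so the centroid is exact);
* the K–E cluster realizes a requested Lys Nζ – Glu Oε1 minimum distance,
  with Oε2 placed strictly farther;
* the DFG cluster realizes a requested pseudo-dihedral via internal
  coordinates (3.8 Å virtual bonds, 110° virtual angles);
* an optional one-donor ligand sits at a requested distance from the Glu
  carboxylate.

Trajectories draw named conformational states independently per frame,
replica and protomer according to scheduled fractions (no kinetics), realize
the corresponding geometry, and add isotropic Gaussian coordinate noise.
Everything is reproducible from the schedule's seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc

from .errors import ConstructionError
from .metrics import torsion_angle
from .structure import (
    KinaseStructure,
    TrajectoryEnsemble,
    set_coordinates64,
    structure_from_atoms,
    write_multimodel,
)

LIGAND_RESNAME = "LIG"
LIGAND_RESID = 900

#: scheduled state name → (ScaffoldSpec field, value when on, value when off)
STATE_GEOMETRY = {
    "salt_bridge_on": ("ke_distance", 2.8, 6.0),
    "alpha_c_in": ("alpha_c_position", 18.3, 22.0),
    "dfg_in": ("dfg_dihedral", 100.0, 290.0),
    "ligand_hbond_on": ("ligand_glu501_distance", 2.9, 6.5),
}


@dataclass(frozen=True)
class ScaffoldSpec:
    """Target geometry of one synthetic protomer.

    Defaults are the dimer-compatible holo regime: αC-in near the crystal
    value, formed K–E salt bridge, DFG-out, stable ligand–Glu501 h-bond.
    """

    alpha_c_position: float = 18.3
    ke_distance: float = 2.8
    dfg_dihedral: float = 290.0
    ligand_glu501_distance: float | None = 2.9
    include_ligand: bool = True

    def __post_init__(self):
        for name in ("alpha_c_position", "ke_distance"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConstructionError(f"{name} must be finite and positive, got {v}")
        if not 0 <= self.dfg_dihedral < 360:
            raise ConstructionError("dfg_dihedral must be in [0, 360)")
        if self.ligand_glu501_distance is not None and (
            not np.isfinite(self.ligand_glu501_distance)
            or self.ligand_glu501_distance <= 0
        ):
            raise ConstructionError("ligand_glu501_distance must be positive")

    def replace(self, **kw) -> "ScaffoldSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class TrajectorySchedule:
    """State fractions and noise for a synthetic replica ensemble."""

    n_frames: int
    n_replicas: int = 3
    state_fractions: dict = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1 or self.n_replicas < 1:
            raise ConstructionError("need at least one frame and one replica")
        if self.noise_sigma < 0:
            raise ConstructionError("noise_sigma must be non-negative")
        for name, frac in self.state_fractions.items():
            if name not in STATE_GEOMETRY:
                raise ConstructionError(
                    f"unknown state {name!r}; choose from {sorted(STATE_GEOMETRY)}"
                )
            if not 0 <= frac <= 1:
                raise ConstructionError(f"fraction for {name!r} must be in [0, 1]")


# ---------------------------------------------------------------------------
# geometry realization
# ---------------------------------------------------------------------------

def _dfg_chain(dihedral_deg: float) -> np.ndarray:
    """Four Cα positions realizing the requested torsion (3.8 Å, 110° frame)."""
    r, theta = 3.8, np.radians(110.0)
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([r, 0.0, 0.0])
    # bend by the supplement of the bond angle in the xy-plane
    bend = np.pi - theta
    p2 = p1 + r * np.array([np.cos(bend), np.sin(bend), 0.0])
    phi = np.radians(dihedral_deg)
    # place p3 by rotating the reference (trans) direction about the p1→p2 axis
    bc = (p2 - p1) / np.linalg.norm(p2 - p1)
    d = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(phi), r * np.sin(theta) * np.sin(phi)]
    )
    n = np.cross(p1 - p0, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    p3 = p2 + frame @ d
    pts = np.stack([p0, p1, p2, p3])
    measured = float(torsion_angle(*pts))
    if not np.isclose(measured, dihedral_deg, atol=1e-6):
        # torsion sign convention mismatch: mirror the out-of-plane component
        p3 = p2 + frame @ (d * np.array([1.0, 1.0, -1.0]))
        pts = np.stack([p0, p1, p2, p3])
        measured = float(torsion_angle(*pts))
    if not np.isclose((measured - dihedral_deg + 180) % 360 - 180, 0.0, atol=1e-6):
        raise ConstructionError(
            f"could not realize dihedral {dihedral_deg}° (got {measured}°)"
        )
    return pts


def _scaffold_atoms(spec: ScaffoldSpec):
    """Atom records and exact coordinates of one protomer (local frame).

    Returns (records, coords): records are tuples
    (res_id, res_name, atom_name, element, hetero).
    """
    records: list[tuple[int, str, str, str, bool]] = []
    coords: list[np.ndarray] = []

    def add(res_id, res_name, atom_name, element, xyz, hetero=False):
        records.append((res_id, res_name, atom_name, element, hetero))
        coords.append(np.asarray(xyz, dtype=float))

    # αC cluster around the origin
    add(582, "ILE", "CA", "C", (0.0, 0.0, 0.0))
    center = np.array([spec.alpha_c_position, 0.0, 0.0])
    ring = 2.0  # Cα spread around the helix-center centroid; cancels exactly
    for rid, rname, ang in ((500, "ASN", 0.0), (501, "GLU", 120.0), (502, "VAL", 240.0)):
        off = ring * np.array([0.0, np.cos(np.radians(ang)), np.sin(np.radians(ang))])
        add(rid, rname, "CA", "C", center + off)
    add(500, "ASN", "CB", "C", center + np.array([0.0, 3.5, 0.0]))

    # K–E cluster, 60 Å along +y
    base = np.array([0.0, 60.0, 0.0])
    add(483, "LYS", "CA", "C", base + np.array([0.0, -3.0, 0.0]))
    add(483, "LYS", "NZ", "N", base)
    oe1 = base + np.array([0.0, spec.ke_distance, 0.0])
    add(501, "GLU", "OE1", "O", oe1)
    add(501, "GLU", "OE2", "O", oe1 + np.array([2.2, 0.0, 0.0]))

    # HRD histidine cluster, 60 Å along +z (backbone carbonyl exposed)
    hb = np.array([0.0, 0.0, 60.0])
    add(574, "HIS", "CA", "C", hb)
    add(574, "HIS", "C", "C", hb + np.array([1.5, 0.0, 0.0]))
    add(574, "HIS", "O", "O", hb + np.array([2.1, 1.0, 0.0]))

    # DFG cluster, 60 Å along +x
    dfg = _dfg_chain(spec.dfg_dihedral) + np.array([60.0, 0.0, 0.0])
    for (rid, rname), xyz in zip(
        ((592, "ILE"), (593, "GLY"), (594, "ASP"), (595, "PHE")), dfg
    ):
        add(rid, rname, "CA", "C", xyz)
    add(594, "ASP", "N", "N", dfg[2] + np.array([0.0, 1.4, 0.0]))

    # optional minimal amide-bearing ligand near the Glu carboxylate
    if spec.include_ligand:
        d = spec.ligand_glu501_distance
        if d is None:
            n1 = np.array([30.0, 30.0, 30.0])  # parked far from everything
        else:
            n1 = oe1 + np.array([0.0, d, 0.0])
        add(LIGAND_RESID, LIGAND_RESNAME, "N1", "N", n1, hetero=True)
        c2 = n1 + np.array([0.0, 1.35, 0.0])
        add(LIGAND_RESID, LIGAND_RESNAME, "C2", "C", c2, hetero=True)
        add(LIGAND_RESID, LIGAND_RESNAME, "O2", "O", c2 + np.array([1.0, 0.72, 0.0]),
            hetero=True)
        add(LIGAND_RESID, LIGAND_RESNAME, "C3", "C", c2 + np.array([-1.2, 0.9, 0.0]),
            hetero=True)

    return records, np.stack(coords)


#: rigid offsets separating the protomers of a synthetic dimer
_PROTOMER_OFFSETS = {0: np.zeros(3), 1: np.array([0.0, 0.0, 150.0])}


def _build_structure(specs: dict[str, ScaffoldSpec], source: str) -> KinaseStructure:
    all_records = []
    all_coords = []
    chains = []
    for k, (label, spec) in enumerate(specs.items()):
        records, coords = _scaffold_atoms(spec)
        all_records += records
        all_coords.append(coords + _PROTOMER_OFFSETS[k])
        chains += [label] * len(records)
    coords = np.concatenate(all_coords)
    n = len(all_records)
    atoms = struc.AtomArray(n)
    atoms.chain_id = np.array(chains)
    atoms.res_id = np.array([r[0] for r in all_records])
    atoms.res_name = np.array([r[1] for r in all_records])
    atoms.atom_name = np.array([r[2] for r in all_records])
    atoms.element = np.array([r[3] for r in all_records])
    atoms.hetero = np.array([r[4] for r in all_records])
    set_coordinates64(atoms, coords)
    structure = structure_from_atoms(atoms, source=source)
    structure.scaffold_specs = dict(specs)
    return structure


def make_protomer(spec: ScaffoldSpec, label: str = "A") -> KinaseStructure:
    """A single synthetic protomer whose measured metrics equal ``spec``
    (within 1e-6 Å / degrees)."""
    return _build_structure({label: spec}, source="synthetic:protomer")


def make_dimer(
    spec_a: ScaffoldSpec, spec_b: ScaffoldSpec, labels: tuple[str, str] = ("A", "B")
) -> KinaseStructure:
    """A synthetic two-protomer structure; the protomers are rigidly separated
    so their metrics are fully independent."""
    return _build_structure(
        {labels[0]: spec_a, labels[1]: spec_b}, source="synthetic:dimer"
    )


def make_trajectory(
    base: KinaseStructure,
    schedule: TrajectorySchedule,
    burn_in_fraction: float = 0.0,
    out_prefix: str | os.PathLike | None = None,
) -> TrajectoryEnsemble:
    """Synthesize a replica ensemble over ``base`` (a structure produced by
    :func:`make_protomer` or :func:`make_dimer`).

    Per frame, replica and protomer, each scheduled state is drawn
    independently (Bernoulli with its fraction); the frame's geometry
    realizes the resulting targets and isotropic Gaussian noise of width
    ``noise_sigma`` is added to every coordinate.  With ``out_prefix`` set,
    one multi-model PDB per replica plus a JSON manifest (schedule + seed)
    are written.
    """
    if base.scaffold_specs is None:
        raise ConstructionError(
            "make_trajectory needs a synthetic base structure "
            "(built by make_protomer/make_dimer)"
        )
    specs = base.scaffold_specs
    rng = np.random.default_rng(schedule.seed)
    state_names = sorted(schedule.state_fractions)
    n_atoms = len(base.atoms)

    # frames only differ in a few discrete state targets: cache realizations
    coords_cache: dict[tuple[int, ScaffoldSpec], np.ndarray] = {}

    def realized(k: int, frame_spec: ScaffoldSpec) -> np.ndarray:
        key = (k, frame_spec)
        if key not in coords_cache:
            _, c = _scaffold_atoms(frame_spec)
            coords_cache[key] = c + _PROTOMER_OFFSETS[k]
        return coords_cache[key]

    replicas = []
    for _ in range(schedule.n_replicas):
        frames = np.empty((schedule.n_frames, n_atoms, 3))
        for f in range(schedule.n_frames):
            pieces = []
            for k, (label, spec) in enumerate(specs.items()):
                updates = {}
                for name in state_names:
                    fieldname, on, off = STATE_GEOMETRY[name]
                    draw = rng.random() < schedule.state_fractions[name]
                    if fieldname == "ligand_glu501_distance" and not spec.include_ligand:
                        continue
                    updates[fieldname] = on if draw else off
                frame_spec = spec.replace(**updates) if updates else spec
                pieces.append(realized(k, frame_spec))
            xyz = np.concatenate(pieces)
            if schedule.noise_sigma > 0:
                xyz = xyz + rng.normal(0.0, schedule.noise_sigma, xyz.shape)
            frames[f] = xyz
        replicas.append(frames)

    ensemble = TrajectoryEnsemble(
        topology=base, replicas=replicas, burn_in_fraction=burn_in_fraction
    )
    if out_prefix is not None:
        prefix = os.fspath(out_prefix)
        for r, frames in enumerate(replicas):
            write_multimodel(base, frames, f"{prefix}_rep{r + 1}.pdb")
        manifest = {
            "n_frames": schedule.n_frames,
            "n_replicas": schedule.n_replicas,
            "state_fractions": dict(schedule.state_fractions),
            "noise_sigma": schedule.noise_sigma,
            "seed": schedule.seed,
            "burn_in_fraction": burn_in_fraction,
            "protomers": list(specs),
            "files": [f"{prefix}_rep{r + 1}.pdb" for r in range(schedule.n_replicas)],
        }
        with open(f"{prefix}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return ensemble
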