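"""Empirical three-tier dimer-selectivity call from a dimeric co-crystal structure.

Dimer-compatible BRAF inhibitors donate a hydrogen bond to the αC-helix
glutamate (Glu501); the stability of that h-bond across the two protomers of
a dimeric co-crystal structure is reflected in how closely the two protomers
agree on the αC position and the K–E (Lys483–Glu501) distance.  The rule:

1. no Glu501 h-bond in either protomer  → ``MONOMER_SELECTIVE``;
2. h-bond present but the two protomers disagree (Δ ≥ 0.3 Å in αC position
   and/or K–E distance, after rounding to 0.1 Å) → ``EQUIPOTENT``;
3. h-bond present and both deltas < 0.3 Å → ``DIMER_SELECTIVE_LIKELY``.

A DFG-in conformation in either protomer is a secondary indicator of
equipotency and is appended to the notes without changing the call.  The
call is always returned with its full evidence record — given typical
crystal-structure resolutions of 2–3 Å this screen is an indicator, not a
replacement for rigorous (e.g. simulation-based) assessment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .anchors import DEFAULT_ANCHORS, DEFAULT_THRESHOLDS, AnchorMap, Thresholds
from .fingerprint import has_glu501_hbond, type_ligand_atoms
from .metrics import (
    STATE_IN,
    alpha_c_position,
    classify_dfg,
    dfg_pseudo_dihedral,
    ke_min_distance,
)
from .structure import KinaseStructure, require_dimer

MONOMER_SELECTIVE = "MONOMER_SELECTIVE"
EQUIPOTENT = "EQUIPOTENT"
DIMER_SELECTIVE_LIKELY = "DIMER_SELECTIVE_LIKELY"


@dataclass(frozen=True)
class ProtomerComparison:
    """Per-protomer metrics of a dimer and their rounded absolute differences."""

    protomer_labels: tuple[str, str]
    alpha_c_positions: tuple[float, float]
    ke_distances: tuple[float, float]
    delta_alpha_c: float
    delta_ke: float
    glu501_hbond: tuple[bool, bool]
    glu501_distances: tuple[float, float]
    dfg_states: tuple[str, str]

    def as_dict(self) -> dict:
        return {
            "protomer_labels": list(self.protomer_labels),
            "alpha_c_positions": list(self.alpha_c_positions),
            "ke_distances": list(self.ke_distances),
            "delta_alpha_c": self.delta_alpha_c,
            "delta_ke": self.delta_ke,
            "glu501_hbond": list(self.glu501_hbond),
            "glu501_distances": list(self.glu501_distances),
            "dfg_states": list(self.dfg_states),
        }


@dataclass(frozen=True)
class SelectivityCall:
    call: str
    evidence: ProtomerComparison
    notes: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"call": self.call, "notes": list(self.notes),
                "evidence": self.evidence.as_dict()}


def _round1(x: float) -> float:
    return round(x, 1)


def compare_protomers(
    structure: KinaseStructure,
    ligand: str | None = None,
    anchors: AnchorMap = DEFAULT_ANCHORS,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    round_before_delta: bool = False,
) -> ProtomerComparison:
    """Protomer-resolved metrics of a dimeric structure and their deltas.

    Deltas are absolute inter-protomer differences rounded to one decimal
    (the reporting precision of crystal-structure comparisons).  By default
    the difference is taken at full precision and then rounded;
    ``round_before_delta=True`` rounds the per-protomer values first.

    ``ligand`` may be a full ligand id, a bare residue name (each protomer's
    own copy is then used), or None (no h-bond evaluation; both flags False).
    """
    label_a, label_b = require_dimer(structure)
    pos = tuple(alpha_c_position(structure, p, anchors) for p in (label_a, label_b))
    ke = tuple(ke_min_distance(structure, p, anchors) for p in (label_a, label_b))
    dfg = tuple(
        classify_dfg(dfg_pseudo_dihedral(structure, p, anchors), thresholds)
        for p in (label_a, label_b)
    )

    hbond = [False, False]
    dists = [float("inf"), float("inf")]
    if ligand is not None:
        for k, prot in enumerate((label_a, label_b)):
            lig_id = ligand if ligand in structure.ligands else \
                structure.ligand_for_protomer(prot, name=ligand.split(":")[0])
            if lig_id is None:
                continue
            typing = type_ligand_atoms(structure, lig_id)
            formed, d = has_glu501_hbond(
                structure, prot, lig_id, anchors, thresholds, typing
            )
            hbond[k], dists[k] = formed, d

    if round_before_delta:
        d_ac = _round1(abs(_round1(pos[0]) - _round1(pos[1])))
        d_ke = _round1(abs(_round1(ke[0]) - _round1(ke[1])))
    else:
        d_ac = _round1(abs(pos[0] - pos[1]))
        d_ke = _round1(abs(ke[0] - ke[1]))

    return ProtomerComparison(
        protomer_labels=(label_a, label_b),
        alpha_c_positions=(float(pos[0]), float(pos[1])),
        ke_distances=(float(ke[0]), float(ke[1])),
        delta_alpha_c=d_ac,
        delta_ke=d_ke,
        glu501_hbond=(hbond[0], hbond[1]),
        glu501_distances=(dists[0], dists[1]),
        dfg_states=(dfg[0], dfg[1]),
    )


def classify_inhibitor(
    comparison: ProtomerComparison,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> SelectivityCall:
    """Apply the three-tier rule to a protomer comparison.

    Precedence is fixed: the h-bond check first (absence in *both* protomers
    → monomer-selective), then the deviation check (Δ ≥ threshold in either
    metric → equipotent), else dimer-selective-likely.  Presence in a single
    protomer counts as presence; a one-sided h-bond with discordant metrics
    lands in the equipotent tier, the conservative call.
    """
    notes: list[str] = []
    if STATE_IN in comparison.dfg_states:
        notes.append(
            "DFG-in conformation in at least one protomer: secondary indicator "
            "of an equipotent inhibitor"
        )
    if not any(comparison.glu501_hbond):
        call = MONOMER_SELECTIVE
    elif (
        comparison.delta_alpha_c >= thresholds.deviation_threshold
        or comparison.delta_ke >= thresholds.deviation_threshold
    ):
        call = EQUIPOTENT
    else:
        call = DIMER_SELECTIVE_LIKELY
    return SelectivityCall(call=call, evidence=comparison, notes=tuple(notes))


def classify_structure(
    structure: KinaseStructure,
    ligand: str,
    anchors: AnchorMap = DEFAULT_ANCHORS,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> SelectivityCall:
    """Convenience wrapper: compare the protomers of a dimeric co-crystal
    structure and classify its inhibitor."""
    comparison = compare_protomers(structure, ligand, anchors, thresholds)
    return classify_inhibitor(comparison, thresholds)
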