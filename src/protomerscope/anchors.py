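"""Residue anchors and numeric cutoffs for BRAF kinase-domain analysis.

Every residue number and distance/angle cutoff used by the metrics lives in
these two frozen dataclasses, so that (a) the constants are reviewable in one
place and (b) the same machinery can be pointed at a different kinase by
overriding fields.

Residue numbering is the author (PDB) numbering of human BRAF: the catalytic
lysine is Lys483, the αC-helix glutamate is Glu501, the DFG motif starts at
Asp594.  No renumbering is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class AnchorMap:
    """Residue ids of the structural anchors used by the conformational metrics.

    Attributes
    ----------
    alpha_c_center_residues :
        Three consecutive αC-helix residues whose Cα centroid marks the helix
        center (default Asn500, Glu501, Val502).
    alpha_c_reference_residue :
        Stable β7-strand reference residue (default Ile582); the αC position
        is the distance from its Cα to the helix-center centroid (the KLIFS
        αC metric).
    catalytic_lysine :
        β3 catalytic lysine (default Lys483); its sidechain ζ-nitrogen forms
        the K–E salt bridge.
    alpha_c_glutamate :
        αC glutamate (default Glu501); carboxylate partner of the salt bridge
        and the h-bond acceptor targeted by dimer-compatible inhibitors.
    dfg_dihedral_residues :
        Four consecutive residues whose Cα atoms define the DFG pseudo-dihedral
        (default Ile592, Gly593, Asp594, Phe595).
    hrd_histidine :
        HRD-motif histidine (default His574); its backbone carbonyl is an
        accessory h-bond acceptor for some back-pocket inhibitors.
    """

    alpha_c_center_residues: tuple[int, int, int] = (500, 501, 502)
    alpha_c_reference_residue: int = 582
    catalytic_lysine: int = 483
    alpha_c_glutamate: int = 501
    dfg_dihedral_residues: tuple[int, int, int, int] = (592, 593, 594, 595)
    hrd_histidine: int = 574

    def __post_init__(self):
        if len(set(self.dfg_dihedral_residues)) != 4:
            raise ValueError("dfg_dihedral_residues must be four distinct residues")
        if len(set(self.alpha_c_center_residues)) != 3:
            raise ValueError("alpha_c_center_residues must be three distinct residues")
        if self.alpha_c_reference_residue in self.alpha_c_center_residues:
            raise ValueError("αC reference residue must differ from the helix-center residues")

    def replace(self, **kw) -> "AnchorMap":
        return replace(self, **kw)

    @property
    def all_residues(self) -> tuple[int, ...]:
        return tuple(
            sorted(
                {
                    *self.alpha_c_center_residues,
                    self.alpha_c_reference_residue,
                    self.catalytic_lysine,
                    self.alpha_c_glutamate,
                    *self.dfg_dihedral_residues,
                    self.hrd_histidine,
                }
            )
        )


@dataclass(frozen=True)
class Thresholds:
    """Numeric cutoffs for state classification and interaction detection.

    Distances in Å, angles in degrees.  Boundary conventions (documented per
    predicate): αC-in and DFG-in are strict (<); salt bridge, h-bond,
    hydrophobic-contact, contact and stability cutoffs are inclusive (≤ / ≥);
    the inter-protomer deviation test is inclusive (≥).
    """

    alpha_c_in_cutoff: float = 19.6          # KLIFS αC-in/out boundary
    salt_bridge_cutoff: float = 4.0          # Lys483 Nζ – Glu501 Oε cutoff
    alpha_c_in_sidechain_cutoff: float = 4.5  # alternative αC-in definition
    dfg_in_cutoff: float = 140.0             # DFG pseudo-dihedral in/out boundary
    hbond_cutoff: float = 3.5                # donor–acceptor heavy-atom distance
    hydrophobic_aromatic_cutoff: float = 4.0
    hydrophobic_cutoff: float = 4.5
    contact_cutoff: float = 4.5              # residue contact (any heavy-atom pair)
    contact_stability: float = 0.7           # stable-contact probability threshold
    deviation_threshold: float = 0.3         # inter-protomer Δ marking "inconsistent"

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.hbond_cutoff >= self.hydrophobic_cutoff:
            raise ValueError("hbond_cutoff must be below hydrophobic_cutoff")
        if not self.contact_stability <= 1:
            raise ValueError("contact_stability is a fraction")

    def replace(self, **kw) -> "Thresholds":
        return replace(self, **kw)


DEFAULT_ANCHORS = AnchorMap()
DEFAULT_THRESHOLDS = Thresholds()
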