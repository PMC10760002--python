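# protomerscope

Protomer-resolved conformational analysis of BRAF kinase-domain dimers, for
structural biologists and medicinal chemists asking one question of a RAF
inhibitor: **will it prefer the monomeric or the dimeric BRAF^V600E^?**

The oncogenic BRAF^V600E^ kinase signals both as a monomer and as a
side-by-side dimer, and inhibitors split into monomer-selective, equipotent
and dimer-selective classes. The structural discriminators live in a handful
of well-defined collective variables, all computed here per protomer:

* **αC-helix position** — the KLIFS metric: the distance between the Cα of
  Ile582 (β7) and the Cα centroid of Asn500, Glu501 and Val502 (αC center);
  `d < 19.6 Å` is αC-in, above is αC-out.
* **K–E salt bridge** — `min(d(Lys483 Nζ, Glu501 Oε1), d(Lys483 Nζ, Glu501
  Oε2))`; formed at ≤ 4.0 Å (a 4.5 Å minimum-sidechain-distance variant is
  exposed as the alternative αC-in definition).
* **DFG pseudo-dihedral** — the torsion over the Cα atoms of
  Ile592–Gly593–Asp594–Phe595, reported in [0°, 360°); `θ < 140°` is DFG-in.
* **Ligand–Glu501 h-bond** — minimum distance between the ligand's donor
  atoms and the Glu501 carboxylate; a donor within 3.5 Å marks the h-bond
  that anchors dimer-compatible binding.

On top of the metrics sit residue-level **interaction fingerprints**
(h-bond ≤ 3.5 Å; hydrophobic contacts at 4.0 Å aromatic / 4.5 Å otherwise),
replica-**ensemble statistics** (50-bin distributions, state probabilities
reported as mean ± across-replica SD, 2D densities), **difference
contact-network analysis** (4.5 Å contacts, 0.7 stability threshold, four
communities, inter-protomer Δ-contact sums), and the empirical
**three-tier selectivity rule** read off a dimeric co-crystal structure:

1. no Glu501 h-bond → `MONOMER_SELECTIVE`;
2. h-bond present but the protomers disagree by ≥ 0.3 Å in αC position
   and/or K–E distance → `EQUIPOTENT`;
3. h-bond present and both deltas < 0.3 Å → `DIMER_SELECTIVE_LIKELY`.

A synthetic-structure generator builds minimal geometric scaffolds and
replica trajectories with dialled-in states, so the full pipeline is testable
without any downloads.

## Worked example

```python
import protomerscope as ps

# a dimer whose protomers differ by 0.3 Å in the alphaC position
a = ps.ScaffoldSpec(alpha_c_position=18.3, ke_distance=2.8,
                    dfg_dihedral=290.0, ligand_glu501_distance=2.9)
b = a.replace(alpha_c_position=18.6)
dimer = ps.make_dimer(a, b)

call = ps.classify_structure(dimer, "LIG")
print(call.call)
print(call.evidence.delta_alpha_c, call.evidence.delta_ke)
print(call.evidence.glu501_hbond)
```

prints

```
EQUIPOTENT
0.3 0.0
(True, True)
```

— both protomers h-bond Glu501 (donor at 2.9 Å ≤ 3.5 Å), but the 0.3 Å
αC-position deviation between protomers flags the helix as insufficiently
restrained, hence the equipotent (rather than dimer-selective) call.

The same classification runs on a real deposition:

```sh
protomer-scope classify dimer.pdb --ligand LIG
# EQUIPOTENT  (Δ alphaC 0.3 Å, Δ K–E 0.0 Å, Glu501 h-bond [True, True])
```

Other subcommands: `inspect`, `metrics`, `fingerprint`, `ensemble`, `dcna`,
`simulate` (see `protomer-scope --help`).

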