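# Methods

## Scope and model

`protomerscope` quantifies the conformational state of each protomer of a
BRAF kinase-domain structure (or trajectory frame) with three collective
variables, derives ligand interaction fingerprints and ensemble statistics
from them, and applies an empirical co-crystal-structure rule for inhibitor
dimer selectivity. There is no fitted statistical model: every quantity is a
deterministic geometric functional of atomic coordinates, so correctness
hinges on exact definitions, boundary conventions and reproducible
numerics — all collected here.

All residue numbers are author (PDB) numbering of human BRAF (Lys483,
Asn500/Glu501/Val502, His574, Ile582, Ile592–Phe595); no renumbering is ever
performed, insertion codes are honored, and every anchor is overridable
through `AnchorMap` so the machinery can be pointed at another kinase.
Hydrogens, when present, are carried through I/O but excluded from every
metric: the h-bond criterion is a heavy-atom donor–acceptor distance.
Unresolved anchor residues raise explicit `MissingResidueError`s; silent NaN
propagation is never allowed.

## Collective variables and conventions

**αC position.** Distance from the Ile582 Cα to the centroid of the
Asn500/Glu501/Val502 Cα atoms. The three center atoms are identical nuclei
(Cα carbons), so the unweighted centroid coincides with their center of
mass. αC-in iff the distance is strictly below 19.6 Å. The boundary
convention (strict `<`) matters only on a measure-zero set; it is fixed and
tested.

**K–E distance.** Minimum of the two Lys483 Nζ – Glu501 Oε distances. Two
predicates are exposed and never mixed: the salt bridge proper
(≤ 4.0 Å, used for state probabilities) and the looser minimum-sidechain
αC-in surrogate (≤ 4.5 Å). Both are inclusive.

**DFG pseudo-dihedral.** Standard signed four-point torsion over the
Cα atoms of Ile592, Gly593, Asp594, Phe595, computed by the cross-product
atan2 formulation and wrapped to [0°, 360°) (negative IUPAC angles map to
360° + θ). The [0, 360) range was chosen because the DFG-out regime of
interest lies around 210–330°, which a (−180°, 180°] convention would split
across the discontinuity. DFG-in iff θ < 140° (strict). Collinear inner
triplets make the torsion undefined and raise an error rather than
returning an arbitrary angle. The sign convention matches biotite and
MDAnalysis (verified by cross-library test); if protomer trajectories ever
place the apo DFG-out peak near 150° instead of ~210°, the convention — not
the cutoff — should be suspected first.

**Ligand–Glu501 h-bond.** Minimum distance between the ligand's donor heavy
atoms and the Glu501 carboxylate oxygens; the bond is counted at ≤ 3.5 Å.
No donor–H–acceptor angle filter is applied by default: crystal structures
rarely carry hydrogens and the distance-only criterion keeps static and
trajectory analyses consistent.

## Interaction fingerprints

Records are per (residue, interaction-type), keeping the minimum qualifying
distance; `H_DONOR` always means the ligand donates. Cutoffs: 3.5 Å for
either h-bond direction; hydrophobic contacts at 4.0 Å when both atoms are
aromatic-ring members and 4.5 Å for all other carbon–carbon pairs; all
inclusive. Aromatic stacking is deliberately reported as hydrophobic —
face/edge geometry classification is out of scope.

Protein donor/acceptor roles come from standard residue templates (backbone
amide N donor except proline; backbone carbonyl O acceptor; sidechain roles
per residue chemistry, N/O only). Ligand typing is perceived from
covalent-radius connectivity: donors are N/O with a bonded hydrogen, or —
for the usual hydrogen-free depositions — under-coordinated N (≤ 2 heavy
neighbours) and hydroxyl-like O (single neighbour at single-bond length
> 1.32 Å); acceptors are all O plus low-coordination N; aromatic atoms are
members of planar 5–7-membered rings (≤ 0.15 Å plane deviation). Automated
perception is fallible by design intent, so a per-atom override table is the
escape hatch and takes absolute precedence. A dual-capable pair (both sides
donor-and-acceptor) yields records in both directions; this is deliberate
and documented rather than averaged away.

## The selectivity rule

For a dimeric co-crystal structure with the inhibitor bound in both
protomers: absence of the Glu501 h-bond in both protomers calls
`MONOMER_SELECTIVE`; presence (in at least one protomer) with an
inter-protomer deviation ≥ 0.3 Å in αC position and/or K–E distance calls
`EQUIPOTENT`; presence with both deltas < 0.3 Å calls
`DIMER_SELECTIVE_LIKELY`. Deltas are absolute differences rounded to 0.1 Å
(crystal-structure reporting precision); by default the difference is taken
at full precision and then rounded, with round-then-difference available as
an option. One-sided h-bond presence counts as presence: with discordant
metrics it lands in the equipotent tier anyway, which is the conservative
call. A DFG-in conformation in either protomer appends a secondary
equipotency note without changing the call. The call is never emitted
without its evidence record — at typical 2–3 Å resolutions this screen is an
indicator, not a verdict, and LY3009120 and Ponatinib are the known
exceptions where near-identical protomers do not imply dimer selectivity.
Dimers with fewer than two resolved ligand copies and monomeric inputs are
rejected with explicit errors rather than guessed at.

## Ensemble statistics

Replica trajectories (default three) are analysed after discarding a
burn-in fraction of 0.4 — the convention of keeping the last 3 µs of a 5 µs
production run — configurable per run. Distributions pool all replicas and,
for dimers, both protomers by default (the protomer-resolved mode serves
asymmetric, e.g. singly-ligated, dimers) and use 50 bins over the pooled
data range padded by 1%; fixed ranges are accepted for cross-ensemble
overlays. State probabilities are per-replica frame fractions, reported as
their unweighted mean with the across-replica standard deviation (n−1
denominator) as the error bar; a single replica reports SD 0 with a
warning. 2D densities are plain normalized joint histograms (total mass 1) —
no kernel smoothing, no autocorrelation correction, no free-energy
transformation. "Peak position" means the midpoint of the
highest-probability bin, ties resolved toward the lower bin.

## Difference contact networks

Two residues are in contact in a frame when any heavy-atom pair is within
4.5 Å; intra-protomer pairs need sequence separation ≥ 3, inter-protomer
pairs are always eligible. Contact probabilities are frame fractions pooled
over replicas. Stable contacts (probability ≥ 0.7, inclusive) form a
weighted graph that is partitioned into exactly k communities (k = 4 for a
two-lobe dimer) by modularity maximization. Graphs of ≤ 12 nodes are solved
exactly by enumerating all k-partitions (deterministic tie-break by
canonical block structure); larger graphs use greedy modularity
agglomeration merged down to exactly k with lowest-residue-index
tie-breaking. The exact small-graph path exists because greedy agglomeration
carries no optimality guarantee even on toy graphs, while determinism and
testability demand one; isolated residues are attached to their
nearest-in-sequence community rather than forming spurious singletons.

The difference network reports, per community pair, the mean (default; sum
available, since the aggregated edge statistic is a genuine design choice)
of the holo − apo probability changes over admitted residue pairs. A pair is
admitted when the larger of its two ensemble probabilities reaches the
stability threshold ("union" mode, default) so that contacts stable in
*either* state contribute a signed change; per-ensemble thresholding before
differencing is available. Both modes are exactly antisymmetric under
swapping the ensembles. The inter-protomer sum aggregates every community
pair whose majority-membership protomers differ — the four N/C-lobe cross
pairs for a two-lobe dimer.

## Synthetic data

The generator emulates the *analysis-relevant* features of kinase-dimer MD
data — per-protomer anchor geometry, replica structure, scheduled
conformational state fractions, Gaussian coordinate noise — and nothing
else. Scaffolds are geometric minimal models: each anchor residue carries
exactly the atoms the metrics read, in spatially separated clusters, so
every collective variable can be set independently and exactly (measured =
requested to better than 1e-6, in double precision). Scheduled states
(salt bridge on/off at 2.8/6.0 Å, αC in/out at 18.3/22.0 Å, DFG in/out at
100°/290°, ligand h-bond on/off at 2.9/6.5 Å) are drawn independently per
frame, replica and protomer; there are no kinetics, no autocorrelation, no
solvent, no forces. Noise is added after geometry realization, so targeted
distances stay unbiased in expectation and recovery tests can use binomial
confidence bounds.

Consequently, passing tests demonstrate that the *measurement machinery* is
correct — metric definitions, binning, replica statistics, network
differencing — not that any physical system behaves a particular way.
Results derived from microsecond-scale simulations (population shifts upon
dimerization and binding, the ~0.3 inter-protomer contact gain) are not
reproducible at desk scale; the test suite substitutes property-based
checks at the stated problem sizes (3 × 2000 frames for state recovery,
1000 random fixtures for oracle equivalence), chosen so the whole suite
runs in seconds.

## Numerical choices

Coordinates are held in double precision internally (biotite's float32
storage is overridden) so closed-loop geometric contracts hold to ~1e-12;
PDB output rounds to the format's 3 decimals, and one write–read cycle is a
fixed point of that rounding. Alt-locs resolve to the highest-occupancy
conformer, ties to the first listed — deterministic across runs. All
randomness flows from explicit integer seeds through `numpy.random.
default_rng`; identical seeds give bit-identical ensembles. Histogram
normalization is enforced to 1e-12. The run pipeline logs every threshold
and anchor actually in effect, checksums its inputs, and serializes the
full configuration into the run manifest, so identical manifests imply
bit-identical outputs.

## Known limitations

* Ligand typing without hydrogens is heuristic; genuinely ambiguous ligands
  (tautomers, charged species) need the override table.
* The h-bond criterion has no angular term, so tightly packed polar
  contacts can be counted as h-bonds.
* The selectivity rule inherits the resolution limits of its inputs and has
  documented exceptions; it complements, never replaces, simulation- or
  assay-based assessment.
* Community detection above 12 residues is greedy and therefore
  heuristic — deterministic, but without an optimality certificate.
* The synthetic generator's frames are temporally independent; nothing
  about convergence or autocorrelation of real trajectories can be inferred
  from it.
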