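# Methods

This note documents the models and numerical choices behind `cyclopep`,
in the order the pipeline uses them.

## Linear peptide construction

Backbone atoms are placed by internal coordinates (NeRF) with ideal bond
lengths (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å) and
angles, at one of two backbone states:

| state | φ (deg) | ψ (deg) | description |
|---|---|---|---|
| `beta` | −140 | 135 | extended β-strand |
| `polypro` | −78 | 149 | polyproline-II helix |

ω is trans (180°) throughout. Both states are configurable
(`builder.BACKBONE_DIHEDRALS`). Proline is the one exception: its
pyrrolidine ring fixes φ near −75°, so proline residues are built at
φ = −75° in either state.

Residue geometry (heavy atoms, hydrogens, intra-residue bonds) is grafted
from the idealised Chemical Component Dictionary entries bundled with
biotite, superimposed on the placed N/Cα/C triad. Carbonyl oxygens, amide
hydrogens and terminal groups are re-placed analytically so they are
consistent with the local backbone geometry rather than the template's.

Protonation follows pH-7 defaults: Asp/Glu deprotonated, Lys/Arg
protonated, His neutral in the Nε2-H tautomer, free Cys with thiol H;
cysteines declared in a disulfide pair lose the thiol hydrogen at build
time. Termini are either charged (NH3+/COO−) or capped with ACE/NME —
caps are residues of their own, and a head-to-tail cyclization requires
charged termini.

Side chains are built extended (all χ = 180°) with two deliberate
exceptions: aromatic χ2 is set perpendicular (±90°; His/Phe/Tyr +90°,
Trp −90°) because a coplanar ring collides with the neighbouring carbonyl
in the PPII state. These choices were fixed by an exhaustive
residue-context scan for heavy-atom contacts below 1.8 Å; the builder's
contract is that every build is clash-free, deterministic and
bit-reproducible.

## Energy surrogate

The annealing engine does not attempt to reproduce a production force
field. Its five terms are chosen to preserve covalent geometry, planarity
and chirality while distance restraints reshape the backbone:

* **Bonds/angles** — harmonic, k = 300 kcal mol⁻¹ Å⁻² and
  60 kcal mol⁻¹ rad⁻²; equilibria are *measured from the as-built
  ideal-geometry conformer*, so the built structure is the energy
  minimum of the bonded terms by construction.
* **Torsions** — periodic `k (1 − cos(φ − φ0))`, k = 15 kcal mol⁻¹, on
  every inter-residue amide (ω = 180°) and on disulfide
  Cβ–Sγ–Sγ–Cβ (φ0 = 90°).
* **Impropers** — same periodic form, k = 40 kcal mol⁻¹, one per
  ≥3-coordinated centre with the equilibrium measured at build time.
  These lock Cα chirality (the N–Cα–C–Cβ improper is ≈ −120° for
  L-residues) and sp² planarity.
* **Contact repulsion** — purely repulsive truncated-and-shifted
  Lennard-Jones, `ε[(r_min/r)¹² − 2(r_min/r)⁶ + 1]` for r < r_min and 0
  beyond, with r_min = 0.85 × the summed van-der-Waals radii. C¹
  continuity matters: the gradient is verified against central finite
  differences at 10⁻⁴ relative error.
* **Electrostatics (optional)** — Coulomb with a distance-dependent
  dielectric ε(r) = 4r and coarse partial charges carrying only the
  formal charges of titratable groups. Off during all annealing phases
  (with electrostatics on, charged side chains collapse into the ring
  centre); on during final minimisations.

Distance restraints use a flat-bottom soft-square: zero inside
[d − d⁻, d + d⁺], harmonic outside (k = 50 kcal mol⁻¹ Å⁻²), switching to
a linear asymptote 2 Å past the bound. Ambiguous restraints act on the
r⁻⁶-summed effective distance `(Σ d⁻⁶)^(−1/6)`, which is bounded above by
the minimum pairwise distance.

For cycle closure, term equilibria spanning the new bond cannot be
measured from the (open) build. Bond and angle values come from ideal
amide/disulfide geometry (C–N 1.329 Å, S–S 2.04 Å); improper equilibria
at the rebonded centres are measured *by analogy* from the chemically
identical junction between residues 1 and 2 of the linear reference.

## Annealing and closure

Each model runs a Langevin-style integrator in Cartesian space
(dt = 0.02, friction 0.85, per-atom gradient clipping at 200) through
four phases of (2000, 2000, 4000, 4000) steps cooling geometrically from
1000 to 50 thermal units (kB = 0.005 energy units per thermal unit).
Velocities are drawn per model from a counter-based stream
`(master_seed, model_index)`, making runs reproducible and
order-independent. The peptide is fully flexible in every phase; the
staged-flexibility masks (`all`, `side_chains`, `backbone_side_chains`,
`none`) exist for configurations that freeze degrees of freedom.

The final-refinement stage of each run is an L-BFGS minimisation with
electrostatics on — a deliberately cheap stand-in for a solvated MD
refinement, with the contract that the energy never increases. In the
distance-reduction run the restraints stay active everywhere including
the final minimisation; in the closure run they act only in the first two
phases and the final relaxation is unrestrained with a doubled iteration
budget (400).

Closure criteria: N–C within 3.5 Å for head-to-tail, Sγ–Sγ within 4 Å
for a disulfide, evaluated on step-2 cluster representatives. Closing the
head-to-tail bond edits the topology — the carboxylate OXT and two of the
three ammonium hydrogens are removed, the survivor becoming the amide H.
If no representative qualifies, the run aborts and asks for more step-2
sampling rather than forcing a bond.

Model scoring is internal plus restraint energy; the docking engine's
composite score is out of scope here.

## Clustering

Greedy largest-neighbourhood (Daura-style) clustering on pairwise
backbone RMSD (N, Cα, C, O) at 2.5 Å. All ties — neighbour counts,
cluster ranks, centre selection — break toward the lower model id, which
makes the partition deterministic and order-independent. The cluster
centre (member with minimal mean RMSD to its co-members) is the
representative; up to 10 representatives per seed, fewer when fewer
clusters form. Whether conformer clustering should use backbone or
heavy-atom RMSD is genuinely open; backbone-only is the default and the
selection mask is an explicit argument.

## Docking configuration

`protocol_config` is a pure lookup of the nine protocol rows
(ensemble size 5–60; flexibility and solvent-shell flags; the combined
protocol switching both on only for peptides of more than 10 residues)
on top of the shared base setup: 5000/400/400 models per stage,
semiflexible step counts ×4, cyclic-peptide flag, interface-ligand-RMSD
clustering at 5 Å. The run-parameter writer emits only deviations from
engine defaults as a flat `key=value` file; unlisted parameters follow
the engine's defaults.

AIRs are one effective-distance restraint per active receptor residue
(2.0 Å target, 2.0/0.0 corrections — the convention of the standard
active/passive-to-ambiguous generator) against every passive peptide
residue; the peptide is fully passive, the receptor binding site (all
receptor residues with a heavy atom within 5 Å of the peptide in the
reference complex) active. Body restraints connect consecutive rigid
bodies (chain breaks: C–N over 2.5 Å or a numbering gap) with two
deterministic Cα–Cα restraints per pair — first-to-first and
last-to-last residue — fixing the measured distances exactly; the
reference generator picks random atom pairs instead, and determinism was
preferred here.

## Assessment

Contacts are heavy-atom (all non-hydrogen atoms, side chains included)
residue pairs within 5 Å. The i-rmsd interface is defined on the
reference at a 10 Å heavy-atom cutoff — the CAPRI convention; the cutoff
is an explicit argument because published i-rmsd values are sensitive to
it. Model/reference residue correspondence is by residue id after
receptor preparation; there is no alignment fallback. Ranking ties break
by model id. Clusters with fewer than four members contribute the members
they have to the cluster success rate.

## Synthetic fixtures

`make_toy_complex` plants an exact number of residue–residue contacts at
4.5 Å between a rigid mini-receptor and mini-peptide; perturbed copies
displace whole residues by 40 Å, so the surviving-contact count — and
hence f_nat — is known by construction. `make_quality_table` plants
(rank, class) events in otherwise-incorrect ranked model lists, with
representative f_nat values drawn inside each class interval so
classification round-trips. These fixtures exercise bookkeeping, ranking
and threshold logic exactly; they do not emulate docking physics, scoring
noise, or correlated model quality, so passing tests validate the
statistics, not docking accuracy on real complexes.

## Problem sizes

Production defaults are 400 models per cyclization stage at the full
(2000, 2000, 4000, 4000) schedule. The test suite and the acceptance
script run the same pipeline at reduced sampling — 40 models and a 0.025
step scale (50/50/100/100 steps) for the closure property, smaller still
for unit tests — chosen so the whole suite completes in a few minutes on
one CPU while still exercising every stage end to end.

## Known limitations

* The energy surrogate has no attractive dispersion, hydrogen bonding or
  solvation; ensembles are geometrically valid but their relative
  energies are not thermodynamically meaningful.
* No rotamer library: side-chain packing relies entirely on annealing.
* D-amino acids and non-standard residues (beyond ACE/NME caps) are not
  supported.
* The docking engine itself (rigid-body search, scoring, explicit-solvent
  refinement) is out of scope: this package generates its inputs and
  evaluates its outputs.
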