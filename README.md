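# cyclopep

Cyclic peptides — macrocycles closed head-to-tail through an N/C-terminal
peptide bond, through a disulfide bridge, or both — are a growing class of
therapeutics, but modelling their receptor complexes is hard: the ring
constrains conformational sampling while the chain stays highly flexible.
`cyclopep` is a toolkit for the *preparation and evaluation* side of
restraint-driven cyclic peptide–protein docking:

1. **Conformer generation** — build linear all-atom peptides from sequence
   in two starting states (β-strand and polyproline-II), then close the
   macrocycle by restrained simulated annealing and pick cluster
   representatives as the conformational ensemble for docking.
2. **Restraint generation** — cyclization distance restraints, ambiguous
   interaction restraints (AIRs) encoding a known binding site, and body
   restraints for gapped/multichain receptors, all serialized in the CNS
   `assign` tbl dialect.
3. **Docking configuration** — receptor cleanup (chain merging, hetero-atom
   removal, renumbering) and the run parameters of nine benchmark docking
   protocols, including the length-adaptive combined protocol.
4. **Model assessment** — fraction of native contacts (f_nat), interface
   RMSD, CAPRI quality tiers, and single-structure / cluster success rates.

It is aimed at structural bioinformaticians who run restraint-driven
docking engines and need reproducible inputs and quality statistics, and at
method developers who need a desk-scale, fully scriptable reimplementation
of the surrounding protocol.

## The protocol in brief

**Cyclization restraints.** Head-to-tail closure is encoded as two
distance restraints, C(last)–N(1) at 1.3 Å and O(last)–N(1) at 2.3 Å (the
O–N restraint shapes the O–C–N angle); a disulfide bridge as
Cα–Cα 4 Å, Cβ–Cβ 3.5 Å and Sγ–Sγ 2 Å. All carry ±0.1 Å bound
corrections. When both cyclizations are present the Cβ–Cβ restraint is
dropped.

**Annealing.** Starting from the β and PPII linear builds, each model runs
four simulated-annealing phases of (2000, 2000, 4000, 4000) steps —
the semiflexible-refinement defaults multiplied by four — cooling from
1000 to 50 thermal units with electrostatics off, then a final
minimisation. The covalent bond is formed on cluster representatives whose
closure geometry is within 3.5 Å (N–C) or 4 Å (Sγ–Sγ); the closure run
applies restraints only in the first two phases and ends with an
unrestrained relaxation at doubled step budget. Models are clustered by
backbone RMSD at 2.5 Å (greedy largest-neighbourhood clustering) and up to
10 cluster centers per seed form the docking ensemble.

**Assessment.** A residue pair across the interface is a contact when any
heavy-atom pair is within 5 Å. For a model *m* against reference *r*,

    f_nat(m) = |contacts(r) ∩ contacts(m)| / |contacts(r)|

with CAPRI peptide tiers: f_nat > 0.8 high, > 0.5 medium, > 0.2
acceptable. The top-N single-structure success rate is the percentage of
complexes with at least one model of the requested tier among their N
best-ranked models; the cluster success rate searches the top four members
of the best N clusters.

## Worked example

Build a disulfide-cyclized hexapeptide, emit its restraints, and cyclize a
glycine-rich peptide at reduced sampling:

```console
$ cyclopep build --sequence ACGCAK --state beta \
    --cyclization disulfide --disulfide-pair 2,4 --out pep.pdb
wrote 72 atoms to pep.pdb

$ cyclopep restraints --mode cycle --sequence ACGCAK \
    --cyclization disulfide --disulfide-pair 2,4 --out cycle.tbl
wrote 3 restraints to cycle.tbl
$ head -3 cycle.tbl
assign (resid 2 and name CA) (resid 4 and name CA) 4 0.1 0.1

assign (resid 2 and name CB) (resid 4 and name CB) 3.5 0.1 0.1

$ cyclopep cyclize --sequence GGGGGG --seeds 1 --models 6 \
    --step-scale 0.012 --out ens.pdb --scores scores.tsv
wrote ensemble of 1 conformations to ens.pdb
$ head -2 scores.tsv
model_id	stage	energy	angle	bond	coulomb	improper	repulsion	restraint	torsion	n_c
0	step3	19.550	2.658	0.034	0.000	16.858	0.000	0.000	0.000	1.329
```

The `n_c` column is the closed C(6)–N(1) bond length: 1.329 Å, i.e. an
ideal peptide bond. The same pipeline is available as a library
(`cyclopep.anneal.generate_ensemble`), where model counts, annealing step
scales and clustering cutoffs are explicit arguments.

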