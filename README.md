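# fvkit

A toolkit for the infrastructure around antibody variable-fragment (Fv)
homology modeling and antibody–antigen docking: curation of a
Chothia-numbered structural template database with explicit quality
filters, per-region template selection, automatic V_H–V_L
glutamine–glutamine distance constraints (plus K-of-N composites for
ambiguous experimental restraints), fold-tree rigid-body kinematics with
virtual residues for multi-body docking, and the benchmarking metrics —
per-region backbone RMSD and the backbone-dihedral chord distance — used
to evaluate the resulting models.

It is aimed at structural bioinformaticians who build or maintain
antibody modeling pipelines and want the template-database and
constraint plumbing as an inspectable, testable library rather than as
scripts buried inside a large molecular-modeling suite.

## What it computes

**Regions.** Antibody Fv chains are partitioned in the Chothia numbering
convention into six CDR loops (L1 24–34, L2 50–56, L3 89–97 on the light
chain; H1 26–35, H2 50–65, H3 95–102 on the heavy chain), framework
regions FRL/FRH, and an Orientation span (L5–L104, H5–H109).

**Template database.** From a directory of pre-numbered (SAbDab-style)
PDB files and a summary table, entries are selected (first reported
antibody per PDB; scFvs skipped), truncated to the Fv (L1–109, H1–112),
and filtered: resolution < 3 Å, complete backbones, no C–N bond > 2 Å,
CA–C–N angles in [89.5°, 144.5°] and C–N–CA angles in [95°, 151°], no
zero-occupancy atoms, no missing region-anchor residues, and no
duplicate Fv sequences. Surviving region sequences (CDRs with chain
breaks omitted) are pooled by region and length into FASTA files such as
`database.L1.11`, with per-CDR average B-factors in accompanying info
tables.

**Template selection.** Framework queries are scored against framework
pools by Smith–Waterman local alignment with BLOSUM62 (gap open 11 /
extend 1); CDR queries search the pool of matching length ungapped with
PAM30. Hits can be filtered by PDB id (benchmarking) and by the proline
rule (a proline in query or template but not both disqualifies the
template).

**Constraints.** The conserved glutamine pair (light Gln 38, heavy Gln
39) forms two candidate side-chain hydrogen bonds, restrained by a
flat-harmonic penalty on the donor–acceptor distance x:

    f(x) = ((|x − x₀| − d_m) / σ)²  if |x − x₀| > d_m, else 0

with defaults x₀ = 2.91 Å, σ = 0.23 Å, d_m = 0.5 σ, fitted from observed
N–O distances (`fit_qq_parameters` refits from any distance sample). A
`KofNConstraint` adds only the K lowest of N member penalties.
Constraints serialize to a Rosetta-compatible text format.

**Kinematics.** `linear_foldtree` builds the conventional daisy-chained
fold tree over chains in file order; `hierarchical_foldtree` places
virtual residues at chain, group, and complex centres of mass, so that
perturbing an inter-group jump moves a whole sub-complex rigidly without
touching any other group — the layout that makes V_H–V_L refinement,
antibody–antigen docking, and heavy-chain-only antibodies coexist in one
tree.

**Metrics.** `backbone_rmsd` superimposes model onto native over the
framework backbone (N, CA, C, O) and reports a region's RMSD without
re-fitting. `mean_chord_distance` compares dihedral windows via
D²(θ₁, θ₂) = 2 − 2 cos(θ₂ − θ₁) averaged as
⟨D⟩ = (1/n) Σ (D²_φ + D²_ψ)/2, which is 0 for identical windows and 4 at
a uniform 180° offset; `similarity_cdf` turns a fragment set's distances
into an empirical CDF.

All inputs needed for testing are generated synthetically by
`fvkit.fixtures` (idealized Chothia-numbered poly-peptide traces with
controllable defects); no downloads are required.

## Worked example

```sh
$ fvkit make-fixtures --out corpus --n 4 --seed 11
wrote 4 fixtures to corpus

$ fvkit build-db --structures corpus --summary corpus/summary.tsv --out db
accepted 4 / 4 entries; 11 pools written to db

$ fvkit qq-constraint --structure corpus/f000.pdb --out qq.cst && cat qq.cst
AtomPair NE2 38L OE1 39H FLAT_HARMONIC 2.910 0.230 0.115
AtomPair NE2 39H OE1 38L FLAT_HARMONIC 2.910 0.230 0.115

$ fvkit select-templates --query corpus/f001.pdb --db db --exclude-pdb f001 --top 2
region  rank  pdb_id  score  template_sequence  flags
CDR_L1  1     f003    -40    WYATVHALITA
CDR_L1  2     f000    -42    EQKEREVSYVY
CDR_L1  -     f001    86     IKAFAQTMVLY        excluded_pdb
...
```

The constraint file carries the two glutamine–glutamine hydrogen-bond
restraints with the default fitted parameters (x₀ = 2.910 Å, σ = 0.230 Å,
d_m = 0.115 Å). In the selection output, the query's own structure
(`f001`, self-score 86 under PAM30) has been excluded and flagged — the
benchmarking workflow — so the best foreign template ranks first;
negative scores are expected between unrelated random CDR sequences.

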