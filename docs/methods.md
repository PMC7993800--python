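# Methods

## Scope and model

fvkit implements the data-curation, constraint, kinematic, and
measurement layers of an antibody-modeling pipeline. It deliberately
stops short of conformational sampling: there is no score function, no
Monte Carlo or loop-closure machinery, and no coordinate grafting. The
library's contract is that everything upstream and downstream of
sampling — which templates exist, which constraints apply, how rigid
bodies move, how models are scored against natives — is deterministic,
inspectable, and testable in isolation.

## Region definitions and numbering

Regions follow the Chothia convention as adapted for antibody homology
modeling: CDR L1 24–34, L2 50–56, L3 89–97, H1 26–35, H2 50–65,
H3 95–102; FRL as six ranges (10–23, 35–39, 46–49, 57–66, 71–88,
98–104) and FRH as five (10–25, 36–39, 46–49, 66–94, 103–109); the
Orientation span is L5–L104 plus H5–H109. The framework ranges do not
complement the CDRs: the loops between framework ranges (e.g. L40–L45)
belong to no region and are reported as "unassigned" rather than being
forced into a framework.

Insertion-coded residues (H100A, …) inherit the region of their parent
number, consistent with how the convention absorbs loop-length
variation. Residue ordering is (number, insertion code) with the blank
code first; this is a strict total order within a chain.

Non-standard residues map to 'X'. They do not fail the loadability
criterion (chemically modified residues generally load fine in modeling
software), but any region containing an 'X' is excluded from template
pools, because such sequences cannot be aligned against a standard
substitution matrix.

## Quality control

Five criteria are applied per structure, and all five always appear in
the report:

| criterion   | rule                                                                 |
|-------------|----------------------------------------------------------------------|
| resolution  | present and strictly < 3.0 Å (configurable); absent (NMR/EM) fails   |
| loadability | file parses, summary-named chains exist, every residue has N/CA/C/O  |
| geometry    | C–N ≤ 2.0 Å, CA–C–N in [89.5°, 144.5°], C–N–CA in [95°, 151°]        |
| occupancy   | no atom with exactly zero occupancy (0 < q < 1 passes)               |
| anchors     | all region-boundary positions + Orientation endpoints present        |

Resolution is taken from the summary table, not parsed from coordinate
headers, because the pipeline is summary-driven and header dialects
vary. The anchor list is the set of range boundaries of every region on
the chains present (light anchors are skipped for heavy-only
antibodies); this is a deliberate superset, since no canonical list of
"conserved framework residues" exists in the modeling literature at
this granularity.

Geometry violations are classified by where they fall. A violation
inside a CDR marks that CDR as chain-broken — the loop is omitted from
template pools but the structure survives; a violation in the framework
(or an unassigned segment) rejects the whole structure. This resolves
the inherent ambiguity of using one threshold set both as whole-entry
QC and as the per-loop chainbreak detector: a broken loop is a local
defect, a broken scaffold is not. A CDR is also flagged when a Chothia
number inside its range is absent while the chain continues on both
sides; terminal absences are treated as truncation. Note this
missing-number heuristic will also flag genuinely short loops whose
numbering omits interior positions — it trades a few false positives
for never missing an unmodeled loop segment.

Alternate locations: only blank or 'A' altloc atoms are kept, which
makes parsing deterministic.

scFv detection uses the summary rule only (heavy id equals light id).
A sequence-based fallback is not possible once a structure is
Chothia-numbered, because light and heavy chains occupy the same number
range and cannot be distinguished by position sets alone within one
chain id.

## Database construction

Pipeline order per entry: select the first non-scFv summary row → parse
→ truncate to the Fv (light 1–109, heavy 1–112) → QC → drop entries
whose concatenated light+heavy Fv sequence duplicates an earlier
accepted entry (first in summary order wins, mirroring the
first-reported selection rule) → extract region sequences, skipping
chain-broken CDRs and 'X'-containing regions → pool by (region, length).
Per-CDR average B-factors (arithmetic mean over all atoms in the loop)
and the CA coordinates of the four Orientation anchors are recorded so
that downstream filters and V_H–V_L orientation measures can be
computed without re-reading coordinates.

Every rejection is logged with its criterion, and accepted + rejected
equals the number of entries processed. Rebuilding from identical
inputs is byte-identical in all pool and info files (the provenance
manifest is the only file free to differ, and currently does not).

Heavy-only entries (nanobodies) are first-class: the dedupe key is then
the heavy sequence alone, and light-chain regions are simply absent.
Per-chain deduplication was considered and rejected because two
antibodies sharing one chain but not the other are genuinely distinct
templates.

## Template selection

CDR queries search only the pool of their exact length, scored
ungapped: pools are length-partitioned by construction, so a gapped
alignment could only pair a query with a template of different loop
length, which the grafting step cannot use. Frameworks align gapped.
Gap penalties default to the conventional pairings: BLOSUM62 11/1 and
PAM30 9/1, with a gap of length k costing open + k·extend. The
alignment engine is Biopython's `PairwiseAligner` in local mode; an
independently written affine-gap Smith–Waterman serves as the oracle in
the test suite.

The proline filter applies to CDR pools only (where sequences are
equal-length and positionally comparable) and hard-removes offending
templates while keeping them, flagged, in verbose output — so a
demotion policy can be layered on later without re-scoring.

Ties break deterministically: score, then lower template resolution,
then lower average CDR B-factor, then PDB id.

## Constraints

The flat-harmonic penalty is implemented exactly as
f(x) = ((|x − x₀| − d_m)/σ)² for |x − x₀| > d_m, else 0. The boundary
|x − x₀| = d_m falls in the zero branch (the condition is strict). With
the shipped defaults x₀ = 2.91 Å, σ = 0.23 Å, d_m = 0.5 σ, the penalty
at one standard deviation is ((σ − 0.5σ)/σ)² = 0.25 score units — a
quarter, not a half; descriptions stating 0.5 at 1 σ are inconsistent
with this functional form, and the formula is authoritative here.

Fitting uses the sample mean and the sample (n−1) standard deviation,
with d_m = 0.5 σ; fewer than two observations or zero variance is a fit
error rather than a silent degenerate constraint. Parameter recovery on
synthetic Normal(2.91, 0.23) samples converges within ±0.01 Å by
n = 10⁴.

The automatic Q–Q constraint is emitted only when light residue 38 and
heavy residue 39 are both glutamines with their side-chain amide atoms
(NE2, OE1) present; each glutamine's NE2 pairs with the partner's OE1,
giving two member constraints. For reporting, a hydrogen bond is called
geometrically at N–O ≤ 3.5 Å, a standard donor–acceptor cutoff chosen
because no energy-based hydrogen-bond detector is in scope.

`KofNConstraint` sums the K smallest member penalties; it is monotone
in K and equals the plain sum at K = N.

## Fold-tree kinematics

Nodes are physical residues (anchored at CA) or virtual residues —
position-only markers that never participate in any energy, QC, or
sequence operation. "Centre of mass" is the unweighted heavy-atom
centroid; mass weighting would move anchors by fractions of an Ångström
with no effect on any property the tree guarantees.

Jumps store a proper rotation (det +1, orthonormality checked on
application) plus translation. Applying a jump update rotates the
downstream subtree about the jump's upstream node position, then
translates; atoms move with their residues. Peptide edges fan outward
in both directions from each chain's COM-proximal anchor residue, which
keeps every node single-parented without a separate cutpoint notion;
full loop-opening kinematics is out of scope.

The hierarchical tree is rooted at a virtual node at the complex COM.
Rooting at the first group instead would preserve all documented
independence properties (the root choice only renames which subtree is
"fixed"); the complex COM was chosen for symmetry. Guaranteed
invariants, exercised at 1e−6 Å tolerance: perturbing an inter-group
jump preserves all intra-group pairwise distances and leaves other
groups bit-identical; perturbing jump i of a linear tree moves exactly
the chains after i.

## Metrics

Backbone RMSD fits model onto native over the shared framework
(FRL + FRH) backbone atoms N, CA, C, O by least squares
(`Bio.SVDSuperimposer`), then measures the named region in that frame
without re-fitting, so loop error is expressed relative to the
conserved scaffold rather than absorbed by a per-loop fit. The chord
distance is computed on angles wrapped to (−180°, 180°]; wrapping is
mathematically moot for the cosine but normalizes reported values.
Fragment windows are only comparable at equal length. ⟨D⟩ is defined
without a square root over (D²_φ + D²_ψ)/2 — the only reading on which
the maximum of the window average is 4.

## Synthetic fixtures

The generator emulates SAbDab-style inputs: Chothia-numbered PDB files
plus a summary TSV. Chains are idealized extended poly-peptide traces
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, canonical angles, φ/ψ
jittered ±8° around (−139°, 135°)), built by sequential internal-
coordinate placement, with light, heavy, and antigen chains separated
in space. The default residue alphabet excludes proline (so link
geometry stays trivially ideal) and 'X'. Glutamines at L38/H39 carry
analytically placed side-chain amides realizing a configurable
donor–acceptor distance (default 2.91 Å, reproduced within the 0.001 Å
coordinate precision of the PDB format).

What the fixtures do **not** emulate: the immunoglobulin fold, real
V_H–V_L packing, side-chain rotamers, sequence statistics of real
antibodies, crystallographic artifacts beyond the injected defect menu.
Passing tests therefore demonstrate correctness of bookkeeping,
geometry arithmetic, filtering logic, and kinematics — not modeling
accuracy on real antibodies.

Defects are constructed to be surgically single-criterion: bond
stretches translate the downstream tail along the bond axis (angles
unchanged); angle defects rotate the tail about the link's C atom in
the CA–C–N plane (bond length unchanged); deleted residues are removed
before the trace is built, so the backbone stays geometrically
continuous and only numbering-based checks fire. Corpus generation
derives per-entry seeds from a `SeedSequence` over the corpus seed
(default 20190215) and is byte-deterministic.

## Problem sizes and tolerances

Test corpora use 3–20 fixtures; alignment oracles run on random 6-mers;
parameter-recovery uses 10⁴ draws; rigid-body invariants are asserted
at 1e−6 Å and superposition identities at 1e−6 Å. These sizes were
chosen as the smallest at which every code path and invariant is
exercised with non-trivial diversity.

## Known limitations

- No Chothia renumbering of raw PDB entries: inputs must be
  pre-numbered, as SAbDab provides.
- No mmCIF, assemblies, hydrogens, or altloc selection beyond blank/'A'.
- Query sequences must arrive Chothia-annotated (as a numbered
  structure or explicit per-region sequences); plain-FASTA numbering
  is a separate problem not attempted here.
- The missing-number chainbreak heuristic flags short loops whose
  numbering legitimately omits interior positions (see above).
- Constraint files use the conventional text grammar and should be
  consumable by the original modeling software, but this compatibility
  is not integration-tested against it.
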