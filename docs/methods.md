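# Methods

`flexsig` reimplements a flexibility-signature pipeline for protein
activation states: constraint-network rigidity analysis of individual
structures, hydrogen-bond dilution with an energy-selection rule, a
segment-wise flexibility encoding for class A GPCRs, and feature selection
with a Jaccard nearest-neighbour classifier. This note records the models,
the parameter choices, and the limits of what the synthetic experiments
demonstrate.

## Constraint network

A sanitized single-chain structure (waters, ligands, alternate chains and
hydrogens removed; hydrogens re-added either by the user's protonation
protocol or by the package's deliberately minimal backbone-amide
protonator) is turned into a typed interaction inventory:

- **Covalent bonds** from residue templates plus peptide (C–N < 1.7 Å) and
  disulfide (S–S < 2.5 Å) links. Bonds with partial double-bond character —
  peptide bonds, carbonyls/carboxylates, amides, guanidinium, aromatic and
  imidazole rings — are *locked*; all other covalent bonds are *rotatable*.
  Bonds to hydrogen are locked: a point-like terminal atom has no
  orientational freedom, and treating X–H as rotatable would manufacture
  one spurious spin mode per hydrogen. Unknown residues fall back to
  generic distance bonding (< 1.9 Å) with a warning.
- **Hydrogen bonds** from D–H···A geometry with d(D,A) ≤ 3.6 Å,
  d(H,A) ≤ 2.6 Å and θ(D,H,A) ≥ 110°, scored by a Mayo-form well
  E = V₀ [5(d₀/d)¹² − 6(d₀/d)¹⁰] cos²θ with V₀ = 8 kcal/mol and
  d₀ = 2.8 Å; only E < 0 is kept. The angular term is simplified to
  cos²θ(D,H,A); a hybridization-dependent case analysis is an extension
  point. These values reproduce the qualitative dilution behaviour of the
  FIRST/ProFlex lineage; exact parity with any specific program version is
  not claimed.
- **Salt bridges** (Arg/Lys/His side-chain N to Asp/Glu carboxylate O
  within 3.6 Å) at a fixed −10 kcal/mol so they persist deep into the
  dilution. Side-chain amine to backbone-oxygen contacts are ordinary
  hydrogen bonds.
- **Hydrophobic tethers** between carbon/sulfur atoms of residues at least
  two apart in sequence, within the van der Waals radii sum (C 1.7, S
  1.8 Å) plus 0.25 Å; one tether (closest atom pair) per residue pair.

## Body-bar rigidity and the (6,6) pebble game

Each atom is a rigid body with six degrees of freedom. Interactions
contribute bars: 5 for a rotatable covalent bond (one dihedral left), 6
for a locked bond, 5 for a hydrogen bond or salt bridge, 2 for a tether.
Generic rigidity of the resulting multigraph is decided by the (6,6)
pebble game: a bar is independent exactly when seven pebbles can be
gathered onto its endpoints. Edge insertion order (sorted endpoint
serials) and depth-first pebble searches with ascending neighbour order
make the decomposition deterministic.

Floppy modes are free pebbles summed per connected component minus the six
trivial motions of each component. Mutual rigidity of two bodies is tested
by attempting to free a seventh pebble on the pair; because a shared body
carries a full six degrees of freedom, mutual rigidity is transitive, and
rigid clusters are recovered by union-find over network edges whose
endpoints test rigid.

The pebble game is validated against an independent numerical oracle: a
generic bar-and-body rigidity matrix (random body reference points and
attachment offsets; each bar constrains the relative velocity of its
attachment points along the bar). Floppy modes follow from the matrix
rank, pairwise rigidity from the rank increment of six generic extra bars.
On 200 random networks of up to 12 bodies with bar counts drawn from
{2, 5, 6}, floppy modes and the full rigid-pair relation agree exactly.

## Dilution and energy selection

Hydrogen bonds and salt bridges are removed one at a time from weakest
(least negative) to strongest, ties broken by donor then acceptor serial.
After each removal the decomposition is recomputed; a profile line is
recorded whenever any residue label changes, annotated with the energy and
donor/acceptor of the bond just broken. Since constraint removal can only
shrink the rigid-pair relation, floppy modes are non-decreasing and the
largest rigid region non-increasing along any profile — checked on 50
jittered helix fixtures.

Residue labels: a residue belongs to the cluster of its Cα atom (majority
over heavy atoms as fallback); a cluster is a rigid *region* only when it
spans ≥ 2 residues (`min_cluster_residues`, excluding trivially locked
peptide units). Labels are `l` (largest region, by residue span, ties to
the lowest minimum atom serial), `s` (other rigid region), `f` (flexible).

The analysis energy is the most negative profile energy at which at least
70% of residues are rigid (`theta_rigid = 0.70`). The alternative reading
— the first step *past* that level — is available as
`AnalysisConfig(cutoff_rule="first_below")`. If no step reaches 70%, the
weakest-energy step is used with a warning.

The per-residue flexibility index (0 = rigid, 100 = maximally flexible)
contracts each rigid cluster to a single body; each connected linkage
region scores 100 × (its floppy modes) / (its rotatable bonds), and a
residue averages the scores of its incident rotatable bonds. On a tree
every rotatable bond is independent, so a free chain scores exactly 100;
the exact normalization used by other implementations is not derivable
from published output, so only the 0–100 scale and the rigid→0 convention
are relied upon.

## Segment scheme and encoding

The 29 segments are the seven transmembrane helix thirds (split N→C with
sizes ⌈n/3⌉, n−n₁−n₃, ⌊n/3⌋ — extracellular-first for odd-numbered
helices), two halves of helix 8, and the six loops. The loop before helix
1 is excluded. Segment residue ranges are user-supplied per structure
(TOML), since helix boundaries vary; a helper derives the splits from
whole-helix ranges.

Each segment takes one state per structure by plurality vote of its
residue labels (ties l > s > f; residues without coordinates abstain; a
fully missing segment defaults to `f`, the high-mobility interpretation).
One-hot encoding over {f, s, l} yields 87 binary features (`H2.2s`,
`ECL1l`, ...), exactly 29 bits set per row.

Prevalence profiles are class-conditional feature frequencies; *sensitive*
features show an absolute difference ≥ 0.25 (`delta_prevalence`), keeping
at most the largest-difference state per segment.

## Classification and subset search

Nearness is the Jaccard coefficient; two all-zero restrictions are defined
maximally similar (identical points must be nearest neighbours; full rows
can never be all-zero, restricted rows can). The classifier is k-nearest
neighbours with odd k (default 3), similarity ties at the neighbourhood
boundary resolved toward the lower training-row index. Accuracy is scored
by leave-one-out cross-validation and by out-of-bag bootstrap (default
10 000 iterations; iterations with an empty out-of-bag set or single-class
training sample are skipped). The reported "standard error" is the spread
(sample standard deviation) of per-iteration accuracies, consistent with
the ~12–15% magnitudes such tables show; the mean's standard error would
be two orders of magnitude smaller.

Sequential selection (forward/backward, optional floating with
strict-improvement re-entry) and exhaustive search over all subsets up to
8 features (guarded at 5×10⁶ subsets) both maximize LOOCV accuracy, with
ties broken lexicographically. Exhaustive results are ranked by accuracy
(descending), subset size (ascending), then name. The discovery pipeline
feeds the exhaustive search the union of the sensitive features and each
sequential run's best-predictor subset (restricted to the size ceiling),
and reports bootstrap statistics for the top subsets next to a
majority-class dummy baseline. Accuracies are reported to one decimal
(round-half-even). Subset scoring runs in a compiled kernel that compares
similarities by exact integer cross-products; the exhaustive search walks
the subset lattice depth-first, updating the pairwise intersection matrix
by rank-one increments so each subset costs a single scoring pass. The
pure-Python `knn_predict`/`loocv_accuracy_slow` pair defines the reference
semantics the kernels are tested against.

## Synthetic data: what it emulates, what it does not

- **Body-bar networks** (chains, rings, cliques, seeded random graphs)
  have closed-form or oracle-checkable rigidity. They probe the counting
  algorithm, not molecular geometry.
- **Ideal peptides**: poly-alanine at φ = −57°, ψ = −47° (helix; its
  geometry guarantees n−4 backbone i→i+4 hydrogen bonds within the
  detection criteria) or φ = −140°, ψ = 135° (strand; none). Backbone
  amide hydrogens are placed analytically. Optional Gaussian coordinate
  jitter (0.05 Å in the monotonicity experiment) varies bond energies and
  breaks dilution-order ties between fixtures. These fixtures have no side
  chains beyond Cβ, no tertiary contacts, and no crystallographic noise.
- **Planted feature matrices** emulate the average rigidity-profile
  structure of the receptor panel: 18 inactive / 9 active rows, background
  segment states drawn at l 0.6 / s 0.2 / f 0.2, and four planted features
  named for the strongest observed signature (ECL1l and H5.1l prevalent in
  inactive structures at 0.85 vs 0.20; H2.2s and H3.1f prevalent in active
  structures at 0.65/0.00 and 0.70/0.05) — every separation ≥ 0.5, with
  segment states sampled independently per structure.

Passing tests on these fixtures demonstrate the correctness of the
counting, dilution, encoding, and search machinery. They do not
demonstrate recovery of the published receptor results, which would
require the original coordinate files and an optimized protonation
protocol.

### Exact-set signature recovery is not attainable at these conditions

The planted-recovery experiment asks whether the full pipeline ranks the
planted 4-feature set first, over 100 generator seeds. Under the ranking
rule (accuracy, then smaller size, then name) and independent per-segment
sampling this is rarely the case, for a structural reason: with
per-feature class separations ≥ 0.5 and only 27 rows, some 2- or 3-feature
subset — usually a subset of the planted four, or a sibling state of a
planted segment, which carries the same signal through the one-hot
encoding — reaches the accuracy ceiling (often 100%) and wins the
smaller-size tie-break. A grid search over admissible planted prevalences
(separations 0.5–0.9, both feature directions) bounds the exact-set
recovery probability at roughly 10%. The experiment is implemented and
reported with the strict equality definition regardless; the generator
defaults were chosen for fidelity to the observed prevalence profile and
were not tuned toward the recovery threshold.

## Alignment annotation

Pairwise structural alignments are read either from Dali-style
`Query`/`Sbjct` blocks (lowercase = structurally unaligned; such residues
are kept but never paired) or from two-record aligned FASTA, and written
back as aligned FASTA. Key residues are defined by explicit ranges or by
any-heavy-atom distance to ligand atoms. The residue-annotation view flags
key residues (CSV `*`, HTML boldface); the value view lays per-residue
B-column values (mean over the residue's atoms — the per-residue reduction
is unspecified in published tables, and Cα-only is a plausible
alternative) on the reference residue grid, with `-` at unaligned
positions.

## Problem sizes and numerical choices

Validation experiments use 200 random networks of ≤ 12 bodies for the
rank-oracle comparison, 50 jittered 12-residue helices for dilution
monotonicity, and 100 generator seeds for signature recovery — sizes at
which the oracle (SVD ranks) and the exhaustive searches are comfortable
on a single CPU. Rank decisions use default SVD tolerances on
order-one-magnitude generic matrices. All randomness flows from explicit
seeds; every experiment is a pure function of its parameters and seed.

## Known limitations

- Hydrogen placement: the built-in protonator handles backbone amides
  only; side-chain donors require pre-protonated input. It is not
  equivalent to an energy-optimized protocol, and results on real
  structures depend on that choice.
- Hydrogen-bond parameters are stated design values, not a calibrated
  reproduction of any specific program's output.
- The flexibility-index normalization is package-defined (see above).
- π-stacking, cation–π, metal coordination and bridging waters are not
  modelled; mmCIF, NMR ensembles and symmetry expansion are out of scope.
- The pebble game is O(V·E) per decomposition and is re-run from scratch
  at every dilution step; this is fine for fixtures and single receptors
  but not optimized for proteome-scale sweeps.
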