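# Methods

## Model and procedure

### Contact definition

Two residues of one parent are in contact when the minimum distance over
all pairs of their heavy atoms (hydrogens never stored) is strictly below
the cutoff, default 4.5 Å. The strictness of the inequality is a
convention choice — at 4.5 Å exactly nothing physical distinguishes the
two readings — and the cutoff is configurable. The neighbor search uses a
k-d tree over all heavy atoms; a quadratic all-pairs scan is kept as the
test oracle and the two must agree exactly.

Contacts between sequence-adjacent residues are kept as graph edges by
default: noncontiguous blocks can split sequence neighbors, so those
contacts are genuinely breakable. A flag (`include_adjacent=False`) drops
them for sensitivity analysis.

### Recombination graph

Per-parent contacts are lifted to alignment columns through the
column-residue maps. A lifted contact with at least one conserved endpoint
is discarded: whichever parents contribute the two residues, the resulting
pair already occurs in a parent, so recombination cannot break it. The
remaining column pairs form an undirected graph over non-conserved columns
with weight 1.0 when both parents share the contact and 0.5 when only one
has it. Columns where one parent has a gap still carry nodes but can only
acquire 0.5-weight edges (only one structure exists there).

### Block design

A k-way partition of the graph nodes gives the blocks (labels A, B, …
assigned in order of each block's smallest column). For a two-parent
library each inter-block edge is broken in exactly half of the 2^k
chimeras, so the library average SCHEMA energy obeys the closed form
⟨E⟩ = cut/2; the implementation asserts this against brute-force
enumeration in the tests. ⟨m⟩ is the enumerated mean of the distance to
the closer parent; because every non-conserved column differs between the
parents, a chimera's distance to a parent is simply the total size of the
blocks taken from the other parent.

The partitioner is a multi-restart recursive bisection: each bisection
starts from a random split of the required sizes and is refined by
Kernighan–Lin-style pairwise swaps (sizes held fixed, so uneven splits for
odd k stay valid); the assembled k-way partition is then polished by
greedy single-node moves within the balance bounds plus
balance-preserving swaps. The best cut over restarts wins; ties go to the
lexicographically smallest canonical label vector so results are
reproducible bit-for-bit for a given seed. This is an in-house stand-in
for the external hMETIS package traditionally used for the partitioning
step. Block sizes are constrained to (1 ± tol)·n/k with tol = 0.3 by
default, matching a design of roughly equal blocks (~16 non-conserved
residues per block at n ≈ 130, k = 8). An exhaustive enumerator over
restricted-growth strings (n ≤ 14) provides the global optimum for
verification; on random 8–12-node graphs the heuristic has matched it in
every tested case.

### Chimera scoring and subset selection

E is the summed weight of edges whose endpoint blocks come from different
parents; m is the minimum over parents of differing non-conserved columns.
Both are invariant under swapping the parent labels (code complementation),
which the tests assert. Sequence assembly emits the shared residue at
conserved columns and the chosen parent's residue elsewhere, skipping gap
positions, so chimera lengths interpolate between the parents' lengths.

The informative-subset step picks n chimeras greedily, maximizing the
minimum pairwise Hamming distance over block codes among the chosen set
plus both parents, subject to E ≤ ceiling; ties prefer lower E, then
lexicographically smaller codes. The historical study described its subset
choice only qualitatively ("high mutual m, low E"); this objective is this
package's concrete rendering of that preference, documented as a design
choice rather than asserted as the original procedure.

### Additive stability models

The design matrix is an intercept plus k indicators (1 when the block
comes from P1), so the intercept is the P2 baseline and each δ_b the
temperature effect of inheriting block b from P1. Fitting is OLS through
the Moore–Penrose pseudoinverse: with ten training records and nine
coefficients the design is routinely rank-deficient or nearly so, and the
pseudoinverse returns the minimum-norm solution instead of failing. r² is
the training-set coefficient of determination; no cross-validation is
applied. Degenerate inputs (all trait values equal, fewer than two
records) raise.

On the packaged GH5 table (parents + C1–C8) this fully specified
estimator yields r² = 0.998 for T50 and r² = 0.872 for TA50. The
published statistics are 0.83 and 0.88. The TA50 value agrees to within
0.01; the T50 value cannot be reconciled with plain training-set OLS — a
rank-9 fit of 10 points is near-saturated, and leave-one-out variants do
not produce 0.83 either (LOOCV q² = 0.66, squared correlation 0.71). The
estimator behind the published T50 number is under-specified, so this
package reports its own computed value and treats the discrepancy as a
documented finding. Supporting the transcription and coding, the fitted
T50 block signs reproduce the published classification exactly (A, B, G,
H stabilizing; C, D, E, F destabilizing relative to P2), and the designed
codes C9–C11 score above both parents, with the empirically best chimera
C10 among the model's top picks.

Prediction is the plain dot product; candidate ranking sorts by predicted
T50, then predicted TA50, then lower E, with the name as the final
deterministic tie-break.

### Structure comparison

Superposition computes the Kabsch least-squares rotation (via SVD-based
vector alignment, determinant forced to +1) and translation over paired
atoms, Cα by default — the standard reading of a per-residue RMSD over a
~300-residue domain. Degenerate (collinear) point sets are rejected since
the rotation is then undetermined. Polar contacts report all N/O atom
pairs between queried residues below 3.5 Å; with no hydrogens in the
models, a donor–acceptor heavy-atom distance stands in for a hydrogen
bond and no angle term is applied.

## Synthetic data

The generator lays a shared backbone on a compact cubic-lattice coil
(3.8 Å spacing, so lattice neighbors fall under the 4.5 Å cutoff and the
contact map is non-empty and connected), attaches 1–4 pseudo side-chain
heavy atoms per residue within 1.5 Å of the Cα, and gives the two parents
identical coordinates but different residue identities at a chosen
fraction of positions. Defaults: 60 residues, conservation fraction 0.5,
k = 4 planted blocks (non-conserved columns chunked in column order) —
large enough for nontrivial partitions, small enough for exhaustive
oracles. Stability assays are simulated from the planted additive model,
baseline 72 °C (a P2-like T50), per-block effects drawn uniformly from
±6 °C (spanning the magnitude range of the fitted GH5 block effects), and
homoscedastic Gaussian noise with σ = 1 °C (the scale of the measured ±
entries). Everything is reproducible bit-for-bit from the seed.

What the toy worlds do *not* emulate: real backbone divergence between
parents (all synthetic contacts are shared, so 0.5-weight edges only
arise in hand-built test graphs), alignment gaps (gapless by default;
gap handling is exercised by dedicated unit tests), realistic side-chain
packing, and any correlation between sequence and structure. Passing
tests therefore demonstrate the correctness of the bookkeeping, the
combinatorics, the optimization and the statistics — not that the 4.5 Å
contact model captures real protein energetics.

## Numerical choices and problem sizes

- Partitioner: seeds derive from one `numpy` generator; 20 restarts by
  default; swap/move gains must exceed 1e-12 to count, avoiding cycling
  on floating-point ties.
- Exhaustive enumeration is capped at 14 nodes; the cross-checks use
  8–13-node graphs, where a full run takes seconds.
- Closed-form/enumeration agreement is checked to 1e-9 over 50 random
  designs with k up to 10 (2^10 chimeras each).
- Parameter recovery uses 10 training codes (including both parents) and
  200 replicates; the acceptance script reports the largest |z| of the
  mean estimate against the planted truth.
- Analysis drivers run on the default 60-residue world; the whole suite
  and the acceptance script complete in well under a minute.

## Known limitations

- Two parents only; the ⟨E⟩ = cut/2 closed form and the 1.0/0.5 weighting
  are specific to that case.
- The subset-selection objective is a documented interpretation of a
  qualitative description, not a reproduction of the original search.
- Real-structure headline numbers (the 8-block ⟨E⟩ = 16.25 design on the
  deposited GH5 structures, the 0.486 Å chimera-vs-parent RMSD, 58%
  aligned identity) require the deposited PDB entries as inputs; the code
  paths are the same ones exercised on synthetic structures, but those
  numbers are not recomputed here.
- Predictions from the near-saturated T50 fit extrapolate poorly in
  absolute terms; they are meaningful as rankings.
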