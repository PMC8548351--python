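# Methods

This note records the models, conventions and numerical choices behind
the package, and what the synthetic experiments do and do not show.

## Evolutionary features

**Column profile.** MSA rows are projected onto query (match) columns;
A3M lowercase insertion states are removed on reading. Per column, gap
and 'X' characters are excluded and the remaining counts, plus an
additive pseudocount λ per amino acid, are renormalised. Rows whose gap
fraction exceeds `trim.max_row_gap_fraction` (default 0.5) are removed
first; the query is always kept. No sequence weighting is applied by
default: the features are intentionally simple column statistics, and
weighting would make them depend on a similarity threshold that is
another tunable. The default background is a packaged standard
amino-acid frequency table (the Robinson–Robinson frequencies used by
PSI-BLAST's null model); `background_mode="pooled"` switches to
frequencies pooled over the MSA itself.

**Relative entropy.** RE_i^a is the binary KL divergence between f_i^a
and p^a, with the standard convention 0·ln 0 := 0 so fully absent or
fully conserved frequencies are well defined. RE is non-negative and
vanishes exactly when f = p. The degree of conservation D_i is the exact
row sum — a machine-precision identity, not an approximation.

**PSSP.** The site terms h_i of a Potts-type sequence energy are fitted
in the independent-site closed form: with couplings ignored, the
likelihood factorises per column and the maximum-likelihood field is
h_i(a) = ln f̃_i(a) up to an additive constant, fixed by the zero-sum
gauge. Consequently softmax(h_i) reproduces the λ-smoothed frequencies
exactly (tested to 1e−9), which makes the construction deterministic
and testable; no iterative Potts optimisation is involved, and pairwise
couplings are out of scope throughout.

## Torsions and the basin potential

**Dihedrals.** φ_i is the dihedral of C_{i−1}–N_i–CA_i–C_i and ψ_i of
N_i–CA_i–C_i–N_{i+1}, computed with the quadrant-aware atan2 form and
reported in degrees in [−180, 180) (+180 wraps to −180). φ of the first
and ψ of the last residue do not exist and are always masked, as are
angles spanning an incomplete residue or a broken peptide bond. The
chain-break threshold is 2.0 Å on the C–N distance (the ideal peptide
bond is ≈1.33 Å, so 2.0 Å cleanly separates bonded from broken without
flagging strained geometries).

**Basin potential.** Observations (left, center, right, φ, ψ) are
binned into 72×72 half-open 5° bins. Triplet-conditioned maps with
fewer than `min_triplet_count` (default 20) observations back off to
the center-residue map; a residue whose center was never observed backs
off to the global pooled map. 20³ triplet contexts are sparse in any
desk-scale corpus, hence the three-level backoff. Maps are smoothed
with a per-bin pseudocount (default 1/72² so the total added mass is
1 observation) and normalised; with zero pseudocount the center map is
exactly the count-weighted mixture of its triplet maps. Secondary
structure is not conditioned on (mode 'A').

**Reduction.** Each 72×72 map is treated as 72 points — the φ-rows —
in the 72-dimensional ψ-bin space and embedded to 72×2 per key. This
orientation had to be fixed by convention; embedding φ-rows keeps one
embedded point per φ-band, which is the axis the downstream feature
indexes. Two reducers are provided: t-SNE (perplexity 30, PCA
initialisation, 500 iterations, seeded) and PCA with a deterministic
sign convention (the largest-magnitude loading of each component is
made positive). PCA is the default in tests and fixtures because it is
bit-reproducible; the serialized potential records method and seed. The
per-residue RBP row is the row-major flattening of the 72×2 embedding
of the residue's (left, self, right) key, with the backoff chain above
for terminals and unseen contexts.

## Feature assembly

Block order is fixed as AA(20) | PP(7) | PSSM(20) | RE(20) | DC(1) |
PSSP(20) | RBP(144) = 232. The physicochemical table holds the seven
standard descriptors per residue; 'X' rows take the per-property mean,
and 'X' one-hot rows are zero. All channels are min-max scaled into
[−1, 1]; bounds are fitted on the training set only, persisted with the
model, and test-time values outside the bounds clip. One-hot channels
(values ⊆ {0, 1}) and constant channels pass through unchanged, the
latter with a warning. Scaling is dataset-level, not per protein, so a
residue's feature vector does not depend on which chain it sits in.
PSSM scores get the same min-max treatment as every other channel.

## Network

Input (L×232) feeds a unidirectional LSTM and a bidirectional LSTM in
parallel; their per-position outputs are concatenated and passed to a
second bidirectional LSTM, then per-position FC-1 (256 units, ReLU,
dropout 0.8 during training only) and FC-2 (4 sigmoid units). Targets
are t = (x + 1)/2 for x ∈ {sin φ, cos φ, sin ψ, cos ψ}, mapping the
trigonometric range onto the sigmoid range; decoding inverts the affine
map and applies atan2(sin, cos), which restores the quadrant the naive
arctangent ratio loses. Positions where both decoded sin and cos are
within 1e−6 of zero are masked with a warning rather than decoded.

The implementation is plain numpy with hand-written backpropagation
through time; the test suite checks every parameter block against
central finite differences. Variable-length chains are padded per batch
and masked: at padding steps the recurrent state is carried through
unchanged (the reversed direction is realised by flipping sequence and
mask together), so per-position outputs are provably independent of the
amount of padding — asserted to 1e−6 in the tests.

Training uses Adam (lr 0.001), masked MSE (masked target entries
contribute exactly zero loss and gradient), batch size 32, and a
maximum of 5000 optimizer steps; "iterations" are read as optimizer
steps, configurable. The best checkpoint by validation MAE is restored
at the end; `target_loss` optionally stops an overfitting run early.
All randomness — initialisation, shuffling, dropout — is driven by
explicit seeds, and identical seeds reproduce loss histories
bit-identically.

Default hidden sizes are 352 per LSTM direction, chosen via the
analytic parameter count (4(I+H+1)H per direction plus the FC terms) to
land at 6,620,292 ≈ 6.6M learnable parameters at input width 232. All
sizes are configurable; tests and fixtures use hidden sizes 8–24.

## Evaluation

The wrap-aware MAE pools min(|P−E|, 360°−|P−E|) over all residues of
all chains whose torsion is defined. Masked residues (terminal φ/ψ,
chain breaks) are excluded from both the numerator and the residue
count Σ L_i: counting angles that do not exist would silently deflate
the error, and excluding them is the only self-consistent reading.
The per-class breakdown applies the same estimator restricted to
residues carrying a given Q8/Q3 label; labels come from the user (any
assignment tool), and classes with no scoreable residue are reported as
missing rather than zero. The pooled MAE equals the residue-count-
weighted mean of the class MAEs, which the tests assert numerically.

## Synthetic data

The generators make the whole pipeline testable without downloads.
MSAs: column distributions are Dirichlet draws concentrated on the
query residue in proportion to a per-column conservation profile
(default 0.6), depth 50, 5% gaps. Backbones: ideal-geometry chains
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard bond angles, trans
ω) built from prescribed (φ, ψ) by sequential internal-coordinate
placement; extraction reproduces the prescribed torsions to ≤1e−3°.
The end-to-end set (default 50 chains of 30–60 residues) plants a
learnable signal: residues are drawn from helix-, strand- and
coil-preferring groups in segments (≈45/30/25%), and each residue's
(φ, ψ) is its group's basin centre — (−60, −45), (−120, 130),
(−70, 150) — plus 10° wrapped-normal noise. A synthetic PSSM is
derived from the MSA columns as integer log-odds, and the RBP uses a
potential built from the same synthetic corpus.

What this does not emulate: real structural context (angles here
depend only on local residue identity, not on long-range packing),
realistic MSA phylogeny (rows are i.i.d. given the column
distributions), database-search noise in PSSMs, or experimental
artefacts in structures. Passing the learning-sanity tests therefore
shows the architecture, masking, optimisation and metrics are correct
— not that the benchmark accuracies on real protein datasets are
reproduced; those require large structure corpora, database searches
and GPU-scale training, which are out of scope here.

## Numerical conventions and edge cases

* Angles live in [−180, 180); +180 wraps to −180; bin index
  floor((angle+180)/5).
* 0·ln 0 := 0 in the RE; background probabilities must lie strictly in
  (0, 1).
* Degenerate dihedrals (coincident points, parallel bonds) raise rather
  than return an arbitrary value.
* PDB altloc: highest occupancy wins, ties by label order; MSE maps to
  M, other nonstandard residues to 'X'; first model only.
* The constant baseline uses the circular mean (atan2 of mean sin/cos),
  so wrap-around angle distributions are handled correctly.
* Problem sizes in tests and the acceptance script (50 chains ≤60
  residues, hidden sizes 16–24, ≤2000 steps) are chosen as the smallest
  sets on which the learning-sanity properties are stable across seeds.
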