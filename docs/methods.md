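# Methods

## Problem setting

Geometric pocket detectors (Fpocket and its relatives) find candidate
ligand-binding sites by analysing the concavity of a protein surface. They
are tuned for recall: the true site is almost always among the candidates,
but so are many false positives. `pocketgt` implements the rescoring half of
a hybrid predictor: each candidate is converted into a small residue graph
and scored in (0, 1) by a graph transformer, and candidates are ranked per
protein by that score.

## From structure to pocket graph

1. Waters, ligands and all other HETATM content are removed before
   detection and featurization; bound ligands are used only for labeling.
2. A candidate is a cloud of alpha-sphere centers ("vertices"). Its
   barycenter is the arithmetic mean of the vertices.
3. **Label.** A candidate is a true pocket iff DCA < 4 Å, where DCA is the
   minimum Euclidean distance between the barycenter and any atom of any
   bound ligand. The boundary is strict: DCA = 4.0 Å labels false.
4. **Nodes.** Every residue whose Cα lies within 10 Å (inclusive) of *any*
   vertex becomes a node, carrying its amino-acid token (20 standard
   residues + one unknown token), its solvent-accessible surface area
   (SASA), and its Cα coordinates.
5. **Edges.** All node pairs with Cα–Cα distance ≤ 25 Å. Pocket graphs are
   compact, so they are usually dense.

SASA is computed with the Shrake–Rupley rolling-probe method (probe 1.4 Å,
1000 sphere points per atom by default, heavy polymer atoms only) via
biotite. Per-residue values carry a few percent of sphere-discretization
error; whole-protein totals are stable to ~0.5%. Ligands are excluded from
the SASA calculation, consistent with detection on stripped structures.

## Input features

- Amino-acid block: one-hot over 21 tokens, mapped through a learned
  embedding `E_aa` (21 × d, no bias).
- SASA block: Gaussian radial basis expansion
  `S_ik = exp(-γ (s_i − μ_k)²)` with d centers equally spaced on
  [0, 350] Å² (the cap reflects the upper range of per-residue SASA).
- Edge features: the same expansion of the Cα–Cα distance with d centers on
  [3, 25] Å.
- γ defaults to `1 / (2 Δ²)` with Δ the center spacing — neighbouring basis
  functions overlap at ~0.88, a standard smooth-coverage choice. The
  embedding width is tied to the hidden width d so the edge projection
  stays square.

With SASA enabled, the embedded amino-acid vector (d) and the SASA block
(d) are concatenated and projected 2d → d by a learned linear layer so the
transformer stack sees width d.

## The graph transformer

Each of L layers runs multi-head attention restricted to graph edges. For
edge (i, j) and head h with head width d_h = d / H:

    logit_ij = (1 / √d_h) · Σ_k  q_ik · k_jk · b_ijk

an elementwise *triple* product — the projected edge feature b_ij gates
every query–key channel multiplicatively rather than entering as an
additive bias. Logits are clamped to [−5, 5] before the softmax over each
node's neighbour set (clamping the softmax *input* is the only placement
that affects numerical stability; clamping its output, which already lies
in (0, 1), would be a no-op). Attention output is
`o_i = Σ_j a_ij v_j`; a node with no neighbours gets `o_i = 0` and survives
through the residual path. Heads are concatenated and the layer finishes
with the usual transformer plumbing: output projection, dropout, residual,
layer normalization, then a ReLU feed-forward block (hidden width 2d) with
its own dropout, residual and normalization. Edge features are not updated
across layers.

Node states are sum-pooled (`h = Σ_i f_i^L`), passed through a d → d → 1
ReLU MLP and a sigmoid. Training minimizes binary cross-entropy, computed
from the pre-sigmoid value via softplus for stability.

Only pairwise distances and per-residue scalars enter the computation, so
the score is *exactly* invariant under rigid rotations, translations and
reflections (E(3)) of the input coordinates, and sum pooling makes it
invariant under node relabeling. Both properties are asserted in the test
suite rather than assumed.

### Architecture defaults and parameter counts

Baseline: L = 8, d = 128, H = 8 heads, FFN width 2d, dropout 0.1 →
1,244,161 trainable parameters with the SASA input (1.24 M). Enlarged:
L = 12, d = 256 → 7,317,505 (7.32 M). Head count, FFN width, dropout and
the head-MLP shape are conventional choices; the parameter totals are the
anchor for them.

The network is implemented over a small in-repo reverse-mode automatic
differentiation tape on numpy float64 (see `pocketgt.autodiff`): the model
needs only ~20 primitives, and the sparse gather/segment-sum pair that
implements edge-restricted attention is validated against a dense
masked-attention reference and against central finite differences in the
tests.

## Training recipe

- Adam (β = 0.9/0.999), batch size 128, epoch-level learning-rate schedule:
  linear warmup from max_lr/25 to max_lr = 2·10⁻⁴ at epoch 25, then
  half-cosine decay to 0 at the final epoch (300 by default).
- **Label balancing.** Candidate sets are heavily imbalanced (~7%
  positives). Each epoch uses every negative once plus uniform draws with
  replacement from the positives up to the negative count.
- **Augmentation.** Every training graph is perturbed on the fly:
  bootstrap node resampling of round((1 − σ_node)·N) nodes with
  replacement (σ_node = 0.03; drops some nodes, duplicates others), then
  Gaussian positional noise (σ_pos = 0.5 Å per coordinate), then
  multiplicative SASA noise `s·(1 + σ_SASA·ε)` floored at 0
  (σ_SASA = 0.3). Edges and distance features are rebuilt from the noised
  coordinates so the graph stays self-consistent. Fresh noise is drawn
  every epoch; repeated positives are therefore never identical, which is
  what keeps balanced training from overfitting the minority class.
- Validation data are never balanced or augmented. After each epoch the
  model is scored on the validation split (stratified, since positives are
  rare) and the parameters with the best validation PR-AUC are kept; ties
  keep the earlier epoch. The internal stratified holdout defaults to 20%.
- 5-fold cross-validation at the pocket level; prediction is the ensemble
  mean of the member sigmoid outputs; ranks are assigned per protein by
  descending score with deterministic pocket-id tie-breaks.

## Evaluation

PR-AUC (step-wise interpolated precision-recall area) is the primary
metric on imbalanced candidate sets; ROC-AUC is reported alongside. The
Top-(n+i) success rate asks, per ligand: for a protein with n bound
ligands, is some pocket ranked in the top n+i within 4 Å (DCA) of this
ligand? Reported for i = 0..6, aggregated per ligand over the dataset. All
three metrics are checked against exhaustive brute-force recomputations in
the tests.

## Synthetic data generator

The generator produces the study conditions for all offline tests: toy
proteins as confined self-avoiding Cα walks (3.8 Å steps, ≥ 3.5 Å
clearance, confinement radius 3.3·n^⅓ Å giving protein-like density), 1–4
pseudo side-chain atoms per residue, pocket candidates as 5–20 vertices in
a 3 Å ball around a surface locus, and planted labels that the DCA rule
reproduces exactly: positive plants place a 5–15 atom ligand whose nearest
atom sits 0.5–3.5 Å from the barycenter; negative plants keep every ligand
> 4.5 Å away.

The learnable signal is the amino-acid composition of the pocket lining:
residues within 10 Å of a positive pocket's vertices are redrawn from a
5-residue "binding" palette with probability `signal_strength` (0.9 by
default) per residue; all other residues are uniform over the 20 standard
amino acids. Negative loci are kept ≥ 25 Å from positive loci so linings
are distinct surface sites. Candidate lists mirror a detector run on
ligand-bound structures: whenever prevalence allows
(pockets·positive_fraction ≥ 1) each protein carries exactly ≥ 1 true site
and the remainder are drawn to keep the overall positive share at
`positive_fraction` (default 0.07, matching real candidate sets); at lower
prevalence the generator falls back to per-pocket Bernoulli labels and
adds a far-away ligand so every structure stays labelable.

Defaults are 30 proteins × 20 candidates × 90 residues (~600 pockets).
What the generator does *not* emulate: real fold topology, side-chain
chemistry, detector-specific vertex geometry, sequence redundancy between
proteins, and any physicochemical coupling between composition and
geometry. Passing tests therefore demonstrate that the pipeline and the
optimization behave as specified — not that the model reaches any
particular accuracy on real structures.

## Desk-scale training checks

The learning-sanity test trains the model at reduced size (d = 32, L = 2,
H = 4) for 40 epochs (20 warmup) on ~600 synthetic pockets at 7%
prevalence and signal strength 0.9, with stratified test (25%) and
validation (30%) splits. The budget was fixed from pilot runs at a point
where the recipes are distinguishable: the full recipe (balancing +
augmentation) reliably exceeds held-out PR-AUC 0.9 there, while the same
model trained on the raw imbalanced stream typically lags well behind on
best validation PR-AUC. Given unlimited epochs on this nearly separable
synthetic signal both variants eventually saturate (and on some random
seeds the raw stream already catches up within the budget), so the short
budget is what makes the qualitative ordering observable at desk scale; on
real data, where the signal is far from separable, the gap persists at
full budget.

## Numerical and design choices

- Float64 throughout; no GPU path. Batches are processed as one disjoint
  graph union (block-diagonal batching), so a batch is one tape pass.
- Altloc resolution: highest occupancy, first-in-file on ties. Insertion
  codes are appended to the residue number in residue keys.
- Non-standard residues map to the unknown token; residues missing from
  the SASA table contribute 0 Å² with a warning.
- The 10 Å selection radius and 25 Å edge cutoff are boundary-inclusive.
- Empty candidate selections are dropped with a warning at featurization.
- The fallback cavity detector (grid points ≥ 3 Å from every atom, ≥ 12
  atoms within 6 Å, single-linkage clusters at twice the grid spacing) is
  deliberately simple plumbing for when no detector output is available;
  it makes no claim of Fpocket equivalence.
- Checkpoints are `.npz` archives holding all parameter arrays plus a JSON
  header (config, member count, format version).

## Known limitations

- CPU-only and eager: training the full-size model on hundreds of
  thousands of pockets is out of reach; the architecture is exact at any
  size, but throughput targets desk-scale data.
- Per-residue SASA inherits Shrake–Rupley discretization error (a few
  percent between orientations at 1000 points/atom).
- The PQR reader consumes only vertex coordinates; Fpocket's own pocket
  descriptors and scores are ignored by design.
- mmCIF input, hydrogens, protonation states and symmetry expansion are
  out of scope.
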