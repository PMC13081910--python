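# Methods

This note documents the modelling conventions, defaults, and numerical
choices behind `epigat`, and what the synthetic data used in the tests does
and does not establish.

## Problem and labels

An antibody–antigen complex is a set of chains with roles heavy / light /
antigen (the light chain may be absent; the antigen may span several
chains). Residues are indexed 0-based within each chain and concatenated
heavy → light → antigen; author numbering from the structure file is kept
only as metadata. Two distinct distance criteria are used, deliberately:

* **Adjacency / contact map** — residues are connected if *any* atom pair
  (hydrogens included when present) lies within the cutoff, default 10 Å.
  The contact map is the dense symmetric form of the same criterion with a
  unit diagonal.
* **Interface labels** — a residue is positive if any of its *heavy* atoms
  lies within the cutoff of a heavy atom on the opposite side. The default
  cutoff is 10 Å, reflecting the physical range of non-bonded interactions;
  4.5 Å is retained as the conventional crystallographic contact
  definition. Positives at 4.5 Å are always a subset of positives at 10 Å,
  and the test suite asserts this monotonicity everywhere.

Non-standard residues (HETATM ligands, waters, glycans) are dropped before
any geometry; alternate locations resolve to highest occupancy, ties to
first occurrence. No missing-atom reconstruction is attempted. Secondary
structure is read from precomputed 8-class files when available; the
built-in φ/ψ window fallback (helix φ∈[−90,−30], ψ∈[−77,−17]; strand
φ∈[−150,−90], ψ∈[90,150]; else coil) exists so the pipeline runs without an
external assignment program and should not be mistaken for one.

## Sequence representation

The token vocabulary is the 20 amino acids (alphabetical one-letter order),
unknown `X`, gap `-`, `<pad>`, `<eoc>` — 24 ids, configurable. Chains are
stacked with one `<eoc>` column after each chain (so graph indices and
column indices agree after offsetting); shallow alignments are padded with
`<pad>` rows rather than duplicated queries, which would bias column
statistics. Diversity selection featurizes rows as flattened one-hot
profiles and runs k-means with M−1 centers, keeping the member nearest each
center; duplicate picks are topped up with the rows farthest from all
centers so the output size is exactly M.

## Losses and schedules

* Cross-entropy uses smoothed targets (true class `1−ε+ε/C`, others `ε/C`,
  ε = 0.05) and a positive-class weight `w(e) = 1 + 19·exp(−e/8)`; the mean
  is taken over valid positions (weighted terms divided by the position
  count, not the weight sum). The epoch variable is stage-local: each CTSR
  stage restarts its schedules.
* The AUPR surrogate sweeps thresholds at bin centers `t_k = (k−½)/K`
  (K = 64), avoiding degenerate all-pass/all-fail end bins, computes soft
  TP/FP/FN through `sigmoid((p−t_k)/T)` with T = 0.05, orders bins by
  increasing recall with R₀ = 0, and integrates precision over recall. The
  surrogate loss is `1 − ÂUPR` (bounded, minimized at perfect ranking).
  Ratio denominators carry a stabilizer of 1e−8. As T → 0 and K → ∞ the
  surrogate converges to the exact step-function area; the tests bound the
  gap by 0.02 at T = 1e−4, K = 1024 on tie-free scores (exact ties at the
  domain boundary are a pathology of clipped scores, which softmax outputs
  never produce).
* The smoothness penalty averages squared probability differences over
  deduplicated undirected edges; an empty edge set contributes 0. Its
  coefficient ramps linearly from 0 at epoch 5 to 0.05 at epoch 15
  ("gradually introduced" is otherwise unspecified, so the simplest ramp is
  used).
* Single-class label sets make the surrogate undefined; the composite loss
  then falls back to cross-entropy only and flags the fact in its breakdown.

## Architecture choices

* DyM gates emit one scalar per residue (broadcast over features), computed
  from the sublayer output they modulate; a per-feature variant was
  rejected for interpretability. Gates sit after every attention and
  feed-forward sublayer, after each graph-attention layer, and directly
  after the embedding. With all gate biases pushed large the network
  reproduces an ungated reference — a tested equivalence.
* Pre-norm residual blocks throughout (norm placement is unstated in the
  recipe; pre-norm is the stable choice at small scale).
* Row attention is computed independently within each chain segment
  (including its end-of-chain column); cross-segment weights are exactly
  zero, not merely small. Column attention masks padded rows. Padded
  columns carry no graph edges and are masked from attention and losses —
  growing L must not change any valid output, and a test holds this to
  1e−5.
* Graph attention is GAT-style: per-head linear projections with additive
  source/target scores, LeakyReLU(0.2), a per-destination softmax over
  incoming edges plus a self-loop, no edge features (none are defined for
  this graph).
* The contact-map head symmetrizes its logits with their transpose before
  the loss, since contact maps are symmetric but attention is not.
* Depths default to 2 MSA blocks / 2 GNN layers / 2 attention layers and
  are plain config keys; the desk-scale experiments below use 1/1/1.

## Training engine

AdamW (decoupled weight decay 0.01, applied to matrices only), linear
warmup to the base rate over 10 epochs then cosine decay to 1 % of base.
Gradient accumulation 2, global-norm clipping at 0.5 (post-clip norms are
logged and asserted). EMA (decay 0.995) updates every optimizer step; SWA
snapshots per epoch from epoch 20 (per-epoch rather than per-step is the
standard convention). Final prediction averages the EMA-weights and
SWA-weights *probabilities* — probability-space averaging is the
calibration-friendly reading of "averaging the outputs". Gradient noise is
implemented but off by default (no magnitude is specified anywhere).
Model selection is by validation AUPR of the stage task (macro
one-vs-rest over observed classes for secondary structure).

CTSR stage transfer copies the backbone bitwise, re-initializes only the
incoming task head from a seeded fresh model, and keeps the other heads.
"Soft restart" means optimizer state and learning-rate schedule restart
each stage. Later interface fine-tunes use lr × 0.5 and dropout + 0.05
(configurable; the recipe says "reduced / increased" without values).

## Synthetic data: what it emulates and what it does not

`SyntheticSpec` defaults: 20 heavy + 10 light + 30 antigen residues,
patch of 3 contact pairs at 4.0 Å, all other cross-side residues beyond
25 Å, 1–3 pseudo side-chain atoms per Cα, coordinate noise 0.2 Å, MSA depth
16, background column mutation rate 0.3, interface-column conservation
probability 0.9. This plants the interface signal in **both** pathways the
model consumes — geometry (cross-chain edges appear only near the patch)
and sequence statistics (interface columns are conserved across rows) — so
ablating either pathway remains meaningful. The positive fraction at 4.5 Å
is 6/60 = 10 %, inside the 5–10 % regime of real complexes. Labels are
always derived by the real labeling operations; generation retries until
the 4.5 Å labels equal the planted set exactly, so the generator can never
bypass the pipeline it is meant to exercise.

What passing these tests shows: the full pipeline (parsing → featurization
→ training → evaluation) is wired correctly, the optimization recipe can
extract a recoverable signal under realistic imbalance, and the cyclic
schedule does not degrade the interface task. What it does not show:
performance on real antibody–antigen complexes, whose geometry, MSA depth
structure, and label noise are far richer than straight-chain walks with
planted conservation.

## Desk-scale experiment sizes

The reference experiments (`epigat.experiments`) use the reduced model
(M = 4, L = 64, D = 32, H = 4, depths 1/1/1), 50 synthetic complexes per
seed (34 train / 6 validation / 10 held-out test), one 30-epoch interface
stage for the learnability check, and stage epochs 12/5/5/5/8 for the CTSR
cycle, averaged over 3 seeds. At this model and data size the full-scale
default learning rate of 2e−4 underfits severely, so the experiments use
1e−3 for the interface stage and 5e−4 for auxiliary stages — a standard
scale-dependent adjustment; the schedule shape and every other
hyperparameter keep their defaults, and `TrainConfig` defaults remain the
full-scale values. Typical results: held-out interface AUPR ≈ 0.64 against
a 0.10 base rate (≈ 6×), and the CTSR cycle raising validation AUPR from
≈ 0.52 (first interface stage) to ≈ 0.74 (final), as recomputed by
`scripts/acceptance.py`.

## Known limitations

* The autodiff engine is minimal by design (no views/in-place ops, float64
  only); it is sized for desk-scale runs, not GPU-scale training.
* The dihedral secondary-structure fallback distinguishes only
  helix/strand/coil.
* The antibody embedding for splitting is a 3-mer composition vector — a
  deterministic, dependency-free choice; the function is pluggable so a
  learned embedding can replace it.
* Waters, glycans and other HETATM entities are excluded from all geometry;
  protonation and biological-assembly expansion are out of scope.
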