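# Methods

## Problem and model

`idrfuse` predicts, per residue, whether a protein position lies in an
intrinsically disordered region (IDR). Disorder is length-heterogeneous:
long disordered regions (LDRs, runs of more than 30 disordered residues)
and short ones (SDRs, runs of 1–30) have different sequence signatures, and
a single model tuned to one regime degrades when the LDR:SDR mixture of the
input changes. The package therefore combines six complementary per-residue
predictors and fuses them with weights chosen to be *stable across
mixtures*:

    p_fused[i] = Σ_k w_k · p_k[i],   w_k ≥ 0, Σ w_k = 1,

with the weight vector maximizing the fused ROC AUC summed over several
validation datasets that span different SDR:LDR ratios. Because AUC is
invariant to monotone rescaling, the simplex constraint costs no fitness
and keeps the fused output a probability.

Protein taxonomy: a protein with at least one run longer than 30 residues
is an *LDR protein*; otherwise any disordered residue makes it an *SDR
protein* (a run of exactly 30 counts as short); no disordered residue means
*fully ordered*. The 30-residue boundary is the only length constant in the
taxonomy; the fate of exactly-30 runs is not fixed by the usual definitions
("more than 30" vs "shorter than 30"), and this package assigns them to the
short class.

## Residue representation

Three L×20 evolutionary profiles per protein — PSI-BLAST log-odds (PSSM),
observed frequencies (PSFM) and HH-suite profile-HMM emissions — plus an
L×L coevolution/contact matrix (CCM) and precomputed structural tracks
(8-state secondary structure, contact number ×2, half-sphere exposure ×4,
seven physico-chemical scales, solvent accessibility ×1). Two encodings are
derived:

* **Windowed tensor** (for the searched network): a 20-residue window with
  the residue at row 10, stacked over the three profiles → 20×20×3.
  Out-of-protein rows are zero-padded (the same rule the CCM window states
  explicitly). HHM stored values decode as 2^(−v/1000), the standard
  HH-suite rule; `*` is 0.
* **Block vector** (for the five sequence models): concatenation in the
  fixed order PSSM, PSFM, HHM, SS, CN, HSE, SEVEN, SA, CCM-window
  (widths 20/20/20/8/2/4/7/1/21). The full set is 103-dimensional; the
  hierarchical-attention model omits CN and HSE → 97. The CCM window is
  row i of the matrix in a 21-wide band around the diagonal, zero-padded.
  The concatenation order is a determinism choice; nothing downstream
  depends on it.

Indices are 1-based in files and error messages, 0-based in memory.

## Base predictors

Five sequence-labelling architectures realize complementary mechanisms.
They are reference implementations at desk scale (hidden widths ~8,
conv channels ~8; all scale parameters in `BaseModelSpec`) — the framework
exercised here is the ensemble, not any single model's full-scale weights:

* **CAN** — conv stack + attention pooling over a 7-residue local window;
  trained on SDR proteins only (short-disorder specialist).
* **HAN** — hierarchical attention: residues → fixed 20-residue segments
  (the hierarchy granularity is a package choice) → sequence; trained on
  LDR proteins only.
* **SEQ2SEQ** — BiLSTM encoder with a decoder attending over all encoder
  states (global context).
* **CNN-LSTM** / **LSTM-CNN** — convolution and BiLSTM stacked in the two
  orders; trained, like SEQ2SEQ, on the full LDR+SDR+ordered mixture.

Training: per-residue binary cross-entropy with the disordered class
upweighted by the negative:positive ratio (capped at 10), Adam (lr 0.02),
one protein per step, early stopping on a held-out protein split
(patience 5). The loss and optimizer are package choices; nothing in the
method constrains them.

The networks run on a compact numpy reverse-mode autodiff engine
(`idrfuse.autograd`) whose gradients are verified against central
differences in the test suite. At these sizes a tape of small dense ops is
fast enough that a full test-suite training run takes seconds.

## Architecture search

The sixth predictor is found by differentiable architecture search over
the 20×20×3 tensors. Cells are DAGs with two input nodes and N=2
intermediate nodes; each edge carries a softmax(α)-weighted mixture of 8
candidate operations (zero, identity/skip, separable 3×3/5×5, dilated
3×3/5×5, max/avg 3×3 pooling — identity plays the residual role).
Search alternates first-order steps: α against validation loss, network
weights against training loss (the second-order unrolled gradient is not
used). Discretization keeps, per edge, the strongest non-zero operation
and, per node, the two strongest incoming edges (ties resolve to the
lowest operation index / lowest source node, deterministically), and the
discrete network is retrained from scratch.

Macro-structure (package choices, all in `SearchConfig`): a pointwise stem
(3→C channels, C=4 default), a stack of normal–reduction–normal cells where
*both* inputs of a cell are the previous cell's output, reduction
implemented as stride-2 subsampling of the assembled cell output, and a
classifier head that averages over the amino-acid axis only — keeping the
window-position axis — before the final linear map. Keeping the position
axis matters: the disorder signal lives in specific window rows, and a
fully global pool would discard it.

The search history records both per-step batch losses and whole-validation-
set loss at epoch boundaries (`val_epoch`); descent checks use the latter,
since a single mini-batch loss is too noisy an estimator to compare two
points in training.

## Fusion

A real-coded GA (written in-package: tournament selection of size 3,
BLX-0.5 blend crossover with probability 0.9, Gaussian mutation σ=0.05
with probability 0.1, elitism 2, population 50 × 100 generations by
default; every candidate projected back to the simplex) maximizes

    fitness(w) = Σ_{k=1..M} AUC_k(fused with w),

over M validation datasets (five in the reference setting) with residues
pooled across each dataset's proteins. The fitness optimized is the
*fused* track's AUC sum — the quantity the weights actually control.
Although the approach is often described as multi-objective, the printed
fitness is a scalar sum, so a single-objective GA on the sum is the
default; a Pareto mode over the per-dataset AUC vector is available behind
`ga_optimize(..., pareto=True)`. The uniform-weight average fusion is
provided as the baseline.

## Metrics and stability experiments

Sn = TP/(TP+FN), Sp = TN/(TN+FP), BACC = (Sn+Sp)/2, MCC, and AUC (equal to
the Mann-Whitney pair-ranking probability, ties ½). Residues are pooled
across a dataset's proteins (no per-protein macro-averaging). Metrics with
a zero denominator are reported as NaN and flagged, never coerced to 0.
The binary call threshold defaults to 0.5 and is exposed as a flag; no
particular operating point is canonical.

Two harnesses probe mixture stability: `ratio_sweep` removes SDR proteins
in seeded-random equal increments (11 steps by default) from the full
mixture down to LDR-only and re-scores every method at each step;
`resample_compare` samples protein subsets repeatedly (400×50 in the
reference design; smaller here) and tallies pairwise wins.

## Synthetic data

The generator produces every input the framework consumes, so the whole
pipeline is testable offline:

* **Labels**: runs placed in an ordered background; SDR run lengths
  truncated-geometric on 1–30, LDR lengths shifted-geometric from 31.
  Class composition is exact by construction and verified with
  `classify_protein`.
* **Sequences**: background Robinson–Robinson-like composition; disordered
  runs enriched in disorder-promoting residues (P, E, S, Q, K, G, A) with
  tunable divergence.
* **Profiles**: PSFM/HMM rows are Dirichlet draws (concentration 50)
  around the residue's class composition, mixed toward background by
  `signal_strength` (0 ⇒ label-independent); PSSM is the log2 ratio
  against background. CCM is symmetric short-range decay plus noise.
  Structural tracks have the correct widths; the seven physico-chemical
  columns carry a mild label shift.
* **Predictor streams**: the binormal model — negatives N(0,1), positives
  N(d,1) with d = √2·Φ⁻¹(AUC), squashed by the normal CDF (monotone, so
  AUC-preserving). Chosen because it gives a closed-form AUC↔effect-size
  map; calibration is within ±0.02 at n = 10⁵. Per-class targets plant
  length specialists for the complementarity experiments.

What passing on this generator shows: the encoders, search, fusion and
harnesses behave as specified on data with the right marginal structure.
What it does not show: performance on real proteins — the generator has
no true covariation, no alignment-depth variation, no annotation noise,
and its "disorder signal" is planted rather than biophysical.

## Problem sizes and numerical choices

Tests and the acceptance pipeline run at deliberately small sizes chosen
as the package's reference desk-scale conditions: tens of proteins of
length 50–90, hidden widths 4–8, search on a few hundred residue tensors
for 1–2 epochs, GA populations of 24–30 for 25–30 generations. Determinism
is end-to-end: every stochastic component takes a seed, and identical
(seed, config, data) triples give identical parameters, trajectories and
outputs. Degenerate inputs (L=1 proteins, single-class datasets, empty
regime filters, even window widths, non-square matrices) raise typed
errors rather than silently proceeding.

## Known limitations

* The five base architectures are mechanism-faithful small references, not
  reimplementations of the original published networks.
* Reduction-cell downsampling by output subsampling is simpler than
  stride-2 convolution inside input-adjacent ops; at 20×20 inputs the
  difference is immaterial, but genotypes are not interchangeable with
  those of the original cell design.
* The GA is single-objective on the AUC sum by default; the Pareto mode is
  provided but lightly exercised.
* No post-smoothing of per-residue probabilities along the sequence is
  applied before or after fusion.
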