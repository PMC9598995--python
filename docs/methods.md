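# Methods

This note documents the models and procedures `bindfeat` implements, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Scope and assumptions

The package operates on *predicted* single-chain structures reduced to one
Cα coordinate per residue. Its premise is that raw coordinates are a poor
network input and must be re-encoded; all encodings below are functions of
the Cα geometry plus standard per-residue annotations (HHblits profile,
DSSP secondary structure and ASA). Multi-chain complexes, mmCIF input,
insertion codes and altlocs are out of scope; running the upstream tools
(structure prediction, HHblits, mkdssp) is the user's responsibility — the
package consumes their output files. pLDDT is parsed from the B-factor
column and carried as metadata only; it feeds no feature.

Residue indices are 1-based at every public interface (PDB/DSSP
convention) and converted to 0-based array rows exactly once at the
boundary.

## Input decoding

**HHM profiles.** hh-suite stores scores as `−1000·log2(p)` rounded to
integers, with `*` for probability zero. All 30 columns (20 match
emissions + 7 transitions + 3 Neff) are decoded uniformly by
`2^(−s/1000)`, `*` → 0. The format itself does not prescribe whether a
consumer should use raw integers or decoded values; decoding is the common
practice and is isolated in one function, with `read_hhm(..., raw=True)`
exposing the raw integers for anyone wanting the alternative.

**DSSP.** The classic fixed-column format is parsed (header line
`#  RESIDUE`, SS at column 17, ACC at columns 35–38). Chain-break rows are
skipped with a warning count. The parser is cross-checked in the tests
against Biopython's independent DSSP-file reader.

## Feature encodings

**Spatial filtering.** Neighborhood membership is the *closed* ball
`d ≤ r`, so `r = 0` keeps only the residue itself and reproduces the
no-filtering baseline exactly — the property the radius sweep's 0 Å row
relies on. The filtered row is the unweighted arithmetic mean over the
neighborhood. Filtering is applied to all 30 profile columns uniformly.

**Distance-map SVD.** `svd_reduce` implements the literal projection
`A′ = A·V_k` (not the equivalent-up-to-signs `UΣ` truncation). SVD signs
are arbitrary, so each selected right-singular vector is flipped to make
its largest-magnitude entry positive; this makes features reproducible
across runs and platforms. Ties in degenerate spectra are left to the
underlying LAPACK ordering; tests avoid constructing degenerate spectra.

**Secondary structure.** The 8-state DSSP alphabet is merged H/G/I → H,
B/E → E, rest (T, S, P, blank, unknown) → C; the function is total so
newer DSSP outputs (P for polyproline II) degrade gracefully to coil.

**rASA.** `ASA/MaxASA` with the Tien et al. (2013) *theoretical* maxima,
stored as a named constant and overridable per call. Observed ASA can
exceed the theoretical maximum, so the ratio is clipped to 1.0, keeping
the model-input contract `rasa ∈ [0, 1]`.

**OneHot.** 20 standard residues; non-standard codes (X, U, B, Z, …) map
to an all-zero row with a warning — the least-information encoding, since
no convention is prescribed.

## Window dataset

One window per residue (N = ΣL), width 31, centre at position 16.
Termini are zero-padded; mirroring was the plausible alternative, but
zero-padding keeps padding distinguishable from data and is the
convention of comparable site predictors. Splits are by whole protein,
never by residue, to prevent leakage. Class weights default to 10:1
(binding:non-binding) for the PPI task and 3:1 for the metal task, with
arbitrary overrides allowed.

## Classifier

Per feature block, a branch of two ReLU hidden layers (default 256/64),
dropout (0.3), batch normalization and a dense branch output (64), then
concatenation and a 2-class softmax. The loss is weighted cross-entropy:
each example's term is multiplied by its class weight — implemented as
per-example loss multipliers, the `class_weight` idiom of the major
frameworks. Decisions are argmax; no threshold tuning.

Hidden widths, dropout, optimizer (Adam, lr 1e-3), and epoch count are
free configuration: the reference protocol fixes only the batch size
(1024), the loss and the class weights, so these defaults are ordinary
"adjusted by experience" values and are recorded in run manifests.
Implementation is pure numpy in float64; backpropagation (including the
batch-norm backward pass) is verified against central finite differences
in the test suite, and training is bitwise reproducible given
`random_state`. A non-finite loss aborts with a diagnostic rather than
training on.

**Evaluation** is precision `TP/(TP+FP)` only. When no positive is
predicted the metric is undefined and reported as a distinguished
`None`/NaN, never silently 0; replicate reductions skip undefined
replicates. Experiments run five seeded replicates and report mean and
**population** standard deviation (ddof = 0). Population STD was chosen
because it is the convention that best reproduces the printed STDs of the
reference replicate tables from their per-replicate values; `ddof` is a
parameter for anyone preferring the sample convention.

## Mutation change-rate analysis

For a point substitution (equal wild-type/mutant lengths), the change
rate `(mut − orig)/orig` is computed element-wise for the raw profile,
the spatially filtered profile, and each residue's distance to the
mutated site. Cells with `orig = 0` (possible after `*` decoding, and the
site's own 0/0 distance) are *masked*, not dropped or set to infinity, so
heatmap scaling stays finite and the mask is reported.

Distances to the site are internal coordinates, so the distance rate is
invariant under any global rotation/translation of either structure — no
superposition is performed, by construction.

The case-study filter is a *sequential* variant: neighbors are visited
nearest-first and the running row is replaced by the pairwise mean
(running + neighbor)/2 after each step. The phrase "average each time a
neighbor is added" also admits a cumulative-mean reading, but that is
algebraically identical to the plain neighborhood mean and would amplify
nothing; the pairwise reading, which geometrically up-weights later
(more distant) neighbors, is the one that changes the smoothing, so it is
the default here — confined to the mutation workflow and flagged in
output metadata (`filter_mode`), with `cumulative` selectable. Distance
ties are broken by residue index, making the recurrence deterministic.

Window clipping centres the mutated site at position 16 of 31 with
zero-padding, mirroring the classifier's window geometry.

## Synthetic data

The fixture generator emulates *formats and geometry*, not biology:

- `ideal_helix` places Cα on an α-helical wheel (radius 2.3 Å, rise
  1.5 Å, 100°/residue), giving the realistic ≈3.8 Å consecutive spacing,
  so the {0,3,5,6,7,8,9,11} Å radius grid produces genuinely growing
  neighborhoods; `perturbed_chain` adds seeded Gaussian jitter.
- Profiles are random integer-coded scores in [0, 6000] with ~2% `*`
  cells, exercising decoding and zero-masking; DSSP ASA is uniform on
  [0, 1.2×MaxASA], exercising rASA clipping.
- Label rules are exactly verifiable: i.i.d. Bernoulli at a set
  prevalence (default 6.8%, the reference training-split class balance),
  an rASA threshold, or a threshold on a supplied signal.

The learnability dataset (`synth_smoke_proteins`) plants a spatially
smooth latent field (radius-7 Å neighborhood mean of white noise) whose
70th percentile defines the labels, observed in one profile column
through strong i.i.d. noise (σ = 0.8) with 29 pure-noise distractor
columns. Spatial filtering at a suitable radius denoises the observed
column, so a radius sweep should beat its own 0 Å baseline. The ~30%
prevalence is chosen for statistical stability of precision on small
fixture test splits, not to mimic the 6.8% real-data imbalance.

A green radius-sweep test therefore establishes that the pipeline can
recover a planted spatial signal end-to-end — not that any particular
radius is optimal for real proteins, and not the absolute precision
levels of real-data experiments, which depend on external datasets and
GPU-scale training that are explicitly out of scope.

## Known limitations

- Single chain, PDB format only; no mmCIF.
- The MLP is CPU-bound numpy: suitable for fixtures and small studies,
  not for ~10⁶-window real datasets at the default architecture.
- Fixture profiles are i.i.d. noise; they carry no real conservation
  statistics, so feature-importance comparisons between blocks on
  fixtures are meaningless.
- Precision is the only built-in metric, matching the reference
  protocol's deliberate single-metric design; recall/F1/AUC are easy to
  add on top of `EvalResult` counts but are not reported.
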