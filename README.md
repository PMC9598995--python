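# bindfeat

Per-residue feature encodings of predicted protein 3D structures for
single-sequence binding-site prediction.

Sequence-based predictors of binding residues (protein–protein interaction
sites, metal-binding sites in membrane proteins) traditionally rely on
conservation profiles and predicted secondary structure alone. With accurate
predicted structures now available for most single chains, the open question
is *how to encode* the predicted coordinates so that a deep network can use
them — feeding raw coordinates directly does not work well. `bindfeat`
implements five encodings of a predicted structure, the windowed
classification harness to evaluate them, and a wild-type/mutant change-rate
analysis, for structural bioinformaticians who want to reproduce or extend
that style of feature-engineering study.

## The encodings

Given a chain of `L` residues with Cα coordinates `x_i`, an HHblits profile
`P ∈ R^{L×30}` and DSSP output:

- **OneHot** (`L×20`) — amino-acid identity.
- **HHblits** (`L×30`) — the conservation profile, decoded from the
  integer-coded HHM file by the hh-suite rule `2^(−s/1000)` (`*` → 0).
- **Space-HHblits** (`L×30`) — *spatial filtering*: row `i` is replaced by
  the mean of the profile rows of all residues within a radius `r` of
  residue `i`, `N_r(i) = { j : ‖x_i − x_j‖ ≤ r }`; `r = 0` keeps only the
  residue itself (no filtering).
- **SVD** (`L×k`) — with the pairwise Cα distance map `A = UΣVᵀ`, the
  embedding `A′ = A·V_k` onto the top-`k` right-singular vectors (`k` = 8
  or 16 in the evaluated settings).
- **SS** (`L×3`) — DSSP 8-state secondary structure merged to three states
  (H/G/I → H, B/E → E, everything else → C), one-hot encoded.
- **rASA** (`L×1`) — relative accessible surface area `ASA/MaxASA`, with
  the theoretical MaxASA table of Tien et al. (2013), clipped to `[0, 1]`.

A sliding window of 31 residues (zero-padded at the termini) around each
residue is classified by a multi-branch MLP — one branch per feature block,
each *two hidden layers → dropout → batch-norm → dense*, concatenated into
a 2-class softmax — trained with weighted binary cross-entropy (class
weights 10:1 for PPI sites, 3:1 for metal sites) and scored by precision
`TP/(TP+FP)`, over five seeded replicates (reported as mean and population
STD). For a wild-type/mutant pair the package computes the change rate
`R = (mutated − original)/original` of the raw profile, of the spatially
filtered profile, and of each residue's distance to the mutated site.

## Worked example

Everything is testable offline from the synthetic fixture generator:

```bash
bindfeat fixtures demo --n-proteins 5 --seed 7
bindfeat featurize demo/fix000.pdb --hhm demo/fix000.hhm \
    --dssp demo/fix000.dssp --radius 7 --out demo/fix000.tsv
bindfeat sweep demo --radii 0,3,5,7,9,11 --out demo/sweep.tsv
```

Or in Python, a radius sweep on proteins whose labels follow a spatially
autocorrelated signal observed through heavy noise:

```python
from bindfeat import fixtures as fx
from bindfeat.harness import (ProteinData, radius_sweep_config,
                              run_experiment, split_proteins)

prots = fx.synth_smoke_proteins(n_proteins=20, length=60, seed=5)
splits = split_proteins([ProteinData(s, p, None, lab)
                         for s, p, lab in prots], seed=5)
cfg = radius_sweep_config(radii=(0., 3., 5., 7., 9., 11.),
                          blocks=("space_hhblits",), seeds=(11, 22, 33, 44, 55),
                          epochs=12, hidden=(16, 8), branch_units=8,
                          batch_size=128)
print(run_experiment(cfg, splits).round(3))
```

prints (one row per filter radius; E1–E5 are test-set precisions of the
five replicates):

```
                       E1     E2     E3     E4     E5  Average    STD
0 Å (no filtering)  0.386  0.583  0.316  0.371  0.291    0.389  0.103
3 Å                 0.351  0.414  0.255  0.328  0.288    0.327  0.054
5 Å                 0.412  0.452  0.531  0.314  0.371    0.416  0.073
7 Å                 0.408  0.667  0.574  0.281  0.370    0.460  0.140
9 Å                 0.433  0.559  0.531  0.320  0.417    0.452  0.086
11 Å                0.495  0.585  0.554  0.333  0.427    0.479  0.091
```

Filtering at several positive radii beats the 0 Å baseline because the
neighborhood mean denoises the spatially smooth label signal — the
qualitative shape such sweeps are designed to detect. On this synthetic
data the curve is noisier than on real proteins; only the
baseline-vs-best comparison is meaningful, not individual cells.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the main computation from scratch: it generates a fixture protein
set, round-trips all three file formats, computes every feature block,
assembles the window dataset, runs the 5-replicate radius sweep above, and
performs the mutant change-rate analysis, writing the target-metric JSON
to `--out` (plus the sweep table next to it).
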