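# Methods

## Problem and model

`ionseg` treats residue-level ion-binding prediction as binary
classification of sliding windows. A window of odd length `L` is centered
on every residue of a chain; `(L−1)/2` pad residues `X` are appended at
both termini so that terminal residues are valid centers. The window is
positive iff its center is annotated as binding the ligand. Coordinates
are 1-based, matching binding-annotation tables.

The model assumes binding is determined by the local sequence neighborhood:
window content under five residue properties (identity, hydropathy class,
polarization charge, predicted secondary structure, predicted relative
solvent accessibility). No structural coordinates, evolutionary profiles or
inter-chain context enter the model. Structure tracks are consumed as
externally predicted inputs, never computed here.

### Property alphabets

Symbol order is fixed and part of the feature layout (last symbol is always
the pad class):

| property | symbols (in order) | size |
|---|---|---|
| AA  | `A C D E F G H I K L M N P Q R S T V W Y X` | 21 |
| HYD | strongly hydrophilic {R,D,E,N,Q,K,H}, strongly hydrophobic {L,I,V,A,M,F}, weakly hydrophilic {S,T,Y,W}, P, G, C, pad | 7 |
| CHG | positive {K,R,P}, negative {D,E}, uncharged, pad | 4 |
| SS  | H, E, C, pad | 4 |
| SA  | exposed (> 0.25 strictly), buried, pad | 3 |

Proline is listed in the positive-charge class deliberately, following the
grouping this feature set was defined with; changing it would silently
change every charge feature. Non-standard residue letters (B, Z, U, O, J)
are folded into the pad symbol with a warning. Every alphabet carries an
explicit pad class so that composition vectors over padded windows remain
normalized instead of silently dropping positions; consequently the AA
composition block has 21 entries, not 20.

### Position matrix scoring

Per class (binding / non-binding) and property, with `A` the alphabet size
and `N` the number of training segments:

- frequency matrix `p[i,j] = (n[i,j] + √N/A) / (N + √N)` — the √N
  pseudocount guarantees strictly positive columns that sum to 1 exactly;
  the constant `A` generalizes the 21-symbol amino-acid case to the smaller
  alphabets (keeping 21 would break column normalization);
- weight matrix `m[i,j] = log(p[i,j]/p0[j])` against a background `p0`;
- conservation `C[i] = 100/log A · (Σ_j p log p + log A) ∈ [0, 100]`;
- segment score
  `S = Σᵢ C[i](m[i,j(i)] − m[i,min]) / Σᵢ C[i](m[i,max] − m[i,min])`.

`C` and `S` are invariant to the logarithm base (verified by test); natural
logarithms are used. The background `p0` is not prescribed by the scoring
scheme itself; the default is the add-one-smoothed pooled symbol frequency
over all training segments of both classes (`background: pooled`), with
`uniform` (1/A) available as a config option. A fully uninformative matrix
(zero denominator in `S`) yields `S = 0` with a logged warning rather than
an exception, so a degenerate training fold cannot abort a CV run.

### Increment of diversity

For count vectors, `D(X) = N log N − Σ nᵢ log nᵢ` with `0·log 0 := 0`, and
`ID(X,Y) = D(X+Y) − D(X) − D(Y)` — nonnegative, symmetric, and zero exactly
for proportional compositions. The class "standard source" pools symbol
counts over all training segments of that class; a test segment enters with
its raw length-`L` counts (the formulas are count-based, so counts rather
than frequencies are the literal reading). Natural logs; the base only
rescales the feature and is absorbed by standardization.

### Feature sets

- `component`: 39 = 21+7+4+4+3 concatenated composition blocks.
- `position`: per property the 2L lookups `(m_pos[i,j(i)], m_neg[i,j(i)])`,
  10L total; a one-hot per-position encoding (`position_encoding: onehot`)
  is provided as an alternative realization of position-conservation
  features, since more than one encoding is defensible.
- `refinement`: 20-dim = 10 ID values then 10 S scores, each ordered
  (AA, HYD, CHG, SS, SA) × (positive model, negative model).
- `all`: concatenation of the three.

### Classifier

A soft-margin SVM with the Pearson VII universal kernel
`K(x,y) = 1/[1 + (2‖x−y‖√(2^{1/ω}−1)/σ)²]^ω` (ω = σ = C = 1 by default, all
configurable; ω=1 is the Lorentzian shape, large ω approaches a Gaussian).
The dual problem is solved by a from-scratch Platt-style SMO: two
multipliers optimized analytically per step, first/second-choice heuristics
with an error cache, and endpoint evaluation of the dual gain along the
constraint when the curvature `η = K₁₁+K₂₂−2K₁₂` is non-positive (which
occurs for duplicate feature vectors). Convergence = no KKT violation
beyond the tolerance (default 1e-3); exceeding the generous step cap
(200n + 10000) raises an error carrying iteration diagnostics. Features are
standardized per dimension using training-fold statistics — the kernel is
distance-based and the feature blocks are heterogeneous in scale, so
standardization is required for the kernel width to be meaningful. A
decision value of exactly 0 is called positive.

### Evaluation protocol

Binding residues are rare (typically < 5% of windows), so evaluation is
balanced: each of 10 resamples draws `|positives|` negatives uniformly
without replacement (seeded), runs a stratified 5-fold CV on the balanced
set, and every fit artifact — frequency/weight matrices, conservation,
diversity sources, background, standardization — is computed on training
folds only (a state-hash test pins this). Per resample, fold confusion
counts are pooled and metrics computed; the report averages the 10
per-resample metrics (macro). Micro pooling of all counts is available via
`averaging: micro`. Metrics are Sn, Sp, Acc (percent) and MCC; an MCC whose
denominator has a zero factor is reported as 0, an Sn/Sp with a zero
denominator as missing. The window scan repeats the protocol for odd
`L ∈ [5, 17]` and selects the MCC-optimal size, ties breaking toward the
smaller window (cheaper features, less padding).

Segments whose window overhangs both termini (`L >` chain length) are kept;
padding makes them well-defined, and dropping them would silently remove
short-chain residues from prediction.

## Synthetic data generator

`simulate_dataset` emulates the statistical structure the predictor
exploits: residues within a window of influence (default 7) of a planted
binding position are drawn from
`signal·motif + (1−signal)·background`, the default motif being uniform
over R, G, K, S, H, T — residues preferentially observed near acid-radical
binding sites — and the default background uniform over the 20 residues
(config-overridable with empirical frequencies). SA is drawn from an
exposed-mode Beta(6,2) or buried-mode Beta(2,6), the exposed-mode
probability rising from 0.35 to 0.8 at binding sites; SS has a mild coil
bias at binding sites. All binding-dependent biases scale with
`signal_strength`, so `signal = 0` generates genuinely null data — the
right negative control for the pipeline. Defaults (70 proteins of 100–200
residues, binding rate 0.05) yield roughly 500 positive windows.

The generator does **not** reproduce real marginals: no BioLip-like
composition, no chain-level redundancy, no spatial clustering of sites, no
correlated SS/SA structure along the chain, and the annotation noise of
semi-manual databases is absent. Passing tests therefore demonstrate that
the pipeline recovers a planted local-composition/exposure signal and stays
at chance on null data — not any particular performance level on real
proteins.

`make_worked_example` fixes a tiny 8-protein dataset (seed constant in the
source); golden values of its matrices, conservation vectors, S scores and
ID values — computed with independent literal-formula oracles — are frozen
in `tests/data/worked_example_golden.json`.

## Numerical choices and problem sizes

- Pseudocounts make all `p > 0`; `xlogy` handles `0·log 0` exactly.
- Column sums of `p` are asserted to 1e-12; oracle agreement to 1e-10.
- SMO reference check: 50-point problems against an independent
  precomputed-kernel QP solution, dual objective within 1e-4 relative
  (observed ~1e-13).
- The acceptance script runs the full balanced 10×5 CV at ~500 positives
  (the default study conditions) and a window scan at 25 proteins with 2
  resamples — a deliberately reduced scan, since it is a recovery check of
  the motif span rather than a protocol measurement.
- Derived seeds are kept below 2³¹; identical seeds give bit-identical
  reports.

## Known limitations

- No evolutionary information (PSSMs/profiles), often the strongest signal
  for binding-site prediction.
- Per-ligand models must be trained separately; there is no multi-ion joint
  model or per-ion hyperparameter tuning.
- The SMO solver materializes the full Gram matrix (fine at balanced-CV
  sizes, quadratic memory in general).
- Decision values are uncalibrated margins, not probabilities.
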