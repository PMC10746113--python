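# Methods

## Model

The package treats protein-variant activity prediction as a linear
regression in a frequency-domain feature space. A variant sequence of
length N is digitized under an AAindex1 index a — a lookup table
assigning one real value to each of the 20 standard residues — giving a
signal s(n), n = 0..N−1. The discrete Fourier transform

    S(k) = Σ_{n=0}^{N-1} s(n) · exp(−2πikn/N)

is reduced to the amplitude half-spectrum |S(k)|, k = 0..⌊N/2⌋ (real
signals have conjugate-symmetric spectra, so the upper half is
redundant). An *extended descriptor* concatenates the spectra of one
variant under an ordered set of indices; the descriptor's identity is
the index **set** (a linear model is invariant to permuting feature
blocks, which the test suite verifies down to the LOOCV prediction
vector).

The response is the thermal half-life T1/2 in minutes: the time for
residual enzyme activity to fall to 50% at the assay temperature.
Partial least squares regression (PLSR) maps features to response.
PLSR is the appropriate linear family here because the feature count
(hundreds of amplitude bins, more with each connected index) far
exceeds the sample count (13–21 variants); its latent-variable
projection regularizes where ordinary least squares is underdetermined.

Model quality is scored by leave-one-out cross-validation (LOOCV):
every sample is predicted by a model trained on the others, and the
prediction vector ŷ yields

    cvRMSE = sqrt( Σ_i (y_i − ŷ_i)² / S )        [minutes]
    R²     = corr(y, ŷ)²                          [0..1]

Both are computed on the LOOCV predictions, not the training fit (the
training-fit R² is also recorded on every `ModelFit` for comparison,
since selection tables in this literature do not always say which is
shown). Selection minimizes cvRMSE; ranked reports order by R² where
that is the field's convention (the combination table), and both
metrics always appear together.

## Descriptor search

Scoring every index subset is infeasible (2^553 − 1 subsets for a full
index database — of order 10^166), so two tractable strategies are
implemented:

* **Combination strategy** — screen every usable index alone, keep the
  top K by cvRMSE, and exhaustively LOOCV all Σ_{q≤Q} C(K,q) subsets
  (31 for K = Q = 5). Exact within its restricted pool, but blind to
  indices outside the top K.
* **Iterative connection strategy** — greedy forward selection: round 1
  keeps the single index with lowest cvRMSE; round r+1 evaluates the
  incumbent chain extended by each remaining index and keeps the best
  extension; the pool shrinks by one per round; Q rounds in total.
  Cost is Q·|pool| model fits instead of exponential.

The greedy search always runs its Q rounds, recording a per-round
`improved` flag, because a fixed-length chain is the behavior being
reproduced; an `early_stop` switch instead keeps the incumbent when no
extension lowers cvRMSE, which is the safer variant for new studies
(the suite exercises both). Ties everywhere break by pool (file)
order, making every strategy deterministic for fixed inputs.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `n_components` | `auto` = min(5, n_train−1, p) | PLS latent dimensions. Small-n datasets cap what is usable; `"sweep"` selects 1..8 by inner-LOOCV cvRMSE when reproducing published fits whose component count is unstated; an integer pins it. |
| spectrum `mode` | `half` | ⌊N/2⌋+1 amplitude bins; `full` keeps all N for comparison (adds only redundant bins). |
| `drop_dc` | off | the k=0 term is the sum of index values — pure composition information; kept because there is no principled reason to discard it. |
| `zscore_index` | off | optional z-scoring of an index's 20 values before encoding; raw values are used by default, as amplitude scale differences between indices are absorbed by PLS weights. |
| `top_k` / `max_connections` | 5 / 5 (combine), 3 (iterate) | the study conditions for each strategy. |
| threshold inequality | strict | "predicted above the best measured variant" uses >, configurable to ≥. |

X and y are mean-centered; columns are **not** variance-scaled:
amplitude magnitudes within one spectrum are commensurate and carry
signal. If a training fold's X has zero variance after centering the
fold predicts the training mean. Predictions are never clipped;
negative half-lives (possible under linear extrapolation far from the
training cloud) are reported with a warning so the user sees the
extrapolation rather than a silently sanitized number.

## Mutant libraries

Mutation strings (`F115L`) are 1-based on the user-supplied wild-type
FASTA; the package does not attempt to reconcile any other residue
numbering frame — the FASTA defines it, and every application verifies
the expected wild-type residue at the stated position. The library of
n observed single mutations is the full power set: 2^n variants
including the wild type, enumerated in bitmask order with canonical
labels. Observed and novel variants partition the library (21 observed
of 1024 for the packaged 10-site table, leaving 1003 novel).

## AAindex handling

Only entries with all 20 finite values are usable for encoding;
entries with `NA` holes are parsed, retained, and excluded — no
imputation, since a partially defined property cannot encode a full
sequence without inventing values. Only the numeric `I` record is
consumed; reference and correlation lines are carried as opaque text so
a parsed pool serializes back to the flat-file dialect losslessly
(accessions and values round-trip exactly).

## Synthetic data

The generator fabricates what the real study provides: a complete
index pool (values i.i.d. standard normal per residue, optionally with
NA-holed entries), a random wild type, n distinct single substitutions,
and a variant set of the wild type, all singles, and random
combinations. The response is planted *in the model's own feature
space* — y = Σ_a w_a·features_a + ε, ε ~ N(0, σ²) — then shifted to
positivity (y ← y − min(y) + 5 min; the shift is part of the recorded
ground truth), because real half-lives are positive and the shift
leaves the linear structure untouched.

Defaults mirror the driving study: wild-type length 325 residues,
10 mutated sites, 21 variants, planted signal of sd ≈ 5 min against
noise of sd 1 min (the measured half-lives span ~7–66 min, and a
noise floor around 20% of the signal spread is what cross-validated
R² in the 0.8–0.96 range implies). Recovery *tests* instead use short
sequences (7–13 spectral bins) with more variants than features: with
fewer samples than features any decoy index can interpolate the
response, so planted-signal identifiability — and hence a meaningful
pass/fail — requires the overdetermined regime. That is a property of
the test design, not of the method.

What the generator does **not** emulate: epistasis beyond the additive
spectral form, residue-correlated index structure (real AAindex entries
are mutually correlated; synthetic ones are independent), measurement
error that grows with half-life, and any biophysics linking sequence to
stability. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and self-consistent, not that the
spectral-linear model is true of real proteins.

## Numerical choices and degenerate inputs

* DFT via numpy's FFT; the O(N²) direct sum lives in the tests as the
  independent oracle (agreement ≤ 1e−9).
* PLS via scikit-learn's NIPALS implementation (`scale=False`); with
  full components it reproduces least squares to ≤ 1e−6, which the
  suite checks against the closed-form solution.
* Datasets must hold ≥ 3 variants, equal-length sequences, finite
  positive half-lives; unequal lengths are rejected rather than padded
  (zero-padding would misalign frequency bins between variants).
* Infeasible component requests are clipped in the `auto` policy but
  are hard errors when pinned explicitly, naming the feasible maximum.
* R² is undefined for a zero-variance prediction vector and raises
  rather than returning 0 or NaN.
* Subset enumeration refuses pools larger than 20 indices unless
  explicitly overridden.

## Known limitations

* The published numbers for the transaminase study (best single index
  AURR980108 with cvRMSE ≈ 4.56/R² ≈ 0.81, the 31-combination table,
  the three-index iterative chain at R² ≈ 0.96) can only be reproduced
  with the archived AAindex1 release and the enzyme's wild-type
  sequence, neither of which is redistributable here; the reproduction
  harness in `tests/test_acceptance.py` runs whenever those files are
  dropped at `data/external/`. The PLS component count behind the
  published fits is unstated, so that harness sweeps 1..8.
* One printed claim in the source literature — ~5.4 × 10^165 candidate
  descriptors for a 553-index pool — does not match 2^553 − 1
  (≈ 3 × 10^166); the package uses the exact combinatorial formula.
* Non-standard residues (B, Z, X, U, O) are rejected, not imputed.
* No insertions/deletions; the library grammar is substitution-only.
* No uncertainty quantification beyond the LOOCV residuals.
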