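# Methods

## Problem setting

The package targets the small-data QSAR regime: a few hundred compounds,
each described by ~50 continuous physicochemical/pharmacokinetic
descriptors, with a binary activity label derived from potency
measurements.  The workflow augments the labelled set with a conditional
GAN, trains a gradient-boosted activity classifier under a strict
no-leakage policy, screens an external descriptor library, and
post-processes orbital-energy and binding-energy tables for the
prioritised hits.  Everything operates on descriptor tables; no molecular
structures are involved anywhere.

## Synthetic descriptor fixtures

Real descriptor tables of this kind come from commercial software and
licensed databases, so the package ships a generator that emulates their
statistical shape rather than their chemistry.  Descriptors are drawn from
a latent-factor Gaussian model: with loadings L (p descriptors × r
factors, entries N(0, 1/r)), factors z ~ N(0, I_r) and residual noise
ε ~ N(0, σ²I_p), a row on the latent scale is x = ±½·s + Lz + ε, where the
class-mean offset s is `class_shift` pooled standard deviations
(√(‖L_j‖² + σ²)) on the first `n_shifted` descriptors and zero elsewhere.
Rows are then mapped affinely onto descriptor-like locations and scales,
and designated count-like columns (emulating H-bond donor/acceptor
counts) are rounded and clipped at zero.

Defaults are the study conditions: 138 active / 150 inactive compounds,
50 descriptors, 5 latent factors, residual sd 1.  The class shift defaults
to 1.5 sd; the classifier-recovery settings use 2.0 sd.  These were chosen
once as a realistic degree of separability — a nearest-centroid rule
reaches ~90% accuracy at 1.5 sd, which matches the intuition that
descriptor-space QSAR problems with curated decoys are learnable but not
trivial — and are exposed, not hard-coded.

A screening library is drawn from the same populations: each compound is
active with probability `true_active_fraction`, and a chosen fraction of
compounds receives missing descriptor fields (empty CSV cells), emulating
library compounds for which descriptor computation fails.  The true labels
are returned separately so recovery can be measured.

What the fixtures do *not* emulate: heavy-tailed and bounded descriptor
marginals, discrete multimodality, structure-driven correlation blocks,
and activity cliffs.  Passing tests therefore demonstrate that the
machinery is correct and that signal of a stated magnitude is recovered —
not that any particular real dataset would yield the same metric values.

## Conditional GAN

Architecture (the reference workflow's): generator
(noise 64 + label embedding 8) → Dense 128 → BatchNorm → LeakyReLU(0.2) →
Dense 256 → BatchNorm → LeakyReLU → Dense p → sigmoid; discriminator
(descriptors p + label embedding 8) → Dense 256 → LeakyReLU → Dense 128 →
LeakyReLU → Dense 1 → sigmoid.  Batch normalisation is used in the
generator only.  Both networks receive the class through separate learned
embeddings concatenated to their inputs.

Training: descriptors are min-max normalised (scaler fit inside the model
on the full labelled table, stored with the results for inversion);
alternating updates with binary cross-entropy — the discriminator sees
real rows with smoothed target 0.9 and generated rows with target 0, the
generator maximises log D(G(z)) (non-saturating form); Adam with learning
rate 10⁻⁴, β₁ = 0.5, β₂ = 0.999; 1,000 epochs, batch size 32.  Losses are
averaged per epoch; a non-finite epoch loss aborts with the epoch named.

The implementation is pure NumPy with explicit forward/backward passes
(the backward pass is verified against central finite differences in the
test suite).  All randomness flows from one `numpy.random.Generator`
seeded by the config, so a run is bit-reproducible on a single-threaded
platform; cross-platform bit-exactness is not promised.

Free choices not fixed by the reference settings — noise dimension 64,
embedding dimension 8, batch size 32, LeakyReLU slope 0.2, smoothing
target 0.9 — follow common GAN practice and are all configurable.

Sampling runs the generator in evaluation mode (batch-norm running
statistics), inverse-transforms through the stored min-max scaler (so
every generated value lies strictly inside the training range of each
feature), labels the rows, and assigns ids with a reserved `SYN-` prefix
that the leakage guard recognises downstream.

## Fidelity diagnostics

Because the generator works in descriptor space, validation is
statistical: per-descriptor two-sample KS distances and moment deltas
(pooled and per class), PCA and t-SNE overlays (perplexity 30, 1,000
iterations, seeded; perplexity is auto-reduced with a warning on small
inputs), a cross-validated logistic real-vs-synthetic discriminability
score (0.5 = indistinguishable, floored at the majority-class fraction),
and a collapse ratio — mean pairwise distance among synthetic rows over
the same among real rows, on jointly z-scored features.  Features are
z-scored jointly before any geometry so the diagnostics are scale-free.
The collapse threshold (flag strictly below 0.2) and the discriminability
warning level (0.85) are engineering defaults, labelled as such in the
report output.

## Classifier and leakage policy

Real compounds are split stratified 70/15/15 with a documented rounding
rule (per class: ⌊0.70n⌋ train, ⌊0.15n⌋ validation, remainder test).
Synthetic rows join the training split only; `augment_training` emits a
leakage certificate and raises on any synthetic id in an evaluation
split.  Features are z-scored (sample sd, n−1) with statistics of the
combined real + synthetic training rows — the synthetic rows are
training data, so they legitimately contribute to the scaler.

XGBoost runs a fixed 2,000 rounds with no early stopping (matching the
reference configuration, which inspects convergence on log-loss curves
instead), `hist` trees, single thread, fixed seed.  Evaluation computes
every metric from its defining formula rather than delegating: confusion
matrix at threshold 0.5 (predicted active at p ≥ 0.5), accuracy,
precision, recall, F1, MCC, ROC-AUC by the trapezoidal rule over the full
threshold sweep (tie groups collapsed, which equals pairwise
concordance), average precision by step-wise PR integration, and a
calibration curve over 10 equal-width probability bins.  Degenerate
denominators return 0; a single-class evaluation set reports AUC as
absent with a warning.  Stratified 5-fold cross-validation applies the
same augmentation policy per fold (synthetic rows join only the in-fold
training part).

## Screening

The library must contain the bundle's full feature list; extra columns
are ignored with a warning and compounds with any missing required
descriptor are dropped and logged (no imputation — this mirrors the
attrition narrative of descriptor-generation failure).  Remaining rows
are scaled with the stored training scaler — never refit — scored, and
ranked by descending probability with ties broken lexicographically by
compound id.  The ≥ boundary at the default 0.5 threshold is a
deliberate, documented convention.

## Reactivity and binding post-processing

Koopmans descriptors are closed-form: I = −E_HOMO, A = −E_LUMO,
ΔE = E_LUMO − E_HOMO, η = (I−A)/2, S = 1/η, χ = (I+A)/2, μ = −χ.  Two
electrophilicity conventions circulate: the textbook ω = μ²/(2η) and a
table-style ω = μ²·η/2; published descriptor tables in this area are
internally consistent with the latter while stating the former, so the
package computes and labels both rather than silently choosing.  η = 0
marks softness and the stated electrophilicity undefined (NaN plus a
flag); η < 0 warns about inverted orbitals.  Units pass through
unchanged.  The ranking report orders by gap descending, ties by id.

Binding aggregation implements ΔG_bind = E_complex − (E_ligand +
E_receptor) in kcal/mol — the parenthesised form implied by the verbal
definition of the minimized-energy difference — and ΔΔG against a chosen
reference ligand, sorted ascending with deterministic tie-breaks.  Energy
decomposition columns are pass-through metadata: published component
columns do not generally sum to the printed ΔG, so no reconstruction is
attempted.

## Pipeline and reproducibility

One global seed (default 42) feeds every stage through fixed offsets
(fixture +1, GAN +2, sampling +3, split +4, boosting +5, library +6,
fidelity +7), so stages can be re-run in isolation and the whole run is
deterministic: the manifest records the config echo, stage seeds, row
counts (with the algebra curated = train + validation + test,
train_combined = train_real + synthetic, scored + dropped = library),
the leakage certificate and a SHA-256 checksum per artifact, and two runs
from the same config produce identical checksums.

## Problem sizes

The default demo and the acceptance script run at the study's native
scale: 288 labelled compounds, 50 descriptors, 1,000 GAN epochs, 100
synthetic samples, 2,000 boosting rounds, 5-fold cross-validation, and a
2,648-compound screening library.  Unit tests use smaller fixtures
(tens of rows, tens of epochs/rounds) chosen to exercise the same code
paths quickly; the stochastic invariants (fidelity improvement, signal
recovery) are asserted as 3-seed majorities at full scale in the
acceptance tests.

## Known limitations

- The GAN is CPU/NumPy; it is sized for descriptor tables (hundreds of
  rows, tens of features), not large tabular corpora.
- Fixtures are Gaussian; conclusions about real descriptor data require
  real descriptors.
- Deduplication is by compound id and exact descriptor equality;
  structure-aware deduplication is out of scope (no structures).
- No hyperparameter search, alternative classifiers, Wasserstein/GP GAN
  variants, imputation, or docking/toxicity integrations.
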