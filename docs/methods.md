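# Methods

This note documents the model implemented by `cogmap`, the choices made
where the procedure was genuinely open, and what the tests do and do not
establish.

## Ground-truth successor representation

States are rows of a semantic feature table. Similarity-based transition
probabilities are inverse Euclidean distances of the raw feature vectors:
`w(s,s') = 1/‖m_s − m_s'‖` for s ≠ s', `w(s,s) = 0`, rows normalized to
probabilities. The diagonal is forced to zero because a sampled successor
must be a *different*, similar state; the inverse distance is undefined at
zero distance anyway, and duplicate feature vectors are rejected with an
error naming the colliding states.

The SR is the truncated discounted occupancy sum `M = Σ_{k=0..t} γ^k T^k`
with `T^0 = I`. The truncation (default horizon t = 10) makes γ = 1
well-defined; each row then sums to the geometric partial sum
`(1 − γ^{t+1})/(1 − γ)` (t + 1 at γ = 1), which the tests assert to 1e-9.
Everything downstream — label sampling, RMSE comparison, map building —
uses the row-normalized SR, because the network's softmax rows are
probability vectors and inverse-CDF sampling needs a distribution.

Feature values enter distances **raw** (no scaling). The feature table
mixes scales wildly (grams to tonnes), so raw distances are dominated by
weight and height; this is a deliberate, literal reading of the source
procedure. A `zscore_features` flag (and `--zscore-features` on the CLI)
standardises features first for experimentation; it changes the task (the
ground-truth SR, the Bayes ceiling, and the maps), and our measurements
show it produces strongly class-clustered maps at every γ rather than the
graded multi-scale effect, so it is off by default.

## Training-sample generation

Each of the 50,000 samples: start state uniform over states; input = the
stored memory with every feature independently multiplied by a factor
uniform in [0.85, 1.15] (multiplicative, hence scale-free across feature
magnitudes; applied to all features including the categorical codes);
label = inverse-CDF draw from the normalized SR row of the start state.
The last 10% of the generated stream is the validation split — samples are
i.i.d., so this equals a random split. A single master seed fans out via
`numpy.random.SeedSequence` into independent sampler and
weight-initialisation streams.

## Network and training

Architecture: inputs = features (7), one hidden layer of the same width
with ReLU, softmax output over states (32). Training: 500 epochs, batch
size 50, Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7), categorical
cross-entropy, Glorot-uniform initial weights, per-epoch reshuffling. The
loop is a numba-compiled kernel in double precision (no fastmath), bit-for-
bit reproducible for a fixed seed and verified against a pure-NumPy
reference implementation to 1e-14.

The learned SR is the stack of softmax rows for the unperturbed memories.
Accuracy is top-1 against the *sampled* label, so its ceiling is the mean
per-row maximum of the normalized SR (≈ 0.71 / 0.34 / 0.22 for
γ = 0.3 / 0.7 / 1.0 on the animal space) — far below 1 by design.

### Fidelity limits of the 7-unit hidden layer

Distilling the exact normalized SR into this architecture directly
(full-batch Adam on soft targets, no sampling noise — an upper bound on
anything sample-based training can reach) floors the RMSE at about
0.058 / 0.036 / 0.013 for γ = 0.3 / 0.7 / 1.0 with raw inputs, and only
slightly lower with standardized or log-scaled inputs. Published values
for this protocol are lower still (≈ 0.020 / 0.015 / 0.009); our
measurements cannot reach them under any input conditioning we tried, so
the acceptance checks that compare RMSE levels fail honestly while the
qualitative structure (RMSE ordering across γ, accuracy ceilings, GDV
monotonicity) reproduces. The same capacity limit depresses the γ = 0.7
converged validation accuracy to ≈ 0.16–0.28 across seeds (ceiling 0.34).

## Interpolation

Unknown entries hold the sentinel −1 and the partial vector is fed to the
network unmodified — no imputation, no clamping of known entries
afterwards; the reconstruction `pᵀ M(m)` is reported in full. It is a
convex combination of memory rows, so every reconstructed feature lies
within that feature's observed range (asserted as a property test).

The dissimilarity evaluation masks k ∈ {0..6} positions uniformly at
random without replacement (10 masks per test state per model, seeded),
and reports the mean absolute error per feature as a percentage of that
feature's max − min over the training memory — the only normalizer
computable from stated inputs. Note its consequence: a binary feature has
range 1, so blending across classes costs tens of percent there, while
height/weight ranges (500 / 6000) forgive large absolute errors. Our
profiles therefore show binary features *worst* at many masks, the
opposite of the published qualitative claim, which appears to presuppose a
different (unstated) normalizer.

## MDS and GDV

Classical (Torgerson) metric MDS: eigendecomposition of the doubly
centered squared-distance matrix of SR rows; axes ordered by eigenvalue,
negative eigenvalues clipped, per-axis sign fixed so the largest-magnitude
coordinate is positive (output otherwise defined up to rotation/
reflection). Cross-checked against an independent principal-coordinates
implementation in the tests.

GDV: z-score each dimension over all points, drop zero-variance dimensions
with a warning, scale by ½, then (mean intra-class pairwise distance −
mean inter-class pairwise distance)/√d. Two far-separated point masses
give exactly −1; identically distributed classes give 0. The GDV is
computed on the 2-D projection by default (matching how the published maps
are annotated); `compute_gdv` accepts full SR rows too. Mammals are one
class even where the published figure renders them in two colours.

## Synthetic-space generator

`generate_random_space` draws class centroids as isotropic Gaussians
scaled by `class_separation` and scatters states with unit within-class
noise, assigning classes round-robin. It emulates the one structural
property the animal table needs for these methods — classes of states
closer to each other than to other classes — and nothing else: features
are homoscedastic and Gaussian, with none of the heavy-tailed scale
disparity or categorical coding of the real table. Tests passing on
generated spaces therefore establish the math (row-stochasticity, CDF
sampling, oracle equivalence), not robustness to real-data pathologies.

## Problem sizes and numerics

Unit and property tests run on toy spaces (2–12 states) in seconds; the
acceptance tests and `scripts/acceptance.py` run the full protocol
(50,000 samples, 500 epochs) — three discounts × three seeds in the test
suite, three discounts plus ten interpolation models in the script —
chosen to match the study's stated sizes exactly. One full training run
takes ≈ 25–30 s on one CPU. Tolerances: matrix identities at 1e-9,
softmax normalization at 1e-6, stochastic assertions at 3–4σ binomial
bounds or χ² at α = 0.01. Single-feature toy networks in tests widen the
hidden layer (4 units) because a 1-unit ReLU layer can die at
initialisation; the study architecture ties hidden width to feature count
(7), where this is not a practical risk.

## Known limitations

- The 7-unit hidden layer cannot represent the sharp diagonal of
  small-γ normalized SRs; quantitative RMSE/accuracy levels sit above
  the published ones (see the distillation-floor analysis above).
- Raw-distance transitions are dominated by body size; small mammals,
  amphibians and large insects intermingle at fine scales.
- The percent-of-range dissimilarity metric penalises binary features
  disproportionately.
- No reward learning or TD updating: ground truth is closed-form.
- Fixture class labels follow the source's three taxonomic classes; the
  held-out table contains only mammals and insects.
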