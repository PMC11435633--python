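# Methods

## Signal model of the synthetic sessions

Each session emulates one participant of a music-stimulus protocol: ten
one-minute pieces (five positive, five negative valence, in the played order
negative, positive, negative, positive, positive, negative, negative,
positive, negative, positive), each followed by a 10-second silence, sampled
at 500 Hz on C3, C4 and Pz. Every labelled interval is synthesized
independently as

    x_c(t) = A · Σ_b w_b,c · (1/√m) Σ_{i=1..m} sin(2π f_i t + φ_i) + ε(t)

with bands b ∈ {theta 4–7, alpha 8–13, beta2 18–22, beta3 22–30,
gamma 30–45 Hz}, m = 8 random frequencies per band, uniform random phases,
baseline amplitude A = 10 µV and white Gaussian noise ε with σ = 2 µV. The
1/√m normalization makes expected band power independent of m, so the
configured weights w_b,c control relative band power directly.

Default class weights encode the reported physiology of music-evoked
emotion: positive valence has left-dominant alpha (C3 1.2 vs C4 0.5) and
suppressed beta-2/beta-3/gamma; negative valence mirrors the alpha asymmetry
and elevates the high bands (beta2 0.8, beta3 0.7, gamma 0.5); neutral rest
is theta-dominant with symmetric alpha. These defaults are fixed study
conditions, not tuning knobs.

What the generator does *not* model: ocular/muscular artifacts, electrode
impedance drift, 1/f background, inter-subject anatomical variability, or
non-stationarity within an interval. Passing tests therefore demonstrate
that the pipeline recovers class-dependent spectral structure through the
full preprocessing/graph/classifier chain — not that it would reach the same
accuracy on real recordings.

Seeding: every (participant, interval) pair gets its own `SeedSequence`
stream derived from the base seed, so sessions are bit-reproducible and
stable under reordering.

## Preprocessing

Only the central 20 s of each 60-s song is kept (offset = ⌊(L − keep)/2⌋,
half-open sample intervals), avoiding bleed into adjacent silences. Stacking
concatenates same-class segments per participant: 5 × 10,000 = 50,000
valence samples; the neutral class keeps the five silences following the
first five songs in full (5 × 5,000 = 25,000). With GAN augmentation the
per-class stack is topped up and truncated to exactly 125,000 samples — the
binding constraint is 1000 windows of 125 samples downstream; windowing is
non-overlapping (stride = size = 125). Splits are assigned per
(participant, class) stratum: validation and test take round(0.2·n) and
round(0.1·n) windows of a seeded permutation, the remainder trains. At full
scale (20 participants) that yields 42,000/12,000/6,000 of 60,000 sets.

## Augmentation GAN

Generator: latent normal vector (dim 64) → dense projection to 16 × 125 →
six stride-1 1-D convolutions (Leaky-ReLU 0.2 between, linear output) →
3 × 125 segment. Discriminator: two stride-2 convolutions → dense →
sigmoid. Adamax, lr 10⁻³, batch 8. Training alternates one discriminator
ascent step on the two-term minimax value
V(G,D) = E[log D(x)] + E[log(1 − D(G(z)))] (probabilities clamped at 10⁻⁷)
with one non-saturating generator step (maximize log D(G(z))); V is what the
history records. Kernels are 31 samples wide: the receptive field must span
at least one alpha period (~50 samples at 500 Hz) or the discriminator
cannot sense band structure and the adversarial dynamics oscillate without
converging spectrally — with kernel 31, generated segments match the real
segments' dominant-band Welch power within a factor of ~1.2 after 30 epochs
on a 200-window class.

Augmentation is restricted to training-split windows of one class; feeding
any validation/test window raises a hard error, because generated samples
join the training set and would otherwise leak evaluation data.

## Graph construction and spectral filtering

Edges are absolute Pearson correlations between channel time series
(diagonal zero, constant channels zeroed with a warning), thresholded at
τ = 0.3 by default (τ is recorded in the serialized graph; the value is a
package choice, swept in tests). The graph is built from pooled training
data only and then frozen. The Laplacian is the unnormalized L = D − W
(a symmetric-normalized variant sits behind a flag); its symmetric
eigendecomposition L = U Λ Uᵀ defines the graph Fourier transform
q̂ = Uᵀq and exact spectral filtering y = U g(Λ) Uᵀ x. Eigenvalues are
sorted ascending and each eigenvector's sign is fixed by making its
largest-magnitude entry positive, so serialization round-trips are
deterministic.

Trainable layers use the Chebyshev form y = Σ_{k<K} θ_k T_k(L̃) x with
L̃ = 2L/λ_max − I and the T_k recurrence — no eigendecomposition at train
time, cost O(K·nnz(L)·F). For an isolated (edgeless) graph λ_max is
defined as 2. The equivalence of the polynomial and exact spectral paths
for degree-<K responses is the module's core test (500 random graphs,
max |Δ| < 10⁻⁸; measured ~10⁻¹⁴).

## Classifier

Input windows are [3 nodes × 125 features]. The network is dropout (0.3,
input only) → 4 × [Chebyshev graph conv (K = 3) → max-pool (size 2, feature
axis, floor) → Leaky-ReLU (slope 0.01)] → flatten → dense → softmax. Feature
widths run 125 → 62 → 31 → 15 → 7, so the flattened representation has 21
values and the default 3-class model 62,264 parameters. A 3-node graph
admits no meaningful graph coarsening, hence pooling acts on the feature
axis. Weights are Glorot-uniform, seeded; with dropout off the forward pass
is bit-reproducible. Training: Adam, lr 10⁻³, weight decay 6·10⁻⁶, batch 16,
cross-entropy (MSE available), with the best-validation-accuracy weights
retained.

## Evaluation

All indices derive from the confusion matrix (rows = truth): accuracy;
sensitivity, precision and specificity macro-averaged one-vs-rest (classes
absent from the truth are excluded with a warning); Cohen's
κ = (p_o − p_e)/(1 − p_e) with p_e from the marginals; ROC per class by
threshold sweep. 5-fold CV stratifies folds by (participant, class) over the
train+val pool and never touches the test split. Leave-one-subject-out holds
each participant's windows out entirely (graph included) and audits the
exclusion. Noise robustness adds white Gaussian noise at exact per-window
SNR. Baselines: KNN/SVM/MLP (scikit-learn) on 18 handcrafted statistics
(per channel: mean, variance, skewness, kurtosis, crest factor max|x|/RMS,
mean power) or on raw flattened windows, plus a four-layer plain 1-D CNN
without graph mixing.

## Problem sizes and numerical choices

Tests and the acceptance script run a scaled-down cohort chosen to exercise
every stage while remaining separable: 2 participants, 100 windows per
participant per class (12,500-sample class target), 30 training epochs —
test accuracy ≥ 0.97 across seeds. Cross-subject (leave-one-subject-out)
transfer needs more evidence per subject; that test uses 200 windows per
participant per class and 40 epochs. The 5-fold CV test trains 60 epochs per
fold because individual folds lack a validation-checkpoint fallback.
Degenerate inputs: zero-variance channels give zero correlation and zero
skewness/kurtosis by convention; windows shorter than the window size yield
empty sets; split remainders after rounding go to train.

## Known limitations

- The synthetic generator's stationary sinusoid-plus-noise model is far
  cleaner than real EEG; absolute accuracies here do not transfer.
- The GAN matches second-order spectral statistics; it is not evaluated for
  higher-order realism (no FID-like score).
- With three nodes the graph machinery is exercised but not stressed; the
  spectral-filtering tests therefore sweep random graphs up to 8 nodes.
- Parameter-count bookkeeping follows the implemented shapes; no attempt is
  made to reproduce external parameter tables whose dimensions do not
  type-check against a 3-node, 125-feature layout.
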