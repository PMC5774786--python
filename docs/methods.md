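# Methods

This note documents the model implemented by `eegpdm`, the parameter
choices that matter, what the synthetic-cohort generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Signal conditioning

Each channel of each epoch is conditioned as: second-order low-pass IIR
Butterworth at 40 Hz → demean/detrend (least-squares line removal) →
iterative two-sided Grubbs outlier test with interpolation repair.

* Filtering is causal (forward-only) by default; `zero_phase=True` selects
  forward–backward filtering. Causal filtering is the conservative reading
  of a clinical pipeline; zero-phase avoids group delay when phase matters.
* The Grubbs test runs per epoch at α = 0.05 per iteration. A flagged
  sample *leaves the sample* for subsequent iterations (the statistic is
  recomputed on the remaining data, with the critical value at the reduced
  n); all flagged samples are then replaced by linear interpolation of the
  nearest retained neighbours, because deletion would break the uniform
  sampling grid required by the convolution stages. The flag list is
  returned for audit. An earlier variant that reinstated repaired samples
  into the test loops forever on smooth extrema; the leave-out form is
  standard and guaranteed to terminate.
* Filtering and demeaning commute only up to start-up-transient leakage
  (~1e-4 relative for zero-phase, larger for causal on short series); this
  is inherent to finite-length filtering, not an implementation artefact.

## Laguerre–Volterra estimation

Kernels are expanded on `L` discrete Laguerre functions with decay
parameter `α ∈ (0, 1)`; the closed form is cross-checked against the
two-term recurrence to 1e-10 in the tests. Estimation is ordinary least
squares on the design matrix `[1 | V_F | V_T | V_FF | V_TT | V_TF]`,
solved by orthogonal decomposition (LAPACK `gelsd`); a config flag enables
the literal normal-equation path for comparison. Second-order blocks hold
the `L(L+1)/2` unique Hadamard products with triangular index
`(j1, j2 ≤ j1)`, serialized explicitly so models are portable.

Numerical choices:

* **Memory `M` = 64 samples** (250 ms at 256 Hz), configurable. The
  Laguerre decay bounds the effective memory; note that for `α = 0.7` the
  slowest function only falls below 1% of its peak near lag 100, so the
  64-lag basis is *not* orthonormal over its own window (Gram error ~4e-2;
  <1e-6 requires M ≳ 130). Orthonormality of the infinite-horizon family
  is verified in the tests at M = 160. Estimation does not require window
  orthonormality — least squares is basis-agnostic — so the shorter,
  faster default is kept.
* **Self kernels** are symmetrized exactly (off-diagonal triangular
  coefficients split evenly; the reconstructed matrix is averaged with its
  transpose to remove matmul rounding asymmetry). The **cross kernel** is
  reconstructed in the single orientation implied by the design-matrix
  columns `(b_{j1}*F)⊙(b_{j2}*T)` and is *not* symmetrized: T and F are
  distinct inputs, and only this orientation keeps the kernel-domain
  forward sum exactly equal to `Vβ` (a tested invariant).
* **Row convention:** the first sample of each epoch is dropped from the
  regression (`N = T − 1` rows); convolutions use zero-padded pre-history.
* **Conditioning:** with band-limited inputs the design matrix is well
  conditioned at the default sizes; a rank-deficient design falls back to
  the minimum-norm solution with a warning.

## Global PDM extraction

Per input, each epoch contributes a `(1 + M) × M` block to `Q`: its
first-order kernel as one row, then its second-order self kernel scaled by
the epoch's (preprocessed) input standard deviation, so first- and
second-order rows are commensurate. Interictal blocks are stacked before
ictal ones (the SVD is invariant to row order; the layout is kept for
audit). The PDMs are the `H` leading right singular vectors — the only
orientation in which a PDM has length `M` and convolves with the input —
with each column's sign fixed so its largest-magnitude element is
positive, making extraction deterministic. Cross kernels are excluded from
`Q`. `H` defaults to 5 per the BIC optimum; an energy rule (singular
values capturing ≥95% of the Frobenius norm) is available. Separate `Q`
and separate SVD per input.

## ANFs, cross-terms, gains

ANF fitting is per subject-state epoch on the *fixed* global basis (bases
are never refit on test data; `run_apply` enforces this structurally).
One joint regression of the output on `{u_i^p : p ≤ order}` for all `2H`
branches, the selected cross products, and an intercept. PDM outputs are
not variance-normalized: scale lives in the ANF coefficients, consistent
with the gain-coefficient biomarker. Cross-term screening operationalizes
the w-statistic as Pearson correlation of each candidate product with the
output against a circular-shift surrogate null (200 surrogates, level
0.99); shifts preserve the product's autocorrelation. Each selected cross
term receives an estimated scalar coefficient in the joint regression.

Calibration caveat: on outputs *independent* of the inputs the screen's
false-selection rate is ~1–2% as designed, but on no-interaction cohorts
whose output depends on the branch outputs through the ANFs, the rate
rises to ~8% — the output and the products are then dependent even at zero
correlation, and shift surrogates do not null higher-order dependence.
Selected sets remain small; treat retained cross terms on real data as
candidates, not certainties.

The linear gain of a branch is the least-squares slope of its fitted ANF
evaluated at the subject's observed PDM-output samples — i.e. the gain is
weighted by the branch's actual operating range, so for a cubic ANF it
equals `a1 + a3·m4/m2 + …` in the sample moments. Group contrasts use a
paired t-test on within-subject ictal−interictal differences by default
(the unpaired Welch form is available; "paired with Welch correction" is
internally contradictory, and the within-subject design makes pairing the
natural default — the mode is recorded in every report). Normality checks
use Shapiro–Wilk. The classifier is a Fisher linear discriminant with the
threshold at the midpoint of the projected class means — the canonical
parameter-free linear discriminator — cross-checked against
scikit-learn's LDA in the tests. `feature_pair_search` reproduces the
exhaustive two-feature search; the default pair is (input 2, branch 2) ×
(input 2, branch 4).

## BIC model selection

`model_selection` grids over `(α, L, H, order)`, runs the full
kernel → PDM → ANF chain per tuple on every training epoch, and scores
`BIC = N ln(RSS/N) + p ln(N)` averaged over epochs, with `p` the
ANF-stage parameter count (`2H·order + 1`); ties break toward fewer
parameters. Counting only ANF-stage parameters reflects that the grid
compares ANF configurations on equal kernel-estimation footing; the
kernel stage's count is common within each `(α, L)` slice. Cross-term
screening is skipped inside the grid so the search is a pure
`(α, L, H, order)` comparison. Infeasible tuples (H above the achievable
rank, or too many parameters for the epoch length) are skipped with a
note.

## The synthetic-cohort generator

The generator produces epoch triplets from a known forward model so that
every downstream stage has a recoverable ground truth:

* **Inputs:** zero-mean, unit-sd Gaussian noise, *exactly* band-limited
  below 40 Hz by an rFFT mask. A spectral mask rather than the
  preprocessing Butterworth is used because a second-order IIR leaves
  ~20% of white-noise power above its cutoff, violating the band-limited
  premise the analysis assumes; the mask gives ≥99% (in fact 100%) of
  power in-band while keeping Gaussianity.
* **PDMs:** two constructors. `make_ground_truth` builds Hann-windowed
  cosines at band centers 22, 14, 8, 5, 1 Hz — the qualitative
  beta/alpha/theta/delta structure of cohort EEG PDMs — for
  spectrum-facing tests. `make_ground_truth_laguerre` draws exactly
  orthonormal PDMs *inside* the `L = 6` Laguerre span for recovery
  experiments: a Laguerre–Volterra estimator can only represent dynamics
  in its basis span, and the 22/14 Hz windowed cosines project onto the
  `α = 0.7, L = 6, M = 64` span with norms of only 0.03/0.23. This is a
  fundamental bandwidth limitation of the default basis (its slowest
  resolvable oscillations sit near the theta/alpha range), so recovery
  claims are only meaningful for in-span systems.
* **ANF coefficients:** deterministic baseline with magnitudes decreasing
  geometrically in the branch index (ratio 0.8 for `a1`, 0.73 for `a2`)
  and mixed signs on input 2 — mirroring cohort observations that gain
  magnitude is highest for the first PDM and lowest for the last, with
  both positive and negative trends. The decreasing `a2` profile also
  separates the singular values of `Q`, making branch identity
  recoverable by the SVD. Cubic coefficients are small (`0.12×` the
  linear magnitude); recovery experiments that require the generative
  model to sit inside the second-order Volterra class set `anf_order=2`.
* **Cohorts:** one interictal and one ictal epoch per subject (default 10
  subjects). Each subject receives multiplicative Gaussian jitter
  (sd 10%) on all ANF coefficients, identical across the two states; the
  ictal state then multiplies the coefficients of the designated branches
  (default branches 2 and 4 of input 2) by `gain_shift` (default −1, a
  sign flip). The two states therefore differ *only* in the designated
  branches — a testable invariant. `gain_shift = 1` gives a null cohort.
* **Noise:** additive Gaussian on the output. No clinical SNR is known,
  so `noise_sd` is free (default 0.1 a.u.); `calibrate_noise_sd` converts
  a target SNR in dB into a noise sd against the measured deterministic
  output. Experiments use 20 dB unless stated.
* **Epochs:** default 69 s at 256 Hz (17,664 samples), matching clinical
  epoch lengths; the test suite and acceptance script shorten epochs to
  6–8 s, which keeps every least-squares problem comfortably
  overdetermined (≥ 1500 rows versus 76 kernel and 31 ANF parameters)
  while the whole suite runs in well under a minute.

What the generator does **not** emulate: real EEG artefacts (ocular,
muscle, electrode pops) beyond additive Gaussian noise; non-stationarity
within an epoch; volume-conduction correlation between the two inputs
(inputs are independent); any neural-mass seizure dynamics. Passing the
synthetic experiments therefore demonstrates that the estimation chain
recovers what it models — not that clinical recordings satisfy the model.

## Experiment design notes

* Recovery experiments run the pipeline with `preprocess=False`: the
  simulator's output is already zero-mean and band-limited, and a causal
  filter applied to input and output separately does not commute with the
  nonlinear generative system, which would contaminate exact-recovery
  oracles with distortion unrelated to the estimator.
* The PDM subspace-recovery experiment uses zero noise and `anf_order=2`
  (within-class): recovery is then exact to machine precision. With cubic
  ANFs the third-order Hermite component of `u³` is uncorrelated with all
  regressors only in expectation, leaving finite-sample kernel
  perturbations of a few degrees at desk-scale epoch lengths.
* The held-out worked confusion example (188 ictal epochs, 8 false
  negatives → 95.7% sensitivity; 10 false positives with the interictal
  count implied by the printed 95.2% specificity) is arithmetic on
  published counts, reported by `scripts/acceptance.py` alongside the
  simulated-cohort results.

## Known limitations

* The default Laguerre basis cannot represent beta-band (≥ 20 Hz) kernel
  dynamics at 256 Hz; analyses targeting fast rhythms need smaller `α`,
  larger `L`, or a shorter `M` with higher `α` trade-offs, and should
  re-run the BIC grid.
* Gains from a 2-D feature pair assume the discriminating information is
  in exactly two branches; `feature_pair_search` explores alternatives but
  no multivariate (>2 feature) classifier is provided.
* The w-statistic screen is anticonservative when the output depends
  nonlinearly on the branch outputs (see above).
* Specificity on clinical data is not reproducible from published counts
  alone (the interictal test-epoch denominator is implied, not printed).
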