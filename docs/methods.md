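# Methods

## Model

`perturbcf` predicts the outcome of applying interventions
$t = (t_1,\dots,t_K)$ to an unperturbed profile $x$ as
$\hat{y} = d(\sum_k t_k f_k(e(x)))$: a shared encoder $e$, one branch
$f_k$ per perturbation, linear aggregation of active branches in an
$d$-dimensional latent space, and a shared decoder. The central
modelling assumptions are (i) perturbation effects compose *additively
in latent space*, with all nonlinearity of their combination delegated
to the decoder, and (ii) a branch can be learned from any experiment
in which its perturbation took part — singles or combinations — so the
model extrapolates to combinations never measured.

The empty treatment ($t = 0$) is defined by the empty-sum convention
$z = 0$, so `decode(0)` is the model's control-state prediction. This
is only meaningful if untreated triplets are part of training, which
the simulator therefore emits by default; a dedicated control
pseudo-branch is not used.

Observed treatment entries are 0/1; fractional entries arise only from
proxy vectors (below). Weights enter the aggregation linearly, which
gives two exactly testable identities: aggregation is permutation-
invariant and linear in the weight vector, and skipping zero-weight
branches is bitwise-identical to evaluating them (a branch is skipped
when no sample in the batch activates it; inactive samples of an
evaluated branch are annihilated by their exact-zero weights).

### Heads and losses

* **scalar** head: one output, mean-squared-error loss. Used for
  drug-synergy screens where the outcome is a precomputed score.
* **gaussian** head: $2p$ outputs — per-gene mean and log-variance —
  trained with the heteroscedastic Gaussian negative log-likelihood
  $\sum_{i,j} \tfrac12 (\log \sigma^2_{ij} + (\mu_{ij}-y_{ij})^2 / \sigma^2_{ij})$.
  The per-gene variance lets the fit down-weight noisy genes. The
  floor $\sigma^2 \ge \varepsilon = 10^{-6}$ is applied as a clamp of
  the log-variance pre-activation at $\log \varepsilon$ (gradient zero
  where it binds), which avoids exp/log round trips in the loss. The
  written objective is a sum over cells and genes; training uses the
  mean reduction for learning-rate stability, and the sum is available
  in `gaussian_nll(..., reduction="sum")` for exact-value checks.

### Dosage conditioning

Dose conditions the *first layer of the treated branch only* — the
encoder and decoder never see it. The default transform is
$\log_{10}$(dose) min-max standardized to $[0,1]$ over the training
doses, a numeric encoding that supports interpolation to unseen
concentrations; a one-hot categorical option exists for screens where
dose levels are genuinely discrete. The "no dose recorded" sentinel
maps to feature 0.0, which coincides with the smallest training dose —
the declared reference value — so undosed screens degrade to the pure
multi-hot case.

### Architecture and training defaults

ELU activations; encoder $p \to 64 \to 16$, single-layer branches
$16 (+\text{dose}) \to 16$, decoder $16 \to 64 \to$ head. Fan-in
scaled random initialization under the model seed. Adam
(lr $10^{-3}$), batch size 128, up to 300 epochs with early stopping
(patience 30) on a validation split carved from the *training* fold
(fraction 0.1) — never from test data. All randomness (init,
validation split, shuffling, dropout masks) flows from explicit seeds;
two runs with the same inputs produce bitwise-identical parameters.
The network is dense numpy with hand-derived reverse-mode gradients,
verified against central finite differences at $10^{-4}$ relative
tolerance in the test suite.

## Gene-set proxies for unseen perturbations

An unseen gene knockout $j'$ has no trained branch. Its proxy
treatment vector sets $t^{(j)} \propto J_{j,j'}$, the Jaccard overlap
of pathway-membership sets, L1-normalized over the observed
perturbations (the normalization makes the weights sum to 1, matching
the natural reading of "determined by normalization" and keeping the
proxy on the scale of one intervention). Proxies are computed against
observed *single* perturbations only; combinations never serve as
anchors. When a combination includes both observed and unseen members,
proxy vectors are added to the observed multi-hot row without
renormalization, so a pair contributes total mass 2 whether or not its
members were observed. A target with zero similarity to every observed
perturbation yields an all-zero, `degenerate`-flagged proxy — the
model then returns its control-state prediction rather than failing.
The similarity is pluggable (any gene-pair function); Jaccard over GMT
annotations is the default.

## Baselines

* **linear baseline** — the mean of the observed single-perturbation
  mean outcome profiles of a combination: the prediction of a purely
  additive-in-outcome world, requiring no model at all.
* **linear branch average** — ablation of a *trained* model: branches
  are decoded one at a time and combined in outcome space, removing
  the decoder's nonlinear effect combination. Two combination rules
  are provided. `mode="additive"` (default) is the exact
  linearization $y_0 + \sum_k (y_k - y_0)$ with $y_0 =$ `decode(0)`;
  for an affine decoder it reproduces the full forward pass exactly,
  which makes it the clean test of whether decoder nonlinearity
  matters. `mode="mean"` is the plain average of single-branch
  predictions; it halves a two-branch effect by construction and is
  kept as the conventional form of this ablation.
* **random baseline** — the control centroid (default) or a
  seed-drawn training profile; its reconstruction error is the
  denominator of normalized MSE.

## Evaluation

Metrics are computed on mean post-perturbation profiles per condition:
R² ($1 - SS_{res}/SS_{tot}$ over the gene scope), Pearson and Spearman
correlations, MSE, and normalized MSE (MSE divided by the random
baseline's MSE, per condition). Top-$k$ DEGs are ranked by absolute
difference of the true condition mean versus the control mean, ties
broken by input order ($k = 50$ or 20 in the standard protocols).
"Effect" correlations subtract the control mean from both sides first,
so reproducing the control background earns nothing. Correlations of
an all-constant vector are undefined and reported as missing — except
in the proxy benchmark's baseline comparison, where the control
centroid's identically-zero effect is scored PCC 0, the natural score
for "predicts no effect".

Cross-validation schemes: `random_triplet` (plain k-fold),
`leave_combination_out` (distinct combinations partitioned across
folds; singles always remain in training since they anchor branches),
and `leave_perturbation_out` with `0of1` / `1of2` / `0of2` seen modes
(held-out perturbations appear in no training row). Every generated
split is re-validated post hoc by an independent leak scan.

## Synthetic screens

The simulator generates the study conditions the benchmarks run on.
Each cell has a latent state $u \sim N(0, \sigma_u^2 I)$,
$\sigma_u = 0.2$, in $L = 10$ dimensions. Perturbation $k$ shifts the
latent state by $\delta_k$ (norm scaled so the induced per-gene shift
is of order `effect_scale` = 1 on the log-expression scale); a pair
adds $\gamma_{kl} (\delta_k \odot \delta_l)/\sqrt{L}$ with
$\gamma = 1$ by default — a Hadamard interaction chosen because it is
invisible to any additive model. Latent states map to expression
through a fixed Gaussian loading matrix and an elementwise softplus
(smooth, positive, so even additive latent effects combine
non-additively in expression space), plus gene-wise Gaussian noise
(sd drawn uniformly in $0.3 \times [0.5, 1.5]$ per gene, exercising
the heteroscedastic head). Dosed screens scale $\delta_k$ by a Hill
curve $d^s/(d^s + \mathrm{EC}_{50}^s)$, slope 1.5, EC50 at the
geometric mid-range of the seven log-spaced dose levels. Pathway
blocks make same-block $\delta_k$ directions correlated (shared block
direction plus individual deviation, `block_within_sd` = 0.4) and the
generated GMT gives same-block gene pairs Jaccard 0.6 and cross-block
pairs 0 — effect similarity and annotation similarity are correlated
by construction, which is precisely the assumption the proxy scheme
relies on.

Because perturbation measurements are destructive, each perturbed
cell's control is generated from the *same* latent state with
independent noise: counterfactual pairing is exact by construction.
For real screens, where this is impossible, `pair_controls` offers
random-control (seeded) and mean-control pairing. An untreated
condition is included by default (see above).

What the simulator does **not** emulate: count noise (no
dropout/negative-binomial model — the generator targets the log-scale
Gaussian regime the loss assumes), batch effects, cell-cycle or
cell-type heterogeneity beyond the isotropic latent term, and
annotation noise (the GMT matches the effect structure perfectly).
Passing benchmarks therefore demonstrate that the architecture,
losses, proxies and protocols work as specified — not that the model
handles the full messiness of real single-cell data.

### Benchmark protocols and problem sizes

* **Interaction recovery** — 200 genes, 8 perturbations, 12 pair
  conditions (10 in training, 2 held out), $\gamma = 1$, 200
  cells/condition; R² on top-50 DEGs of held-out pairs, model vs.
  linear baseline, median over 3 seeds.
* **Additive null** — same design with $\gamma = 0$; the gap between
  the full model and the additive branch-average ablation isolates
  whether the decoder invents interactions that are not there.
* **Dose interpolation** — 4 perturbations × 7 log-spaced doses, 100
  cells/condition, second-highest dose held out.
* **Proxy recovery** — two pathway blocks of four perturbations,
  singles only, 100 cells/condition; one perturbation fully held out
  (0-of-1-seen), predicted through its proxy vector, scored by
  effect-scale PCC against the control-centroid baseline.
* **Reproducibility** — a reduced pipeline (40 genes, 4
  perturbations, 20 cells/condition, 30 epochs) run twice under one
  seed must produce identical reports, to the last bit of the
  parameter checksum.

These sizes keep one protocol in the tens of seconds on a single CPU
while leaving effects far above the sampling noise
(SE $\approx$ noise/√200 per gene), so the pass/fail margins reflect
method behaviour, not statistical flukes.

## Numerical choices and edge cases

* float64 throughout; no threading nondeterminism beyond BLAS
  summation order (batched and single-sample forward passes agree to
  ~1e-15 relative, and are asserted at 1e-12).
* Gene filtering drops a gene only when its expression *never*
  reaches `min_expr` **and** its variance is below `min_var` (defaults
  1.0 and 0.8 on log scale); either rule alone keeps the gene. The
  filter and the most-variable-gene selection are order-independent
  and preserve input gene order; variance ties keep the
  earlier-indexed gene.
* Identifier matching is exact and case-sensitive; misaligned files
  raise an alignment error naming the offenders.
* Training aborts with a diagnostic on non-finite losses rather than
  silently continuing.

## Known limitations

* Branches are fully independent; no parameter sharing across related
  perturbations (the proxy scheme shares information only at
  inference time).
* The dose feature extrapolates linearly in log-dose outside the
  training range; predictions beyond the tested concentration range
  are unvalidated.
* The decoder sees no dose directly; dose effects must flow through
  the branch representation.
* Scalar and profile heads are separate models; there is no joint
  multi-task training.
* The simulator's Gaussian, log-scale regime means benchmark numbers
  should not be read as expected performance on raw count data.
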