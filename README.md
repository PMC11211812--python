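# perturbcf

Counterfactual prediction of perturbation responses in high-throughput
screens (HTS).

## The problem

A perturbation screen records, for many experiments, a triplet: an
unperturbed molecular profile (a bulk cell line or a single cell), the
intervention applied (one or several drugs or gene knockouts, possibly
with dosages), and the downstream outcome — a scalar readout such as a
drug-synergy score, or the full perturbed transcriptome. The
combinatorial space of interventions is far too large to measure, so
the scientific question is counterfactual: *what would this sample have
done under an intervention we did not test?* `perturbcf` is for
computational biologists who want to train such a predictor on screen
data (bulk drug-combination panels, Sci-Plex-style dosed single-cell
screens, Perturb-seq-style combinatorial CRISPRi) and use it to rank
untested combinations, doses, and even perturbations absent from the
training data.

## The model

For an unperturbed profile $x_i \in \mathbb{R}^p$, a multi-hot
treatment vector $t_i = (t_{i1},\dots,t_{iK})$, and optional dosages
$d_i$, the prediction is

$$\hat{y}_i = d\Big(\sum_{k=1}^{K} t_i^{(k)}\, f_k(e(x_i))\Big)$$

with a shared encoder $e: \mathbb{R}^p \to \mathbb{R}^d$, one
latent-to-latent branch $f_k$ per known perturbation, and a shared
decoder $d$. Branches of a combination are summed *in latent space*;
the decoder then captures nonlinear combinatorial effects. Zero-weight
branches are skipped — provably without changing the result. Dosage
enters as a standardized feature on the first layer of its branch only,
so unseen concentrations can be interpolated.

Two decoder heads are supported:

* **scalar** — trained with mean squared error, for synergy-score screens;
* **gaussian** — per-gene mean $d_\mu(z)_j$ and variance
  $d_{\sigma^2}(z)_j$ trained with the heteroscedastic Gaussian
  negative log-likelihood
  $\sum_{i,j}\tfrac12\big(\log \sigma^2_{ij} + (\mu_{ij}-y_{ij})^2/\sigma^2_{ij}\big)$,
  with $\sigma^2 \ge \varepsilon = 10^{-6}$ for numerical stability.

For a perturbation never observed in training, a **proxy treatment
vector** stands in for the missing branch: with $N_u$ the set of
annotated pathways containing gene $u$, the Jaccard similarity
$J_{j,j'} = |N_j \cap N_{j'}| / |N_j \cup N_{j'}|$ between the unseen
target and each observed perturbation is L1-normalized into fractional
branch weights, and added to the observed part of the treatment vector
(e.g. $(1,0,0,0,0) + (0,0.4,0.35,0.25,0) = (1,0.4,0.35,0.25,0)$).

The network is implemented in numpy with hand-derived reverse-mode
gradients and an Adam optimizer, in float64 — training is exactly
reproducible from a seed, and the gradients are verified against
central finite differences in the test suite.

## Worked example

`examples/01_combinations.py` simulates a combinatorial knockout
screen (100 genes, 6 perturbations, 6 pair conditions with latent
interactions, 100 cells per condition), holds one pair out of training
and compares the model with the additive linear baseline:

```
screen: 1300 triplets, holding out pair ('g3', 'g4')
trained: best epoch 197
R^2 on top-50 DEGs  model:  0.963
R^2 on top-50 DEGs  linear: 0.820
the gap is the nonlinear interaction the additive baseline cannot see
```

The model reconstructs 96% of the variance of the held-out pair's mean
profile over its top-50 differentially expressed genes; the linear
baseline, which averages the two single-knockout responses and is
therefore blind to their interaction, trails by 0.14. The other
examples cover dose interpolation (`02`), unseen perturbations through
gene-set proxies (`03`), and scalar synergy scores under
leave-combination-out cross-validation (`04`); each prints the metrics
it computes and one line on how to read them.

A thin CLI mirrors the library for shell pipelines:
`perturbcf simulate | ingest | train | predict | evaluate | proxy`.

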