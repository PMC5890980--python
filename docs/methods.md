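# Methods

## Model

`content-ehr` models a patient's longitudinal EHR as an ordered sequence of
visits $V_1, \dots, V_{T_p}$, each a *set* of event codes from a fixed
vocabulary of size $C$ (codes within one visit are treated as simultaneous
binary indicators; duplicates carry no information).  The supervised target is
a per-visit binary label: was the patient readmitted as an inpatient within 30
days of this discharge?

Two kinds of context drive risk:

* **Local context** — short-term disease progression across recent visits —
  is captured by a GRU over visit embeddings.  A visit embeds as
  $x_t = W_v^\top V_t$ (the *sum* of its codes' embedding rows), and

  $$
  z_t = \sigma(U_z x_t + W_z h_{t-1} + b_z),\qquad
  r_t = \sigma(U_r x_t + W_r h_{t-1} + b_r),
  $$
  $$
  \tilde h_t = \tanh(U_h x_t + r_t \odot W_h h_{t-1} + b_h),\qquad
  h_t = z_t \odot h_{t-1} + (1 - z_t) \odot \tilde h_t .
  $$

  The input at step $t$ is the embedding of the *previous* visit, with $V_0$
  defined as the empty visit, so $h_1 = \mathrm{GRU}(0, 0)$ is a bias-driven
  learned start state.

* **Global context** — chronic conditions and comorbidities that persist over
  the whole record — is captured by a per-patient latent vector
  $\theta \in \mathbb{R}^N$ with prior $N(0, I)$.  Each code $m$ carries a
  topic vector $b_m$ (row $m$ of the $C \times N$ matrix $B$); a visit's topic
  bias is the mean $B_t = \frac{1}{M_t}\sum_{m \in V_t} b_m$ (zero for an
  empty visit), and the per-visit score is

  $$
  \mathrm{logit}_t = Q^\top h_t + q_0 + B_t^\top \theta,\qquad
  p_t = \sigma(\mathrm{logit}_t).
  $$

The GRU-only ablation drops the $B_t^\top\theta$ term; with $\theta = 0$ the
two coincide exactly, which the tests exploit.

## Variational inference

The posterior over $\theta$ is approximated by a diagonal Gaussian produced by
a recognition network — a two-layer rectified MLP over the patient's
bag-of-events count vector $p$ (optionally scaled by $1/T_p$, the
`scale_counts` flag):

$$
r_1 = \mathrm{ReLU}(W_{r1} p + b_{r1}),\quad
r_2 = \mathrm{ReLU}(W_{r2} r_1 + b_{r2}),\quad
\mu = W_\mu r_2 + b_\mu,\quad
\log\sigma = W_\sigma r_2 + b_\sigma .
$$

Training maximizes the single-sample reparameterized ELBO per record,

$$
\mathcal{L} = \sum_{t \in \text{mask}} \big[ y_t \log p_t + (1-y_t)\log(1-p_t) \big]
  - \mathrm{KL}\big(q(\theta\mid p)\,\|\,N(0,I)\big),
$$

with $\theta = \mu + \sigma \odot \varepsilon$, one $\varepsilon \sim N(0,I)$
draw per record per pass, and the KL in closed form
$\tfrac12\sum_n(\mu_n^2 + \sigma_n^2 - 1 - 2\log\sigma_n)$.  The KL weight is
fixed at 1 throughout (no annealing).  Gradients are derived analytically
(backpropagation through time for the GRU; the reparameterization trick for
the recognition network) and implemented directly in NumPy; the test suite
verifies them against central finite differences to relative error $10^{-4}$.
Optimization is Adam (learning rate 0.001, $\beta_1{=}0.9$, $\beta_2{=}0.999$,
$\epsilon{=}10^{-8}$) over shuffled records with batch size 1, with early
stopping on pooled validation ROC-AUC (patience 10, max 100 epochs by
default); the returned parameters are those of the best validation epoch.
Gradient clipping at global norm 5 is a numerical safeguard only
(`strict=True` disables it).

### Posterior-collapse countermeasures

With a flexible recurrent likelihood the latent pathway is prone to posterior
collapse: the GRU explains the labels, the KL term prunes $\theta$, and the
full model degenerates into its own ablation.  Since the objective is fixed
(no KL annealing or free bits), the package counteracts collapse purely
through initialization, chosen once as defaults:

* the topic matrix $B$ is initialized at scale $1/\sqrt{N}$ (the dimension of
  the product $B_t^\top\theta$) rather than $1/\sqrt{C}$, so the context
  pathway contributes at usable magnitude from the first updates;
* the $\mu$ head of the recognition network is initialized 8× larger than
  plain fan-in scaling, so posterior means start dispersed across patients at
  roughly the prior's scale — a signal the output layer can latch onto
  immediately;
* $b_\sigma$ is initialized at $-1$ ($\sigma \approx 0.37$), keeping early
  reparameterization noise below that signal.

### Full vs causal recognition input

By default one $\theta$ per patient is inferred from the *whole* record
(`theta_context="full"`), during training and prediction alike.  A strictly
causal mode is available at prediction and embedding time: a fresh posterior
per step from the counts of visits before $t$.  Training always uses the
full-record posterior: a per-step causal posterior would require either
summing per-step KL terms (changing the objective) or an arbitrary cut point
for a single partial-record posterior.  The `causal` flag exists for
leakage-sensitive deployment of a trained model.

## Hyperparameters

| parameter | default | meaning / rationale |
|---|---|---|
| `embed_dim` (H) | 100 | code-embedding dimension |
| `hidden_dim` (D_h) | 200 | GRU hidden width; the output vector Q lives in this dimension |
| `n_topics` (N) | 50 | context dimension; also the width of the topic vectors |
| `rec_hidden1/2` | 200 | recognition MLP widths (mirroring the RNN hidden size) |
| `learning_rate` | 0.001 | Adam step size |
| `batch_size` | 1 | records per update |
| `patience` / `max_epochs` | 10 / 100 | early stopping on validation ROC-AUC |
| `scale_counts` | off | divide recognition counts by $T_p$ |

## Labels, evaluation, embedding

`build_labels` anchors the 30-day clock at *discharge* (visit time plus
`duration_days`, default 0) and uses the window `(discharge, discharge + 30]`
— a readmission exactly 30 days after release counts as positive.  Only
inpatient visits are supervised when labels are built from timestamps;
pre-labeled corpora supervise every labeled visit.

Evaluation micro-pools all supervised visit predictions across test patients,
then computes ROC-AUC (Mann–Whitney, ties ½), PR-AUC (step-wise average
precision) and accuracy (threshold 0.5, `>=` convention), repeated over
`n_runs` seeds with a fixed split and reported as mean ± sample (n−1)
standard deviation.  ROC/PR-AUC delegate to scikit-learn, which implements
exactly these conventions; the tests check both against brute-force counting
oracles.

A patient embeds as the concatenation of the posterior mean $\mu$ and the
final hidden state $h_{T_p}$ (dimension $N + D_h$).  Clustering is seeded
k-means (k-means++ initialization, 10 restarts) with $k{=}20$ by default;
cluster summaries report the mean per-patient count of positive labels and
the top event codes by within-cluster count after removing the globally most
frequent codes (default 3, or an explicit clinically chosen list).

## Synthetic data

`subsample_combine` reproduces the benchmark-style corpus construction: per
record a fraction $u \sim U(0.3, 0.5)$ of visits is kept
($\lceil u\,T_p\rceil$, uniformly without replacement, order preserved),
records are permuted and paired, the second member's times are shifted so its
first kept visit aligns with the first member's, and the two streams are
merged by time (stable; first member wins ties; simultaneous visits are not
fused).  Labels travel with their source visits.

`generate_de_novo` is a fully generative simulator with stored ground truth.
Defaults emulate the benchmark corpus's shape: 3000 patients, a 618-code
vocabulary, Poisson(80) visits per patient and Poisson(2.86) codes per visit
(≈ 230 events/patient).  Each of K topics is a sparse positive distribution
over ~20% of codes plus a 2% uniform floor; a patient draws
$\theta^* \sim N(0, I_K)$ and emits codes from the mixture weighted by
$\mathrm{softmax}(\theta^*)$.  Risk combines a global term
$g_w\,\langle w_g, \theta^*\rangle$ — where $w_g$ is a fixed zero-sum unit
vector (an alternating-sign topic contrast; a loading on the all-ones
direction would be invisible to the codes, since softmax is shift-invariant)
— and a local term $l_w\,s_t$ with $s_t = 0.7\,s_{t-1} + (a_t - E[a])$, a
damped random walk driven by the count $a_t$ of "acute" codes (a designated
10% of the vocabulary) in the visit:
$p^*_t = \sigma(\text{bias} + g_w\langle w_g,\theta^*\rangle + l_w s_t)$,
labels Bernoulli($p^*_t$), all visits supervised.  The default bias −1 gives
≈ 30% visit-level prevalence under the default weights ($g_w{=}2$,
$l_w{=}1$).  The stored $p^*_t$ yield the Bayes ROC-AUC, an upper bound on
any model's test performance.

What the simulator does **not** emulate: code co-occurrence beyond topic
structure, visit-timing irregularity tied to health state, censoring,
location mixtures, coding drift, or label noise from imperfect chart
abstraction.  Passing the recovery tests therefore shows that the estimator
recovers the signal its own model family posits — not that it attains any
particular performance on real claims data.

## Recovery / ablation study

The canned study (`content_ehr.experiments.recovery_experiment`) simulates
600 patients (C=100, K=8, Poisson(20) visits, $g_w{=}2$, $l_w{=}1$), splits
400/100/100, and fits both variants 5 times with consecutive seeds.  Model
dimensions for this study are deliberately small (H=32, D_h=64, N=16,
recognition 128/128, `scale_counts` on, max 12 epochs, patience 4) so ten
fits complete in a few minutes on one core; N intentionally exceeds the
simulator's K, since a practitioner would not know the true topic count.
Expected outcome, asserted by the tests: the full model's mean pooled test
ROC-AUC is far above chance, at least the ablation's mean, and at most the
Bayes bound.  The margin over the ablation is small — a GRU over ~20 visits
can itself accumulate much of the bag-of-codes signal — mirroring the
near-tie between the two approaches reported on sequence-rich synthetic
benchmarks in the literature.

## Numerical choices and degenerate inputs

* All arithmetic is float64.  Sigmoids are computed via `tanh`; Bernoulli
  log-likelihoods via `log1p`-stable soft-plus forms.
* Empty visits are legal: they embed to the zero vector and contribute zero
  topic bias.
* A record must contain at least one supervised visit to enter the objective;
  records with zero supervised visits raise an error.
* ROC-AUC requires both classes; PR-AUC requires a positive; accuracy scores
  `>= 0.5` as a positive call.
* `split_corpus` permutes records with a seeded generator; equal seeds give
  identical assignments.
* k-means ties and restarts are governed by the passed seed; the best of 10
  restarts by within-cluster sum of squares is kept.

## Known limitations

* Training is plain Python/NumPy with per-record updates; it is intended for
  cohorts of up to a few thousand patients, not millions.
* The benchmark supplementary corpus has its own undocumented serialization;
  no loader for it ships here (a dialect can be registered once the file
  format is known).  The published corpus-level statistics and scores on that
  file are therefore not reproduced by this repository's tests.
* Causal-mode prediction re-runs the recognition MLP per visit and is
  correspondingly slower.
* The demographic / side-information extension is out of scope.
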