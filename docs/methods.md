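# Methods

## Effect sizes

Each observation is a correlation between contest duration and an
RHP-linked trait for either the winner or the loser of a contest series.
Reported statistics are converted as

- `r` from `t`: `r = t / sqrt(t² + df)` (sign follows t);
- `r` from `F` (1 numerator df only): `|r| = sqrt(F / (F + df_error))`,
  with the direction supplied separately because F is unsigned; F tests
  with numerator df > 1 are rejected — they do not determine a unique r;
- raw data: Pearson r over pairwise-complete pairs, with n reduced to the
  pairs actually used so the variance below stays honest.

The meta-analytic scale is Fisher's Z, `z = atanh(r)`, with sampling
variance `v = 1/(n − 3)` and weight `w = 1/v`. Correlations with
`|r| ≥ 0.9999` are rejected rather than clamped: a clamped value would
enter the weighted fit with an essentially arbitrary huge z. The sign of
the original relationship is always preserved.

Which n enters `1/(n − 3)` when winners and losers come from the same
contests is ambiguous in principle; the package uses the per-regression
sample size as supplied on each row, which is the only quantity available
per record.

## Classification rules

Cost category is a pure function of two booleans: **high** iff weapons are
physically used during contact phases (weapon use without contact is an
input inconsistency), **low** otherwise. Strategy calls use the
Taylor–Elwood sign table (see `classify` module docstring). Signs come
from Wald 95% CIs on the pooled per-species, per-role Fisher Z
(fixed-effect pooling within the cell); an interval exactly touching zero
counts as non-significant — a conservative tie-break. Escalation is a
three-valued input (true / false / unknown): *true* asserts both that
distinct phases exist and that they run from low-cost display to
high-cost contact behaviour. Unknown escalation is not collapsed to
false, because the evidence is only needed to split SAM from CAM; a
(positive, negative) sign pattern with unknown escalation is reported as
`CAM_or_SAM`.

## Phylogenetic correlation

Topology-only trees are made ultrametric with Grafen's method at ρ = 1:
node height = (descendant tips − 1), normalized to unit depth. This is a
deterministic, fully reproducible choice for taxonomy-derived trees that
carry no usable branch lengths. Under Brownian motion on an ultrametric
tree the tip correlation is the shared root-to-MRCA path fraction; the
resulting matrix is symmetric, unit-diagonal and PSD (checked to
−1e-10 on the smallest eigenvalue). Trees whose tip depths differ by more
than a relative 1e-6 are rejected, naming the worst pair. Species in the
dataset but absent from the tree abort the fit — no grafting or fuzzy
matching, since a silently wrong match corrupts the matrix.

## The multilevel model

`V = Σ_k σ²_k Z_k G_k Z_k' + diag(v)` with random intercepts for species
(identity), phylogeny (species factor with G = C), article, study type and
observation. Species deliberately enters twice so the exchangeable and
phylogenetic shares can be reported separately. The study-type factor has
only two levels (field / laboratory); its variance component is weakly
identified and the fitter warns about it, but the term is kept because the
target model specifies it. The observation-level σ²_obs is identifiable
alongside the known v_i because the v_i are fixed constants, not free
parameters.

Estimation minimizes the −2 restricted log-likelihood
`log|V| + log|X'V⁻¹X| + (y − Xβ̂)'V⁻¹(y − Xβ̂)` by L-BFGS-B on
`log σ²_k` (analytic gradient
`σ²_k · [tr(P M_k) − y'P M_k P y]`, `P` the REML projection), with
multi-starts at σ² ∈ {1e-4, 0.01·var(y), 0.1·var(y)} and a log-σ² box of
[−30, 10] to keep exponentials finite; convergence at relative criterion
change below 1e-12. With no random terms the fit reduces exactly to
weighted least squares with weights 1/v.

Moderators are treatment-coded with reference cell (loser, high):
intercept, role[winner], cost[low], interaction. The QM test is the joint
Wald chi-square of the three non-intercept coefficients (df = 3). Cell
means are `Lβ̂` with normal-theory 95% CIs (multiplier 1.96, no df
adjustment) and `mean_r = tanh(mean_z)`. The Wald/normal choice is
slightly anticonservative in small samples; the calibration test below
quantifies it at the default problem size.

## Heterogeneity and publication bias

The typical sampling variance is Higgins–Thompson:
`ṽ = (k−1) Σw_i / ((Σw_i)² − Σw_i²)`. Level shares are
`I²_k = 100 σ²_k / (Σ σ² + ṽ)` and sum to the total by construction; all
shares are invariant to a common rescaling of σ² and v.

The modified Egger test refits the same random structure with moderator
√v_i (the sampling standard error — the only per-record dispersion
quantity available) plus intercept; the reported quantity is the √v
*slope* with a 1.96-SE CI and Wald p. The phylogenetic term is retained by
default ("same random structure as the main analysis"); a flag drops it
for the variant without phylogeny. A dataset where every record shares the
same n has a constant predictor and is rejected.

## Synthetic generator

`simulate_dataset` draws data from exactly the generative model the
fitter assumes: a random labeled topology (uniform joins, matching the
Yule labeled-shape distribution) with Grafen lengths; species assigned to
cost categories; per-study sample sizes uniform on a range; paired
winner/loser records sharing article and n; random intercepts at each
level; and sampling noise N(0, 1/(n−3)). Records are emitted as
correlations (`stat_kind="r"`), so refits exercise the full derivation
chain. A single root seed feeds a named substream per level, so changing
one variance component or the suppression probability never perturbs the
other draws; suppression (drop non-significant records with probability
p) therefore yields a strict subset of the unsuppressed dataset at the
same seed.

Defaults encode the study-scale conditions the pipeline targets: 36
species, 22 high / 14 low cost, 40 pairs = 80 effects (each species one
study, four species a second one), escalation in 20/22 high- and 10/14
low-cost species, per-study n uniform on [10, 60], ~30% field studies,
true cell means (loser, high) = 0.35, (loser, low) = 0.20, winners 0 —
the self-assessment pattern in the high-cost group — and variance
components σ²_obs = 0.35, σ²_article = 0.04, zero at the species,
phylogeny and study-type levels, i.e. heterogeneity dominated by the
observation level with a small article share. What the generator does
*not* emulate: real RHP traits vary across studies (here a single trait
label), articles can span species, sample sizes and study types may
correlate with effect size, and true effects need not be exchangeable
within a cell. Passing recovery tests therefore demonstrates correctness
of the estimation machinery under the model's own assumptions, not
robustness to violations of them.

## Experiment sizes and numerical choices

The calibration and coverage experiments in the test suite use the
study-scale generator (80 effects) with the species/article/observation
random structure: 1000 null replicates for the QM type-I error, 200
replicates for cell-mean recovery, 500 for Egger CI coverage and 200 for
the suppression-bias direction — sizes at which the Monte-Carlo error on
a 5% rate is about ±0.7 points and a full run stays in the minutes range.
Degenerate inputs are rejected rather than repaired throughout: n ≤ 3,
|r| ≥ 0.9999, rank-deficient designs, non-PSD correlation matrices,
constant Egger predictors, weapons without contact.

## Known limitations

- Wald-type inference (normal CIs, chi-square QM) ignores uncertainty in
  the variance components; with ~40 independent units the measured type-I
  error is ≈ 0.06 rather than 0.05. Satterthwaite/Knapp–Hartung
  corrections are out of scope.
- Grafen ρ = 1 is one of several defensible ultrametricizations; variance
  shares attributed to phylogeny are sensitive to this choice.
- The two-level study-type variance is reported but should not be
  over-interpreted.
- No trim-and-fill, selection models or robust (cluster) standard errors.
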