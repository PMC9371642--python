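# Methods

## The problem

Task-related changes in functional connectivity are widespread and
individually small: contrasting task with rest, most edges of a connectome
shift a little rather than a few edges shifting a lot.  The level at which
inference is performed — individual edges, clusters of contiguous edges,
predefined large-scale networks, or the whole brain at once — then governs
statistical power far more than most analysis choices.  `connbench`
implements seven inferential procedures spanning those four levels, and a
resampling benchmark that measures their power and specificity against a
ground truth fixed by a large population sample.

## Data model

A connectome is a symmetric `V x V` matrix of connectivity values (e.g.
z-scored Pearson correlations).  All computation uses the vectorized upper
triangle: `E = V(V-1)/2` values in row-major order over pairs `(i, j)`,
`i < j` — the canonical edge order every module consumes and emits.  A
partition maps each node to one of `K` communities, inducing a map from
each edge to one of `K(K+1)/2` unordered community pairs ("network
pairs"); within-community pairs `(k, k)` are distinct from
between-community pairs.

The design is paired: each subject is measured under two conditions (task
and rest), and the unit of analysis is the within-subject difference.  Per
edge, the test statistic is the one-sample t of the differences
(`t = mean / (sd / sqrt(n))`, sample sd) and the effect size is the paired
Cohen's d (`d = mean / sd`).

## Permutation scheme

Exchangeability of the condition labels within subject justifies the
standard exact scheme for paired designs: each permutation draw flips the
sign of each subject's difference vector independently with probability
1/2.  Draw 0 is reserved as the identity; draws are derived from
`(seed, draw index)` so any draw regenerates in isolation.  Because sign
flips leave each edge's sum of squared differences unchanged, the entire
permuted-t ensemble `(P x E)` reduces to one matrix product; all
nonparametric procedures share this ensemble, which is what makes the
benchmark loop fast.  Permutation p-values use the `+1` convention,
`p = (1 + #{null >= observed}) / (P + 1)`, so p is never zero and the test
is valid at finite P; ties count against the observed statistic.

## The seven procedures

Directional inference is performed as two one-sided analyses per contrast
(task > rest, task < rest).  **Each tail runs at `alpha/2`** by default so
that the two directional analyses jointly control their error at the
nominal `alpha`; running each tail at full `alpha` (an equally common
convention) is available via `InferenceSettings(alpha_tail=...)` but makes
the combined weak-sense FWER approach `2 alpha`.

1. **edge-fwer** — Bonferroni on parametric one-sided t p-values; a
   significant edge asserts an effect at that edge.
2. **edge-fdr** — Storey q-values per tail.  pi0 is estimated with a fixed
   lambda (default 0.5 — simple and stable when signal is dense; no
   smoother), floored at `1/m` to guard the degenerate case where every
   p-value falls below lambda.  The q-value is the step-up minimum
   `min_{p_j >= p_i} pi0 * m * p_j / rank(p_j)`.
3. **nbs** — the network-based statistic: edges with one-sided t above a
   cluster-determining threshold (CDT) form components (connected through
   shared nodes); component size is referred to the permutation null of the
   maximal component size.  The CDT default is the t quantile of one-sided
   p = 0.01 at the sample's degrees of freedom, configurable as a statistic
   or a p-value.  A significant cluster asserts at least one effect within
   the cluster.
4. **nbs-tfce** — threshold-free cluster enhancement on the graph:
   `tfce(e) = sum_k extent_k(e)^E * h_k^H * dh` over heights
   `h_k = k * dh`, `dh = max(t)/n_steps`, with `extent_k(e)` the edge count
   of the supra-threshold component containing `e` at height `h_k`.
   Defaults `E = 0.5`, `H = 2`, 100 steps (the classical choices).  Edge
   scores are referred to the permutation null of the maximal score
   (FWER control by the max-statistic argument).
5. **cnbs-fwer** — pooled network statistics: `T_k` is the mean edgewise t
   over the edges of network pair k.  The permutation ensemble supplies the
   null of each `T_k`; p-values are then Bonferroni-corrected across the
   `K(K+1)/2` pairs.  A significant pair asserts a pooled effect, not any
   particular edge.
6. **cnbs-fdr** — the same pooled statistics with the Simes
   (Benjamini–Hochberg) step-up across pairs.
7. **mv-cnbs** — whole-brain omnibus: the observed pooled-statistic vector
   `T` is scored by squared Mahalanobis distance from the permutation null
   cloud, `D2 = (T - mu)' Sigma^{-1} (T - mu)`, with moments estimated from
   the null draws and ridge regularization
   `Sigma + eps I, eps = 1e-6 * trace(Sigma)/K_pairs`.  Null distances are
   computed leave-one-out so each null draw is exchangeable with the
   observed point.  This is a signless test of inequality; a detection
   implicates the whole connectome but localizes nothing.

### Network-level p-values

The pooled statistic is a mean over tens to hundreds of edges, so its
sign-flip null is very nearly Gaussian.  By default the per-pair p-values
come from a normal tail calibrated on the permutation-null mean and sd
rather than from the empirical `+1`-convention count.  This is a
resolution requirement, not a convenience: with P permutations the
smallest attainable empirical p is `1/(P+1)`, which already exceeds the
Bonferroni threshold `alpha_tail / K_pairs` at practical P (e.g. P = 500,
21 pairs, `alpha_tail = 0.025`), leaving the FWER variant with exactly
zero rejections.  The raw permutation p-values remain available
(`cnbs_p_method="permutation"`).

## Ground truth

The full population sample is designated the reference: per-edge paired
Cohen's d is treated as exact, two-sided t p-values with Storey FDR at
alpha give the edge significance mask, and the edge sign is the sign of d.
Network-level truth pools d and t within pairs and applies the same
testing recipe to permutation-null pooled statistics (two-sided), for
internal consistency with the cNBS procedures.  The whole brain is
non-null iff any edge is significant.

Two variants probe robustness.  *Weak* multiplies all effect sizes by a
factor (default 0.5); the construction is multiplicative shrinkage because
it preserves signs and spatial structure while scaling difficulty.
*Sparse* declares every element with `|d|` below a cutoff (default 0.2)
null — its sign and significance are zeroed (at both the edge and network
level), so detections there count as false positives; d is retained for
bookkeeping.

`network_heterogeneity` characterizes an effect map: a one-way F of d
grouped by network pair, with two shuffle nulls — permuting node-community
memberships, and permuting edge values separately within the
within-community and between-community edge sets (which preserves that
coarse structure while destroying pair identity).

## Benchmark and the six measures

A benchmark experiment cell is (procedure, contrast, group size).  At each
repetition a group of n subjects is drawn without replacement from the
population, inference is run, and detections are classified against the
ground truth by sign.  The real contrast is task vs rest; the fake
contrast pairs the two rest runs with labels shuffled per subject — null
by construction — and supplies weak-sense FWER.  Repetition seeds are
derived from (base seed, contrast, group size, repetition) through a
`SeedSequence`, so any repetition re-runs in isolation and all procedures
see identical resampled groups and one shared permutation ensemble.

Accounting operates at two granularities, matching what each quantity
means:

* **Power** is counted at the level the procedure localizes to: edges for
  edge- and cluster-level procedures (a cluster detection credits its
  implicated edges), network pairs for network procedures, one element for
  the whole brain.  Mean power averages the per-element TPR over non-null
  elements; its Monte-Carlo se is taken from the spread of the
  per-repetition TP fraction, which respects between-element dependence.
* **Error** is counted at the level of the claim a detection makes.  An
  edge detection asserts that edge's direction.  A cluster detection
  asserts at least one same-direction effect within the cluster, so a
  cluster claim is false only when it contains none.  A network detection
  asserts the pooled direction of its pair; its member edges are not
  individually asserted — that cost appears in *spatial precision*, the
  fraction of all implicated edges overlapping same-sign true effects.
  Strong-sense FWER is the fraction of real-contrast repetitions with at
  least one false claim; weak-sense FWER the fraction of fake-contrast
  repetitions with any detection; empirical FDR is FP/(TP+FP) per
  repetition (edge counts for edge- and cluster-level procedures, claim
  counts otherwise); FP spatial extent is the fraction of the connectome
  implicated by false claims.  Validity uses the binomial criterion: the
  empirical rate must fall below
  `alpha + 1.96 sqrt(alpha(1-alpha)/R)`.

  The alternative accounting — counting every wrong-sign member edge of a
  network or cluster detection as a familywise error — makes broad-scale
  procedures appear catastrophically invalid (a detected network pair with
  a correctly-signed pooled effect always contains some small
  opposite-signed edges) while saying nothing their claims assert; we
  surface that cost through precision instead.

## Synthetic populations

The generator emulates the structure that makes multi-scale inference
interesting, with the effect injected on the difference scale under unit
total noise sd so the target map delta *is* the population Cohen's d —
ground truth is analytically known, not merely estimated:

    rest run r:  x_ser = mu_e + u_se + v_ser          (r = 1, 2)
    task:        y_se  = x_se1 + delta_e + eps_se
    eps_se = sqrt(1 - rho^2) z_se + rho g_{s,k(e)}

`u` is a subject effect (sd 0.3), `v` run noise (sd 0.5), `z` iid standard
normal, and `g` a standard-normal factor shared by all edges of a network
pair within a subject — the simplest dependence structure that makes
cluster- and network-level procedures meaningfully different from edge
procedures (it induces correlation `rho^2` between same-pair edge
differences).  Baseline connectivity is 0.3 within and 0.1 between
communities.  An optional extra rest-run noise sd stands in for unequal
scan durations (off by default).

The default effect map: within-community edges at d = -0.5 (task lower
than rest), one designated between-community block at -0.4 (a motor–visual
analog), remaining between-community edges drawn `N(+0.1, 0.1)` — dense,
weak, sign-coherent within blocks.  The desk-scale design is V = 60 nodes
in K = 6 equal communities (1,770 edges, 21 network pairs), N = 600
subjects, rho = 0.3; these sizes run the full benchmark grid in minutes on
one CPU while keeping every structural feature of the full-scale problem
(the acceptance runs use R = 200 repetitions and P = 500 permutations at
n = 40, and R = 100 at n = 20 and 60).

What the generator does *not* emulate: empirical marginal distributions of
real connectivity, motion and scanner artifacts, heavy-tailed or
spatially-graded noise covariance beyond the one-factor-per-pair block
model, and between-subject effect heterogeneity.  Passing benchmarks here
demonstrate correctness of the machinery and the direction of the
level-of-inference trade-offs, not numerical power values for any real
dataset.

## Numerical choices

* Degenerate zero-variance edges are flagged, with t = 0 (zero mean) or
  signed infinity (nonzero mean), not silently dropped.
* The TFCE kernel processes heights top-down with a union-find whose
  per-component accumulators propagate lazily through merge potentials;
  it is exact (matched against a per-height reference) and O(E + steps·V)
  per map.  Because `dh = max(t)/n_steps` is map-dependent, raising the
  global maximum rescales the height ladder and perturbs other scores at
  the discretization level; score monotonicity holds exactly on a fixed
  ladder.
* Ridge regularization of the mv-cNBS null covariance uses
  `1e-6 * trace / K`; a covariance still singular after regularization
  raises a diagnostic error rather than returning garbage.
* Ties in permutation statistics resolve conservatively (`>=` against the
  observed value).
* Matrix symmetry is validated to 1e-8; text floats are serialized with 17
  significant digits so file round-trips are exact.

## Known limitations

* The mv-cNBS statistic is one reasonable construction of a whole-brain
  omnibus on pooled network statistics (permutation-null Mahalanobis with
  leave-one-out nulls); other choices (e.g. rank-based depth) would also
  be defensible.  At the smallest desk-scale group size (n = 20) its null
  distance distribution is heavy-tailed enough that it misses in a small
  fraction (~2%) of repetitions; from n = 40 up it detects the widespread
  effect in every repetition.
* Only the paired two-condition design is supported; no covariates, GLM
  contrasts, or unpaired designs.
* The benchmark's FDR/FWER accounting at claim level and power at element
  level is one coherent choice among several; both granularities are
  exposed (`Classification`) so alternative summaries can be built.
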