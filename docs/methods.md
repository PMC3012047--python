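# Methods

## Model

`netcondense` treats a curated molecular network as prior knowledge and
two-condition differential measurements as evidence, and asks, link by
link: did this relationship plausibly start up or shut down between
conditions E1 and E2?

The per-node differential is `D_A = M_A,E2 − M_A,E1`, or its
Welch-standardised form `(M_A,E2 − M_A,E1) / sqrt(Var_A,E1/n1 +
Var_A,E2/n2)` when replicate variances are supplied. The standardised
form is exactly the Welch two-sample *t* statistic; it is used as an
effect measure only — no p-value is attached, so no distributional
assumption beyond approximate normality and independent sampling is
leaned on, and no multiple-testing machinery applies.

The signed link score is `D_src + D_tgt` for interaction and stimulation
edges and `D_src − D_tgt` for inhibition edges. Positive scores are read
as startups, negative as shutdowns. Two modelling assumptions are
inherited from the score's mass-action motivation: measurement values
are proportional to molecular abundance, and for interaction edges the
values are on a log scale, so that the score equals the log-ratio of
mass-action complex formation between the conditions. Neither
equilibrium constants nor kinetics are modelled. Interaction edges are
symmetric; they are stored with lexicographically ordered endpoints so
output is deterministic.

### Consistency classes

Each scored edge is classified by how its endpoint changes relate to the
edge type (with an optional dead-band `epsilon`, default 0, under which
a differential counts as no change):

* `consistent` — both endpoints change, in the direction the type
  rewards (same sign for interaction/stimulation, opposite for
  inhibition);
* `source_principle` / `target_principle` — one endpoint's change
  dominates (strictly larger magnitude) while the other is zero or
  disagrees; the call rests on the dominant endpoint and the other is
  attributed to unmodelled counteracting or cooperating effectors;
* `inconsistent` — disagreement with neither side dominant (including
  exact magnitude ties: neither principle wins a tie);
* `no_change` — both within the dead-band.

The principle and inconsistent classes are exported as a `wavy` flag.
Because the score formula itself damps disagreement (an anticorrelated
stimulation pair never exceeds the correlated pair of the same total
change), such links disappear first as the threshold tightens; the
classes exist for interpretation, not filtering.

## Condensation

Thresholds are two-sided and independent: an absolute pair
`lower ≤ 0 ≤ upper`, or tail quantiles in `[0, 0.5)` resolved against
the empirical distribution of the *signed* scores as `Q(lower)` and
`Q(1 − upper)`. The quantile estimator is linear interpolation on the
order statistics (the widespread "type 7" convention, numpy's default);
links lying exactly on a cutoff are kept. With n distinct scores and
quantile q per side this keeps `floor(1 + (n−1)·q)` links per tail — at
q = 0.03 roughly 94% of links are removed, with a deviation of up to two
links at sizes where the interpolated cutoff falls just past an order
statistic. Nodes with no surviving link are pruned. Edges left unscored
because an endpoint lacks measurements can never exceed a threshold and
are always removed (and counted).

`condensation_series` applies an ordered list of specs; because keeping
is a threshold test on a fixed score, kept sets are nested as specs
tighten, and condensing an already-condensed set at its own resolved
absolute cutoffs is a no-op.

### Preprocessing

Microarray-style inputs are commonly log-transformed and
quantile-normalized before scoring. `preprocess` applies an elementwise
log (base 2, e, or 10; nonpositive values are an error, reported per
node), then quantile normalization across sample columns (rank-mean
substitution; tied ranks receive the average of the tied rank means),
then per-condition means and (with ≥2 replicate columns per condition)
ddof-1 variances. Nothing is transformed implicitly: scoring consumes
whatever the table contains.

### Degenerate and mixed variance

A pooled variance of zero makes the Welch differential undefined and is
a hard error naming the node; callers can opt in to a variance floor
(default suggestion 1e−12) instead, which is never applied silently.
Tables must be uniformly with or without variance: Welch-standardised
and raw differentials live on incomparable scales, and a quantile
threshold over a mixture would be meaningless.

## Visual encodings

Node colors follow the heat-map metaphor: the pooled values of both
conditions are anchored at their 10%/50%/90% quantiles (user-settable);
values are clamped to pure green below the low anchor and pure red above
the high anchor and linearly interpolated through white at the median
between them. A fully degenerate scale (constant input) maps everything
to the mid color. Each node exposes two halves, E1 left and E2 right.
Edge color is red for positive and green for negative scores, with
saturation and width linear in |score| over the kept range — the exact
saturation and width laws are this package's convention; linear is the
simplest mapping that is monotone in the score, and when all kept scores
share one magnitude every edge takes the maximum width. Default palette:
green (0,200,0), white (255,255,255), red (220,0,0). The styled network
is exported as attributes (hex colors, widths, wavy flags) in
GraphML/TSV; the optional matplotlib rendering is deterministic for a
fixed layout seed, but only the attribute export is contract-tested.

## Synthetic data

The generator emulates the structure of the method's real inputs: a
typed network (uniform random topology over the requested type mix) and
log-normal-style baseline expression (normal on the log2 scale, default
mean 8, sd 2, the typical range of log2 microarray intensities). A
requested number of planted startup/shutdown edges receive endpoint
shifts of ±`effect_size` (default 2 log2 units, a strong but realistic
4-fold change) in the pattern their type rewards; all nodes additionally
receive independent noise of sd `noise_sd` (default 0.1 per condition).
With `replicates=(n1, n2)` the generator draws per-replicate values and
summarises them into means and ddof-1 variances.

Planted edges are chosen endpoint-disjoint and, where the topology
permits, isolated from each other (no background edge between shifted
nodes, no parallel duplicate of a planted edge); under that construction
every background score is strictly smaller in magnitude than the planted
2·effect, so with zero noise a sufficiently tight quantile recovers the
planted set exactly. On dense graphs where isolation is impossible the
generator falls back to plain endpoint-disjointness and exact recovery
holds only with high probability.

What the generator does **not** emulate: scale-free or modular topology,
correlated noise across genes, probe-level effects, or
condition-dependent variance. Passing tests therefore demonstrate the
correctness of the arithmetic and the filtering machinery, not the
biological error rate of the method on real networks.

## Problem sizes and numerical choices

The test and acceptance workloads use networks of 50–206 edges and up to
1000 scorer-vs-oracle replicates — comfortably representative, since
every operation is linear in edges and the method has no iterative or
stochastic fitting step. Scores are plain double arithmetic; the
independent brute-force reference agrees to better than 1e−12.
Determinism: fixed seeds drive the generator, file exports sort nodes
and preserve edge order, and repeated CLI runs are byte-identical.

## Known limitations

* A link score is correlational: a high score neither proves nor a low
  score excludes mechanistic change, and network incompleteness bounds
  what can ever be highlighted.
* Only pairwise links are scored; no subnetwork/module search is
  attempted, by design.
* GPML input is not supported (SIF/GraphML/XGMML cover the method);
  session-archive extraction handles zip-of-XGMML containers and reads
  whatever node attributes the XGMML itself carries.
* Edges without a resolvable type attribute are rejected rather than
  defaulted — silent typing would corrupt inhibition scores.
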