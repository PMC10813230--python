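# Methods

`dynhubs` analyses the time-varying hub structure of parcellated
resting-state fMRI-like signals, and ships a synthetic-cohort generator
with planted ground truth so the whole chain can be validated without any
imaging data. This note records the models, the defaults, and the design
choices that were genuinely open — together with what the synthetic
validation does and does not demonstrate.

## The analysis chain

### Jackknife correlation (time-varying connectivity)

For two region signals x, y of length T, the connectivity *at* time point
t is estimated by the jackknife correlation

    JC_t(x, y) = - corr(x_{-t}, y_{-t}),

the negated Pearson correlation with time point t deleted (leave-one-out
means throughout). Deleting a point that carries strong positive
co-fluctuation lowers the remaining correlation, so the minus sign makes
JC_t *rise* exactly when the edge is strongly engaged; the static
correlation level enters as a negated offset. The per-edge z-score of the
JC series over time ("normalized") removes that offset. Both the raw and
normalized T x N x N stacks are computed for every subject. Degenerate
edges (zero variance after a deletion) raise an error naming the edge and
time point rather than emitting NaN.

### From connectivity to graphs

The literature this pipeline follows does not specify how the per-time-
point connectivity matrix becomes a graph, so this is the package's own
construction, and it matters. Three value modes are offered:

* **local** (default): the windowed jackknife pseudo-correlation

      v_t = r_full + g * (T - 1) * smooth_w(JC_t - mean_t JC),

  with shrinkage gain g = 0.5 and a centred moving average of w = 21 time
  points. The pseudo-value term is an unbiased estimate of the time-local
  departure from the static correlation; the shrinkage and window tame
  its single-sample noise (SD of order 1 per point) while staying shorter
  than typical connectivity-state dwell times. Graphs in this mode retain
  the static network scaffold *and* track state dynamics with the correct
  sign.
* **normalized**: the per-edge z-scored JC as-is. Analytically appealing
  but destructive in practice: z-scoring forces every edge to the same
  time-average retention rate, so no node can have elevated time-average
  degree, and high-degree moments of a node coincide with its
  co-fluctuating neighbours interconnecting (the product of two edge
  signals sharing a node fixes the sign of the third edge of the
  triangle). Betweenness is therefore *suppressed* exactly where coupling
  is strong. The mode is kept for comparison.
* **raw**: the sign-corrected raw JC (the leave-one-out correlation).
  Graphs are essentially static, since one deleted point moves the
  correlation by O(1/T).

Each time slice is proportionally thresholded: edges ranked by value, the
top `density` fraction retained (round(density * E), minimum 1, ties at
the cutoff kept), binarized, undirected. Density defaults to 0.15, the
common proportional-threshold operating point that keeps density
comparable across time points and subjects; a weighted mode (shortest
paths on lengths 1/value over positive values) exists behind a flag.

### Betweenness centrality and the two hub thresholds

Per time slice, normalized betweenness centrality

    BC_n = 2 / ((N-1)(N-2)) * sum_{h<j, h,j != n} sigma_hj(n) / sigma_hj

is computed (disconnected pairs contribute 0; values lie in [0, 1]).
Aggregates: per-node time average, whole-brain mean, per-RSN means.

* **TH1 / candidate hubs**: across-node mean of time-averaged BC plus one
  across-node sample SD (ddof = 1); nodes strictly above are candidates.
  An exposed multiplier (mean + m SD) supports sensitivity analyses.
* **TH2 / active hubs**: per candidate, its own time mean plus one
  across-time sample SD; the candidate is active where its BC strictly
  exceeds this. Note TH2 is *relative*: for any stationary BC series
  roughly 10-35% of time points end up active, whether or not the node
  carries planted dynamics. This has consequences for what pattern
  clustering can recover (below).

### Overlap measures and pattern clustering

* **SND**: share of active-hub events (node x time entries) per RSN;
  pooled over subjects by summing events before normalizing.
* **SO**: Jaccard overlap of the active-hub sets of two time points;
  time points with an empty active set are invalid-masked (0/0), excluded
  from the mean SO and from clustering, and counted in the run report.
* **Clustering**: agglomerative average linkage on d = 1 - SO over valid
  time points, cut at height 0.90 on the *distance* scale (similarity
  0.90 would shatter realistic data into near-singletons; the scale of
  the published threshold is ambiguous and both are supported via
  `cut_scale`). Singletons count as clusters.
* **TO**: fraction of all T time points at which two candidates are
  co-active; the diagonal holds each candidate's own active fraction.
  Ranked pair lists break ties lexicographically.

### Group statistics

Independent two-sample t-tests (Student pooled-variance by default, Welch
behind a flag), two-sided. The whole-brain BC test is reported
unadjusted; the five RSN-level tests form one Benjamini-Hochberg family
(step-up, implemented from its definition); mean spatial overlap is
compared through the same interface. Significance level 0.05.

## The synthetic generator

Each subject is a T x N Gaussian signal matrix (defaults N = 90, T = 142,
matching a 90-parcel atlas and a ~4.7-minute recording at TR = 2 s) with
a block-contiguous five-network partition (SMN/VN/AN/DMN/LSN, shares
0.22/0.13/0.21/0.27/0.17).

**States.** A quasi-periodic sequence of `n_states` connectivity states:
cyclic rotation, each visit lasting uniform [dwell/2, 3 dwell/2] time
points (dwell default 30). A cyclic rotation rather than a free Markov
chain keeps state occupancy balanced within a short recording. Because
the hub thresholds are relative, a state is detectable only against
epochs where it is off; with a single state the engagement epochs
therefore alternate with baseline rest intervals (ground-truth code -1).

**Correlation structure.** Each state's matrix is an explicit factor
model, hence positive semi-definite by construction: one latent factor
per RSN with member loadings sqrt(background_coupling) (default 0.2);
two designated *connector hubs* per state instead load on the foreign RSN
factors — 0.886 x hub_coupling on two primary target networks (primary
pairs unique across hubs so bridges do not compete for the same shortest
paths) and 0.457 x hub_coupling on the rest, at 0.65 of these values
outside their state. Connectors bridge otherwise-independent modules and
so become betweenness hubs while their state is engaged. A connector
coupled uniformly to all other regions — the naive plant — is *not* PSD
(minimum eigenvalue ~ 1 - 0.7 sqrt(89) at N = 90) and after any repair
collapses into a diffuse factor that crowds betweenness out instead of
raising it; this failure mode motivated the bridge design and was
verified numerically.

**Sampling.** z_t = a z_{t-1} + sqrt(1 - a^2) L_{s(t)} eps_t with AR
coefficient a = 0.3, plus independent N(0, noise_sd^2) measurement noise
(noise_sd default 0.5). All randomness flows from per-subject seeds
derived deterministically from the cohort seed.

**Group effect.** The SZ group plants the dysconnectivity phenotype the
schizophrenia graph-theory literature reports — weakened hub dynamics and
reduced network segregation — via two components scaled by
`group_effect` (default 0.5): the epoch-related elevation of connector
loadings is attenuated by 1 - group_effect (the static scaffold is kept:
removing it outright rewires the topology and, counter-intuitively,
*raises* mean betweenness, because losing an exclusive bridge lengthens
shortest paths and spreads betweenness over many intermediate nodes), and
a diffuse global-integration factor (variance share 0.4 x group_effect on
every region) adds the unspecific cross-network coupling of reduced
segregation, shortening paths and lowering mean betweenness. Together
these give SZ < NC in whole-brain BC. At group_effect = 0 the groups are
exchangeable, which the type-I-error validation exploits.

## What the validation shows — and does not

Monte-Carlo experiments (module `dynhubs.validation`, also driven by
`scripts/acceptance.py`):

* **Hub recovery**: at the default conditions, planted connectors pass
  TH1 in ~96% of (seed x hub) events; a handful of *noise candidates*
  (typically 2-10 per subject) appear alongside, driven by frozen
  sampling noise of the static correlation at T = 142 — real recordings
  of this length will show the same.
* **State-count recovery**: the modal per-subject cluster count tracks
  the planted state count only loosely. The per-subject count
  distribution is broad (for 3 states roughly {2: 0.3, 3: 0.4, 4: 0.25}
  across seeds, at any cut in 0.90-0.97), because the relative TH2 makes
  noise candidates sporadically active and their patterns form extra
  small clusters, while chaining through shared members occasionally
  merges two state clusters. In particular a 1-state cohort can never
  yield a single cluster: with no second state there is no contrast, and
  threshold-noise patterns always fragment. The monotone property (more
  planted states never fewer recovered clusters) does hold. Conclusions
  about exact cluster counts on real data should be drawn with the same
  caution.
* **Group effect**: at a scaled cohort (N = 30, T = 60, dwell 12, 20
  subjects per group — sizes chosen to keep hundreds of replicates
  affordable; recovery behaves the same at full size) the whole-brain BC
  comparison detects SZ < NC in ~98% of replicates, with a null rejection
  rate of ~0.04 at alpha = 0.05.

The generator emulates state-switching covariance structure, not real
BOLD: no hemodynamic convolution, scanner drift, motion, physiological
nuisance or spatial autocorrelation. Passing these validations shows the
chain recovers what it is designed to recover under its own assumptions;
it does not certify performance on real recordings.

## Numerical choices

* Leave-one-out variances below 1e-12 x max(1, sum of squares) count as
  degenerate and raise.
* Z-scoring uses sample SD (ddof = 1); constant edges map to all-zero
  z-series.
* Proportional thresholding keeps ties at the cutoff; slices that would
  retain no edge warn and stay empty.
* TH1/TH2 comparisons are strict (ties excluded); both SDs use ddof = 1.
* Cluster cuts are validated to (0, 1); empty-active time points are
  excluded everywhere (SND uses events, so needs no mask).
* BH adjustment caps at 1 and is order-invariant; the RSN family has
  exactly the RSNs present in the region table.
* Pipeline outputs are written with 17 significant digits, making reruns
  byte-identical; wall-clock timings go to a separate `timings.json`.
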