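# Methods

`flysin` re-implements, as a tested pipeline over synthetic data with known
ground truth, a complete group-phenotyping workflow for *Drosophila*:
social interaction networks (SINs) from arena trajectories, locomotor
activity / sleep / circadian period from beam-break monitors, negative
geotaxis, and glutathione/H₂O₂ redox assays, with genotype comparisons on
top. This note records the models, the defaults and why, the numerical
choices, and what the synthetic generators do and do not emulate.

## Social interaction networks

**Interaction criterion.** Fly A interacts toward fly B at a frame when (i)
the centroid distance is at most 2.5 body lengths — with a 2 mm body length,
5 mm — and (ii) B lies inside A's field-of-view cone of 160°, i.e. the
angular offset between A's heading and the A→B bearing is at most 80°.
Maximal runs of consecutive qualifying frames lasting at least 0.6 s
(inclusive; 18 frames at 30 Hz) become directed events. Choices worth
flagging:

* The 160° "facing each other" rule is read as a per-actor half-cone (±80°),
  because edges are directed per actor; the full-angle reading is available
  via `InteractionCriteria(angle_convention="full")`.
* Distance is centroid-to-centroid and the 2.5-body-length threshold is a
  fixed 5 mm, not per-fly morphometry.
* Tracking gaps break runs; bridge them beforehand with
  `trajectory_io.fill_gaps` (default `max_gap_frames = frame_rate/10`).
  The detector is then a pure function of the filled tracks.
* The facing test is evaluated as a projection inequality
  (`d·ĥ ≥ |d|·cos θmax`), which is algebraically identical to the angular
  comparison but avoids per-frame `atan2` calls.

Events aggregate into a directed graph on all flies (isolates kept) with two
edge weights: event `count` and summed `duration_s`.

**Metrics.** Four measures per graph and weight mode, with edge path-distance
`1/weight` (strong ties are short; the convention is the standard one for
interaction-strength weights):

* *global efficiency* — mean over ordered pairs of inverse shortest-path
  distance, unreachable pairs contributing 0;
* *clustering coefficient* — Fagiolo's directed weighted generalization
  (geometric-mean triangle weights, total-degree denominator, weights scaled
  by the graph maximum); nodes with total degree < 2 score 0;
* *betweenness centrality* — shortest-path betweenness normalized by
  (n−1)(n−2);
* *closeness centrality* — incoming-distance closeness with the
  Wasserman–Faust reachability correction, since observed SINs can be
  disconnected (`variant="harmonic"` switchable).

Betweenness, closeness and clustering are computed by networkx on the
distance-annotated graph; weighted global efficiency is implemented here.
The test suite checks all four against an independent brute-force
path-enumeration oracle on every 3-node weighted digraph (4096 graphs,
weights {1,2,3}) and random 4–5-node digraphs, to 1e-9. Exhaustive
enumeration at 5 nodes is combinatorially impossible (≈3²⁰·2²⁰ weighted
structures), so exhaustiveness is claimed at 3 nodes and sampled above.

Local metrics are summarized per recording by their mean over nodes before
z-scoring; per-node values remain available from the metric functions. The
mean is the least-structured summary; nothing downstream depends on it.

**Random-network null and z-scores.** For each experimental group, chimeric
"random networks" are assembled by drawing `group_size` (default 12)
(recording, fly) pairs uniformly without replacement from the pooled flies
of that group's recordings — never all from a single recording (a stricter
all-distinct-recordings mode exists) — overlaying their trajectories in the
common arena frame, and re-running event detection. Interactions in a
chimera can only reflect spatial coincidence, so observed metrics are
normalized as `z = (observed − mean(null)) / sd(null)` with the n−1
standard deviation; a degenerate null (sd = 0) yields z = 0 when the
observation equals the null mean and is flagged undefined otherwise.
Sampling is with replacement across networks. The production default is
10,000 networks per group.

Because non-social (attraction-0) flies are statistically independent, a
chimera is then distributionally identical to a genuine recording, and the
z-scores must be centred on 0. This *null honesty* is the pipeline-level
acceptance property: across 50 replicate runs (10 recordings × 12 flies,
500 networks each) every metric's mean z must stay within ±0.5 and 99% of
scores within |z| < 4.

## Synthetic trajectory generator

A correlated random walk in a 61 mm circular arena: headings receive
Gaussian turning noise per frame, positions advance `speed/frame_rate`
along the heading, and the wall reflects both position and heading
(specularly). Optional sociality pulls each fly's heading toward the
centroid of its planted group-mates by a fraction `attraction_strength ∈
[0, 1]` of the angular offset per frame, before the noise.

Defaults: frame rate 30 Hz (typical tracking-camera rate; the 0.6 s minimum
spans 18 frames), walking speed 5 mm/s and turning noise 0.2 rad/frame —
unhurried exploratory walking that makes chance 5 mm encounters last long
enough for null networks to be non-degenerate (a few dozen events per
60 s recording of 12 flies). Recordings used in the tests and in
`scripts/acceptance.py` are 60 s (30 s for the 10,000-network smoke run);
z-score calibration and the direction of the planted sociality effect are
invariant to recording length, which only scales edge density. The
generator makes no claim of behavioral realism beyond the statistical
structure the pipeline assumes: no wall-following, no collision avoidance,
no bouts of running and stopping, no courtship or aggression structure. A
passing null-honesty test therefore certifies the *pipeline's* calibration
under exchangeability, not the realism of fly motion.

With `attraction_strength = 0` flies are exactly independent (the null).
With attraction, chimeric groups — whose members were attracted to absent
group-mates — interact less than genuine groups, so clustering z rises with
attraction; this is the planted effect the recovery test checks, in the
same direction as reduced-sociality genotypes scoring lower clustering z.

## Activity, sleep, circadian period

Activity is beam-break counts per minute. The generator modulates a Poisson
rate by a circadian profile with Gaussian peaks (width 1.5 h) at the
morning (08:00) and evening (20:00) phase marks, a midday siesta dip
(`siesta_depth`, default 0.6), and a quiescent night (15% of daytime
baseline), normalized to mean 1 so `mean_counts_per_min` (default 2) is the
overall rate. For periods other than 24 h the profile is a function of
circadian phase, so the whole pattern compresses or dilates. Sleep bouts
are *planted*, not emergent: Poisson-many forced-zero windows
(exponentially distributed length, mean 20 min, minimum 6 min, disjoint and
non-adjacent) whose flanking minutes are forced nonzero, so the ground
truth bout boundaries are exact by construction.

Phase summaries average per-minute counts over [08:00, 20:00) (light) and
[20:00, 08:00) (dark) across complete civil days only; incomplete first and
last days are excluded to avoid partial-phase bias.

Sleep is a maximal zero run *strictly longer than* 5 minutes — a 5-minute
run is wakefulness, a 6-minute run is sleep — matching the
arousal-threshold-validated criterion; the common ≥ 5 convention is a
switch. Bouts spanning a phase boundary are attributed minute by minute,
which is the exact proportional split.

The free-running period of constant-darkness series is estimated with the
Sokolove–Bushell chi-square periodogram on a 16–32 h grid at 0.1 h steps
(integer minutes at every grid point): the series is folded at each
candidate period, and the between-column variance statistic Qp is referred
to χ²(columns − 1). The significance line is Bonferroni-corrected for the
number of candidate periods so that rhythmless series are non-significant
at the stated α (default 0.01) overall. The reported period maximizes
Qp minus its significance line, which removes the trivial growth of Qp
with column count; an autocorrelation estimator with parabolic peak
refinement is the switchable alternative. On 5-day series at the
generator's default noise, planted periods 20–28 h are recovered within
±0.2 h (the acceptance band is ±0.25 h).

## Geotaxis

A trial's score is `100 · n_climbed / n_flies` (flies crossing 5 cm within
5 s). A group's score is the mean over its (five) trials; the genotype
summary is mean ± SEM over group scores, so the group — not the trial — is
the unit of replication (`scheme="pooled"` switches this, since published
descriptions of such designs are sometimes ambiguous about the replication
unit).

## Redox

The calibration is an OLS line A415 = slope·conc + intercept on ≥ 3 distinct
GSH standards; constant readings flag the assay (R² undefined) rather than
erroring. Concentrations are back-calculated by inversion; negative values
are clipped to 0 with a warning (plate noise near zero), and
GSSG = (total − free)/2 because borohydride reduction converts each GSSG to
two GSH before the DTNB reaction. If total < free the record is flagged and
GSSG clipped at 0; the identity is asserted exactly on every unflagged
record. DHE fluorescence is reported only as blank-corrected values and
fold-change against the control group mean — DHE is an indirect probe and
no absolute H₂O₂ concentration is claimed.

## Group statistics

For each measure, a variance-homogeneity gate (Brown–Forsythe by default;
Bartlett switchable) decides the branch at α = 0.05: homogeneous → one-way
ANOVA with Tukey's HSD; heterogeneous → Kruskal–Wallis with Dunn's test,
Holm-adjusted. Such gates are often loosely called normality checks; they
test variance homogeneity, and an optional Shapiro–Wilk add-on exists for
actual normality. Dunn's test is implemented in-package (rank-based z with
the standard tie correction) since no installed library provides it; Holm
adjustment comes from statsmodels. Post hocs are reported when the omnibus
p < α (configurable). Under null simulations (3 normal groups × 10), each
branch's omnibus type-I error must fall in [3%, 7%] at α = 0.05 over 1,000
replicates. Degenerate inputs (all groups constant) are flagged and not
tested.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy `default_rng` /
`SeedSequence`); the pipeline runner derives per-stage seeds from the run
seed and writes CSVs with fixed float formatting, so repeated runs are
byte-identical — asserted file-by-file in the acceptance suite. Problem
sizes in the test suite (60 s recordings, 500-network nulls in the
replicated honesty runs, 1,000-network nulls in the analysis scripts,
10,000 in the smoke run) are the package's own scaling choices for a
desk-scale validation; all are configurable up to the production sizes.

## Known limitations

* The trajectory model is statistical, not behavioral; effect sizes
  measured on it do not transfer to real flies.
* With planted attraction the group's meeting point wanders from recording
  to recording, and the chimeric null inherits that spatial
  nonstationarity; z-scores of weakly attracted groups therefore carry
  substantial recording-set-level variance when few recordings feed the
  null. Real arenas, where flies aggregate at fixed features, are less
  affected; interpret weak-attraction simulations accordingly.
* The group size default is 12 flies per arena (configurable); upstream
  descriptions of comparable experiments vary between 12 and 20 flies per
  recording, so `n_flies` is always taken from the data/config.
* Which clustering/closeness variants a given published analysis used is
  rarely stated; the defaults here (Fagiolo, Wasserman–Faust) are declared
  in output metadata and switchable, not asserted as anyone else's choice.
* Whether z-scoring should apply to global metrics, node-level means, or
  individual nodes is likewise under-specified in the field; this package
  z-scores the per-recording summaries and also exposes per-node values.
* The DAMS-style monitor reader covers the common tab-separated layout
  (metadata columns then one count column per channel) and a simplified
  CSV dialect; exotic monitor firmware layouts need a column-map.
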