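# Methods

## Model and procedure

The package stratifies a cohort of subjects by three physical parameters —
age (years), weight (kg), height (m) — and relates the strata to tibial
rotation pathology. Two deterministic rules define the ground truth:

* **Rule clusters.** C1: age strictly above 30 years. Among the rest,
  C2: weight at most 60 kg, C3: weight above 60 kg. Height is accepted by
  the rule's interface but does not enter the decision: in the population
  the rule was designed for, the 60 kg and 1.70 m thresholds select nearly
  the same subjects, so weight alone is authoritative and conflicting
  weight/height combinations resolve by weight.
* **Rotation types.** Per angle θ (degrees): type 1 (pathological) on
  [0, 20], type 2 (normal) on (20, 65], type 3 (pathological) on (65, ∞).
  Both boundary closures follow from the stated "≤ 20°" and "> 65°"; the
  middle interval is what remains.

An unsupervised clustering of the physical features is then scored against
these rules, per rotation (RTER, RTIR, LTER, LTIR).

### K-means

Lloyd's iteration on squared Euclidean distance: assign each point to its
nearest centroid (ties to the lowest index, deterministically), move each
centroid to its cluster mean, repeat. The SSE is non-increasing across
iterations and the run stops when the assignment is stable, the relative
SSE improvement falls below `tol` (default 1e−6), or `max_iter` (default
300) is reached. Initialization picks k distinct data points uniformly at
random under the given seed. A cluster emptied by an assignment step is
repaired by re-seeding its centroid at the point currently farthest from
its nearest centroid — the globally worst-fit point — which cannot
increase the SSE.

### Particle swarm

Minimization only. Per particle and iteration:

    V ← w·V + c1·r1·(Pbest − X) + c2·r2·(Gbest − X),   X ← X + V

Defaults: inertia w = 0.73, c1 = c2 = 1.49, 30 iterations, 30 particles —
the values the swarm-optimization literature established empirically for
this update rule (the iteration count sits at the upper end of the usual
20–30). r1 and r2 are scalars drawn fresh per particle per iteration; a
per-dimension variant is available behind `per_dimension_r`. Velocities
start at zero and are clamped componentwise to ±`v_max_fraction` (default
0.5) of the bound width. A position leaving the search box is reflected
back inside and the offending velocity component negated. Personal bests
update on strict improvement; the global best is the best personal best,
so its fitness history is non-increasing by construction. The stopping
rule is the fixed iteration count. With a fixed seed the full trajectory is
bit-reproducible (one `numpy` Generator drives initialization and all r
draws).

### The hybrid (PSO-KM)

A particle position is the row-major flattening of a candidate (k, dim)
centroid matrix; the fitness is the clustering SSE; the box bounds are the
per-feature data ranges tiled k times. After the swarm finishes, its best
centroid set initializes a single K-means run and that refined partition is
returned. Hybridization order (global swarm search, then local refinement)
is the standard scheme in the hybrid-clustering literature; refinement
never increases the SSE, so the hybrid's final SSE is at most the swarm's.

### Feature scaling

Clustering operates on column-wise z-scores of (age, weight, height) by
default (`scaling="raw"` is available). Raw Euclidean distance would be
dominated by weight (range ≈ 50 kg) and ignore height (range ≈ 0.4 m).

### Evaluation arithmetic

Predicted clusters are identified with rule clusters by maximum-overlap
bijection (optimal assignment on the 3×3 contingency matrix, via the
Hungarian algorithm). Then, per rotation:

* success rate per cluster = 100·min/max of the real and predicted cluster
  sizes;
* type rate = a type's percentage share of its cluster;
* general accuracy = 100·min/max of the real and predicted type rates,
  computed **from the two-decimal rounded rates** — the summary tables this
  arithmetic mirrors chain their percentages that way (e.g. the printed
  44.14 equals 1.92/4.35 but not (1/52)/(2/46));
* Rand index = fraction of subject pairs on which the partition and the
  rule labels agree (both together or both apart), computed from the
  contingency matrix in closed form.

All percentages round half-up to two decimals. Undefined ratios (empty
cluster; a zero rate inside an accuracy) are reported as `None`, the
machine equivalent of a printed dash. One published cell is internally
inconsistent: the type-2 share of 218/239 prints as 91.22 although the
quotient is 91.21, so the chained accuracy from raw counts is 95.99 where
the published chain gives 95.98. The tests pin both facts.

## Synthetic data

The original 484-subject cohort is not deposited, so the generator emulates
its structure rather than its joint distribution:

* exact group sizes 52/249/183 (defaults), each subject's (age, weight,
  height) drawn uniformly inside its group's defining ranges, so the rule
  recovers every generating group label by construction. The default
  ranges — C1 age (31, 60); C2/C3 age (18, 30); C2 weight (45, 60], C3
  weight (60.5, 95); heights tied to the weight split at 1.70 m — respect
  the published thresholds but are otherwise conventions: only the
  thresholds are known.
* rotation types drawn i.i.d. per rotation at the published cohort
  proportions (e.g. 51/414/19 out of 484 for LTIR); the type-1/2/3 counts
  for RTER use the per-cluster table sums (39/391/54), the only value
  consistent with the cohort size. Angles are uniform inside their type's
  band — [5, 20], (20, 65], (65, 90] — with truncated Gaussian jitter
  (`noise_sd`, default 1°) kept inside the band; open band edges stay
  0.01° inside because angles are emitted at two-decimal precision.
* a single seeded `numpy` Generator per call; identical seeds give
  byte-identical cohorts.

What passing tests therefore show: the engines, the rule systems and the
evaluation arithmetic are correct, and the hybrid recovers cluster
structure that is present in the features. What they do not show: anything
about the real cohort's joint distribution (age–weight correlation, the
actual overlap between groups), so numeric results on synthetic cohorts —
Rand indices, success rates — are not estimates of the published ones.

`separated_cohort_config()` narrows the group ranges to compact,
well-separated blobs; there the rule clusters coincide with the unique
3-means optimum, so exact recovery (Rand index 1.0) is the correct outcome
and any miss is an engine defect.

`generate_mixture` draws isotropic Gaussian blobs for engine recovery
tests. The directional-validity benchmark uses one diffuse and two tight
components (means (0,0)/(5,0)/(0,5), spreads 1.5/0.6/0.6, sizes
120/20/20): single-start Lloyd regularly merges the two tight components —
the local-minimum failure the swarm hybrid exists to correct — so the
hybrid's mean Rand advantage is consistently positive there. On balanced
equal-spread mixtures single-start Lloyd almost always finds the global
optimum and the two algorithms tie to within seed noise; that regime would
test nothing.

## Numerical choices

* distances: squared Euclidean throughout; assignment ties to the lowest
  centroid index.
* percentages: decimal half-up rounding to 2 places (`decimal` module), not
  banker's rounding.
* K-means tolerance 1e−6 relative SSE change; swarm stops on iteration
  count alone.
* degenerate inputs: k larger than the number of distinct points is an
  error; constant features standardize to zero; a constant-feature search
  box is widened by 1e−9 so the swarm's bounds stay valid; non-finite
  fitness aborts the swarm with a diagnostic.
* problem sizes in the checks: recovery runs use the full 484-subject
  cohort; enumeration oracles run on ≤ 10 points (3^n assignments); the
  paired comparison uses 30 seeds × 160-point mixtures.

## Known limitations

* The hybrid's advantage over restarted (rather than single-start) K-means
  is not claimed and not tested; with enough restarts Lloyd reaches the
  same optima on these problems.
* The generator's uniform within-group marginals are placeholders; no
  age–weight dependence is modeled.
* Rule clusters are axis-aligned boxes, not Voronoi cells; on cohorts with
  overlapping group ranges even the optimal 3-means partition cannot match
  the rules exactly, so sub-1.0 Rand indices there reflect the geometry,
  not an engine defect.
* No selection of k (fixed at 3 by the study design); no validity indices
  beyond the plain Rand index.
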