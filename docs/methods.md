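# Methods

## The question and the design

Transgenerational environmental effects are hard to study directly: the
exposed generation (grandparents, parents) and the affected generation
(children with a diagnosis) are separated by decades. One exploratory design
sidesteps exposure measurement entirely: if ancestors of affected children
shared the same *places at the same times* more than ancestors of matched
unaffected children did, whatever was present at those places and times
becomes a candidate exposure. Operationally this is a case/non-case
space-time cluster detection problem in which the "case" label belongs to
the descendant but the point locations belong to the ancestor.

The design scans 18 separate models: six ancestor roles (mother, father, and
the four grandparents, splitting maternal from paternal transmission lines)
crossed with three vulnerable developmental windows of the ancestor's own
life — birth/infancy (ages 0–1), childhood (2–11) and adolescence (12–17).
Each model asks: did the ancestors of case children, during that window of
their lives, cluster in space and time relative to the ancestors of matched
control children?

## The scan statistic

Within one stratum of N dated points (one per ancestor, of which C carry the
case label), candidate clusters are elliptic cylinders: a spatial ellipse
(center, semi-major axis a, axis ratio s, orientation θ) crossed with an
inclusive calendar-year interval. For a cylinder containing n points and c
cases, the Bernoulli-model log-likelihood ratio against the exchangeable
null is

    LLR = c ln(c/n) + (n−c) ln((n−c)/n)
        + (C−c) ln((C−c)/(N−n)) + (N−n−C+c) ln((N−n−C+c)/(N−n))
        − [C ln(C/N) + (N−C) ln((N−C)/N)],     with 0 ln 0 = 0.

The most likely cluster maximizes the LLR over all candidates; the cluster
is high-rate when c/n exceeds the outside proportion, low-rate otherwise
(both directions are scanned by default, because case-depleted regions are
findings too). The reported relative risk is the inside risk over the
outside risk, (c/n) / ((C−c)/(N−n)), equivalently (c/e)/((C−c)/(C−e)) with
e = nC/N.

Inference is by Monte Carlo: the C case labels are permuted uniformly over
the N fixed points R times (default R = 999), the maximum LLR is recomputed
each time over the same candidate set, and

    p = (1 + #{replicate max ≥ observed}) / (1 + R).

Because every reported cluster is compared against the null distribution of
the *maximum*, secondary clusters receive valid (conservative) p-values.
With 18 models, each cluster's p-value additionally gets a textbook
Bonferroni adjustment p_adj = min(1, 18·p).

### Candidate windows

Spatial windows are centered on every distinct subject location. For each
(shape, angle) pair in the configured grid (defaults s ∈ {1, 1.5, 2, 3, 4, 5}
with {1, 4, 6, 9, 12, 15} evenly spaced orientations), the window grows
through the inter-point distances in that ellipse's metric, emitting each
successive prefix set until it would hold more than half the subjects.
Windows are deduplicated by member set. Each spatial window is crossed with
every year interval up to half the stratum's year span. Boundary points are
inside (closed ellipse, with 1e-9 relative slack so re-derived arithmetic
agrees); year intervals are inclusive on both ends.

Three deterministic thinning knobs keep large strata at desk scale:
`max_centers` (evenly strided subsample of sorted distinct locations),
`n_size_steps` (evenly spaced subset of the growth radii) and
`time_agg_years` (calendar years aggregated into fixed-width bins before
temporal scanning, as in standard space-time scan practice). Thinning
changes the candidate set, never the validity of the Monte Carlo p-values,
which are computed conditionally on whatever grid is used; what it trades
away is detection resolution. The full enumeration (defaults) is what the
brute-force oracle tests compare against.

### Secondary clusters

Clusters are reported greedily down the LLR ranking; a candidate is reported
only if its spatial ellipse does not intersect the ellipse of any
already-reported cluster (temporal overlap is allowed). Ties in LLR break
toward smaller n, then lexicographic center. Intersection is tested on
64-segment polygonal approximations of the ellipses. Since every year
interval of one spatial window shares its ellipse, greedy selection over
windows' best intervals is exactly greedy selection over all candidates.

### Numerical notes

* LLR values are computed from a k ln k lookup table over integer counts;
  the same table serves the observed statistic and the permutation
  replicates so that ties compare exactly (mixing two arithmetic paths that
  differ by ~1e-13 was measurably anti-conservative at small N before this
  was unified).
* |LLR| < 1e-10 is snapped to exactly 0 (proportional windows).
* Replicate label streams are derived from (seed, replicate index), so
  serial and blocked execution agree bit for bit; per-stratum seeds are
  derived from (master seed, role index, window index) and recorded in the
  run metadata for exact replay.

## The synthetic cohort generator

The registry data the design was built for (a statewide autism registry
linked to a population database with residential histories) is restricted,
so the package ships a generator that emulates its statistical structure:

* case children born 1989–2014; controls cloned 2:1 with identical
  (birth year, sex) — matching is constructive and cannot fail. Child sex
  skews 4:1 male (the diagnosed population's skew); matching makes results
  insensitive to this value.
* six ancestors per child, with integer generation gaps uniform on
  [18, 40] years (parents relative to the child, grandparents relative to
  the relevant parent);
* one residential point per ancestor per window, dated uniformly within the
  window's age span (the design needs one representative dated point per
  window; how a single residence would be chosen from multiple real records
  is a linkage question out of scope here);
* locations drawn from a mixture: with probability `p_urban` (default 0.8) a
  Gaussian urban center (four centers in a north-south line inside a
  200 × 300 km box, spreads 5–7 km — an intermountain-corridor-like
  geography), else uniform background. Consecutive windows reuse the
  previous location with probability `p_stay` (default 0.6, reflecting that
  many subjects in such cohorts do not move between early windows);
* each (ancestor, window) record exists independently with probability
  `p_link` (default 0.9, the typical residential-linkage completeness).

Ground-truth clusters are *planted by relocation*: with probability
`attraction`, a case ancestor of the target role/window is moved to a point
uniform in the planted ellipse and its year redrawn uniformly in the planted
year range. Relocation preserves the marginal 2:1 case:control ratio
exactly, unlike label flipping. Attracting controls instead produces a
case-depleted (low-rate) region. `attraction = 0` is exactly the null model.

What the generator does **not** emulate: real geocoding error structure
(beyond the jitter analysis), address quality differences between urban and
rural records, family relatedness between different children, secular
migration trends, or any dependence of the case label on location (labels
are assigned by design, then planted clusters move people). Passing tests
therefore demonstrate the *detection machinery* works at the stated effect
sizes and sampling structure — not that any particular real-world cluster
is real.

## Experiments (and the problem sizes used)

The experiment drivers in `transgen_scan.experiments` are shared by the test
suite and `scripts/acceptance.py`:

* **Type-I calibration** — 200 independent null cohorts (100 case children
  → 18 strata of ≈270 subjects each), full 18-model studies at R = 99 on a
  thinned circular grid. Measured: fraction of scanned strata whose
  most-likely cluster has p ≤ 0.05 (expected near, and in practice slightly
  below, 0.05 — the max-LLR distribution is discrete, ties make the test
  conservative), and the fraction of cohorts with any Bonferroni-adjusted
  p < 0.05 (should be well under 0.10).
* **High-rate recovery** — planted ellipse (12 × 8 km, 1945–1955) in the
  paternal-grandmother birth stratum at ≈1,600 subjects; `attraction = 0.24`
  was calibrated so the realized inside/outside risk ratio is ≈2.9, the
  magnitude of the strongest clusters this design is meant to find. 50
  seeded generate-and-scan runs; detection = a significant (p ≤ 0.05)
  high-rate cluster whose ellipse contains the planted center with
  overlapping years. The recovered cluster's RR is compared with the
  empirical ratio counted directly from the generated labels.
* **Low-rate recovery** — same geometry, `attraction = 0.12` applied to
  controls, realized risk ratio ≈0.3; detection of a significant
  direction=low cluster.
* **Jitter sensitivity** — every point displaced exactly 10 m in an
  independent uniform direction, full re-run, and a persistence check
  (re-run cluster in the same stratum containing the original center with
  overlapping years). 10 m is three orders of magnitude below the planted
  cluster scale, so persistence is expected; sub-10 m "clusters" may
  legitimately fail and are flagged rather than treated as errors.
* **Determinism** — two full generate+study runs from one master seed must
  render byte-identical cluster tables.

## Post-hoc analyses

* **Overlap** («cohort effect»): for clusters A and B, the fraction of A's
  members whose location lies inside B's spatial *ellipse* (time
  deliberately ignored). The quantity is directional; both directions are
  reported, since "X% shared membership" is otherwise ambiguous.
* **Moran's I diagnostic**: records gridded to square cells (default 1 km),
  cell value = case fraction, rook contiguity, permutation p-value from
  shuffling cell values (two-sided around E[I] = −1/(n−1)). The design this
  package follows checks residential data for spatial autocorrelation
  before trusting density-driven clusters but does not name a method;
  Moran's I is this package's explicit, clearly-labeled choice of
  diagnostic.

## Known limitations

* The elliptic grid applies no non-compactness penalty, so very elongated
  windows can win narrowly; the default shape set stops at ratio 5.
* Candidate thinning (`max_centers`, `n_size_steps`, `time_agg_years`)
  reduces spatial/temporal resolution of reported boundaries; reported year
  ranges are bin-aligned when `time_agg_years > 1`.
* The maximum-LLR cluster's RR is a winner's-curse-prone estimate; in the
  recovery experiments it lands within ~10% of the planted truth, but that
  is at a strong, well-separated signal.
* Monte Carlo p-values have granularity 1/(R+1); with R = 99 the smallest
  attainable p is 0.01.
* The Bonferroni factor m = 18 treats models as the testing unit. Whether
  that matches the original analysis could not be established (the printed
  adjusted values there are smaller than the raw p-values, which no
  standard Bonferroni produces), so the textbook correction is used.
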