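# transgen-scan

Space-time cluster detection for **transgenerational** case-control designs:
a Bernoulli (case/non-case) scan statistic over elliptic space-time cylinder
windows with Monte Carlo permutation inference, run across 18 ancestor
strata — six ancestor roles (mother, father, maternal/paternal grandmothers
and grandfathers) × three vulnerable developmental windows of the ancestor's
life (birth 0–1 y, childhood 2–11 y, adolescence 12–17 y).

The intended user is an epidemiologist exploring whether the ancestors of
affected children shared residential space and time more (or less) than the
ancestors of matched controls — a hypothesis-generating signal for
environmental exposures acting one or two generations upstream of a
diagnosis. Because the registry data such designs run on are restricted, the
package includes a synthetic multigenerational cohort generator that
reproduces their statistical structure (2:1 exact age/sex matching, six
ancestors per child, ~90% record linkage, residential persistence between
windows, urban/rural mixed point density) and can plant ground-truth risk
regions for validation.

## The statistic

For a cylinder (spatial ellipse × year interval) holding n of the stratum's
N subjects and c of its C cases, the Bernoulli scan log-likelihood ratio is

    LLR = c ln(c/n) + (n−c) ln((n−c)/n)
        + (C−c) ln((C−c)/(N−n)) + (N−n−C+c) ln((N−n−C+c)/(N−n))
        − [C ln(C/N) + (N−C) ln((N−C)/N)],      0 ln 0 = 0,

maximized over all candidate cylinders. Significance comes from R uniform
permutations of the case labels (p = (1 + #{replicate max ≥ observed}) /
(1 + R), default R = 999), a Bonferroni factor of 18 accounts for the
multiple models, and each cluster reports RR = risk inside / risk outside.
Secondary clusters are reported greedily down the LLR ranking when their
ellipse does not overlap a better cluster's. See `docs/methods.md` for the
full model description.

## Worked example

The numbered scripts under `analysis/` run a complete demonstration study
and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_run_study.py
python analysis/03_overlap_and_jitter.py
python analysis/04_calibration_summary.py
```

`01` generates a 300-case cohort (900 children, 5,400 ancestors) with a
known risk region planted in the paternal-grandmother birth stratum — an
urban 12 × 8 km ellipse during 1945–1955 into which 24% of case paternal
grandmothers are relocated:

```
children: 900 (300 cases, 2:1 matched)
ancestors: 5400; residential records: 14553
planted cylinder (paternal_grandmother/birth, 1945-1955): 89/103 cases inside vs
180/713 outside -> empirical risk ratio 3.42
```

`02` scans all 18 strata (999 permutations each) and recovers exactly that
cluster — the only Bonferroni-significant one — with an estimated RR close
to the planted truth:

```
scanned 18 strata; 90 clusters reported
1 cluster(s) Bonferroni-significant (m = 18):
                  cluster_id  year_start  year_end  observed  expected       rr direction  p_mc  p_bonf   area_km2
paternal_grandmother:birth:1        1944      1968        99 42.525735 3.101368      high 0.001   0.018 491.655557
```

Reading the row: 99 cases observed inside the cylinder where 42.5 were
expected, relative risk 3.1, Monte Carlo p = 0.001 (the minimum attainable
at R = 999), Bonferroni-adjusted p = 0.018, ellipse area 492 km².

`03` reports membership overlap between clusters (the "cohort effect":
people who did not move appear in clusters of consecutive windows —
150 same-lineage cross-window pairs share ≥ 25% membership in this run),
re-runs the study after displacing every point 10 m in a random direction
(`jitter 10 m: 77/90 clusters persist`, including the planted one), and
computes a Moran's I spatial-autocorrelation diagnostic
(`I = 0.0098, permutation p = 0.688`).

The same machinery is available as a command line:

```
transgen-scan simulate --config run.yaml --out sim/ --seed 4
transgen-scan pipeline --in sim/subjects.csv --config run.yaml --seed 4 --out study/
transgen-scan jitter   --in sim/subjects.csv --config run.yaml --d 10 --seed 4
transgen-scan diagnose-sac --in sim/subjects.csv --cell 1000
```

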