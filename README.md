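# asgroups

Ecological-group partitioning and assembly-process inference for microbiome
OTU tables, built for multi-site amplicon surveys such as activated-sludge
communities sampled across wastewater treatment plants.

Microbial communities are not homogeneous: a few taxa are widespread and
locally abundant (**core**), many are rare and patchy (**satellite**), some
occur across more sites than chance allows (**habitat generalists**) and some
across fewer (**habitat specialists**). These groups need not be assembled by
the same forces — environmental filtering (deterministic, niche) versus
dispersal and drift (stochastic, neutral). `asgroups` classifies taxa into
these groups and quantifies each group's assembly mode, all from a plain
OTU-by-sample count table.

## Methods at a glance

* **Core / satellite** — per-OTU chi-squared test of the index of
  dispersion across the *n* samples. The default statistic is
  *D* = (s² / x̄) · occupancy (with a `classic` option
  *D* = (n−1)·s²/x̄, whose Poisson null is exactly χ²ₙ₋₁). OTUs with *D*
  inside the central 95% χ²ₙ₋₁ band are randomly placed; over-dispersed OTUs
  occupying ≥ 50% of samples are core, the rest satellite.
* **Generalist / specialist** — each OTU's observed occurrence is compared
  with its occurrence over 1,000 **quasiswap** null tables, which preserve
  row sums, column sums *and* the number of occupied cells. Occurrence above
  the null's 97.5th percentile → generalist; below the 2.5th → specialist.
  (Levins' niche breadth *B* = 1/Σpᵢ² is available as an alternative metric.)
* **β-null deviation** — per group, observed mean Bray–Curtis dissimilarity
  minus its expectation over 999 null metacommunities that keep every
  sample's community size and the regional species-abundance distribution
  but randomize composition. Values near zero ⇒ stochastic assembly; values
  away from zero ⇒ deterministic assembly. Group contrasts use the Wilcoxon
  rank-sum test.
* **Supporting statistics** — rarefaction, Hellinger transform, PERMANOVA
  (adonis), ANOSIM, MRPP, Mantel, PCoA, abundance–occupancy regression and
  per-group taxon composition.

A seeded synthetic-metacommunity generator (lognormal regional pool;
neutral multinomial sampling or Gaussian niche filtering along an
environmental axis; plantable ground-truth core/satellite/generalist/
specialist rows) provides data with known answers for every stage.

## Worked example

```python
import asgroups as ag

scen = ag.SyntheticScenario(n_otus=300, n_samples=13, reads_per_sample=7000,
                            assembly_mode="niche", niche_sd=0.15, seed=7)
table = ag.simulate_metacommunity(scen)
table, truth = ag.plant_group_structure(table, seed=8)
table = ag.rarefy(table, depth=7000, seed=9)

disp = ag.core_satellite(table)
occ = ag.generalist_specialist(table, n_null=1000, seed=10)
assignment = ag.assign_groups(table, disp, occ)
print("group counts:", assignment.group_counts)

core = ag.beta_null_deviation(table, sorted(assignment.group_members["core"]),
                              n_null=999, seed=11, group_label="core")
sat = ag.beta_null_deviation(table, sorted(assignment.group_members["satellite"]),
                             n_null=999, seed=12, group_label="satellite")
print(f"core beta-null deviation:      {core.deviation_mean:+.3f}")
print(f"satellite beta-null deviation: {sat.deviation_mean:+.3f}")
cmp = ag.compare_group_deviations(core, sat)
print(f"Wilcoxon core vs satellite: W={cmp['statistic']:.0f}, p={cmp['p_value']:.2e}")
```

prints

```
group counts: {'core': 184, 'satellite': 129, 'generalist': 21, 'specialist': 40}
core beta-null deviation:      +0.532
satellite beta-null deviation: +0.266
Wilcoxon core vs satellite: W=8025, p=1.59e-11
```

This niche-assembled community yields many over-dispersed (core) OTUs, and
the core group's β-null deviation sits far from zero — deterministic
assembly — and significantly above the satellite group's, the expected
contrast when environmental filtering structures the abundant taxa while
rare taxa look closer to random draws from the regional pool.

The same analyses are scriptable from the shell:

```bash
asgroups simulate --mode niche --samples 13 --otus 300 --depth 7000 --seed 7 \
    --out table.tsv --truth truth.tsv
asgroups partition --table table.tsv --n-null 1000 --seed 10 --out-dir out/
asgroups nullbeta --table table.tsv --labels out/labels.tsv --group core \
    --n-null 999 --seed 11 --out core_dev.tsv
asgroups pipeline --config run.yaml        # full run with a JSON manifest
```

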