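# wrepscan

Discovery of W-chromosome-enriched repeats from low-coverage male/female
short-read data, with a synthetic-genome simulator that makes every stage
of the analysis verifiable against planted ground truth.

In female-heterogametic (WZ/ZZ) systems such as Lepidoptera, the
female-limited W chromosome is repeat-rich, non-recombining, and nearly
absent from chromosome-level assemblies. A cheap and effective way to study
its composition is comparative repeatome profiling: sequence a few males
and a few females at very low coverage, cluster the pooled reads into
repeat families by sequence overlap, and look for clusters that are
significantly over-represented in females. `wrepscan` implements that
workflow end to end for researchers in comparative genomics and
cytogenetics who want a transparent, scriptable, fully testable version of
the analysis — including the downstream coverage arithmetic that turns
mapped read depth into copy numbers and internal-deletion calls.

## The method

**Read preparation.** Reads from each individual are cropped to a fixed
length L (default 140 bp), subsampled to the same number n per individual
(default 100,000), tagged with a per-individual read-name prefix, and
pooled.

**Clustering.** A graph is built over the pooled reads with an edge
between two reads whenever their canonical k-mer sets share at least
*m* k-mers (defaults k = 13, m = 20, which on 140-bp reads tolerates
roughly 8–10% pairwise divergence — the emulation of a ~90% read-joining
identity criterion). Connected components of this graph are the read
clusters; each cluster's per-individual read count divided by n, times
100, is its *genome percent* — the fraction of that individual's genome
attributed to the repeat family.

**Enrichment testing.** For each cluster holding at least 0.01% of the
pooled reads, female and male genome percents are compared with Welch's
unequal-variance t-test:

    t = (x̄_F − x̄_M) / √(s²_F/n_F + s²_M/n_M),

with Welch–Satterthwaite degrees of freedom and two-sided P. The
enrichment ratio E = x̄_F / x̄_M is always computed from raw counts. The
empirical false-positive cutoff r_max is the largest male-over-female
enrichment among significantly *male*-enriched clusters — the observed
ceiling of spurious enrichment under the null that no repeat is truly
male-enriched; significant female-enriched clusters with E > r_max are the
putative W repeats. Their "average enrichment" is the geometric mean.

**Coverage analysis.** Reads are mapped to a repeat consensus by exact
k-mer seeding and per-diagonal extension, retained at ≥95% identity over
at least half the read. Copy number is element fold-coverage divided by
genome fold-coverage (total read bases / genome size), rounded half-down.
A localized coverage drop over an internal region yields the fraction and
number of copies carrying an internal deletion; carrier copies are the
difference of the rounded copy numbers outside and inside the region.

**Simulation.** `wrepscan.simgenome` builds WZ/ZZ genomes with repeat
families planted at known per-compartment copy numbers (optionally with a
deletion variant in a set fraction of W copies), records every insert in a
truth manifest, and simulates per-individual reads from the diploid
complement — which reproduces the real dosage effect that a W-limited
repeat is covered at about half the per-copy depth of a diploid locus.

## Worked example

The copy-number arithmetic on the published coverage measurements:

```python
>>> from wrepscan import covmap, report
>>> covmap.estimate_copies(774.6, 2.38).copies   # LINE-like, females
325
>>> covmap.estimate_copies(39.2, 2.24).copies    # LINE-like, males
17
>>> covmap.fold_difference(325, 17)
19
>>> covmap.call_deletion(698.5, 840.0, genome_coverage=2.38)
DeletionCall(region=(0, 0), coverage_inside=698.5, coverage_outside=840.0,
             drop_percent=17, carrier_copies=60)
>>> report.pg_to_mb(0.646)
631
```

Reading: at 2.38× female genome coverage, 774.6× element coverage means
~325 copies per haploid genome equivalent; the deleted region's coverage
drop from 840× to 698.5× means 60 of 353 copies (17%) carry the deletion;
a 0.646 pg C-value is 631 Mb.

A full synthetic run (config in `tests/test_cli.py` style, two W families
planted in a 2 Mb genome, three individuals per sex at 0.77× simulated
depth, 800 reads sampled per individual):

```
$ wrepscan run --config example.yaml --out out --seed 7
899 clusters, 4 putative W repeats; report in out
$ cat out/summary.txt
...
clusters: 899 retained, clustered fraction of pool 0.4673

putative W-enriched repeats
  selected clusters: 4
  empirical cutoff r_max: 6.00
  enrichment: geometric mean 24.39, maximum 116.00

copy-number estimates (element coverage / genome coverage)
  belpao_like [F]: 101.0x / 2.16x = 46.83 -> 47 copies
  ...
recovery vs planted truth (haploid-equivalent copies)
  belpao_like [F]: planted equivalent 54.1, estimated 46.8
  ...
```

The two large selected clusters are the two planted families; the
estimates recover the planted (dosage-adjusted) copy numbers, with the
expected downward bias for short monomers discussed in
`docs/methods.md`.

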