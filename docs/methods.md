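# Methods

This note records the models, conventions, and design choices behind
`wrepscan`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, and what the synthetic validation
does and does not demonstrate.

## Study design being modelled

The pipeline targets a comparative repeatome experiment in a
female-heterogametic (WZ/ZZ) species: a few individuals per sex (default
3 + 3) sequenced at sub-1× depth, reads cropped to 140 bp and subsampled
to an equal count per individual (default 100,000, about 0.02× of a
631 Mb genome), pooled, clustered into repeat families, and screened for
female-biased abundance. A repeat consensus of interest is then profiled
by read mapping at 95% identity to estimate copy numbers and
deletion-variant fractions. Defaults throughout the package are these
reference conditions.

## Synthetic genomes and reads

`simgenome` builds one autosomal, one Z and one W compartment sized by
`genome_size_bp`, `w_fraction` and `z_fraction`. Background sequence is
i.i.d. nucleotides at a configurable GC (default 0.38, a typical
lepidopteran composition). Repeat copies are planted non-overlapping with
multinomially distributed gaps; each copy is the family monomer — or its
deletion variant, for the flagged fraction of W copies — mutated by
independent substitutions at the family's `divergence` rate. Every insert
(family, compartment, 0-based half-open interval, carrier flag, realized
substitution count) is recorded in a truth manifest. Deletion-carrier
counts round the carrier fraction to the nearest integer, ties up, so
that 17% of 353 copies is exactly 60.

Reads are single-end, drawn uniformly over valid start positions of the
*diploid* complement — two autosome sets plus ZW (females) or ZZ (males) —
reverse-complemented with probability 0.5, with i.i.d. substitution
errors. The read count is round(depth × haploid size / read length).
Simulated FASTQ qualities are constant Q30; the pipeline ignores
qualities beyond the cropping step.

**Dosage.** Because reads come from diploid cells while genome
fold-coverage is expressed per haploid genome, a compartment present in
one copy per cell (the W, and the Z in females) yields per-copy depth of
roughly half the genome coverage. Coverage-based copy numbers for
W-limited repeats are therefore haploid-genome equivalents, about half
the per-cell W copy count. The truth manifest exposes the exact expected
value, (Σ copies × ploidy) × haploid/diploid size — the exact ratio
matters for scaled-down test genomes where the W is a sizable fraction of
the total.

What the simulator does **not** model: indel sequencing errors, paired-end
structure, quality decay, nested or truncated insertions, satellite
higher-order structure, and real repeat-family phylogenies (each copy is
independently diverged from a single consensus). Recovery results on
synthetic data therefore demonstrate correctness of the pipeline's
computations under its own generative assumptions, not performance on any
real library.

## Read preparation

Cropping keeps the first `crop_length_bp` bases (3'-end truncation, the
low-quality end of the platform) and discards shorter reads. Subsampling
is uniform without replacement, order-preserving, seeded. Tagging
prepends `<individual_id>_` to read names; pooling concatenates tagged
sets and retains a tag map (individual → sex, prefix, count), which makes
splitting the pool by prefix an exact inverse of pooling.

## Clustering

Two reads are joined by an edge when their canonical k-mer sets (k = 13;
k-mers containing N skipped; canonical = lexicographic minimum of k-mer
and reverse complement, so the graph is strand-independent) share at
least 20 elements. Sharing 20 13-mers requires a 32-bp identical stretch
in the error-free case and, for full-length 140-bp overlaps, tolerates
roughly 8–10% pairwise divergence — the emulation of a ~90% read-joining
identity criterion. Clusters are connected components with at least 2
members, ranked by size (ties by smallest read index). Components of a
deterministic thresholded graph were chosen over hierarchical or
layout-based community detection deliberately: they are reproducible,
cheap, and exactly checkable against a brute-force all-pairs
set-intersection oracle, which the test suite does on pools of ≤500
reads. The cluster-abundance floor (0.01% of the pool) is applied at
tabulation; the clustered fraction reported alongside counts every
clustered read, retained or not.

The low-coverage regime matters: clustering operates on the subsample
(~0.1× pooled), where single-copy reads rarely overlap and the graph
isolates repeat families. At the full simulated depth (0.77× per
individual, several-fold pooled) background reads tile the genome and
percolate into one giant component — the subsampling step is what makes
read-graph clustering meaningful, in the synthetic setting as in the real
protocol.

## Enrichment screen

Per-cluster genome percents (count / sampled reads × 100) are compared
between sexes with Welch's unequal-variance two-sample t-test (sample
variances with divisor n−1, Welch–Satterthwaite df, two-sided P from the
t distribution). Two all-constant equal samples give t = 0, P = 1 rather
than an error. No multiple-testing correction is applied on the default
path, matching the reference procedure of screening at raw P < 0.05; a
Benjamini–Hochberg variant is available but off by default.

Enrichment ratios are always computed from raw counts. Display-rounded
percentages can distort a ratio substantially (0.31/0.09 rounds to 3.44
where the raw counts give 3.57), so rounded values are treated as
display-only everywhere. When one sex has zero reads in a cluster, 0.5
pseudo-reads are added to that sex's pooled count for the ratio only
(the record is flagged; the t-test uses unadjusted values). This guard is
intentionally absolute rather than scale-free, so ratios of flagged
records are not invariant under count rescaling — the one documented
exception to the screen's scale invariance.

The empirical false-positive cutoff r_max is the maximum male-over-female
enrichment among significant male-direction clusters (fallback 1.0 when
none exist): under the assumption that no repeat is genuinely
male-enriched in a WZ/ZZ system, the male side of the screen measures the
enrichment magnitude that noise alone produces. Significant
female-enriched clusters with ratio strictly above r_max are selected.
The summary "average enrichment" is the geometric mean of selected
ratios — the natural average of fold-changes, and the only mean
consistent with summarizing ratios whose arithmetic mean would be
dominated by a single extreme value.

At three individuals per sex, the Satterthwaite approximation is known to
be slightly conservative (empirical type-I ≈ 0.035–0.045 at nominal
0.05); the acceptance suite checks two-sided calibration both at the
3-vs-3 design and at 10-vs-10, where the approximation is accurate.

## Consensus mapping and coverage arithmetic

Mapping is exact-k-mer seeding (k = 13, both strands) followed by
extension along each candidate diagonal; identity = matches / overlapping
columns, with reference-end overhangs free. Because the read model is
substitution-only, gapless per-diagonal extension is exact rather than
heuristic, and indel-aware alignment is out of scope. A read is retained
at its best hit (ties: leftmost reference start, then forward strand) if
identity ≥ 0.95 and the hit spans ≥50% of the read — the deterministic
stand-in for the manual curation of marginal hits; both thresholds are
logged. Each retained read increments depth once over its aligned
columns, so the depth vector sums exactly to the total aligned columns.

Copy number = element fold-coverage / genome fold-coverage, with genome
coverage = total read bases / haploid genome size. Integer copy numbers
use **round-half-down** (⌈x − 0.5⌉): 17.50 → 17 while 325.46 → 325,
352.94 → 353 and 293.49 → 293, the only convention consistent with all
four published quotient→integer pairs this module reproduces. Deletion
carrier copies are the **difference of rounded copy numbers** outside and
inside the region (353 − 293 = 60), not a rounded difference of raw
quotients (which would give 59). Fold-differences between sexes use the
same rounding. The pg→Mb conversion uses the standard 978 Mb/pg factor
with floor rounding, consistent with both published conversions
(0.646 → 631, 0.53 → 518).

Two known biases of the coverage estimator on synthetic data: depth
droops over roughly a read length at each consensus end (overhanging
reads are clipped and short overlaps rejected), and reads from copies in
the divergence tail fall below the identity threshold. Both depress the
element mean, noticeably for short monomers (an element-wide mean over a
540-bp consensus underestimates by ~10–20% at 2% divergence, versus ~2–3%
for a 2-kb consensus at 1%). For precision work, compute the element mean
over the consensus interior or per-region as `CoverageProfile` allows.

The deletion scanner compares fully-contained sliding-window means with a
threshold times the interior mean depth, merges runs of flagged windows,
and orders candidates by depth of drop. End windows are excluded
(`edge_trim_bp`, ideally read length plus a window) because the end droop
would otherwise dominate any genuine internal drop.

## Validation problem sizes

The simulation-based tests run on 1–2 Mb genomes with W fractions of
20–25%, planted families of 90–150 W copies (monomers 540–2118 bp,
divergence 1–2%), three individuals per sex at 0.77–1.5× simulated depth,
and 80–800 sampled reads per individual — sizes chosen so each scenario
preserves the qualitative regime of the full design (low-coverage
sampling, high-copy W families, measurable dosage) while a complete run
takes seconds. Power checks use 50 independently seeded pipeline runs;
type-I checks use 1,500–2,000 simulated null clusters.

## Limitations

Clustering is a transparent emulation, not a re-implementation of
hierarchical repeat-clustering pipelines; absolute cluster counts and
clustered fractions are not comparable to published values from such
tools. The enrichment screen inherits the low power of 3-vs-3 Welch
testing; families below a few dozen sampled reads per sex are frequently
missed, which is a property of the study design, not of the
implementation. Coverage-based copy numbers are haploid-genome
equivalents and undercount per-cell W copies by the dosage factor
described above.
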