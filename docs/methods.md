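# Methods

## The quantification model

2b-RAD-M profiles a microbial community from the fixed-length tags that a
type IIB restriction enzyme excises from genomic DNA. Because a IIB enzyme
(BcgI here) cuts on both sides of its recognition site, every digestion
product has the same length, and the set of tags a genome yields is a
deterministic function of its sequence. Tags that are unique to one species
across a reference genome collection act as species-specific markers; counting
sequenced tags against that marker set gives species-level abundances without
whole-metagenome sequencing.

For species *i* in a sample, with

* `S_i` — reads assigned to markers of species *i*,
* `t_i` — distinct markers of species *i* observed,
* `T_i` — markers of species *i* in the database,

the pipeline computes

```
G_i = sqrt(S_i * t_i)
relative abundance_i = (S_i / T_i) / sum_j (S_j / T_j)   over screened-in j
```

`G` couples read depth with marker breadth: a species supported by many reads
over a single marker (likely cross-mapping or contamination) and a species
with a scattering of single-read markers both score low. Species with
`G >= 5` (inclusive; a strict mode is available) are screened in; the
abundance denominator then runs over screened-in species only.

The `S/T` normalization removes genome-size bias: a genome contributing more
tags absorbs proportionally more reads, and dividing by the marker total
cancels that factor. The source method's printed definitions of `t` and `T`
use identical wording, so both denominator conventions are implemented:
`database` (default, `T` = database marker total) and `observed` (`T = t`).
Under the read model used by the simulator (below), the `database` mode is
the one whose estimates converge to the true composition.

## Digestion and marker-database conventions

* BcgI geometry: recognition core `CGANNNNNNTGC` with 10 nt flanks on each
  side → 32 bp tags, the double-stranded core of the BcgI excision. The
  published enzyme literature does not pin down whether overhang bases are
  sequenced; the geometry (pattern and both flank lengths) is fully
  configurable per enzyme, so a 34-nt convention or other IIB enzymes are a
  registry entry away.
* Both strands are scanned; overlapping sites are all reported (tag sampling,
  not digestion kinetics). A site only counts when its full tag window lies
  inside the contig. Tags overlapping non-ACGT bases are dropped and tallied.
* Tags are identified by their canonical sequence, `min(seq, revcomp(seq))`,
  so the same physical duplex maps to one key regardless of strand.
* A tag is a species-specific marker iff it occurs exactly once in every
  genome of its species where it occurs at all, and in no genome of any other
  species. With several genomes per species this is union-of-genomes
  semantics; requiring presence in *all* genomes of a species would be the
  stricter alternative, but reference collections mix assembly qualities, so
  union semantics keeps markers that incomplete assemblies merely missed.
* Read matching is exact (reads truncated to tag length, canonicalized,
  hashed against the marker index). Tags are short and the database already
  demands uniqueness, so approximate matching buys little and risks
  cross-species bleed; a config hook is reserved.

## Ecology and biomarker statistics

* Chao1 uses the bias-corrected form `S_obs + F1(F1-1)/(2(F2+1))` and
  requires integer read counts (`S_i`), since singleton/doubleton frequencies
  are meaningless on proportions. Shannon (natural log) and Simpson
  (`1 - sum p^2`) renormalize the same counts.
* Beta diversity: Bray-Curtis and Euclidean on relative abundances (depth
  comparability), binary Jaccard on presence/absence.
* PERMANOVA computes the pseudo-F from among/within sums of squared
  distances and permutes group labels; p-values use the add-one convention
  `(1 + #{F_perm >= F_obs}) / (1 + n_perm)`, so the smallest attainable p is
  `1/(1+n_perm)` (0.001 at 999 permutations). The statistic is verified
  against an independent library implementation in the test suite.
* Group comparisons use the unpaired Wilcoxon rank-sum test by default
  (exact enumeration for tie-free samples of <= 10 per group, tie-corrected
  normal approximation otherwise). A paired signed-rank mode exists, but the
  26-vs-18 case-control design has no pairing, so unpaired is the default.
* IndVal follows Dufrene-Legendre: specificity `A` (share of a species'
  across-group mean abundance attributable to a group) times fidelity `B`
  (fraction of the group's samples where the species is detected), maximized
  over groups, with add-one permutation p-values.
* The effect-size ranking (`lefse_lite`) replaces bootstrap-LDA internals
  with a deterministic equivalent for the ranking/display role: a
  Kruskal-Wallis screen at alpha = 0.05, then
  `log10(|mean_a - mean_b| * 1e6 + 1)` signed toward the enriched group.
* `ensemble_importance` is a contract-level reimplementation of the
  randomForest importances: bootstrap bagging of CART trees with
  `mtry = floor(sqrt(p))` candidate features per split; mean decrease in
  Gini is each feature's total split-impurity decrease averaged over trees;
  mean decrease in accuracy is the average out-of-bag accuracy drop when the
  feature's values are permuted among the OOB samples. Every random draw
  comes from one seeded generator, so results are bit-reproducible; output
  ties are broken by species name.
* ROC/AUC uses the rank (Mann-Whitney) formulation with average ranks, which
  gives half credit to ties; thresholds sweep the observed score values.

## The synthetic-data generator

The generator emulates the study conditions end to end:

* **Genomes** — random backgrounds (configurable GC) rejection-sampled free
  of incidental recognition matches, with an exact number of planted sites at
  non-overlapping tag windows. Planted counts are therefore exact by
  construction, which the digestion tests exploit.
* **Reads** — a read's species is drawn with probability proportional to
  `proportion x tag count` (a genome-copy model: a genome contributes reads
  in proportion to the tags it carries), then a uniform tag, then iid
  per-base substitution errors. The tag-count weighting is exactly the bias
  the `S/T` normalization corrects, which is what makes the
  denominator-mode comparison meaningful. FASTQ qualities are constant and
  ignored by the pipeline.
* **Case-control studies** — the default design mirrors an oral-mycobiome
  case-control comparison: 26 cases vs 18 controls over 18 fungal taxa, with
  the dominant taxon (Saccharomyces cerevisiae, base 70%) 10x depleted in
  cases and a rare taxon (Malassezia globosa, base 0.5%) 10x enriched,
  per-taxon log-normal noise with sigma = 0.5 (natural-log scale), and
  multinomial counts at 50,000 reads per sample. The study's abundance
  matrix holds the exact post-noise compositions; the count matrix holds the
  multinomial draw (alpha diversity runs on counts, everything else on the
  matrix).

What the generator does not model: quality-dependent or indel errors, host
DNA, chimeras, taxonomic misannotation, zero-inflation from detection limits,
and real phylogenetic correlation between taxa. Passing recovery tests shows
the statistical machinery is correct under the stated model, not that real
oral-microbiome data meet that model.

### A known limitation of the two-sided fold-change design

With one 10x-enriched and one 10x-depleted taxon under shared log-noise,
both planted taxa are strong single-feature discriminators. After
renormalization the log-separations are `ln 10 - ln D` (enriched) and
`ln 10 + ln D` (depleted), `D = sum_j fold_j * base_j`; the default design
(D = 0.415) favors the enriched taxon in expectation. But when the depleted taxon
dominates the composition, renormalization cancels much of its own noise
(its per-sample value is compressed toward the group mean), and its observed
single-feature AUC stays near 1 across the whole admissible range of base
compositions. As a result the tree ensemble ranks the enriched taxon first
on both importance measures in only roughly half of generated studies — in
the rest, the depleted taxon is genuinely the better feature of that
dataset. Increasing the number of trees does not change this (the flip is
dataset-level, not ensemble noise). The enriched taxon's IndVal significance
and its AUC > 0.9 hold essentially always; the "ranks first on both
importances" recovery property does not reach the 95% level in this design,
and the corresponding end-to-end test documents that honestly. A one-sided
design (enrichment only) recovers the planted taxon as the top feature
essentially always.

## Problem sizes and numerics

Simulation-based checks use 10-kb genomes (100 replicates for the digestion
oracle), 5-6 species references with 25-40 tags per genome, 50k-100k reads
per sample, 99-999 permutations, and 100-200 replicate studies; these sizes
give stable rates (binomial SE <= ~2.5 percentage points on the reported
percentages) while keeping a full run on one CPU in minutes. Screened
abundances are renormalized exactly (sums checked to 1e-9); permutation
p-values can never be 0 by the add-one convention; degenerate inputs
(all-zero samples, constant taxa, empty screens) return defined values or
raise informative errors rather than NaN.

Every stochastic routine takes an explicit seed and uses a
`numpy.random.Generator` seeded from it and nothing else; reruns with one
configuration are byte-identical (content-hash checked in the pipeline
report). All stages are single-threaded, so results are trivially
independent of CPU count.
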