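# Methods

This note documents the models behind `msiburst`, the parameter defaults and
why they were chosen, the numerical conventions, and what the synthetic data
do and do not emulate.

## Serial-passage branching model (`msiburst.growth`)

**Model.** A culture dish is seeded with `seeded_cells = 3 × 10⁵` cells; over
one passage each cell completes `divisions_per_passage = 2` divisions (×4
growth) and a fraction `pass_fraction = 1/4` of the grown dish is re-seeded.
From the point of view of one clone of *n* cells, the next-passage size is
`m ~ Binomial(n · 2^divisions_per_passage, pass_fraction)`. With the defaults
the per-cell offspring distribution is Binomial(4, 1/4) with mean exactly 1:
a *critical* Galton–Watson process, so the mean clone size is a martingale
while extinction probability accumulates.

**Exact recursion.** `clone_size_distribution` iterates the transition matrix
over clone sizes 0..`max_tracked_size` (default 200). Binomial terms are
evaluated via `scipy.stats.binom.logpmf` (log space; rows reach 800 trials).
Mass that lands beyond the cap is accumulated in `truncation_mass` and
treated as absorbing — a clone counted as "large" never re-enters the
tracked range. This overstates truncation slightly but keeps normalization
exact and testable (`Σp + truncation_mass = 1` to 1e-12); from a single
founder the truncation mass is ~3 × 10⁻¹⁰ after 27 passages, i.e. irrelevant.
Extinction (size 0) is absorbing by construction.

**Conditioning convention.** "Surviving" clones are those with final size
≥ 1; `conditional_on_survival()` renormalizes over sizes ≥ 1 plus the
truncated mass.

**Division presets.** The pre-growth-arrest protocol is 12 divisions during
segmentation + 26 during the remainder of embryogenesis (twice daily to
E13.5) + 2/passage for P1–P3 + 1/passage for P4–P7 = 48; the immortal phase
is 27 passages at 2 divisions = 54. `divisions_to_reach(n) = ⌈log₂ n⌉` models
the clonal expansion of a single immortalized cell (3 × 10⁵ → 19 divisions);
only the rounded value is meaningful.

## Burden and detectability (`msiburst.burden`)

**Rates.** `subs_per_genome_per_division = 25` (the canonical-replication
substitution rate of an MMR-deficient mammalian cell) and
`exonic_fraction = 0.015` (exome/genome size ratio). Expected exonic burden
over *D* divisions along one lineage is `D × 25 × 0.015` (18 at D = 48).

**Detectability.** Bulk exome sequencing resolves a mutation once its
carriers constitute ≥ `min_clone_fraction = 10%` of the dish, equated with
the absolute count `detectable_cell_threshold = round(0.10 × 3 × 10⁵) =
3 × 10⁴` cells. The "more than 10%" criterion is implemented as ≥ threshold.

**The IP28 estimate** (`estimate_detectable_ip28`) asks how many mutations
arising during the 19-division clonal expansion become *newly* detectable
27 passages later. Model and conventions:

* The expansion tree is synchronous and binary: at division *d* there are 2ᵈ
  daughter cells, each acquiring `Poisson(25 × 0.015)` new exonic
  substitutions; a mutation arising at division *d* is carried by one
  daughter lineage — `2^(19−d)` of the 2¹⁹ tree leaves (carrier fraction
  2⁻ᵈ).
* Divisions 1–3 are excluded: their carrier fractions (≥ 1/8) exceed the 10%
  cutoff already at IP1, so they are not *newly* detectable at IP28.
* Each mutation's carrier-cell count is propagated through 27 passages of
  the Binomial(4n, 1/4) transition, and the mutation counts as detectable
  when the final count reaches the absolute threshold of 3 × 10⁴ cells
  (`threshold_mode="cells"`, the default). The alternative
  `threshold_mode="fraction"` demands 10% of the full 2¹⁹-cell tree; under a
  near-critical process carrier *fractions* barely drift, so that mode is
  strictly harsher and returns ≈ 0 — exposed for sensitivity analysis, not
  used by default. Under the default the answer is dominated by division-4
  mutations (2¹⁵ = 32768 carriers, just above threshold, retained with
  probability ≈ 1 by the martingale property), giving an expectation of
  ≈ 2⁴ × 0.375 ≈ 6 detectable mutations — a handful, which is the
  scientific point: canonical replication cannot produce a large newly
  detectable burden late in the immortal phase.
* Implementation: clones within a replicate are exchangeable, so per-passage
  draws are bucketed by clone size and sampled with constant-trial binomial
  calls (exact in distribution for the count statistic, ~3× faster than
  per-clone draws). Extinct clones drop out each passage. 1000 replicates
  run in ~4 minutes on one core.

`biallelic_rate(f) = f²` is the independent-allele approximation for the
frequency of cells hit on both alleles.

## Synthetic data (`msiburst.synth`)

**Genome.** A single chromosome tiled with gene blocks (150 bp exon + intron
+ short intergenic spacer) so the exonic fraction lands within 10% relative
of the request (default 1.5%); microsatellite tracts (mono/di units, 15–25
copies) are embedded mostly in introns with repeat-breaking flanks so each
tract contains exactly its declared copies; a replication-timing track tiles
the sequence in 10 kb windows with uniform random values. The genome is a
scaled stand-in: mutation rates are per *genome*, so burdens match the real
design while per-base density is higher.

**Culture.** Mutations along the immortalizing lineage: `Poisson(25 × 48)`
canonical substitutions (clonal, carrier fraction 1, heterozygous on a
random allele); in the MMR-deficient regime under the standard protocol a
single stress burst between growth arrest and immortalization adds
`Poisson(2000)` substitutions and `Poisson(1000)` indels, the indels placed
on microsatellite tracts with probability proportional to
`repeat_bias = 20` per base (slippage of ±1 unit) and otherwise uniformly.
The burst rates are free parameters of the generator — real cultures do not
pin them down — chosen so the clonal exonic substitution burden clearly
exceeds the canonical expectation of 18 (observed ≈ 50 on average), i.e.
calibrated only to reproduce the observed-exceeds-expected contrast, and the
repeat bias so that a five-locus panel is hit with high probability.
Expansion-phase substitutions at division *d* carry fraction 2⁻ᵈ; lineages
below `min_tracked_carrier_fraction = 0.02` are not materialized (they are
beneath any bulk detection limit; tracking them would add ~10⁷ irrelevant
rows). The MMR-proficient regime has no burst and immortalizes tetraploid
(one mutant allele of four → VAF expectation 0.25); the temporary
serum-depleted protocol has no burst and no immortalization, and emits
lineage mutations at the carrier fraction of a single cell in the dish.
Immortalization is imposed (the paper-style frequency difference between
regimes is carried as configurable per-cell rates in the population summary,
not re-derived). At most one mutation per (position, allele).

**Sequencing.** Depths are negative-binomial (`depth_mean = 100`,
shape `depth_dispersion = 10`); alt reads are
`Binomial(depth, carrier_fraction × 1/ploidy)`. Pileups carry per-sample
A/C/G/T/ins/del counts at every truth site plus probed null positions (a
deterministic function of the genome, shared by both samples); sequencing
noise is symmetric substitution error only (`noise_rate = 0.001`), never
indel error, so the MSI signal is attributable entirely to truth indels.
Substitutions are piled up at the substituted base, indels at their anchor
base. Indels are emitted for the stress burst only: the canonical-phase
accounting is substitution-based, and keeping canonical indels out makes the
repeat-context contrast between regimes interpretable.

**What the generator does not emulate.** Read-level artifacts (mapping,
duplicates, strand bias), copy-number change beyond the ploidy flag,
selection among subclones, PCR indel error, inter-locus rate heterogeneity
beyond the repeat bias, and real exome capture geometry. Passing tests
therefore demonstrate correctness of the *analysis* under the stated
statistical model, not robustness to alignment artifacts in real exomes.

## Variant pipeline (`msiburst.variants`)

* **Calling.** Sites need depth ≥ 10 in both samples; the candidate allele is
  the most frequent non-reference call in the case sample; the 2×2 table
  (reference vs candidate, control vs case) is tested with a two-sided
  Fisher's exact test (all tables with probability ≤ observed × (1 + 1e-7)
  are summed — the standard tie convention); calls need p < 0.001. No
  multiple-testing correction by default (the protocol's fixed cutoff);
  Benjamini–Hochberg is available as an option. The p-values are computed by
  a vectorized log-hypergeometric routine with an integer log-factorial
  lookup, which evaluates millions of tables per second; it agrees with
  `scipy.stats.fisher_exact` to ~1e-13 relative and with exhaustive
  enumeration on every table with total ≤ 60 (tested).
* **Spectrum.** Substitutions are collapsed to pyrimidine context (purine
  references reverse-complemented); the G·T-mispair flag marks the two
  transition classes C>T and T>C (the products of an unrepaired wobble
  pair). The class set is a configurable table: indels are never flagged and
  are reported as their own category.
* **VAF band.** Closed interval [0.30, 0.60] on the case alt read fraction.
  Endpoints closed by choice; at depth 100 and p = 0.5 the binomial band
  mass is ≈ 0.98.
* **Repeat context.** The count of exact whole-unit copies of the indel's
  unit in the reference, stepping outward in both directions from the indel
  position; 0 means no flanking copy. The two-sided count is invariant to
  which copy of a run is deleted, so no separate left-alignment pass is
  needed (property-tested).
* **Timing.** Intervals are rank-ordered by timing value (higher = earlier
  by default, flippable) with ties broken by interval start; the top half is
  labelled early. A rank split is used instead of a median threshold because
  it guarantees the 50/50 split even on degenerate (constant) tracks, with
  ties deterministically assigned to early. Positions outside the track are
  "unassigned".
* **Enrichment.** Pearson χ² (no continuity correction) on the 2×2 table of
  (indel count, remaining bases) for introns vs exons; zero indels in both
  regions short-circuits to (0, p = 1).

## MSI calling (`msiburst.msi`)

**Stutter model.** Each allele of *c* repeat units contributes intensity
`stutter_decay^k` at `c − k` units (contraction-only ladder, the dominant
PCR slippage artifact); allele ladders are summed by mixture weight,
Gaussian baseline noise (sd = `noise` × max) is added and clipped at 0, and
the profile is max-normalized. Defaults `stutter_decay = 0.3`,
`noise = 0.02` sit in the realistic range for capillary traces.

**Peak-shift detection.** A locus is shifted when the test profile's modal
length moves by ≥ `min_shift_units` (default 1) repeat units, or when the
test profile contains a new secondary peak: a local maximum with relative
intensity ≥ `min_secondary_fraction = 0.2` at ≥ 1 unit from the reference
mode, where the reference stays below 0.2 *and* the peak exceeds the
reference trace at that length by at least the fraction itself. The third
condition is deliberate: without it, baseline noise can promote a faint
stutter rung into a "new" peak (measured false-positive rate ≈ 2% at decay
0.5 / noise 0.05); with it the rate drops to ≈ 0.1% while construction-test
sensitivity to genuine secondary peaks is unchanged. The default fraction
0.2 is chosen so a clean geometric ladder at decay 0.5 (rungs 1, 0.5, 0.25,
…) never self-triggers — those rungs are present in the reference too.
Detection depends only on length differences, so uniform translation of
both profiles never creates a call.

**Panel scoring.** Any single shifted locus calls the sample MSI (instability
is locus-sporadic, so one clean shift is evidence); the stricter clinical
two-of-five scoring is `min_shifted_loci=2`. Mouse and human five-locus
panels ship with synthetic copy numbers/flanks in the realistic range — the
assay logic depends only on unit length.

## Pipeline and reproducibility (`msiburst.pipeline`)

A master seed is split with `numpy.random.SeedSequence.spawn` into logged
per-stage sub-seeds (genome, culture, control/case pileups, reads,
fragments); every stochastic call takes an explicit seed and a fresh
`numpy.random.Generator` — no global state. Re-running a config reproduces
every table byte for byte (tested). Run directories persist the resolved
YAML config, genome FASTA, BED-like annotation TSVs, truth/pileup/variant
tables, a minimal VCF (validated against pysam's parser in tests), fragment
CSVs and `summary.json`; every summary number is recomputable from the
persisted tables by the corresponding library function (tested for the VAF
band).

Default problem sizes (400 kb pipeline genome, 200 kb test genomes, 10⁵
Monte-Carlo founders, 1000 replicates for the IP28 estimate and MSI
false-positive rate) were chosen so the whole suite runs in minutes on a
single core while keeping every statistical check at ≥ 3-sigma resolution.

## Known limitations

* The IP28 detectability estimate depends on the expansion-scenario
  convention (absolute-count vs fraction thresholding, uniform expansion
  across lineages); both modes are exposed, and the default's answer (≈ 6)
  should be read as "order ten", not a precise value.
* The exact DP treats the truncation bucket as absorbing, so clone-size
  moments are lower bounds when truncation mass is non-negligible (it is
  ~10⁻¹⁰ in all default uses).
* The Fisher caller tests one candidate allele per site (the most frequent
  non-reference call), as paired designs with a clean control warrant;
  multi-allelic sites report only the dominant alternative.
* Fragment profiles model contraction-only stutter; expansion stutter and
  dye/size-standard artifacts are out of scope.
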