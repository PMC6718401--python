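"""Paired-sample somatic calling on a simulated culture.

Generates a 200 kb annotated genome, simulates a mismatch-repair-deficient
culture through immortalization (canonical replication errors plus a
replication-stress hypermutation burst), emits paired control/case pileups,
and calls somatic variants with the depth-10 / Fisher p<0.001 rule.  Calls
are then annotated and summarized the way the study's exome analyses are.
"""

from msiburst import (
    SimulationConfig,
    annotate_repeat_context,
    assign_timing,
    call_somatic,
    classify_substitution,
    emit_pileup_pair,
    make_genome,
    region_enrichment,
    simulate_culture,
    vaf_band_fraction,
)

genome = make_genome(length=200_000, seed=7)
config = SimulationConfig(regime="mmr_deficient", protocol="standard")
truth = simulate_culture(genome, config, seed=8)
pileup = emit_pileup_pair(truth, genome, config, control_seed=9, case_seed=10)
records = call_somatic(pileup, min_depth=10, p_threshold=0.001)

subs = [r for r in records if r.vtype == "substitution"]
indels = [r for r in records if r.vtype != "substitution"]
gt = sum(classify_substitution(r.ref, r.alt)[1] for r in subs)
band = vaf_band_fraction(subs)
annotated = [annotate_repeat_context(genome.sequence, r) for r in indels]
in_repeat = sum(r.repeat_context > 0 for r in annotated)
timed = assign_timing(records, genome.timing)
early = sum(r.timing == "early" for r in timed)
enrich = region_enrichment(records, genome.exons, genome.introns)

print(f"truth mutations:          {len(truth.mutations)}")
print(f"somatic calls:            {len(records)} "
      f"({len(subs)} substitutions, {len(indels)} indels)")
print(f"G.T-mispair transitions:  {gt}/{len(subs)} of substitutions")
print(f"VAF in 30-60% band:       {band:.2f} "
      "(heterozygous diploid clone centres at 50%)")
print(f"indels in repeat context: {in_repeat}/{len(indels)}")
print(f"early-replicating calls:  {early}/{len(records)}")
print(f"intron/exon indel enrichment: chi2={enrich.statistic:.1f}, "
      f"p={enrich.p_value:.2g}")
print("\nA high VAF-band fraction marks the calls as clonal (one immortalized")
print("founder); repeat-context indel concentration is the MSI signature.")
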