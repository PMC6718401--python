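"""Reproducible end-to-end runs: simulate, call, annotate, score MSI, report.

A run is fully determined by a resolved configuration and a master seed; every
stochastic stage receives a sub-seed derived from the master seed through
``numpy.random.SeedSequence``, all of which are logged into the run summary.
Re-running with the same config reproduces every table bit for bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden, growth, msi, synth, variants

__all__ = ["default_config", "load_config", "resolve_config", "run_pipeline"]

logger = logging.getLogger("msiburst")


def default_config() -> dict:
    """The default run configuration (the study conditions)."""
    return {
        "genome": {
            "length": 400_000,
            "exon_fraction": 0.015,
            "n_microsatellites": 30,
            "unit_lengths": [1, 2],
        },
        "simulation": {
            "regime": "mmr_deficient",
            "protocol": "standard",
            "canonical_rate": 25.0,
            "burst_substitution_rate": 2000.0,
            "burst_indel_rate": 1000.0,
            "repeat_bias": 20.0,
            "depth_mean": 100.0,
            "depth_dispersion": 10.0,
            "noise_rate": 0.001,
        },
        "calling": {
            "min_depth": 10,
            "p_threshold": 0.001,
        },
        "vaf_band": [0.30, 0.60],
        "msi": {
            "stutter_decay": 0.3,
            "noise": 0.02,
            "min_secondary_fraction": 0.2,
            "n_panel_loci": 5,
        },
    }


def resolve_config(overrides: dict | None = None) -> dict:
    """Merge user overrides into the defaults, rejecting unknown keys."""
    config = default_config()
    if overrides:
        _merge(config, overrides, path="")
    return config


def _merge(base: dict, overrides: dict, path: str) -> None:
    for key, value in overrides.items():
        if key not in base:
            raise KeyError(f"unknown config key: {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config section {path + key!r} must be a mapping")
            _merge(base[key], value, path + key + ".")
        else:
            base[key] = value


def load_config(path) -> dict:
    with open(path) as fh:
        return resolve_config(yaml.safe_load(fh) or {})


def _stage_seeds(master_seed: int) -> dict[str, int]:
    names = ["genome", "culture", "pileup_control", "pileup_case", "reads", "fragments"]
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
        for name, child in zip(names, children)
    }


def run_pipeline(config: dict | None = None, outdir=None, seed: int = 0) -> dict:
    """Execute the full analysis on one simulated culture and write a run directory.

    Stages: genome generation, culture simulation, exome read sampling, paired
    pileups, somatic calling, annotation (region, spectrum, repeat context,
    timing), VAF-band clonality, intron/exon indel enrichment, fragment-length
    MSI calling, and a summary that juxtaposes the observed clonal exonic
    substitution burden with the expectation from canonical replication.

    Returns the summary dict; when ``outdir`` is given, persists the resolved
    config, all tables (TSV/CSV/FASTA/VCF) and summary.json there.
    """
    config = resolve_config(config if config is not None else {})
    seeds = _stage_seeds(seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
    try:
        return _run(config, out, seed, seeds)
    finally:
        if out is not None:
            handler.close()
            logger.removeHandler(handler)


def _run(config: dict, out: Path | None, seed: int, seeds: dict[str, int]) -> dict:
    gcfg = config["genome"]
    genome = synth.make_genome(
        length=int(gcfg["length"]),
        exon_fraction=float(gcfg["exon_fraction"]),
        n_microsatellites=int(gcfg["n_microsatellites"]),
        unit_lengths=tuple(gcfg["unit_lengths"]),
        seed=seeds["genome"],
    )
    logger.info("genome: %d bp, %d exons, %d microsatellites", len(genome), len(genome.exons), len(genome.microsatellites))

    sim = synth.SimulationConfig(**config["simulation"])
    protocols = synth.CultureProtocols()
    truth = synth.simulate_culture(genome, sim, protocols, seed=seeds["culture"])
    reads = synth.sample_exome_reads(truth, genome, sim, seed=seeds["reads"])
    pileup = synth.emit_pileup_pair(
        truth, genome, sim, control_seed=seeds["pileup_control"], case_seed=seeds["pileup_case"]
    )

    ccfg = config["calling"]
    records = variants.call_somatic(
        pileup, min_depth=int(ccfg["min_depth"]), p_threshold=float(ccfg["p_threshold"])
    )
    annotated = []
    for rec in records:
        rec.region = genome.region_of(rec.position - 1)
        if rec.vtype == "substitution":
            cls, flag = variants.classify_substitution(rec.ref, rec.alt)
            rec.substitution_class = cls
            rec.gt_mismatch_inducible = flag
        else:
            rec = variants.annotate_repeat_context(genome.sequence, rec)
        annotated.append(rec)
    annotated = variants.assign_timing(annotated, genome.timing)
    logger.info("called %d somatic variants", len(annotated))

    sub_records = [r for r in annotated if r.vtype == "substitution"]
    band = tuple(config["vaf_band"])
    band_fraction = (
        variants.vaf_band_fraction(sub_records, band) if sub_records else float("nan")
    )
    indel_records = [r for r in annotated if r.vtype != "substitution"]
    repeat_hist: dict[int, int] = {}
    for r in indel_records:
        repeat_hist[r.repeat_context] = repeat_hist.get(r.repeat_context, 0) + 1
    timing_counts = {"early": 0, "late": 0, "unassigned": 0}
    for r in annotated:
        timing_counts[r.timing] += 1
    if indel_records:
        enrich = variants.region_enrichment(annotated, genome.exons, genome.introns)
        enrichment = {
            "table": enrich.table.tolist(),
            "statistic": enrich.statistic,
            "p_value": enrich.p_value,
        }
    else:
        enrichment = None

    mcfg = config["msi"]
    panel_ids = [ms.locus.locus_id for ms in genome.microsatellites[: int(mcfg["n_panel_loci"])]]
    profiles = synth.emit_fragment_profiles(
        genome,
        truth,
        panel_ids,
        stutter_decay=float(mcfg["stutter_decay"]),
        noise=float(mcfg["noise"]),
        seed=seeds["fragments"],
    )
    locus_calls = []
    for locus_id in panel_ids:
        pre, post = profiles[locus_id]
        ms_locus = genome.microsatellite_by_id(locus_id).locus
        shifted, shift = msi.detect_peak_shift(
            pre,
            post,
            unit_length=ms_locus.unit_length,
            min_secondary_fraction=float(mcfg["min_secondary_fraction"]),
        )
        locus_calls.append(msi.LocusCall(locus_id, shifted, shift))
    msi_call = msi.msi_status(locus_calls)

    pre_divisions = growth.count_divisions(protocols.pre_immortalization)
    observed_exonic_subs = sum(
        1
        for m in truth.mutations
        if m.vtype == "sub"
        and m.carrier_fraction >= 0.99
        and genome.region_of(m.position) == "exon"
    )
    summary = {
        "seed": seed,
        "stage_seeds": seeds,
        "n_truth_mutations": len(truth.mutations),
        "n_calls": len(annotated),
        "n_substitution_calls": len(sub_records),
        "n_indel_calls": len(indel_records),
        "expected_exonic_substitutions_at_ip1": burden.expected_exonic_substitutions(
            pre_divisions,
            burden.MutationRateParams(
                subs_per_genome_per_division=sim.canonical_rate,
                exonic_fraction=genome.exonic_bases / len(genome),
            ),
        ),
        "observed_clonal_exonic_substitutions": observed_exonic_subs,
        "vaf_band": list(band),
        "vaf_band_fraction": band_fraction,
        "repeat_context_histogram": {str(k): v for k, v in sorted(repeat_hist.items())},
        "timing_counts": timing_counts,
        "intron_exon_indel_enrichment": enrichment,
        "msi_status": msi_call.status,
        "msi_loci": [
            {"locus_id": c.locus_id, "shifted": c.shifted, "shift_units": c.shift_units}
            for c in msi_call.per_locus
        ],
        "population_summary": truth.population_summary,
    }

    if out is not None:
        with open(out / "config_resolved.yaml", "w") as fh:
            yaml.safe_dump({"seed": seed, **config}, fh, sort_keys=True)
        genome.to_fasta(out / "genome.fasta")
        genome.exons_to_tsv(out / "exons.tsv")
        genome.introns_to_tsv(out / "introns.tsv")
        genome.timing_to_tsv(out / "timing.tsv")
        genome.microsatellites_to_tsv(out / "microsatellites.tsv")
        truth.to_tsv(out / "truth.tsv")
        reads.to_csv(out / "reads.tsv", sep="\t", index=False, float_format="%.8g")
        pileup.to_csv(out / "pileup.tsv", sep="\t", index=False)
        variants.records_to_dataframe(annotated).to_csv(
            out / "variants.tsv", sep="\t", index=False, float_format="%.8g"
        )
        variants.write_minimal_vcf(
            annotated, out / "variants.vcf", contigs={genome.name: len(genome)}
        )
        profdir = out / "profiles"
        profdir.mkdir(exist_ok=True)
        for locus_id, (pre, post) in profiles.items():
            pre.to_csv(profdir / f"{locus_id}_pre.csv")
            post.to_csv(profdir / f"{locus_id}_post.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary
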