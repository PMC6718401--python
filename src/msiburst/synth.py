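"""Synthetic genomes, cultures and sequencing observables.

Every downstream stage of the pipeline is exercised on data generated here: a
diploid reference with annotated exons/introns, embedded microsatellite loci
and a replication-timing track; a culture simulation that accrues canonical
replication errors per division, adds a replication-stress hypermutation burst
in the mismatch-repair-deficient regime, and clonally expands a single
immortalized cell; and samplers that turn the resulting mutation truth set
into exome read counts, paired pileup tables and fragment-length profiles.

Coordinates are 0-based half-open internally; emitted variant tables are
1-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .growth import (
    IP_PHASE_PROTOCOL,
    PRE_P8_PROTOCOL,
    PassageProtocol,
    count_divisions,
    divisions_to_reach,
)
from .msi import FragmentProfile, MicrosatelliteLocus, simulate_profile
from .variants import PILEUP_COLUMNS

__all__ = [
    "GenomeMicrosatellite",
    "SyntheticGenome",
    "SimulationConfig",
    "TruthMutation",
    "SimulatedVariantTruth",
    "CultureProtocols",
    "make_genome",
    "simulate_culture",
    "sample_exome_reads",
    "emit_pileup_pair",
    "emit_fragment_profiles",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeMicrosatellite:
    """A microsatellite locus embedded at a genomic position."""

    locus: MicrosatelliteLocus
    start: int  # 0-based start of the tandem tract

    @property
    def end(self) -> int:
        return self.start + self.locus.tract_length


@dataclass
class SyntheticGenome:
    """A single-chromosome reference with annotations.

    ``exons``/``introns`` are disjoint 0-based half-open intervals; the
    ``timing`` track tiles the sequence with replication-timing values (higher
    = earlier by default); every microsatellite tract is guaranteed to contain
    exactly its declared number of unit copies (flanks are repeat-breaking).
    """

    name: str
    sequence: str
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    microsatellites: list[GenomeMicrosatellite]
    timing: pd.DataFrame  # columns: start, end, value

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def exonic_bases(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intronic_bases(self) -> int:
        return sum(e - s for s, e in self.introns)

    def region_of(self, pos0: int) -> str:
        for s, e in self.exons:
            if s <= pos0 < e:
                return "exon"
        for s, e in self.introns:
            if s <= pos0 < e:
                return "intron"
        return "other"

    def microsatellite_by_id(self, locus_id: str) -> GenomeMicrosatellite:
        for ms in self.microsatellites:
            if ms.locus.locus_id == locus_id:
                return ms
        raise KeyError(f"unknown microsatellite locus {locus_id!r}")

    def validate(self) -> None:
        n = len(self.sequence)
        spans = sorted(self.exons + self.introns)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 > s2:
                raise ValueError("exon/intron intervals overlap")
        for s, e in spans:
            if not 0 <= s < e <= n:
                raise ValueError("interval out of sequence bounds")
        for ms in self.microsatellites:
            tract = self.sequence[ms.start : ms.end]
            if tract != ms.locus.unit * ms.locus.copies:
                raise ValueError(f"tract mismatch at {ms.locus.locus_id}")

    # -- serialization -----------------------------------------------------
    def to_fasta(self, path) -> None:
        SeqIO.write([SeqRecord(Seq(self.sequence), id=self.name, description="")], path, "fasta")

    def exons_to_tsv(self, path) -> None:
        pd.DataFrame(self.exons, columns=["start", "end"]).assign(chrom=self.name)[
            ["chrom", "start", "end"]
        ].to_csv(path, sep="\t", index=False)

    def introns_to_tsv(self, path) -> None:
        pd.DataFrame(self.introns, columns=["start", "end"]).assign(chrom=self.name)[
            ["chrom", "start", "end"]
        ].to_csv(path, sep="\t", index=False)

    def timing_to_tsv(self, path) -> None:
        self.timing.assign(chrom=self.name)[["chrom", "start", "end", "value"]].to_csv(
            path, sep="\t", index=False, float_format="%.8g"
        )

    def microsatellites_to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "locus_id": ms.locus.locus_id,
                    "unit": ms.locus.unit,
                    "copies": ms.locus.copies,
                    "flanking": ms.locus.flanking,
                    "start": ms.start,
                    "end": ms.end,
                }
                for ms in self.microsatellites
            ]
        ).to_csv(path, sep="\t", index=False)


def make_genome(
    length: int = 1_000_000,
    exon_fraction: float = 0.015,
    n_microsatellites: int = 30,
    unit_lengths: Sequence[int] = (1, 2),
    seed: int | np.random.Generator | None = None,
    name: str = "chr1",
    exon_size: int = 150,
    copies_range: tuple[int, int] = (15, 25),
    timing_window: int = 10_000,
    ms_intron_fraction: float = 0.9,
) -> SyntheticGenome:
    """Generate a synthetic annotated genome.

    The sequence is tiled with gene blocks (one ``exon_size`` exon followed by
    an intron, with a short intergenic spacer) so that the exonic base
    fraction lands within 10% relative of ``exon_fraction``.  Microsatellite
    tracts (units drawn from ``unit_lengths``, copy numbers uniform in
    ``copies_range``) are written into introns (or intergenic spacers for a
    ``1 - ms_intron_fraction`` share), with repeat-breaking flanking bases so
    each tract contains exactly its declared copies.  The timing track tiles
    the genome in ``timing_window`` windows with uniform random values.
    """
    rng = np.random.default_rng(seed)
    if not set(unit_lengths) <= {1, 2}:
        raise ValueError("unit_lengths must be a subset of {1, 2}")
    n_exons = max(1, round(length * exon_fraction / exon_size))
    block = length // n_exons
    intergenic = max(block // 10, 20)
    intron_len = block - exon_size - intergenic
    if intron_len < 200:
        raise ValueError("genome too short for the requested exon layout")
    seq = rng.choice(_BASES, size=length)

    exons, introns = [], []
    spacers = []
    for i in range(n_exons):
        start = i * block
        exons.append((start, start + exon_size))
        introns.append((start + exon_size, start + exon_size + intron_len))
        spacers.append((start + exon_size + intron_len, min(start + block, length)))

    # place microsatellite tracts without overlap, away from exons
    ms_list: list[GenomeMicrosatellite] = []
    occupied: list[tuple[int, int]] = []
    max_tract = 2 * copies_range[1] + 4
    for i in range(n_microsatellites):
        unit_len = int(rng.choice(list(unit_lengths)))
        unit = "".join(rng.choice(_BASES, size=unit_len))
        if unit_len == 2 and unit[0] == unit[1]:
            unit = unit[0] + str(rng.choice([b for b in "ACGT" if b != unit[0]]))
        copies = int(rng.integers(copies_range[0], copies_range[1] + 1))
        tract = unit * copies
        host_pool = introns if rng.random() < ms_intron_fraction else spacers
        placed = False
        for _ in range(200):
            s_host, e_host = host_pool[int(rng.integers(len(host_pool)))]
            if e_host - s_host < len(tract) + 2 * max_tract:
                continue
            start = int(rng.integers(s_host + 2, e_host - len(tract) - 2))
            span = (start - 2, start + len(tract) + 2)
            if any(a < span[1] and span[0] < b for a, b in occupied):
                continue
            seq[start : start + len(tract)] = list(tract)
            breakers = [b for b in "ACGT" if b not in unit]
            seq[start - 2 : start] = [breakers[0], breakers[0]]
            seq[start + len(tract) : start + len(tract) + 2] = [breakers[-1], breakers[-1]]
            ms_list.append(
                GenomeMicrosatellite(
                    MicrosatelliteLocus(f"MS{i:03d}", unit, copies, flanking=100), start
                )
            )
            occupied.append(span)
            placed = True
            break
        if not placed:
            raise ValueError("could not place all requested microsatellite loci")

    edges = list(range(0, length, timing_window)) + [length]
    timing = pd.DataFrame(
        {
            "start": edges[:-1],
            "end": edges[1:],
            "value": rng.random(len(edges) - 1),
        }
    )
    genome = SyntheticGenome(
        name=name,
        sequence="".join(seq),
        exons=exons,
        introns=introns,
        microsatellites=ms_list,
        timing=timing,
    )
    genome.validate()
    achieved = genome.exonic_bases / length
    if exon_fraction > 0 and abs(achieved - exon_fraction) / exon_fraction > 0.10:
        raise ValueError("achieved exonic fraction deviates more than 10% from request")
    return genome


@dataclass(frozen=True)
class CultureProtocols:
    """Division bookkeeping for one immortalization experiment."""

    pre_immortalization: PassageProtocol = PRE_P8_PROTOCOL
    immortal_phase: PassageProtocol = IP_PHASE_PROTOCOL
    expansion_target_cells: int = 300_000

    @property
    def expansion_divisions(self) -> int:
        return divisions_to_reach(self.expansion_target_cells)


@dataclass
class SimulationConfig:
    """Study-condition parameters for one simulated culture.

    The MMR-deficient regime under the standard growth-stimulated protocol
    receives a single replication-stress hypermutation burst (substitutions
    plus repeat-biased indels) between growth arrest and immortalization, and
    immortalizes as a diploid clone with mutations on one allele.  The
    MMR-proficient regime immortalizes without a burst but tetraploid (one
    mutant allele of four).  The temporary serum-depleted protocol removes the
    stress phase: no burst and no immortalization.
    """

    regime: str = "mmr_deficient"  # or "mmr_proficient"
    protocol: str = "standard"  # or "serum_depleted"
    canonical_rate: float = 25.0  # substitutions / genome / division
    burst_substitution_rate: float = 2000.0  # per genome, single stress event
    burst_indel_rate: float = 1000.0
    repeat_bias: float = 20.0  # relative indel rate at microsatellite tracts
    ploidy: int | None = None  # resolved: 2 deficient, 4 proficient
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0  # negative-binomial shape; larger = tighter
    noise_rate: float = 0.001  # per-read substitution error
    min_tracked_carrier_fraction: float = 0.02
    immortalization_rate_deficient: float = 1e-4  # per cell; ~60x the proficient rate
    immortalization_rate_proficient: float = 1.67e-6

    def __post_init__(self) -> None:
        if self.regime not in ("mmr_deficient", "mmr_proficient"):
            raise ValueError("regime must be mmr_deficient or mmr_proficient")
        if self.protocol not in ("standard", "serum_depleted"):
            raise ValueError("protocol must be standard or serum_depleted")
        for r in (
            self.canonical_rate,
            self.burst_substitution_rate,
            self.burst_indel_rate,
            self.noise_rate,
        ):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.ploidy is None:
            self.ploidy = 2 if self.regime == "mmr_deficient" else 4
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.regime == "mmr_deficient" and self.repeat_bias < 1.0:
            raise ValueError("repeat_bias must be >= 1 in the MMR-deficient regime")

    @property
    def has_stress_burst(self) -> bool:
        return self.regime == "mmr_deficient" and self.protocol == "standard"

    @property
    def immortalizes(self) -> bool:
        return self.protocol == "standard"


@dataclass(frozen=True)
class TruthMutation:
    """One ground-truth mutation with its final carrier-cell fraction.

    ``position`` is the 0-based coordinate of the substituted base, or of the
    first base of the inserted/deleted unit for indels (the anchor base sits
    at ``position - 1``).
    """

    chrom: str
    position: int
    ref: str
    alt: str
    vtype: str  # sub | ins | del
    phase: str  # embryonic | canonical | burst | expansion
    allele_index: int
    carrier_fraction: float
    division: int | None = None  # expansion division for expansion-phase mutations

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier fraction must be in [0, 1]")
        if self.vtype == "sub" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("substitutions are single-base")
        if self.vtype in ("ins", "del") and len(self.ref) == len(self.alt):
            raise ValueError("indel alt/ref lengths must differ")


@dataclass
class SimulatedVariantTruth:
    mutations: list[TruthMutation]
    immortalized: bool
    ploidy: int
    population_summary: dict

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f.name for f in dataclasses.fields(TruthMutation)]
        return pd.DataFrame(
            [{c: getattr(m, c) for c in cols} for m in self.mutations], columns=cols
        )

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df["position"] = df["position"] + 1  # 1-based in emitted tables
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _draw_substitution(
    genome: SyntheticGenome,
    rng: np.random.Generator,
    taken: set[tuple[int, int]],
    ploidy: int,
) -> tuple[int, str, str, int]:
    for _ in range(1000):
        pos = int(rng.integers(len(genome)))
        allele = int(rng.integers(ploidy))
        if (pos, allele) in taken:
            continue
        ref = genome.sequence[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        taken.add((pos, allele))
        return pos, ref, alt, allele
    raise RuntimeError("could not place substitution without collision")


def _draw_indel(
    genome: SyntheticGenome,
    config: SimulationConfig,
    rng: np.random.Generator,
    taken: set[tuple[int, int]],
) -> TruthMutation | None:
    """One stress-burst indel: repeat-biased toward microsatellite tracts."""
    ms_bases = sum(ms.end - ms.start for ms in genome.microsatellites)
    other_bases = len(genome) - ms_bases
    w_ms = config.repeat_bias * ms_bases
    p_ms = w_ms / (w_ms + other_bases) if (w_ms + other_bases) > 0 else 0.0
    ploidy = config.ploidy
    for _ in range(1000):
        if genome.microsatellites and rng.random() < p_ms:
            ms = genome.microsatellites[int(rng.integers(len(genome.microsatellites)))]
            unit = ms.locus.unit
            pos = ms.start  # slippage events are recorded at the tract start
            is_del = bool(rng.random() < 0.5)
        else:
            pos = int(rng.integers(1, len(genome) - 2))
            unit_len = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                unit = genome.sequence[pos : pos + unit_len]
                is_del = True
            else:
                unit = "".join(rng.choice(_BASES, size=unit_len))
                is_del = False
        allele = int(rng.integers(ploidy))
        if (pos, allele) in taken:
            continue
        taken.add((pos, allele))
        if is_del:
            return TruthMutation(
                genome.name, pos, unit, "", "del", "burst", allele, 1.0
            )
        return TruthMutation(genome.name, pos, "", unit, "ins", "burst", allele, 1.0)
    return None


def simulate_culture(
    genome: SyntheticGenome,
    config: SimulationConfig,
    protocols: CultureProtocols | None = None,
    seed: int | np.random.Generator | None = None,
) -> SimulatedVariantTruth:
    """Simulate mutation accrual through senescence, stress and immortalization.

    Canonical-phase substitutions accrue along the immortalizing lineage at
    ``canonical_rate`` per division over the pre-immortalization protocol; in
    the MMR-deficient standard-protocol regime a single stress burst adds
    substitutions and repeat-biased indels.  All of these are clonal (carrier
    fraction 1) in the expanded clone.  Expansion-phase substitutions arising
    at division d of the clonal expansion carry fraction 2**-d; lineages below
    ``min_tracked_carrier_fraction`` are not materialized (they are beneath
    any bulk-sequencing detection limit).  Under the serum-depleted protocol
    there is no burst and no immortalization: canonical mutations are emitted
    with the carrier fraction of a single surviving lineage in the dish.
    """
    protocols = protocols or CultureProtocols()
    rng = np.random.default_rng(seed)
    ploidy = config.ploidy
    taken: set[tuple[int, int]] = set()
    mutations: list[TruthMutation] = []

    pre_divisions = count_divisions(protocols.pre_immortalization)
    immortal = config.immortalizes
    clonal_fraction = 1.0 if immortal else 1.0 / protocols.expansion_target_cells

    def add_subs(n: int, phase: str, fraction: float, division: int | None = None):
        for _ in range(n):
            pos, ref, alt, allele = _draw_substitution(genome, rng, taken, ploidy)
            mutations.append(
                TruthMutation(
                    genome.name, pos, ref, alt, "sub", phase, allele, fraction, division
                )
            )

    embryonic_divisions = min(3, pre_divisions)
    add_subs(int(rng.poisson(config.canonical_rate * embryonic_divisions)), "embryonic", clonal_fraction)
    add_subs(
        int(rng.poisson(config.canonical_rate * (pre_divisions - embryonic_divisions))),
        "canonical",
        clonal_fraction,
    )

    n_burst_subs = n_burst_indels = 0
    if config.has_stress_burst:
        n_burst_subs = int(rng.poisson(config.burst_substitution_rate))
        add_subs(n_burst_subs, "burst", 1.0)
        n_burst_indels = int(rng.poisson(config.burst_indel_rate))
        for _ in range(n_burst_indels):
            mut = _draw_indel(genome, config, rng, taken)
            if mut is not None:
                mutations.append(mut)

    if immortal:
        d = 1
        while 2.0**-d >= config.min_tracked_carrier_fraction and d <= protocols.expansion_divisions:
            n = int(rng.poisson(config.canonical_rate * 2.0**d))
            add_subs(n, "expansion", 2.0**-d, division=d)
            d += 1

    mutations.sort(key=lambda m: (m.position, m.allele_index))
    rate = (
        config.immortalization_rate_deficient
        if config.regime == "mmr_deficient"
        else config.immortalization_rate_proficient
    )
    summary = {
        "pre_immortalization_divisions": pre_divisions,
        "immortal_phase_divisions": count_divisions(protocols.immortal_phase),
        "expansion_divisions": protocols.expansion_divisions,
        "expected_immortalized_clones": rate * protocols.expansion_target_cells,
        "n_burst_substitutions": n_burst_subs,
        "n_burst_indels": n_burst_indels,
    }
    return SimulatedVariantTruth(mutations, immortal, ploidy, summary)


def _depths(config: SimulationConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial sequencing depths with mean depth_mean."""
    shape = config.depth_dispersion
    p = shape / (shape + config.depth_mean)
    return rng.negative_binomial(shape, p, size=size)


def sample_exome_reads(
    truth: SimulatedVariantTruth,
    genome: SyntheticGenome,
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-mutation ref/alt read counts from the mutated (case) sample.

    Depth is negative-binomial; alt reads are Binomial(depth, carrier_fraction
    * mutant_alleles / ploidy) with one mutant allele per mutation.  Sites
    whose expected fraction is below any detection limit are still emitted
    with their sampled counts.  Positions are 1-based in the output table.
    """
    if config.depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    rng = np.random.default_rng(seed)
    muts = truth.mutations
    depth = _depths(config, len(muts), rng)
    p_alt = np.array([m.carrier_fraction / truth.ploidy for m in muts])
    alt = rng.binomial(depth, p_alt)
    vaf = np.divide(alt, depth, out=np.zeros(len(muts)), where=depth > 0)
    return pd.DataFrame(
        {
            "chrom": [m.chrom for m in muts],
            "pos": [m.position + 1 for m in muts],
            "ref": [m.ref for m in muts],
            "alt": [m.alt for m in muts],
            "vtype": [m.vtype for m in muts],
            "phase": [m.phase for m in muts],
            "carrier_fraction": [m.carrier_fraction for m in muts],
            "region": [genome.region_of(m.position) for m in muts],
            "depth": depth,
            "alt_count": alt,
            "vaf": vaf,
        }
    )


def _pileup_sample(
    positions: np.ndarray,
    refs: list[str],
    alt_p: np.ndarray,
    alt_kind: list[str | None],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, 6) counts of A/C/G/T/ins/del calls for one sample."""
    n = len(positions)
    depth = _depths(config, n, rng)
    counts = np.zeros((n, 6), dtype=np.int64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3, "ins": 4, "del": 5}
    alt_reads = rng.binomial(depth, alt_p)
    for i in range(n):
        ref_reads = depth[i] - alt_reads[i]
        kind = alt_kind[i]
        if kind is not None:
            counts[i, base_idx[kind]] += alt_reads[i]
        # sequencing noise: symmetric substitution errors on base-call reads
        if config.noise_rate > 0 and ref_reads > 0:
            errors = rng.binomial(ref_reads, config.noise_rate)
        else:
            errors = 0
        counts[i, base_idx[refs[i]]] += ref_reads - errors
        if errors:
            others = [b for b in "ACGT" if b != refs[i]]
            scatter = rng.multinomial(errors, [1 / 3] * 3)
            for b, c in zip(others, scatter):
                counts[i, base_idx[b]] += c
    return counts


def emit_pileup_pair(
    truth: SimulatedVariantTruth,
    genome: SyntheticGenome,
    config: SimulationConfig,
    control_seed: int | np.random.Generator | None = None,
    case_seed: int | np.random.Generator | None = None,
    n_null_sites: int = 200,
) -> pd.DataFrame:
    """Paired pileup table: control (unmutated regime) vs case (mutated).

    Rows cover every truth-mutation site plus ``n_null_sites`` probed
    reference positions (a deterministic function of the genome, shared by
    both samples).  Substitutions are piled up at the substituted base; indels
    at their anchor base (the base preceding the inserted/deleted unit), so
    that downstream calls carry the anchor convention of
    :class:`~msiburst.variants.VariantRecord`.  Control counts reflect the
    reference plus sequencing noise; case counts additionally reflect the
    truth mutations.  With equal seeds, zero noise and no mutations the two
    samples are identical.
    """
    rng_ctrl = np.random.default_rng(control_seed)
    rng_case = np.random.default_rng(case_seed)

    site_of = {}  # 0-based pileup site per mutation (first wins per site)
    for m in truth.mutations:
        site = m.position if m.vtype == "sub" else m.position - 1
        site_of.setdefault(site, m)
    pos_set = set(site_of)
    null_rng = np.random.default_rng([len(genome), n_null_sites, 987654321])
    null_positions: list[int] = []
    while len(null_positions) < n_null_sites:
        p = int(null_rng.integers(1, len(genome) - 2))
        if p not in pos_set:
            null_positions.append(p)
            pos_set.add(p)

    positions = np.array(sorted(pos_set))
    refs = [genome.sequence[p] for p in positions]
    alt_p = np.zeros(len(positions))
    alt_kind: list[str | None] = [None] * len(positions)
    indel_seq = [""] * len(positions)
    for i, p in enumerate(positions):
        m = site_of.get(int(p))
        if m is None:
            continue
        alt_p[i] = m.carrier_fraction / truth.ploidy
        if m.vtype == "sub":
            alt_kind[i] = m.alt
        elif m.vtype == "ins":
            alt_kind[i] = "ins"
            indel_seq[i] = m.alt
        else:
            alt_kind[i] = "del"
            indel_seq[i] = m.ref

    ctrl = _pileup_sample(positions, refs, np.zeros(len(positions)), [None] * len(positions), config, rng_ctrl)
    case = _pileup_sample(positions, refs, alt_p, alt_kind, config, rng_case)
    df = pd.DataFrame({"chrom": genome.name, "pos": positions + 1, "ref": refs})
    for j, a in enumerate(("A", "C", "G", "T", "ins", "del")):
        df[f"{a}_control"] = ctrl[:, j]
    for j, a in enumerate(("A", "C", "G", "T", "ins", "del")):
        df[f"{a}_case"] = case[:, j]
    df["indel_seq"] = indel_seq
    return df[list(PILEUP_COLUMNS)]


def emit_fragment_profiles(
    genome: SyntheticGenome,
    truth: SimulatedVariantTruth,
    locus_ids: Sequence[str] | None = None,
    stutter_decay: float = 0.3,
    noise: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> dict[str, tuple[FragmentProfile, FragmentProfile]]:
    """Paired (pre-immortalization, post) fragment profiles at marker loci.

    The pre profile is the reference allele mixture; the post profile reflects
    any truth indel at the locus, with the mutant allele's DNA share equal to
    carrier_fraction / ploidy.
    """
    if locus_ids is None:
        locus_ids = [ms.locus.locus_id for ms in genome.microsatellites[:5]]
    root = np.random.default_rng(seed)
    out: dict[str, tuple[FragmentProfile, FragmentProfile]] = {}
    for locus_id in locus_ids:
        ms = genome.microsatellite_by_id(locus_id)
        locus = ms.locus
        unit_len = locus.unit_length
        # net copy change carried by the immortal clone at this locus
        mutant_mixture: list[tuple[int, float]] = []
        ref_weight = 1.0
        for m in truth.mutations:
            if m.vtype not in ("ins", "del") or not (ms.start <= m.position < ms.end):
                continue
            seq = m.alt if m.vtype == "ins" else m.ref
            if len(seq) % unit_len != 0:
                continue
            delta = (len(seq) // unit_len) * (1 if m.vtype == "ins" else -1)
            share = m.carrier_fraction / truth.ploidy
            mutant_copies = max(1, locus.copies + delta)
            mutant_mixture.append((mutant_copies, share))
            ref_weight -= share
        pre_seed = int(root.integers(2**31))
        post_seed = int(root.integers(2**31))
        pre = simulate_profile(locus, [(locus.copies, 1.0)], stutter_decay, noise, pre_seed)
        mixture = mutant_mixture + [(locus.copies, max(ref_weight, 0.0))]
        total = sum(w for _, w in mixture)
        mixture = [(c, w / total) for c, w in mixture]
        post = simulate_profile(locus, mixture, stutter_decay, noise, post_seed)
        out[locus_id] = (pre, post)
    return out
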