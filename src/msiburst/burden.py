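"""Expected mutation burden and exome detectability for clonally expanding cultures.

During normal growth a mismatch-repair-deficient cell acquires ~25 base
substitutions per genome per division; ~1.5% of those fall in exons.  A
mutation is visible to bulk exome sequencing only once the cells carrying it
make up a sufficient fraction of the dish (10%, i.e. 3 x 10^4 of 3 x 10^5
cells).  Combining the per-division burden with the serial-passage branching
model of :mod:`msiburst.growth` yields the expected number of
replication-error mutations that become detectable late in the immortal phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth import BranchingParams

__all__ = [
    "MutationRateParams",
    "DetectabilityParams",
    "expected_exonic_substitutions",
    "detectable_cell_threshold",
    "estimate_detectable_ip28",
    "biallelic_rate",
]


@dataclass(frozen=True)
class MutationRateParams:
    """Canonical-replication substitution rate and the exonic share of the genome."""

    subs_per_genome_per_division: float = 25.0
    exonic_fraction: float = 0.015

    def __post_init__(self) -> None:
        if self.subs_per_genome_per_division < 0:
            raise ValueError("substitution rate must be >= 0")
        if not 0.0 <= self.exonic_fraction <= 1.0:
            raise ValueError("exonic_fraction must be in [0, 1]")

    @property
    def exonic_rate(self) -> float:
        """Expected exonic substitutions per daughter cell per division."""
        return self.subs_per_genome_per_division * self.exonic_fraction


@dataclass(frozen=True)
class DetectabilityParams:
    """When a clone's mutations become visible to bulk exome sequencing.

    ``min_clone_fraction`` of ``dish_cells`` defines the carrier-cell threshold;
    ``vaf_band`` is the read-fraction window expected for clonal heterozygous
    mutations in a diploid clone.
    """

    min_clone_fraction: float = 0.10
    dish_cells: int = 300_000
    vaf_band: tuple[float, float] = (0.30, 0.60)

    def __post_init__(self) -> None:
        if not 0.0 < self.min_clone_fraction <= 1.0:
            raise ValueError("min_clone_fraction must be in (0, 1]")
        if self.dish_cells < 1:
            raise ValueError("dish_cells must be >= 1")
        low, high = self.vaf_band
        if not 0.0 <= low < high <= 1.0:
            raise ValueError("vaf_band must satisfy 0 <= low < high <= 1")


def expected_exonic_substitutions(
    divisions: int, rates: MutationRateParams | None = None
) -> float:
    """Expected exonic substitutions accumulated along one lineage over ``divisions``.

    48 divisions at the defaults give 18: the burden expected to be detectable
    at IP1, when the dish is a clone of a single immortalized cell.
    """
    if divisions < 0:
        raise ValueError("divisions must be >= 0")
    rates = rates or MutationRateParams()
    return divisions * rates.exonic_rate


def detectable_cell_threshold(det: DetectabilityParams | None = None) -> int:
    """Carrier-cell count above which a clone's mutations are exome-detectable.

    A clone is detectable iff its cell count >= this threshold (the 10%
    criterion is equated with exactly 3 x 10^4 cells per dish at the defaults).
    """
    det = det or DetectabilityParams()
    return round(det.min_clone_fraction * det.dish_cells)


def biallelic_rate(per_allele_mutant_frequency: float) -> float:
    """Frequency of cells hit on both alleles, assuming independent alleles.

    With a per-allele mutant frequency of 3 x 10^-4, biallelic loss arises in
    ~9 x 10^-8 of cells -- no more than once in 10^7.
    """
    if not 0.0 <= per_allele_mutant_frequency <= 1.0:
        raise ValueError("frequency must be in [0, 1]")
    return per_allele_mutant_frequency**2


def estimate_detectable_ip28(
    branch: BranchingParams | None = None,
    rates: MutationRateParams | None = None,
    det: DetectabilityParams | None = None,
    expansion_divisions: int = 19,
    excluded_early_divisions: int = 3,
    replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
    threshold_mode: str = "cells",
    return_counts: bool = False,
):
    """Expected number of clonal-expansion mutations newly detectable at IP28.

    The single immortalized cell expands through ``expansion_divisions``
    synchronous binary divisions to found the IP1 dish.  Each daughter cell at
    division d acquires exonic substitutions at rate ``rates.exonic_rate``; a
    mutation arising at division d is carried by one daughter lineage, i.e. by
    2**(expansion_divisions - d) cells of the 2**expansion_divisions-cell tree
    (carrier fraction 2**-d).  Mutations from the first
    ``excluded_early_divisions`` divisions are excluded: their carrier fraction
    exceeds the detectability cutoff already at IP1, so they are not *newly*
    detectable later.

    Carrier-cell counts are then propagated through ``branch.passages`` rounds
    of the Binomial(4n, 1/4) passage transition, and a mutation is counted when
    its final carrier count reaches the detectability threshold.  With
    ``threshold_mode="cells"`` (default) the threshold is the absolute
    carrier-cell count from :func:`detectable_cell_threshold`; with
    ``threshold_mode="fraction"`` it is ``min_clone_fraction`` of the full
    expansion tree (a strictly harsher criterion under near-critical passaging;
    see docs/methods.md for why the absolute count is the default).

    Returns the Monte-Carlo mean over ``replicates`` seeded replicates (or the
    per-replicate counts when ``return_counts`` is set).
    """
    branch = branch or BranchingParams()
    rates = rates or MutationRateParams()
    det = det or DetectabilityParams()
    if expansion_divisions <= excluded_early_divisions:
        raise ValueError("expansion_divisions must exceed excluded_early_divisions")
    if excluded_early_divisions < 0:
        raise ValueError("excluded_early_divisions must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if threshold_mode not in ("cells", "fraction"):
        raise ValueError("threshold_mode must be 'cells' or 'fraction'")

    rng = np.random.default_rng(seed)
    depths = np.arange(excluded_early_divisions + 1, expansion_divisions + 1)
    # one daughter lineage per mutation: 2**d daughters exist at division d,
    # each accruing Poisson(exonic_rate) new substitutions
    mutations_expected = rates.exonic_rate * np.exp2(depths)
    start_counts = (2 ** (expansion_divisions - depths)).astype(np.int64)
    if threshold_mode == "cells":
        threshold = detectable_cell_threshold(det)
    else:
        threshold = det.min_clone_fraction * 2**expansion_divisions

    g = branch.growth_factor
    f = branch.pass_fraction
    counts = np.empty(replicates, dtype=np.int64)
    for r in range(replicates):
        carriers = np.repeat(start_counts, rng.poisson(mutations_expected))
        for _ in range(branch.passages):
            if carriers.size == 0:
                break
            carriers = _branch_step(carriers, g, f, rng)
        counts[r] = int(np.count_nonzero(carriers >= threshold))
    if return_counts:
        return counts
    return float(counts.mean())


def _branch_step(
    carriers: np.ndarray,
    growth_factor: int,
    pass_fraction: float,
    rng: np.random.Generator,
    small_max: int = 64,
) -> np.ndarray:
    """One Binomial(g*n, f) passage applied to a multiset of clone sizes.

    Clones are exchangeable within a replicate (only the multiset of final
    sizes is ever used), so sizes <= small_max are bucketed with bincount and
    drawn with constant-trial binomial calls, which is substantially faster
    than one varying-trial call per element.  Extinct clones (size 0) drop out.
    """
    small = carriers[carriers <= small_max]
    large = carriers[carriers > small_max]
    parts = []
    if small.size:
        mult = np.bincount(small, minlength=small_max + 1)
        parts.extend(
            rng.binomial(v * growth_factor, pass_fraction, size=int(mult[v]))
            for v in range(1, small_max + 1)
            if mult[v]
        )
    if large.size:
        parts.append(rng.binomial(large * growth_factor, pass_fraction))
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)
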