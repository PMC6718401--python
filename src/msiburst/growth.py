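"""Serial-passage clone dynamics under the 3T3 culture protocol.

Immortalized fibroblast cultures are maintained by re-seeding a fixed number of
cells (3 x 10^5 per dish) every passage.  Between passages the population grows
roughly fourfold (two divisions), after which a quarter of the cells are carried
over.  From the point of view of a single cell, the number of descendants passed
to the next dish is therefore Binomial(4n, 1/4) given n cells in the current
dish -- a critical Galton-Watson branching process: the mean clone size is
conserved while extinction probability accumulates passage after passage.

This module provides

* :class:`PassageProtocol` -- division bookkeeping for ordered culture stages
  (embryogenesis, P1..P7, the immortal IP phase), with presets matching the
  standard mouse-embryonic-fibroblast protocol;
* :class:`BranchingParams` / :class:`CloneSizePMF` -- an exact dynamic-program
  over clone sizes 0..max_tracked_size with explicit truncation-mass
  accounting;
* :func:`simulate_clone_sizes` -- the Monte-Carlo twin of the exact recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "PassageStage",
    "PassageProtocol",
    "BranchingParams",
    "CloneSizePMF",
    "PRE_P8_PROTOCOL",
    "IP_PHASE_PROTOCOL",
    "count_divisions",
    "divisions_to_reach",
    "passage_transition",
    "clone_size_distribution",
    "simulate_clone_sizes",
]

_NORMALIZATION_TOL = 1e-12


@dataclass(frozen=True)
class PassageStage:
    """One culture stage: ``passages`` rounds at ``divisions_per_passage`` each."""

    label: str
    passages: int
    divisions_per_passage: int

    def __post_init__(self) -> None:
        if self.passages < 0:
            raise ValueError(f"stage {self.label!r}: passages must be >= 0")
        if self.divisions_per_passage < 0:
            raise ValueError(f"stage {self.label!r}: divisions_per_passage must be >= 0")

    @property
    def divisions(self) -> int:
        return self.passages * self.divisions_per_passage


@dataclass(frozen=True)
class PassageProtocol:
    """An ordered sequence of culture stages.

    Total divisions are additive over stages and computable without simulation:
    ``sum(stage.passages * stage.divisions_per_passage)``.
    """

    stages: tuple[PassageStage, ...] = ()

    @classmethod
    def from_stages(cls, stages: Iterable[tuple[str, int, int]]) -> "PassageProtocol":
        return cls(tuple(PassageStage(*s) for s in stages))

    @classmethod
    def from_yaml(cls, path) -> "PassageProtocol":
        """Load a protocol from a YAML/JSON list of {label, passages, divisions_per_passage}."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_stages(
            (d["label"], int(d["passages"]), int(d["divisions_per_passage"])) for d in raw
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                [
                    {
                        "label": s.label,
                        "passages": s.passages,
                        "divisions_per_passage": s.divisions_per_passage,
                    }
                    for s in self.stages
                ],
                fh,
                sort_keys=False,
            )

    def total_divisions(self) -> int:
        return sum(s.divisions for s in self.stages)

    def __add__(self, other: "PassageProtocol") -> "PassageProtocol":
        return PassageProtocol(self.stages + other.stages)


#: Division accounting from fertilization to the growth-arrested P8 state:
#: 12 divisions during segmentation, 26 during the remainder of embryogenesis
#: (twice daily to E13.5), two divisions per passage during P1-P3 and one per
#: passage during P4-P7.  Totals 48 divisions.
PRE_P8_PROTOCOL = PassageProtocol.from_stages(
    [
        ("segmentation", 1, 12),
        ("embryogenesis", 13, 2),
        ("P1-P3", 3, 2),
        ("P4-P7", 4, 1),
    ]
)

#: The immortal phase IP1..IP28: 27 passages at roughly two divisions each (54).
IP_PHASE_PROTOCOL = PassageProtocol.from_stages([("IP1-IP28", 27, 2)])


def count_divisions(protocol: PassageProtocol) -> int:
    """Total cell divisions implied by a protocol (sum over stages)."""
    return protocol.total_divisions()


def divisions_to_reach(target_cells: int) -> int:
    """Smallest number of synchronous binary divisions d with 2**d >= target_cells.

    A clone founded by a single immortalized cell must divide ~19 times to fill
    a 3 x 10^5-cell dish (2**19 = 524288).
    """
    if target_cells < 1:
        raise ValueError("target_cells must be >= 1")
    return int(target_cells - 1).bit_length()


@dataclass(frozen=True)
class BranchingParams:
    """Parameters of the per-passage branching transition.

    A clone of n cells grows by ``2**divisions_per_passage`` per passage and a
    fraction ``pass_fraction`` of cells is re-seeded, so the next-passage size
    is Binomial(n * 2**divisions_per_passage, pass_fraction).  With the default
    two divisions and 1/4 pass fraction the offspring mean per cell is exactly
    1: the process is critical.
    """

    passages: int = 27
    divisions_per_passage: int = 2
    pass_fraction: float = 0.25
    seeded_cells: int = 300_000
    max_tracked_size: int = 200

    def __post_init__(self) -> None:
        if self.passages < 0:
            raise ValueError("passages must be >= 0")
        if self.divisions_per_passage < 1:
            raise ValueError("divisions_per_passage must be >= 1")
        if not 0.0 <= self.pass_fraction <= 1.0:
            raise ValueError("pass_fraction must be in [0, 1]")
        if self.seeded_cells < 1:
            raise ValueError("seeded_cells must be >= 1")
        if self.max_tracked_size < 1:
            raise ValueError("max_tracked_size must be >= 1")

    @property
    def growth_factor(self) -> int:
        return 2**self.divisions_per_passage

    @property
    def offspring_mean(self) -> float:
        return self.growth_factor * self.pass_fraction

    @property
    def offspring_variance(self) -> float:
        return self.growth_factor * self.pass_fraction * (1.0 - self.pass_fraction)


@dataclass
class CloneSizePMF:
    """Probability mass over clone sizes 0..cap, plus explicit overflow mass.

    ``probabilities[k]`` is P(clone size == k); ``truncation_mass`` is the
    probability that the clone exceeded the tracked cap at some passage.  The
    two always sum to 1; overflow is recorded, never silently renormalized.
    """

    probabilities: np.ndarray
    truncation_mass: float = 0.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.validate()

    @classmethod
    def point_mass(cls, size: int, cap: int) -> "CloneSizePMF":
        if not 0 <= size <= cap:
            raise ValueError("point mass size must lie within 0..cap")
        p = np.zeros(cap + 1)
        p[size] = 1.0
        return cls(p)

    @property
    def cap(self) -> int:
        return len(self.probabilities) - 1

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.cap + 1)

    def validate(self) -> None:
        if self.probabilities.ndim != 1 or len(self.probabilities) < 1:
            raise ValueError("probabilities must be a non-empty 1-d array")
        if (self.probabilities < -_NORMALIZATION_TOL).any() or self.truncation_mass < -_NORMALIZATION_TOL:
            raise ValueError("negative probability mass")
        total = float(self.probabilities.sum()) + self.truncation_mass
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pmf not normalized: total mass {total!r}")

    def mean(self) -> float:
        """Mean clone size over the tracked range (truncated clones excluded)."""
        return float(self.sizes @ self.probabilities)

    @property
    def extinction_probability(self) -> float:
        return float(self.probabilities[0])

    def mass_between(self, lo: int, hi: int) -> float:
        """Probability of a size in the closed range [lo, hi]."""
        lo = max(lo, 0)
        hi = min(hi, self.cap)
        if hi < lo:
            return 0.0
        return float(self.probabilities[lo : hi + 1].sum())

    def conditional_on_survival(self) -> "CloneSizePMF":
        """The pmf conditional on non-extinction (size >= 1 or truncated)."""
        surviving = 1.0 - self.extinction_probability
        if surviving <= 0.0:
            raise ValueError("no surviving mass to condition on")
        p = self.probabilities.copy()
        p[0] = 0.0
        return CloneSizePMF(p / surviving, self.truncation_mass / surviving)

    def as_dict(self) -> Mapping[int, float]:
        return {int(k): float(v) for k, v in zip(self.sizes, self.probabilities)}

    def to_tsv(self, path) -> None:
        """Export as two-column TSV (size, probability); truncation in a trailing row."""
        df = pd.DataFrame({"size": self.sizes, "probability": self.probabilities})
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
            fh.write(f"#truncation_mass\t{self.truncation_mass:.12g}\n")


@lru_cache(maxsize=8)
def _transition_matrix(cap: int, growth_factor: int, pass_fraction: float):
    """(cap+1, cap+1) matrix T[n, m] = P(Binomial(g*n, f) == m), plus overflow column.

    Binomial coefficients are evaluated in log space (scipy logpmf) so rows with
    g*n in the hundreds do not overflow.
    """
    n = np.arange(cap + 1)
    m = np.arange(cap + 1)
    trials = (growth_factor * n)[:, None]
    with np.errstate(divide="ignore"):
        logpmf = stats.binom.logpmf(m[None, :], trials, pass_fraction)
    T = np.exp(logpmf)
    T[0] = 0.0
    T[0, 0] = 1.0  # extinction is absorbing
    overflow = stats.binom.sf(cap, growth_factor * n, pass_fraction)
    overflow[0] = 0.0
    return T, overflow


def passage_transition(pmf: CloneSizePMF, params: BranchingParams | None = None) -> CloneSizePMF:
    """One passage of the branching recursion.

    output(m) = sum_n pmf(n) * P(Binomial(g*n, f) == m) for m in 0..cap; mass
    landing beyond the cap joins ``truncation_mass``, which is absorbing (a
    truncated clone is counted as "large", never re-enters the tracked range).
    """
    params = params or BranchingParams()
    if pmf.cap != params.max_tracked_size:
        raise ValueError("pmf cap does not match params.max_tracked_size")
    T, overflow = _transition_matrix(
        params.max_tracked_size, params.growth_factor, params.pass_fraction
    )
    out = pmf.probabilities @ T
    trunc = pmf.truncation_mass + float(pmf.probabilities @ overflow)
    return CloneSizePMF(out, trunc)


def clone_size_distribution(params: BranchingParams | None = None) -> CloneSizePMF:
    """Exact clone-size distribution after ``params.passages`` passages from one cell."""
    params = params or BranchingParams()
    pmf = CloneSizePMF.point_mass(1, params.max_tracked_size)
    for _ in range(params.passages):
        pmf = passage_transition(pmf, params)
    return pmf


def simulate_clone_sizes(
    params: BranchingParams | None = None,
    founders: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo twin of :func:`clone_size_distribution`: one final size per founder."""
    params = params or BranchingParams()
    if founders < 1:
        raise ValueError("founders must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = np.ones(founders, dtype=np.int64)
    g = params.growth_factor
    for _ in range(params.passages):
        alive = sizes > 0
        if not alive.any():
            break
        grown = sizes[alive] * g
        if params.pass_fraction == 1.0:
            sizes[alive] = grown  # deterministic growth, nothing discarded
        else:
            sizes[alive] = rng.binomial(grown, params.pass_fraction)
    return sizes
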