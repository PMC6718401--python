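"""Microsatellite fragment-length profiles and peak-shift MSI calling.

Microsatellite instability (MSI) is scored from capillary electrophoresis of
PCR-amplified marker loci: each allele produces a ladder of fragments (the
true length plus shorter PCR-stutter products, which lose whole repeat units
with geometrically decaying intensity), and an instability event shows up as a
shifted modal peak or a new secondary peak when the profile of a derived
culture is compared against its pre-immortalization reference.

A panel of five mono-/di-nucleotide marker loci is scored per sample; by
default a shift at any single locus calls the sample MSI (single-locus shifts
are accepted as genuine instability; the stricter two-of-five clinical scoring
is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MicrosatelliteLocus",
    "FragmentProfile",
    "LocusCall",
    "MSICall",
    "MOUSE_PANEL",
    "HUMAN_PANEL",
    "simulate_profile",
    "detect_peak_shift",
    "msi_status",
    "load_panel",
    "save_panel",
]


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A marker locus: tandem copies of a 1- or 2-base unit plus primer flank.

    The amplified reference fragment length is ``flanking + unit_length *
    copies``; slippage events change the fragment length in whole units.
    """

    locus_id: str
    unit: str
    copies: int
    flanking: int = 100

    def __post_init__(self) -> None:
        if len(self.unit) not in (1, 2):
            raise ValueError("unit length must be 1 or 2 for the marker panels")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.flanking < 0:
            raise ValueError("flanking must be >= 0")

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def tract_length(self) -> int:
        return self.unit_length * self.copies

    @property
    def reference_fragment_length(self) -> int:
        return self.flanking + self.tract_length

    def fragment_length(self, copies: int) -> int:
        return self.flanking + self.unit_length * copies


#: Mouse marker panel (all di-nucleotide repeats).  Copy numbers and flanking
#: lengths are synthetic stand-ins chosen in the realistic range for these
#: assays; the assay logic depends only on unit length.
MOUSE_PANEL: tuple[MicrosatelliteLocus, ...] = (
    MicrosatelliteLocus("D10mit2", "CA", 22, 110),
    MicrosatelliteLocus("D17mit123", "CA", 20, 95),
    MicrosatelliteLocus("D7mit91", "CA", 24, 120),
    MicrosatelliteLocus("D1mit36", "CA", 18, 105),
    MicrosatelliteLocus("D14mit15", "CA", 21, 100),
)

#: Human marker panel (Bethesda-style: three di- and two mono-nucleotide loci).
HUMAN_PANEL: tuple[MicrosatelliteLocus, ...] = (
    MicrosatelliteLocus("D17S250", "CA", 24, 110),
    MicrosatelliteLocus("D2S123", "CA", 21, 115),
    MicrosatelliteLocus("BAT25", "T", 25, 90),
    MicrosatelliteLocus("BAT26", "A", 26, 85),
    MicrosatelliteLocus("D5S346", "CA", 23, 100),
)


def load_panel(path) -> tuple[MicrosatelliteLocus, ...]:
    """Read a marker panel from TSV (locus_id, unit, copies, flanking)."""
    df = pd.read_csv(path, sep="\t")
    return tuple(
        MicrosatelliteLocus(str(r.locus_id), str(r.unit), int(r.copies), int(r.flanking))
        for r in df.itertuples()
    )


def save_panel(panel: Sequence[MicrosatelliteLocus], path) -> None:
    pd.DataFrame(
        [
            {"locus_id": l.locus_id, "unit": l.unit, "copies": l.copies, "flanking": l.flanking}
            for l in panel
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class FragmentProfile:
    """Fragment length -> relative intensity, max-normalized to 1.

    Lengths are stored sorted ascending; intensities are non-negative with at
    least one positive entry.
    """

    lengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.lengths.shape != self.intensities.shape or self.lengths.ndim != 1:
            raise ValueError("lengths and intensities must be matching 1-d arrays")
        if len(self.lengths) == 0:
            raise ValueError("profile must be non-empty")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be >= 0")
        if not (self.intensities > 0).any():
            raise ValueError("profile needs at least one positive intensity")
        order = np.argsort(self.lengths)
        self.lengths = self.lengths[order]
        self.intensities = self.intensities[order]
        self.intensities = self.intensities / self.intensities.max()

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "FragmentProfile":
        lengths = np.array(sorted(mapping))
        return cls(lengths, np.array([mapping[k] for k in lengths], dtype=float))

    @property
    def modal_length(self) -> int:
        """Fragment length of the global maximum (smallest length on exact ties)."""
        return int(self.lengths[int(np.argmax(self.intensities))])

    def intensity_at(self, length: int) -> float:
        idx = np.flatnonzero(self.lengths == length)
        return float(self.intensities[idx[0]]) if idx.size else 0.0

    def local_maxima(self) -> list[int]:
        """Lengths whose intensity is positive and >= both neighbours."""
        ints = self.intensities
        out = []
        for i in range(len(ints)):
            if ints[i] <= 0:
                continue
            left_ok = i == 0 or ints[i] >= ints[i - 1]
            right_ok = i == len(ints) - 1 or ints[i] >= ints[i + 1]
            if left_ok and right_ok:
                out.append(int(self.lengths[i]))
        return out

    def translated(self, offset: int) -> "FragmentProfile":
        return FragmentProfile(self.lengths + offset, self.intensities.copy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"length": self.lengths, "intensity": self.intensities}).to_csv(
            path, index=False, float_format="%.8g"
        )

    @classmethod
    def from_csv(cls, path) -> "FragmentProfile":
        df = pd.read_csv(path)
        return cls(df["length"].to_numpy(), df["intensity"].to_numpy())


def simulate_profile(
    locus: MicrosatelliteLocus,
    mixture: Sequence[tuple[int, float]],
    stutter_decay: float = 0.3,
    noise: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> FragmentProfile:
    """Simulate the electropherogram of an allele mixture at one locus.

    Each allele of ``copies`` repeat units contributes a stutter ladder:
    intensity ``stutter_decay**k`` at ``copies - k`` units (k >= 0), i.e.
    slippage during amplification loses whole units with geometric decay.
    Ladders are summed with the mixture weights, Gaussian baseline noise of
    standard deviation ``noise`` (relative to the maximum) is added, and the
    profile is max-normalized.
    """
    if len(mixture) == 0:
        raise ValueError("mixture must be non-empty")
    weights = np.array([w for _, w in mixture], dtype=float)
    if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must be non-negative and sum to 1")
    if not 0.0 <= stutter_decay < 1.0:
        raise ValueError("stutter_decay must be in [0, 1)")
    rng = np.random.default_rng(seed)

    max_copies = max(c for c, _ in mixture)
    grid = np.arange(1, max_copies + 1)  # ladder in units of repeat copies
    intensity = np.zeros_like(grid, dtype=float)
    for copies, weight in mixture:
        if copies < 1:
            raise ValueError("allele copy numbers must be >= 1")
        k = copies - grid  # units lost
        ladder = np.where(k >= 0, stutter_decay ** np.maximum(k, 0), 0.0)
        if stutter_decay == 0.0:
            ladder = (grid == copies).astype(float)
        intensity += weight * ladder
    if noise > 0.0:
        intensity = intensity + rng.normal(0.0, noise * intensity.max(), size=len(grid))
        intensity = np.clip(intensity, 0.0, None)
    if not (intensity > 0).any():  # noise wiped everything; keep the modal allele
        intensity[-1] = 1.0
    lengths = locus.flanking + locus.unit_length * grid
    return FragmentProfile(lengths, intensity)


def detect_peak_shift(
    reference: FragmentProfile,
    test: FragmentProfile,
    unit_length: int,
    min_shift_units: int = 1,
    min_secondary_fraction: float = 0.2,
) -> tuple[bool, int]:
    """Compare paired profiles at a locus and report a peak shift, in units.

    A locus is shifted when (a) the test profile's modal length differs from
    the reference modal length by at least ``min_shift_units`` repeat units, or
    (b) the test profile contains a local maximum of relative intensity at
    least ``min_secondary_fraction`` at a length at least that far from the
    reference mode where the reference itself stays below that fraction and
    the peak rises above the reference trace by at least the fraction itself
    (a genuinely new secondary peak; the excess margin keeps baseline noise
    from promoting faint stutter rungs into calls).  Returns (shifted, signed shift
    in repeat units: the modal shift or the nearest qualifying secondary peak).
    """
    if unit_length < 1:
        raise ValueError("unit_length must be >= 1")
    min_dist = min_shift_units * unit_length
    ref_mode = reference.modal_length
    test_mode = test.modal_length
    delta = test_mode - ref_mode
    if abs(delta) >= min_dist:
        return True, int(round(delta / unit_length))
    candidates = []
    for length in test.local_maxima():
        offset = length - ref_mode
        if abs(offset) < min_dist:
            continue
        ref_here = reference.intensity_at(length)
        if test.intensity_at(length) < min_secondary_fraction:
            continue
        if ref_here >= min_secondary_fraction:
            continue
        if test.intensity_at(length) - ref_here < min_secondary_fraction:
            continue
        candidates.append(offset)
    if candidates:
        offset = min(candidates, key=abs)
        return True, int(round(offset / unit_length))
    return False, 0


@dataclass(frozen=True)
class LocusCall:
    locus_id: str
    shifted: bool
    shift_units: int


@dataclass(frozen=True)
class MSICall:
    """Panel-level MSI status: MSI iff at least ``min_shifted_loci`` loci shifted."""

    per_locus: tuple[LocusCall, ...]
    status: str  # "MSI" | "MSS"

    @property
    def n_shifted(self) -> int:
        return sum(c.shifted for c in self.per_locus)


def msi_status(calls: Sequence[LocusCall], min_shifted_loci: int = 1) -> MSICall:
    """Aggregate per-locus shift calls into an overall MSI/MSS status.

    The default accepts a single shifted locus as MSI; ``min_shifted_loci=2``
    gives the clinical two-of-five scoring.
    """
    if len(calls) == 0:
        raise ValueError("at least one locus call is required")
    if min_shifted_loci < 1:
        raise ValueError("min_shifted_loci must be >= 1")
    n_shifted = sum(c.shifted for c in calls)
    status = "MSI" if n_shifted >= min_shifted_loci else "MSS"
    return MSICall(tuple(calls), status)
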