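"""Ploidy classification and discrete alteration calling.

Allele-specific segmented profiles (integer total and minor copy number per
segment) are converted into per-probe LOSS/NEUTRAL/GAIN/AMP states with
cutoffs that depend on the tumour's ploidy class:

* near-diploid: loss ``<=1``, gain ``>=3``, amplification ``>=6``
* near-tetraploid: loss ``<=2``, gain ``>=6``, amplification ``>=8``

LOH is called on segments whose minor-allele copy number is zero while at
least one copy remains; ``total == 0`` is a homozygous deletion and flagged
separately.  Breakpoints are within-chromosome changes of copy number or
allelic composition between adjacent segments.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .maps import SNPMap

logger = logging.getLogger(__name__)


class State(enum.IntEnum):
    """Discrete alteration state; ordering reflects copy-number direction."""

    LOSS = 0
    NEUTRAL = 1
    GAIN = 2
    AMP = 3


class PloidyClass(str, enum.Enum):
    NEAR_DIPLOID = "near_diploid"
    NEAR_TETRAPLOID = "near_tetraploid"
    UNDECLARED = "undeclared"


class LohStatus(str, enum.Enum):
    NONE = "none"
    LOH = "loh"
    HOMOZYGOUS_DELETION = "homozygous_deletion"


@dataclass(frozen=True)
class Segment:
    """One constant-copy-number stretch, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    total: int
    minor: int

    def __post_init__(self) -> None:
        for name in ("total", "minor"):
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
                raise ValidationError(
                    f"{name} copy number must be an integer, got {value!r}"
                )
            if value < 0:
                raise ValidationError(f"{name} copy number must be >= 0")
        if self.minor > self.total - self.minor:
            raise ValidationError(
                f"minor copy {self.minor} exceeds total-minor for total {self.total}"
            )
        if self.end <= self.start:
            raise ValidationError("segment end must exceed start")

    @property
    def major(self) -> int:
        return self.total - self.minor


@dataclass(frozen=True)
class SegmentProfile:
    """One tumour's allele-specific segmented genome."""

    sample_id: str
    segments: tuple[Segment, ...]
    ploidy: PloidyClass = PloidyClass.UNDECLARED

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        by_chrom: dict[str, Segment] = {}
        seen_after: set[str] = set()
        for seg in self.segments:
            prev = by_chrom.get(seg.chrom)
            if prev is not None:
                if seg.chrom in seen_after:
                    raise ValidationError(
                        f"{self.sample_id}: segments of chromosome {seg.chrom} "
                        "are not contiguous in the profile"
                    )
                if seg.start < prev.end:
                    raise ValidationError(
                        f"{self.sample_id}: overlapping/unsorted segments on "
                        f"chromosome {seg.chrom} at {seg.start}"
                    )
            for other in by_chrom:
                if other != seg.chrom:
                    seen_after.add(other)
            by_chrom[seg.chrom] = seg

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for seg in self.segments:
            if not out or out[-1] != seg.chrom:
                out.append(seg.chrom)
        return out


@dataclass(frozen=True)
class PloidyCutoffs:
    """Alteration cutoffs: LOSS ``<= loss_max``, GAIN ``>= gain_min``,
    AMP ``>= amp_min``."""

    loss_max: int
    gain_min: int
    amp_min: int

    def __post_init__(self) -> None:
        if not self.loss_max < self.gain_min < self.amp_min:
            raise ValidationError("require loss_max < gain_min < amp_min")


DEFAULT_CUTOFFS: dict[PloidyClass, PloidyCutoffs] = {
    PloidyClass.NEAR_DIPLOID: PloidyCutoffs(loss_max=1, gain_min=3, amp_min=6),
    PloidyClass.NEAR_TETRAPLOID: PloidyCutoffs(loss_max=2, gain_min=6, amp_min=8),
}

# Length-weighted mean total copy number at/above which a profile with no
# declared ploidy is treated as near-tetraploid.
PLOIDY_SPLIT = 3.0


@dataclass
class StatusProfile:
    """Per-probe alteration states for one sample over a :class:`SNPMap`."""

    sample_id: str
    states: np.ndarray  # int8, State values
    loh: np.ndarray  # bool
    homdel: np.ndarray  # bool
    ploidy: PloidyClass = PloidyClass.UNDECLARED


def estimate_ploidy_class(profile: SegmentProfile) -> PloidyClass:
    """Resolve the ploidy class of a profile.

    A declared class is returned unchanged.  Otherwise the profile is
    near-tetraploid iff its length-weighted mean total copy number is
    ``>= 3.0`` (ties resolve to near-tetraploid), else near-diploid.
    """
    if profile.ploidy is not PloidyClass.UNDECLARED:
        return profile.ploidy
    if not profile.segments:
        raise ValidationError(f"{profile.sample_id}: empty profile")
    lengths = np.array([s.end - s.start for s in profile.segments], dtype=float)
    totals = np.array([s.total for s in profile.segments], dtype=float)
    mean_cn = float(np.average(totals, weights=lengths))
    if mean_cn >= PLOIDY_SPLIT:
        return PloidyClass.NEAR_TETRAPLOID
    return PloidyClass.NEAR_DIPLOID


def call_status(total_cn: int, cutoffs: PloidyCutoffs) -> State:
    """Map one integer total copy number to a discrete state."""
    if isinstance(total_cn, bool) or not isinstance(total_cn, (int, np.integer)):
        raise ValidationError(f"total copy number must be an integer, got {total_cn!r}")
    if total_cn < 0:
        raise ValidationError("total copy number must be >= 0")
    if total_cn <= cutoffs.loss_max:
        return State.LOSS
    if total_cn >= cutoffs.amp_min:
        return State.AMP
    if total_cn >= cutoffs.gain_min:
        return State.GAIN
    return State.NEUTRAL


def detect_loh(total: int, minor: int) -> LohStatus:
    """LOH iff no minor allele remains but the locus is not fully deleted."""
    if minor < 0 or total < 0:
        raise ValidationError("copy numbers must be >= 0")
    if total == 0:
        return LohStatus.HOMOZYGOUS_DELETION
    if minor == 0:
        return LohStatus.LOH
    return LohStatus.NONE


def call_profile(
    profile: SegmentProfile,
    snp_map: SNPMap,
    cutoffs: dict[PloidyClass, PloidyCutoffs] | None = None,
    exclude_chromosomes: tuple[str, ...] = (),
) -> StatusProfile:
    """Project a segmented profile onto per-probe states.

    Each probe takes the state of the segment containing its position; probes
    not covered by any segment stay NEUTRAL (a warning is logged).
    ``exclude_chromosomes`` forces whole chromosomes (typically ``("X",)``) to
    NEUTRAL regardless of the profile.
    """
    cutoffs = cutoffs or DEFAULT_CUTOFFS
    ploidy = estimate_ploidy_class(profile)
    cut = cutoffs[ploidy]

    n = snp_map.n_probes
    states = np.full(n, State.NEUTRAL, dtype=np.int8)
    loh = np.zeros(n, dtype=bool)
    homdel = np.zeros(n, dtype=bool)
    covered = np.zeros(n, dtype=bool)

    for seg in profile.segments:
        if seg.chrom not in snp_map.chromosomes:
            continue
        lo, hi = snp_map.probe_range(seg.chrom, seg.start, seg.end)
        if lo == hi:
            continue
        states[lo:hi] = call_status(seg.total, cut)
        allelic = detect_loh(seg.total, seg.minor)
        loh[lo:hi] = allelic is LohStatus.LOH
        homdel[lo:hi] = allelic is LohStatus.HOMOZYGOUS_DELETION
        covered[lo:hi] = True

    for chrom in exclude_chromosomes:
        if chrom in snp_map.chromosomes:
            sl = snp_map.chrom_slice(chrom)
            states[sl] = State.NEUTRAL
            loh[sl] = False
            homdel[sl] = False
            covered[sl] = True

    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.warning(
            "%s: %d probes not covered by any segment; set NEUTRAL",
            profile.sample_id, n_uncovered,
        )
    return StatusProfile(profile.sample_id, states, loh, homdel, ploidy)


def count_breakpoints(profile: SegmentProfile) -> int:
    """Count within-chromosome transitions of copy number or allelic state.

    Adjacent same-chromosome segments count one breakpoint when they differ
    in total copy number or in (major, minor) composition.  Chromosome
    boundaries are never breakpoints.
    """
    count = 0
    for prev, cur in zip(profile.segments, profile.segments[1:]):
        if prev.chrom != cur.chrom:
            continue
        if prev.total != cur.total or prev.minor != cur.minor:
            count += 1
    return count
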