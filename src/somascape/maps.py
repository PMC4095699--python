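"""Probe position maps.

A :class:`SNPMap` fixes the ordered set of genotyping probe positions that all
per-probe status arrays are laid out against.  Run-length rules ("at least 25
consecutive probes") are defined over this map, so every cohort-level
operation requires the matrices involved to share one map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, ValidationError

# GRCh37 chromosome lengths (bp), autosomes + X.
CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560,
}

# Approximate GRCh37 centromere midpoints (bp); used only to split arms.
CENTROMERES: dict[str, int] = {
    "1": 125_000_000, "2": 93_300_000, "3": 91_000_000, "4": 50_400_000,
    "5": 48_400_000, "6": 61_000_000, "7": 59_900_000, "8": 45_600_000,
    "9": 49_000_000, "10": 40_200_000, "11": 53_700_000, "12": 35_800_000,
    "13": 17_900_000, "14": 17_600_000, "15": 19_000_000, "16": 36_600_000,
    "17": 24_000_000, "18": 17_200_000, "19": 26_500_000, "20": 27_500_000,
    "21": 13_200_000, "22": 14_700_000, "X": 60_600_000,
}

DEFAULT_CHROMOSOMES: tuple[str, ...] = tuple(CHROM_LENGTHS)


@dataclass(frozen=True, eq=False)
class SNPMap:
    """Ordered probe positions, grouped by chromosome.

    Positions are integer base pairs, strictly increasing within each
    chromosome; every chromosome must carry at least one probe.  Probes are
    globally indexed by concatenating chromosomes in ``chromosomes`` order.
    """

    chromosomes: tuple[str, ...]
    positions: Mapping[str, np.ndarray]
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("SNPMap needs at least one chromosome")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValidationError("duplicate chromosome labels")
        offsets: dict[str, int] = {}
        total = 0
        pos = dict(self.positions)
        for chrom in self.chromosomes:
            if chrom not in pos:
                raise ValidationError(f"no positions for chromosome {chrom!r}")
            arr = np.asarray(pos[chrom], dtype=np.int64)
            if arr.size == 0:
                raise ValidationError(f"chromosome {chrom!r} is empty")
            if np.any(np.diff(arr) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {chrom!r}"
                )
            pos[chrom] = arr
            offsets[chrom] = total
            total += arr.size
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_offsets", offsets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SNPMap):
            return NotImplemented
        return self.chromosomes == other.chromosomes and all(
            np.array_equal(self.positions[c], other.positions[c])
            for c in self.chromosomes
        )

    def __hash__(self) -> int:  # identity-based; maps are effectively singletons
        return id(self)

    # -- indexing ---------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return sum(self.positions[c].size for c in self.chromosomes)

    def offset(self, chrom: str) -> int:
        """Global index of the first probe on ``chrom``."""
        try:
            return self._offsets[chrom]
        except KeyError:
            raise ConfigurationError(f"unknown chromosome {chrom!r}") from None

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offset(chrom)
        return slice(off, off + self.positions[chrom].size)

    def global_positions(self) -> np.ndarray:
        return np.concatenate([self.positions[c] for c in self.chromosomes])

    def global_chromosomes(self) -> np.ndarray:
        return np.concatenate(
            [np.repeat(c, self.positions[c].size) for c in self.chromosomes]
        )

    def probe_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global [lo, hi) probe index range with positions in [start, end)."""
        pos = self.positions[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        off = self.offset(chrom)
        return off + int(lo), off + int(hi)

    # -- arms -------------------------------------------------------------

    def arm_interval(self, arm: str) -> tuple[str, int, int]:
        """(chrom, start, end) half-open bp interval for e.g. ``"8q"``."""
        if len(arm) < 2 or arm[-1] not in "pq":
            raise ConfigurationError(f"malformed chromosome arm {arm!r}")
        chrom, side = arm[:-1], arm[-1]
        if chrom not in self._offsets:
            raise ConfigurationError(f"unknown chromosome arm {arm!r}")
        centro = CENTROMERES.get(chrom)
        if centro is None:
            raise ConfigurationError(f"no centromere known for {chrom!r}")
        last = int(self.positions[chrom][-1]) + 1
        return (chrom, 1, centro) if side == "p" else (chrom, centro, last)

    # -- constructors -----------------------------------------------------

    @classmethod
    def default(cls, probes_per_chromosome: int = 1000,
                chromosomes: Iterable[str] = DEFAULT_CHROMOSOMES) -> "SNPMap":
        """Reduced genome: evenly spaced probes on each requested chromosome."""
        chroms = tuple(chromosomes)
        positions = {}
        for chrom in chroms:
            length = CHROM_LENGTHS[chrom]
            grid = np.linspace(1, length, probes_per_chromosome)
            positions[chrom] = np.round(grid).astype(np.int64)
        return cls(chromosomes=chroms, positions=positions)
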