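"""Cohort frequency profiles and recurrent minimal regions.

A recurrent region is a maximal run of at least ``min_snps`` consecutive
probes, within one chromosome, where the cohort frequency of the queried
event is strictly greater than ``min_freq`` at every probe (defaults: 25
probes, 20%).  Group contrasts use the analogous rule on the absolute
frequency difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .calling import State, StatusProfile
from .errors import ValidationError
from .maps import SNPMap

DEFAULT_MIN_SNPS = 25
DEFAULT_MIN_FREQ = 0.20
# Preset for "most frequent" landmark changes.
HIGH_RECURRENCE_FREQ = 0.40

EventSet = frozenset[State]

# Convenience event sets used by the CLI and reports.
EVENT_PRESETS: dict[str, EventSet] = {
    "loss": frozenset({State.LOSS}),
    "gain": frozenset({State.GAIN, State.AMP}),
    "amp": frozenset({State.AMP}),
    "gain_only": frozenset({State.GAIN}),
    "neutral": frozenset({State.NEUTRAL}),
}


def _as_event_set(event: State | Iterable[State]) -> EventSet:
    if isinstance(event, State):
        return frozenset({event})
    out = frozenset(event)
    if not out or not all(isinstance(s, State) for s in out):
        raise ValidationError(f"invalid event set {event!r}")
    return out


@dataclass
class StatusMatrix:
    """Samples x probes grid of discrete states over one :class:`SNPMap`."""

    snp_map: SNPMap
    sample_ids: list[str]
    states: np.ndarray  # (n_samples, n_probes) int8
    loh: np.ndarray | None = None  # same shape, bool
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids must be unique")
        expected = (len(self.sample_ids), self.snp_map.n_probes)
        if self.states.shape != expected:
            raise ValidationError(
                f"states shape {self.states.shape} != expected {expected}"
            )
        if self.loh is not None and np.asarray(self.loh).shape != expected:
            raise ValidationError("loh array shape mismatch")
        if self.groups is not None and len(self.groups) != len(self.sample_ids):
            raise ValidationError("group labels length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[StatusProfile],
        snp_map: SNPMap,
        groups: list[str] | None = None,
    ) -> "StatusMatrix":
        states = np.vstack([p.states for p in profiles])
        loh = np.vstack([p.loh for p in profiles])
        return cls(
            snp_map=snp_map,
            sample_ids=[p.sample_id for p in profiles],
            states=states,
            loh=loh,
            groups=groups,
        )

    def subset(self, indices: Sequence[int]) -> "StatusMatrix":
        idx = list(indices)
        return StatusMatrix(
            snp_map=self.snp_map,
            sample_ids=[self.sample_ids[i] for i in idx],
            states=self.states[idx],
            loh=None if self.loh is None else self.loh[idx],
            groups=None if self.groups is None else [self.groups[i] for i in idx],
        )


@dataclass(frozen=True)
class RecurrentRegion:
    """A maximal qualifying probe run; probe indices are global, inclusive."""

    chrom: str
    start_bp: int
    end_bp: int
    start_probe: int
    end_probe: int
    event: str
    frequency: float  # minimum per-probe frequency across the run
    carriers: tuple[str, ...]

    @property
    def n_probes(self) -> int:
        return self.end_probe - self.start_probe + 1


@dataclass(frozen=True)
class RegionContrast:
    chrom: str
    start_bp: int
    end_bp: int
    start_probe: int
    end_probe: int
    event: str
    freq_a: float  # mean frequency over the run, cohort A
    freq_b: float
    fisher_p: float | None = None
    fisher_q: float | None = None


def frequency_profile(
    matrix: StatusMatrix, event: State | Iterable[State]
) -> np.ndarray:
    """Per-probe proportion of samples whose state lies in the event set."""
    if matrix.n_samples == 0:
        raise ValidationError("empty cohort")
    events = _as_event_set(event)
    member = np.isin(matrix.states, [int(s) for s in events])
    return member.mean(axis=0)


def _qualifying_runs(
    mask: np.ndarray, snp_map: SNPMap, min_snps: int
) -> list[tuple[str, int, int]]:
    """Maximal True runs of mask, per chromosome, of length >= min_snps.

    Returns (chrom, global start index, global end index inclusive).
    """
    runs: list[tuple[str, int, int]] = []
    for chrom in snp_map.chromosomes:
        sl = snp_map.chrom_slice(chrom)
        local = mask[sl]
        if not local.any():
            continue
        padded = np.concatenate(([False], local, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2] - 1
        for lo, hi in zip(starts, ends):
            if hi - lo + 1 >= min_snps:
                runs.append((chrom, sl.start + int(lo), sl.start + int(hi)))
    return runs


def recurrent_regions(
    matrix: StatusMatrix,
    event: State | Iterable[State],
    min_snps: int = DEFAULT_MIN_SNPS,
    min_freq: float = DEFAULT_MIN_FREQ,
) -> list[RecurrentRegion]:
    """All maximal runs where the event frequency strictly exceeds ``min_freq``.

    The run must span at least ``min_snps`` consecutive probes on one
    chromosome.  The reported frequency is the minimum per-probe frequency
    over the run; carriers are samples showing the event at one or more
    probes of the run.
    """
    if min_snps < 1:
        raise ValidationError("min_snps must be >= 1")
    events = _as_event_set(event)
    freq = frequency_profile(matrix, events)
    mask = freq > min_freq
    member = np.isin(matrix.states, [int(s) for s in events])
    positions = matrix.snp_map.global_positions()
    event_name = "+".join(sorted(s.name for s in events))

    regions = []
    for chrom, lo, hi in _qualifying_runs(mask, matrix.snp_map, min_snps):
        carrier_mask = member[:, lo : hi + 1].any(axis=1)
        regions.append(
            RecurrentRegion(
                chrom=chrom,
                start_bp=int(positions[lo]),
                end_bp=int(positions[hi]),
                start_probe=lo,
                end_probe=hi,
                event=event_name,
                frequency=float(freq[lo : hi + 1].min()),
                carriers=tuple(
                    sid for sid, hit in zip(matrix.sample_ids, carrier_mask) if hit
                ),
            )
        )
    return regions


def minimal_common_region(
    intervals: Sequence[tuple[str, int, int]],
) -> tuple[str, int, int] | None:
    """Intersection of per-carrier intervals on one chromosome.

    Intervals are (chrom, start, end) with start < end in any shared
    convention; returns None when the intersection is empty.
    """
    if not intervals:
        raise ValidationError("no intervals given")
    chroms = {chrom for chrom, _, _ in intervals}
    if len(chroms) != 1:
        raise ValidationError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    chrom = next(iter(chroms))
    start = max(s for _, s, _ in intervals)
    end = min(e for _, _, e in intervals)
    if start > end:
        return None
    return (chrom, start, end)


def compare_group_frequencies(
    matrix_a: StatusMatrix,
    matrix_b: StatusMatrix,
    event: State | Iterable[State],
    min_diff: float,
    min_snps: int = DEFAULT_MIN_SNPS,
    fisher: bool = False,
) -> list[RegionContrast]:
    """Maximal runs where |freq_A - freq_B| strictly exceeds ``min_diff``.

    Both cohorts must share one :class:`SNPMap`.  With ``fisher=True`` each
    reported region additionally carries a two-sided Fisher exact p-value on
    carriers-vs-non-carriers (counting samples with the event anywhere in the
    run) and a Benjamini-Hochberg q-value across the reported regions; this
    inference is an optional extra, off by default.
    """
    if matrix_a.snp_map != matrix_b.snp_map:
        raise ValidationError("cohorts are on different SNP maps")
    events = _as_event_set(event)
    freq_a = frequency_profile(matrix_a, events)
    freq_b = frequency_profile(matrix_b, events)
    mask = np.abs(freq_a - freq_b) > min_diff
    positions = matrix_a.snp_map.global_positions()
    event_name = "+".join(sorted(s.name for s in events))

    contrasts = []
    for chrom, lo, hi in _qualifying_runs(mask, matrix_a.snp_map, min_snps):
        contrasts.append(
            RegionContrast(
                chrom=chrom,
                start_bp=int(positions[lo]),
                end_bp=int(positions[hi]),
                start_probe=lo,
                end_probe=hi,
                event=event_name,
                freq_a=float(freq_a[lo : hi + 1].mean()),
                freq_b=float(freq_b[lo : hi + 1].mean()),
            )
        )
    if fisher and contrasts:
        from scipy.stats import fisher_exact as _fisher

        member_a = np.isin(matrix_a.states, [int(s) for s in events])
        member_b = np.isin(matrix_b.states, [int(s) for s in events])
        pvals = []
        for c in contrasts:
            ca = int(member_a[:, c.start_probe : c.end_probe + 1].any(axis=1).sum())
            cb = int(member_b[:, c.start_probe : c.end_probe + 1].any(axis=1).sum())
            table = [
                [ca, matrix_a.n_samples - ca],
                [cb, matrix_b.n_samples - cb],
            ]
            pvals.append(float(_fisher(table, alternative="two-sided")[1]))
        qvals = _benjamini_hochberg(np.array(pvals))
        contrasts = [
            RegionContrast(
                **{**c.__dict__, "fisher_p": p, "fisher_q": float(q)}
            )
            for c, p, q in zip(contrasts, pvals, qvals)
        ]
    return contrasts


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
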