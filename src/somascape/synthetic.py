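"""Synthetic cohorts with planted, fully known structure.

Two genomic archetypes are emulated: a whole-arm profile (8p loss / 8q gain /
16p loss / 16q gain, few amplicons) and a focal-amplifier profile (high-level
amplicons on 8q/17q/20q plus 17p loss), each on near-diploid or
near-tetraploid backgrounds.  Every planted event is recorded in a
:class:`CohortTruth` manifest so downstream calling, recurrence scanning and
clustering can be scored against ground truth.

Event magnitudes are chosen so that planted events clear the ploidy-adaptive
cutoffs of :mod:`somascape.calling` (gains land on the gain cutoff, losses on
the loss cutoff, amplicons at or above the amplification cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import (
    DEFAULT_CUTOFFS,
    PloidyClass,
    Segment,
    SegmentProfile,
)
from .errors import ConfigurationError, ValidationError
from .maps import SNPMap


@dataclass(frozen=True)
class ArmEvent:
    """A whole-arm gain or loss planted with the given probability."""

    arm: str
    event: str  # "gain" | "loss"
    probability: float = 1.0

    def __post_init__(self) -> None:
        if self.event not in ("gain", "loss"):
            raise ConfigurationError(f"unknown arm event {self.event!r}")
        if not 0 <= self.probability <= 1:
            raise ConfigurationError("probability must lie in [0, 1]")


@dataclass(frozen=True)
class FocalAmplicon:
    """A focal high-level amplicon planted somewhere on the given arm."""

    arm: str
    probability: float = 1.0
    copy_number: int = 8
    n_probes: int | None = 40
    length_bp: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ConfigurationError("probability must lie in [0, 1]")
        if (self.n_probes is None) == (self.length_bp is None):
            raise ConfigurationError("give exactly one of n_probes/length_bp")


@dataclass(frozen=True)
class ArchetypeSpec:
    name: str
    arm_events: tuple[ArmEvent, ...] = ()
    amplicons: tuple[FocalAmplicon, ...] = ()
    tetraploid_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.tetraploid_fraction <= 1:
            raise ConfigurationError("tetraploid_fraction must lie in [0, 1]")
        amp_min_needed = (
            DEFAULT_CUTOFFS[PloidyClass.NEAR_TETRAPLOID].amp_min
            if self.tetraploid_fraction > 0
            else DEFAULT_CUTOFFS[PloidyClass.NEAR_DIPLOID].amp_min
        )
        for amp in self.amplicons:
            if amp.copy_number < amp_min_needed:
                raise ConfigurationError(
                    f"amplicon copy number {amp.copy_number} is below the "
                    f"amplification cutoff {amp_min_needed} for this ploidy mix"
                )


def sawtooth_spec(
    probability: float = 0.9, tetraploid_fraction: float = 0.0
) -> ArchetypeSpec:
    """Whole-arm archetype: 8p-/8q+/16p-/16q+, no amplicons."""
    return ArchetypeSpec(
        name="sawtooth_8_16",
        arm_events=(
            ArmEvent("8p", "loss", probability),
            ArmEvent("8q", "gain", probability),
            ArmEvent("16p", "loss", probability),
            ArmEvent("16q", "gain", probability),
        ),
        tetraploid_fraction=tetraploid_fraction,
    )


def firestorm_spec(
    probability: float = 0.9, tetraploid_fraction: float = 0.25
) -> ArchetypeSpec:
    """Focal-amplifier archetype: 8q/17q/20q amplicons plus 17p loss."""
    return ArchetypeSpec(
        name="firestorm_amplifier",
        arm_events=(ArmEvent("17p", "loss", probability),),
        amplicons=(
            FocalAmplicon("8q", probability),
            FocalAmplicon("17q", probability),
            FocalAmplicon("20q", probability),
        ),
        tetraploid_fraction=tetraploid_fraction,
    )


@dataclass(frozen=True)
class SampleTruth:
    sample_id: str
    archetype: str
    ploidy: str  # PloidyClass value


@dataclass(frozen=True)
class PlantedRegion:
    """Planted event coordinates; probe indices are global, inclusive."""

    chrom: str
    start_probe: int
    end_probe: int
    start_bp: int
    end_bp: int
    event: str  # "LOSS" | "GAIN" | "AMP"
    carriers: tuple[str, ...]
    carrier_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.carrier_fraction <= 1:
            raise ValidationError("carrier_fraction must lie in [0, 1]")


@dataclass
class CohortTruth:
    samples: list[SampleTruth]
    regions: list[PlantedRegion]
    seed: int
    variants_somatic: list[bool] = field(default_factory=list)


_EVENT_VALUES = {
    # (event, ploidy) -> (total, minor)
    ("gain", PloidyClass.NEAR_DIPLOID): (3, 1),
    ("gain", PloidyClass.NEAR_TETRAPLOID): (6, 2),
    ("loss", PloidyClass.NEAR_DIPLOID): (1, 0),
    ("loss", PloidyClass.NEAR_TETRAPLOID): (2, 0),
}
_BASELINE = {
    PloidyClass.NEAR_DIPLOID: (2, 1),
    PloidyClass.NEAR_TETRAPLOID: (4, 2),
}


def _round_count(p: float, n: int) -> int:
    return int(math.floor(p * n + 0.5))


def _pick_carriers(
    rng: np.random.Generator,
    indices: np.ndarray,
    probability: float,
    exact_counts: bool,
) -> np.ndarray:
    if exact_counts:
        k = _round_count(probability, indices.size)
        chosen = rng.choice(indices, size=k, replace=False)
    else:
        chosen = indices[rng.random(indices.size) < probability]
    return np.sort(chosen)


def generate_cohort(
    archetype_mix: list[tuple[ArchetypeSpec, int]],
    snp_map: SNPMap | None = None,
    seed: int = 0,
    exact_counts: bool = True,
    probe_jitter: float = 0.0,
) -> tuple[list[SegmentProfile], CohortTruth]:
    """Generate segmented allele-specific profiles with planted events.

    ``exact_counts=True`` converts event probabilities into exact carrier
    counts (round(p * n) carriers chosen at random), which makes planted
    carrier fractions reproducible for recovery experiments.
    ``probe_jitter`` plants, per sample, a Poisson(probe_jitter * n_probes)
    number of single-probe +/-1 copy perturbations.

    Identical arguments (including seed) give bit-identical output.
    """
    snp_map = snp_map or SNPMap.default()
    if not archetype_mix:
        raise ConfigurationError("empty archetype mix")
    rng = np.random.default_rng(seed)
    positions = snp_map.global_positions()
    n_probes = snp_map.n_probes

    # Validate arms before any sampling so errors are deterministic.
    for spec, count in archetype_mix:
        if count < 1:
            raise ConfigurationError(f"{spec.name}: count must be >= 1")
        for ev in spec.arm_events:
            snp_map.arm_interval(ev.arm)
        for amp in spec.amplicons:
            snp_map.arm_interval(amp.arm)

    sample_ids: list[str] = []
    sample_specs: list[ArchetypeSpec] = []
    ploidies: list[PloidyClass] = []
    group_indices: list[np.ndarray] = []
    for spec, count in archetype_mix:
        start = len(sample_ids)
        for i in range(count):
            sample_ids.append(f"S{start + i:03d}_{spec.name}")
            sample_specs.append(spec)
        if exact_counts:
            n_tet = _round_count(spec.tetraploid_fraction, count)
            tet_flags = np.zeros(count, dtype=bool)
            tet_flags[rng.choice(count, size=n_tet, replace=False)] = True
        else:
            tet_flags = rng.random(count) < spec.tetraploid_fraction
        ploidies.extend(
            PloidyClass.NEAR_TETRAPLOID if t else PloidyClass.NEAR_DIPLOID
            for t in tet_flags
        )
        group_indices.append(np.arange(start, start + count))

    n_samples = len(sample_ids)
    totals = np.empty((n_samples, n_probes), dtype=np.int64)
    minors = np.empty((n_samples, n_probes), dtype=np.int64)
    for s, ploidy in enumerate(ploidies):
        totals[s], minors[s] = _BASELINE[ploidy]

    regions: list[PlantedRegion] = []
    for (spec, _), indices in zip(archetype_mix, group_indices):
        for ev in spec.arm_events:
            chrom, astart, aend = snp_map.arm_interval(ev.arm)
            lo, hi = snp_map.probe_range(chrom, astart, aend)
            if lo == hi:
                raise ConfigurationError(f"arm {ev.arm} carries no probes")
            carriers = _pick_carriers(rng, indices, ev.probability, exact_counts)
            for s in carriers:
                totals[s, lo:hi], minors[s, lo:hi] = _EVENT_VALUES[
                    (ev.event, ploidies[s])
                ]
            regions.append(
                PlantedRegion(
                    chrom=chrom,
                    start_probe=lo,
                    end_probe=hi - 1,
                    start_bp=int(positions[lo]),
                    end_bp=int(positions[hi - 1]),
                    event="GAIN" if ev.event == "gain" else "LOSS",
                    carriers=tuple(sample_ids[s] for s in carriers),
                    carrier_fraction=len(carriers) / n_samples,
                )
            )
        for amp in spec.amplicons:
            chrom, astart, aend = snp_map.arm_interval(amp.arm)
            lo, hi = snp_map.probe_range(chrom, astart, aend)
            arm_probes = hi - lo
            if amp.n_probes is not None:
                span = amp.n_probes
            else:
                arm_pos = positions[lo:hi]
                spacing = float(np.median(np.diff(arm_pos))) if arm_probes > 1 else 1.0
                span = max(1, int(round(amp.length_bp / spacing)))
            if span > arm_probes:
                raise ConfigurationError(
                    f"amplicon span {span} probes exceeds arm {amp.arm} "
                    f"({arm_probes} probes)"
                )
            start_idx = lo + int(rng.integers(0, arm_probes - span + 1))
            carriers = _pick_carriers(rng, indices, amp.probability, exact_counts)
            for s in carriers:
                cn = max(amp.copy_number, DEFAULT_CUTOFFS[ploidies[s]].amp_min)
                totals[s, start_idx : start_idx + span] = cn
                minors[s, start_idx : start_idx + span] = 1
            regions.append(
                PlantedRegion(
                    chrom=chrom,
                    start_probe=start_idx,
                    end_probe=start_idx + span - 1,
                    start_bp=int(positions[start_idx]),
                    end_bp=int(positions[start_idx + span - 1]),
                    event="AMP",
                    carriers=tuple(sample_ids[s] for s in carriers),
                    carrier_fraction=len(carriers) / n_samples,
                )
            )

    if probe_jitter > 0:
        for s in range(n_samples):
            n_hits = rng.poisson(probe_jitter * n_probes)
            hit = rng.integers(0, n_probes, size=n_hits)
            delta = rng.choice([-1, 1], size=n_hits)
            totals[s, hit] = np.maximum(totals[s, hit] + delta, 0)
            minors[s, hit] = np.minimum(minors[s, hit], totals[s, hit] // 2)

    profiles = [
        _compress(sample_ids[s], totals[s], minors[s], snp_map, ploidies[s])
        for s in range(n_samples)
    ]
    truth = CohortTruth(
        samples=[
            SampleTruth(sample_ids[s], sample_specs[s].name, ploidies[s].value)
            for s in range(n_samples)
        ],
        regions=regions,
        seed=seed,
    )
    return profiles, truth


def _compress(
    sample_id: str,
    totals: np.ndarray,
    minors: np.ndarray,
    snp_map: SNPMap,
    ploidy: PloidyClass,
) -> SegmentProfile:
    """Collapse per-probe copy numbers into maximal constant segments."""
    segments: list[Segment] = []
    for chrom in snp_map.chromosomes:
        sl = snp_map.chrom_slice(chrom)
        pos = snp_map.positions[chrom]
        t, m = totals[sl], minors[sl]
        change = np.flatnonzero((np.diff(t) != 0) | (np.diff(m) != 0))
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change, [t.size - 1]))
        for i0, i1 in zip(starts, ends):
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(pos[i0]),
                    end=int(pos[i1]) + 1,
                    total=int(t[i0]),
                    minor=int(m[i0]),
                )
            )
    return SegmentProfile(sample_id=sample_id, segments=tuple(segments), ploidy=ploidy)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_NON_STOP_CODONS = sorted(
    set(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
    )
    - {"TAA", "TAG", "TGA"}
)


def generate_variant_table(
    n_sites: int = 500,
    somatic_fraction: float = 0.5,
    depth_model: tuple[float, float] = (80.0, 60.0),
    seed: int = 0,
    somatic_vaf_beta: tuple[float, float] = (16.0, 24.0),
    sequencing_error: float = 1e-3,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Candidate-variant table with known somatic/germline truth.

    Somatic sites carry alt reads in the tumour only, with VAF drawn from a
    Beta distribution centred at 0.40 (high tumour cellularity); germline
    sites are heterozygous in both tumour and normal.  Returns the table and
    a boolean truth array (True = somatic).
    """
    if not 0 <= somatic_fraction <= 1:
        raise ConfigurationError("somatic_fraction must lie in [0, 1]")
    mean_t, mean_n = depth_model
    if mean_t <= 0 or mean_n <= 0:
        raise ConfigurationError("depths must be > 0")
    rng = np.random.default_rng(seed)
    somatic = rng.random(n_sites) < somatic_fraction

    depth_t = np.maximum(rng.poisson(mean_t, n_sites), 1)
    depth_n = np.maximum(rng.poisson(mean_n, n_sites), 1)
    a, b = somatic_vaf_beta
    true_vaf = np.where(somatic, rng.beta(a, b, n_sites), 0.5)
    tumor_alt = rng.binomial(depth_t, true_vaf)
    normal_alt = rng.binomial(
        depth_n, np.where(somatic, sequencing_error, 0.5)
    )
    base_quality = np.clip(rng.normal(36.0, 2.0, n_sites), 2.0, 41.0)
    hq_alt = rng.binomial(tumor_alt, 0.97)

    ref_codons = rng.choice(_NON_STOP_CODONS, n_sites)
    alt_codons = []
    for codon in ref_codons:
        pos = int(rng.integers(0, 3))
        alt_base = rng.choice([x for x in "ACGT" if x != codon[pos]])
        alt_codons.append(codon[:pos] + alt_base + codon[pos + 1 :])

    table = pd.DataFrame(
        {
            "site_id": [f"site{i:05d}" for i in range(n_sites)],
            "sample_id": "TUMOR01",
            "gene": [f"G{i:05d}" for i in range(n_sites)],
            "chromosome": rng.choice([str(c) for c in range(1, 23)], n_sites),
            "ref_codon": ref_codons,
            "alt_codon": alt_codons,
            "tumor_ref": depth_t - tumor_alt,
            "tumor_alt": tumor_alt,
            "normal_ref": depth_n - normal_alt,
            "normal_alt": normal_alt,
            "base_quality": np.round(base_quality, 2),
            "hq_alt_reads": hq_alt,
            "polyphen2": np.round(rng.beta(0.6, 0.6, n_sites), 3),
            "gerp": np.round(rng.normal(2.0, 2.0, n_sites), 2),
            "known_variant": ~somatic & (rng.random(n_sites) < 0.9),
        }
    )
    return table, somatic


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def generate_expression(
    profiles: list[SegmentProfile],
    coupled_genes: list[tuple[str, str, int, float]],
    noise_sd: float = 0.5,
    n_noise_genes: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression matrix (genes x samples) coupled to local copy number.

    Coupled genes are ``(gene, chromosome, position, slope)`` tuples with
    expression = slope * copy number at the locus + Gaussian(0, noise_sd)
    noise; additional pure-noise genes draw from Gaussian(0, max(noise_sd, 1)).
    Positions must fall on territory covered by the profiles.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if not profiles:
        raise ConfigurationError("no profiles given")
    rng = np.random.default_rng(seed)

    bounds: dict[str, tuple[int, int]] = {}
    for seg in profiles[0].segments:
        lo, hi = bounds.get(seg.chrom, (seg.start, seg.end))
        bounds[seg.chrom] = (min(lo, seg.start), max(hi, seg.end))
    for gene, chrom, position, _ in coupled_genes:
        if chrom not in bounds or not bounds[chrom][0] <= position < bounds[chrom][1]:
            raise ValidationError(
                f"gene {gene!r} position {chrom}:{position} outside the genome"
            )

    from .expression import copy_number_at

    sample_ids = [p.sample_id for p in profiles]
    rows = {}
    for gene, chrom, position, slope in coupled_genes:
        cn = np.array(
            [copy_number_at(p, chrom, position) for p in profiles], dtype=float
        )
        rows[gene] = slope * cn + rng.normal(0.0, noise_sd, len(profiles))
    for i in range(n_noise_genes):
        rows[f"NOISE{i:04d}"] = rng.normal(
            0.0, max(noise_sd, 1.0), len(profiles)
        )
    return pd.DataFrame(rows, index=sample_ids).T
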