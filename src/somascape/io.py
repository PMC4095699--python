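"""Readers and writers for all interchange formats plus run configuration.

Everything on disk is headered TSV (or JSON for the truth manifest).  Genomic
coordinates on disk are 1-based inclusive; in memory, segment intervals are
half-open ``[start, end)`` on the same 1-based axis, so a probe at position
``p`` belongs to the segment with ``start <= p < end``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import (
    DEFAULT_CUTOFFS,
    PloidyClass,
    PloidyCutoffs,
    Segment,
    SegmentProfile,
    State,
)
from .errors import ConfigurationError, ValidationError
from .maps import SNPMap
from .recurrence import RecurrentRegion, StatusMatrix
from .synthetic import CohortTruth, PlantedRegion, SampleTruth
from .variants import FilterThresholds, PrioritizationRules

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "total_cn", "minor_cn"]


# ---------------------------------------------------------------------------
# SEG-like segment profiles
# ---------------------------------------------------------------------------


def write_seg(profiles: list[SegmentProfile], path: str | Path) -> None:
    """Write profiles as SEG-like TSV (1-based inclusive coordinates)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SEG_COLUMNS + ["ploidy"])
        for profile in profiles:
            for seg in profile.segments:
                writer.writerow(
                    [
                        profile.sample_id,
                        seg.chrom,
                        seg.start,
                        seg.end - 1,
                        seg.total,
                        seg.minor,
                        profile.ploidy.value,
                    ]
                )


def read_seg(path: str | Path) -> list[SegmentProfile]:
    """Read a SEG-like TSV into validated profiles.

    Raises :class:`ValidationError` naming the sample and line on overlap,
    ordering or type problems.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    order: list[str] = []
    segments: dict[str, list[Segment]] = {}
    ploidy: dict[str, PloidyClass] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(SEG_COLUMNS) <= set(reader.fieldnames):
            raise ValidationError(
                f"{path}: header must contain columns {SEG_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            sample = row["sample"]
            try:
                start = int(row["start"])
                end = int(row["end"])
                seg = Segment(
                    chrom=row["chromosome"],
                    start=start,
                    end=end + 1,
                    total=_int_field(row["total_cn"], "total_cn"),
                    minor=_int_field(row["minor_cn"], "minor_cn"),
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(
                    f"{path}:{lineno} (sample {sample}): {exc}"
                ) from None
            if sample not in segments:
                order.append(sample)
                segments[sample] = []
            prev = segments[sample]
            if prev and prev[-1].chrom == seg.chrom and seg.start < prev[-1].end:
                raise ValidationError(
                    f"{path}:{lineno} (sample {sample}): segment overlaps or is "
                    f"unsorted on chromosome {seg.chrom}"
                )
            prev.append(seg)
            declared = row.get("ploidy", "").strip()
            if declared:
                ploidy[sample] = PloidyClass(declared)
    profiles = []
    for sample in order:
        try:
            profiles.append(
                SegmentProfile(
                    sample_id=sample,
                    segments=tuple(segments[sample]),
                    ploidy=ploidy.get(sample, PloidyClass.UNDECLARED),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} (sample {sample}): {exc}") from None
    return profiles


def _int_field(value: str, name: str) -> int:
    try:
        as_float = float(value)
    except ValueError:
        raise ValidationError(f"{name} {value!r} is not a number") from None
    if as_float != int(as_float):
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    return int(as_float)


# ---------------------------------------------------------------------------
# status matrices (probe rows, sample columns; embeds the SNP map)
# ---------------------------------------------------------------------------


def write_status_matrix(
    matrix: StatusMatrix, states_path: str | Path, loh_path: str | Path | None = None
) -> None:
    chroms = matrix.snp_map.global_chromosomes()
    positions = matrix.snp_map.global_positions()
    frame = pd.DataFrame({"chromosome": chroms, "position": positions})
    names = np.array([s.name for s in State])
    for i, sid in enumerate(matrix.sample_ids):
        frame[sid] = names[matrix.states[i]]
    frame.to_csv(states_path, sep="\t", index=False)
    if loh_path is not None:
        if matrix.loh is None:
            raise ValidationError("matrix has no LOH layer to write")
        loh_frame = pd.DataFrame({"chromosome": chroms, "position": positions})
        for i, sid in enumerate(matrix.sample_ids):
            loh_frame[sid] = matrix.loh[i].astype(int)
        loh_frame.to_csv(loh_path, sep="\t", index=False)


def read_status_matrix(
    states_path: str | Path, loh_path: str | Path | None = None
) -> StatusMatrix:
    frame = pd.read_csv(states_path, sep="\t", dtype={"chromosome": str})
    chrom_order = list(dict.fromkeys(frame["chromosome"]))
    snp_map = SNPMap(
        chromosomes=tuple(chrom_order),
        positions={
            c: frame.loc[frame["chromosome"] == c, "position"].to_numpy()
            for c in chrom_order
        },
    )
    sample_ids = [c for c in frame.columns if c not in ("chromosome", "position")]
    lut = {s.name: int(s) for s in State}
    states = np.vstack(
        [frame[sid].map(lut).to_numpy(dtype=np.int8) for sid in sample_ids]
    )
    loh = None
    if loh_path is not None:
        loh_frame = pd.read_csv(loh_path, sep="\t", dtype={"chromosome": str})
        loh = np.vstack(
            [loh_frame[sid].to_numpy(dtype=bool) for sid in sample_ids]
        )
    return StatusMatrix(
        snp_map=snp_map, sample_ids=sample_ids, states=states, loh=loh
    )


# ---------------------------------------------------------------------------
# recurrent regions (BED-style TSV, 1-based inclusive bp)
# ---------------------------------------------------------------------------


def write_regions(regions: list[RecurrentRegion], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "chromosome", "start", "end", "event", "frequency",
                "n_probes", "n_carriers", "carriers",
            ]
        )
        for r in regions:
            writer.writerow(
                [
                    r.chrom, r.start_bp, r.end_bp, r.event,
                    f"{r.frequency:.6g}", r.n_probes, len(r.carriers),
                    ";".join(r.carriers),
                ]
            )


def read_regions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})


# ---------------------------------------------------------------------------
# variant tables, expression matrices
# ---------------------------------------------------------------------------


def write_variant_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def read_vcf_subset(
    path: str | Path,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> pd.DataFrame:
    """Read CHROM/POS/REF/ALT plus AD-derived tumour/normal counts from a VCF.

    Expects a paired VCF with per-sample ``AD`` (ref, alt depths).  Returns a
    frame with the same count columns the filter engine consumes.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (tumor_sample, normal_sample):
        if name not in samples:
            raise ValidationError(f"sample {name!r} not present in {path}")
    it, inorm = samples.index(tumor_sample), samples.index(normal_sample)
    rows = []
    for variant in vcf:
        ad = variant.format("AD")
        if ad is None:
            raise ValidationError(f"{path}: record without AD at {variant.POS}")
        rows.append(
            {
                "chromosome": variant.CHROM,
                "position": variant.POS,
                "ref": variant.REF,
                "alt": ",".join(variant.ALT),
                "tumor_ref": int(ad[it][0]),
                "tumor_alt": int(ad[it][1]),
                "normal_ref": int(ad[inorm][0]),
                "normal_alt": int(ad[inorm][1]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth manifests
# ---------------------------------------------------------------------------


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1)


def read_truth(path: str | Path) -> CohortTruth:
    with open(path) as fh:
        blob = json.load(fh)
    return CohortTruth(
        samples=[SampleTruth(**s) for s in blob["samples"]],
        regions=[
            PlantedRegion(**{**r, "carriers": tuple(r["carriers"])})
            for r in blob["regions"]
        ],
        seed=blob["seed"],
        variants_somatic=list(blob.get("variants_somatic", [])),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys in a config file are rejected."""

    seed: int = 0
    probes_per_chromosome: int = 1000
    min_snps: int = 25
    min_freq: float = 0.20
    min_diff: float = 0.20
    cluster_k: int = 2
    fisher_p_max: float = 0.05
    min_coverage: int = 10
    min_base_quality: float = 20.0
    min_vaf: float = 0.20
    min_alt_reads: int = 4
    exclude_known_variants: bool = True
    functional_score_min: float = 0.5
    gerp_min: float = 3.0
    diploid_cutoffs: tuple[int, int, int] = (1, 3, 6)
    tetraploid_cutoffs: tuple[int, int, int] = (2, 6, 8)

    def __post_init__(self) -> None:
        # Constructing the typed threshold objects runs their range checks.
        self.filter_thresholds()
        self.prioritization_rules()
        self.cutoffs()
        if self.min_snps < 1 or self.probes_per_chromosome < 1:
            raise ConfigurationError("counts must be >= 1")
        if not 0 <= self.min_freq <= 1 or not 0 <= self.min_diff <= 1:
            raise ConfigurationError("frequency thresholds must lie in [0, 1]")

    def filter_thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            fisher_p_max=self.fisher_p_max,
            min_coverage=self.min_coverage,
            min_base_quality=self.min_base_quality,
            min_vaf=self.min_vaf,
            min_alt_reads=self.min_alt_reads,
        )

    def prioritization_rules(self) -> PrioritizationRules:
        return PrioritizationRules(
            exclude_known_variants=self.exclude_known_variants,
            functional_score_min=self.functional_score_min,
            gerp_min=self.gerp_min,
        )

    def cutoffs(self) -> dict[PloidyClass, PloidyCutoffs]:
        return {
            PloidyClass.NEAR_DIPLOID: PloidyCutoffs(*self.diploid_cutoffs),
            PloidyClass.NEAR_TETRAPLOID: PloidyCutoffs(*self.tetraploid_cutoffs),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            blob = yaml.safe_load(fh) or {}
        if not isinstance(blob, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(blob) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
        for key in ("diploid_cutoffs", "tetraploid_cutoffs"):
            if key in blob:
                blob[key] = tuple(blob[key])
        return cls(**blob)
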