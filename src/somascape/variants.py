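"""Somatic SNV filtering, classification and spectrum summaries.

Candidate variants carrying tumour/normal read evidence are filtered on five
criteria (exact Fisher test p < 0.05, coverage >= 10x, base quality >= 20,
VAF >= 20%, high-quality alt reads >= 4), optionally prioritised on
known-variant status and functional scores, classified by codon effect and
substitution type, and aggregated into a mutation-spectrum summary.

A curated mutation catalogue (one row per validated variant of the reference
breast-carcinoma cohort) ships with the package and is the fixture behind
the spectrum summaries; its transcription is integrity-checked by SHA-256.
"""

from __future__ import annotations

import enum
import hashlib
import math
import re
from dataclasses import dataclass
from importlib import resources
from math import comb
from pathlib import Path

from Bio.Data import CodonTable

from .errors import ValidationError

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_CODON_RE = re.compile(r"^([ACGT]{3})>([ACGT]{3})$")
_SNV_RE = re.compile(r"^([ACGT])>([ACGT])$")

MUTATION_TABLE_RESOURCE = "mutation_table.tsv"
MUTATION_TABLE_SHA256 = (
    "c0779cb42d0fce8db5ec46b82dc1bec4254835cfd6957798eee554e2a048d82f"
)


class Effect(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"


class SubstitutionClass(str, enum.Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"
    INDEL = "indel"


class RnaStatus(str, enum.Enum):
    YES = "yes"
    NO_COVERAGE = "no_coverage"
    ND = "nd"


# ---------------------------------------------------------------------------
# thresholds and rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterThresholds:
    """False-positive exclusion thresholds for candidate somatic SNVs."""

    fisher_p_max: float = 0.05  # exclusive: p < 0.05
    min_coverage: int = 10  # inclusive
    min_base_quality: float = 20.0  # inclusive
    min_vaf: float = 0.20  # inclusive
    min_alt_reads: int = 4  # inclusive, high-quality alt-supporting reads

    def __post_init__(self) -> None:
        if not 0 < self.min_vaf <= 1:
            raise ValidationError("min_vaf must lie in (0, 1]")
        if min(self.fisher_p_max, self.min_coverage,
               self.min_base_quality, self.min_alt_reads) <= 0:
            raise ValidationError("thresholds must be positive")


@dataclass(frozen=True)
class PrioritizationRules:
    """Post-filter prioritisation: drop known variants, keep damaging missense."""

    exclude_known_variants: bool = True
    functional_score_min: float = 0.5  # PolyPhen-2, exclusive (> 0.5)
    gerp_min: float = 3.0  # exclusive (> 3.0)

    def __post_init__(self) -> None:
        if not 0 <= self.functional_score_min <= 1:
            raise ValidationError("functional_score_min must lie in [0, 1]")


@dataclass(frozen=True)
class MutationRecord:
    """One validated mutation with its printed annotations."""

    gene: str
    chromosome: str
    change: str  # "GAA>CAA", "A>G" or an indel descriptor like "c.742_743insA"
    effect: Effect
    substitution: SubstitutionClass
    protein_change: str | None = None
    polyphen2: float | None = None
    gerp: float | None = None
    rna_expression: RnaStatus = RnaStatus.ND
    n_cases: int | None = None
    known_variant: bool = False

    def __post_init__(self) -> None:
        if self.polyphen2 is not None and not 0 <= self.polyphen2 <= 1:
            raise ValidationError(f"PolyPhen-2 score {self.polyphen2} outside [0, 1]")


# ---------------------------------------------------------------------------
# exact Fisher test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(
    tumor_ref: int,
    tumor_alt: int,
    normal_ref: int,
    normal_alt: int,
    alternative: str = "greater",
) -> float:
    """Exact Fisher p-value for a tumour/normal 2x2 read-count table.

    ``alternative="greater"`` (default) is the one-sided tail probability
    that the tumour alt fraction is at least as extreme as observed under
    the hypergeometric null with fixed margins; the observed table's own
    probability mass is included.  ``"two-sided"`` sums all tables with
    probability no larger than the observed one.  Arithmetic is exact
    (integer binomial coefficients; one final division).
    """
    counts = (tumor_ref, tumor_alt, normal_ref, normal_alt)
    if any(c < 0 for c in counts):
        raise ValidationError("read counts must be >= 0")
    total = sum(counts)
    if total == 0:
        raise ValidationError("table total must be > 0")
    n_tumor = tumor_ref + tumor_alt
    n_alt = tumor_alt + normal_alt
    k_min = max(0, n_alt - (total - n_tumor))
    k_max = min(n_tumor, n_alt)

    def weight(k: int) -> int:
        return comb(n_tumor, k) * comb(total - n_tumor, n_alt - k)

    denom = comb(total, n_alt)
    if alternative == "greater":
        numer = sum(weight(k) for k in range(tumor_alt, k_max + 1))
    elif alternative == "less":
        numer = sum(weight(k) for k in range(k_min, tumor_alt + 1))
    elif alternative == "two-sided":
        observed = weight(tumor_alt)
        numer = sum(
            w for k in range(k_min, k_max + 1) if (w := weight(k)) <= observed
        )
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return numer / denom


# ---------------------------------------------------------------------------
# filters and prioritisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failures: tuple[str, ...]
    p_value: float | None
    coverage: int
    vaf: float | None


def apply_filters(
    tumor_ref: int,
    tumor_alt: int,
    normal_ref: int,
    normal_alt: int,
    base_quality: float,
    hq_alt_reads: int,
    thresholds: FilterThresholds | None = None,
) -> FilterVerdict:
    """Evaluate the five exclusion criteria; PASS iff all hold.

    Coverage is tumour depth (ref + alt); VAF is tumour alt over coverage.
    Zero tumour coverage fails the coverage and VAF criteria rather than
    raising.
    """
    th = thresholds or FilterThresholds()
    failures: list[str] = []

    coverage = tumor_ref + tumor_alt
    vaf = tumor_alt / coverage if coverage > 0 else None

    total = tumor_ref + tumor_alt + normal_ref + normal_alt
    p_value = (
        fisher_exact_2x2(tumor_ref, tumor_alt, normal_ref, normal_alt)
        if total > 0
        else None
    )
    if p_value is None or not p_value < th.fisher_p_max:
        failures.append("fisher_p")
    if coverage < th.min_coverage:
        failures.append("coverage")
    if base_quality < th.min_base_quality:
        failures.append("base_quality")
    if vaf is None or vaf < th.min_vaf:
        failures.append("vaf")
    if hq_alt_reads < th.min_alt_reads:
        failures.append("alt_reads")

    return FilterVerdict(
        passed=not failures,
        failures=tuple(failures),
        p_value=p_value,
        coverage=coverage,
        vaf=vaf,
    )


@dataclass(frozen=True)
class PrioritizationResult:
    keep: bool
    reason: str


def prioritize(
    record: MutationRecord, rules: PrioritizationRules | None = None
) -> PrioritizationResult:
    """Advisory keep/drop decision for a filtered variant.

    Known variants are dropped.  Missense variants are kept when their
    available functional scores clear the thresholds (PolyPhen-2 > 0.5 and
    GERP > 3.0 when both are present; the available one decides when only
    one is printed; no scores means no evidence to drop).  Truncating and
    splice variants are kept regardless of scores.
    """
    rules = rules or PrioritizationRules()
    if rules.exclude_known_variants and record.known_variant:
        return PrioritizationResult(False, "known_variant")
    if record.effect is not Effect.MISSENSE:
        return PrioritizationResult(True, "non_missense")
    checks: list[bool] = []
    if record.polyphen2 is not None:
        checks.append(record.polyphen2 > rules.functional_score_min)
    if record.gerp is not None:
        checks.append(record.gerp > rules.gerp_min)
    if not checks:
        return PrioritizationResult(True, "no_scores")
    if all(checks):
        return PrioritizationResult(True, "damaging_missense")
    return PrioritizationResult(False, "low_functional_score")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _translate(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValidationError(f"invalid codon {codon!r}")
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


def classify_effect(ref_codon: str, alt_codon: str) -> Effect:
    """Effect of a codon substitution under the standard genetic code."""
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        return Effect.NONSENSE
    if ref_aa == alt_aa:
        return Effect.SYNONYMOUS
    return Effect.MISSENSE


def classify_substitution(change: str) -> SubstitutionClass:
    """Transition/transversion/indel class of a printed change descriptor.

    Accepts a codon pair ("ATG>ACG", exactly one differing position), a bare
    single-nucleotide change ("A>G"), or an indel descriptor (anything
    containing "ins" or "del").
    """
    lowered = change.lower()
    if "ins" in lowered or "del" in lowered:
        return SubstitutionClass.INDEL
    m = _SNV_RE.match(change)
    if m:
        return _base_substitution(m.group(1), m.group(2))
    m = _CODON_RE.match(change)
    if not m:
        raise ValidationError(f"unrecognised change descriptor {change!r}")
    ref, alt = m.group(1), m.group(2)
    diffs = [(r, a) for r, a in zip(ref, alt) if r != a]
    if len(diffs) != 1:
        raise ValidationError(
            f"codon change {change!r} differs at {len(diffs)} positions; expected 1"
        )
    return _base_substitution(*diffs[0])


def _base_substitution(ref: str, alt: str) -> SubstitutionClass:
    if ref == alt:
        raise ValidationError("not a substitution: identical bases")
    same_family = ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)
    return SubstitutionClass.TRANSITION if same_family else SubstitutionClass.TRANSVERSION


def classify_deleterious(polyphen2: float | None, gerp: float | None) -> bool:
    """Deleterious iff PolyPhen-2 > 0.5 or GERP > 4 (whichever is present)."""
    if polyphen2 is None and gerp is None:
        raise ValidationError("at least one score is required")
    if polyphen2 is not None and polyphen2 > 0.5:
        return True
    if gerp is not None and gerp > 4:
        return True
    return False


def gerp_bin(gerp: float) -> str:
    """Three-band conservation call: <3 benign, 3-5 possibly damaging
    (inclusive), >5 probably damaging."""
    if gerp < 3:
        return "benign"
    if gerp <= 5:
        return "possibly_damaging"
    return "probably_damaging"


# ---------------------------------------------------------------------------
# spectrum summaries
# ---------------------------------------------------------------------------


def round_percent(fraction: float) -> int:
    """Round a proportion to integer percent, half away from zero."""
    return int(math.floor(abs(fraction) * 100 + 0.5)) * (1 if fraction >= 0 else -1)


@dataclass(frozen=True)
class MutationSummary:
    n_variants: int
    n_genes: int
    n_missense: int
    pct_missense: int
    n_transitions: int
    pct_transitions: int
    n_deleterious: int
    pct_deleterious: int
    gene_cases: dict[str, int]
    gene_pct: dict[str, int]
    n_cohort: int


def summarize_mutations(
    records: list[MutationRecord], n_cohort: int = 50
) -> MutationSummary:
    """Aggregate counts and rounded percentages for a mutation catalogue.

    Per-gene cohort percentages use the printed per-gene case counts against
    ``n_cohort`` sequenced cases.  Deleteriousness is scored from whichever
    functional score each record carries (OR rule); records with no score
    count as not deleterious but remain in the denominator.
    """
    if not records:
        raise ValidationError("no records")
    if n_cohort <= 0:
        raise ValidationError("n_cohort must be > 0")
    n = len(records)
    n_missense = sum(r.effect is Effect.MISSENSE for r in records)
    n_transitions = sum(
        r.substitution is SubstitutionClass.TRANSITION for r in records
    )
    n_deleterious = sum(
        (r.polyphen2 is not None or r.gerp is not None)
        and classify_deleterious(r.polyphen2, r.gerp)
        for r in records
    )
    gene_cases: dict[str, int] = {}
    for r in records:
        if r.n_cases is not None:
            gene_cases[r.gene] = max(gene_cases.get(r.gene, 0), r.n_cases)
        else:
            gene_cases.setdefault(r.gene, 0)
    gene_pct = {g: round_percent(c / n_cohort) for g, c in gene_cases.items()}
    return MutationSummary(
        n_variants=n,
        n_genes=len({r.gene for r in records}),
        n_missense=n_missense,
        pct_missense=round_percent(n_missense / n),
        n_transitions=n_transitions,
        pct_transitions=round_percent(n_transitions / n),
        n_deleterious=n_deleterious,
        pct_deleterious=round_percent(n_deleterious / n),
        gene_cases=gene_cases,
        gene_pct=gene_pct,
        n_cohort=n_cohort,
    )


@dataclass(frozen=True)
class ExpressionSupport:
    n_expressed: int
    n_evaluable: int  # records whose RNA status is not ND
    fraction: float | None
    pct: int | None


def expression_support(records: list[MutationRecord]) -> ExpressionSupport:
    """Fraction of evaluable records (RNA status not ND) expressed at RNA level.

    Records with no RNA-seq coverage stay in the denominator; only ND
    (not-determined) records are excluded.  With nothing evaluable the
    fraction is indeterminate (None).
    """
    evaluable = [r for r in records if r.rna_expression is not RnaStatus.ND]
    n_yes = sum(r.rna_expression is RnaStatus.YES for r in evaluable)
    if not evaluable:
        return ExpressionSupport(0, 0, None, None)
    frac = n_yes / len(evaluable)
    return ExpressionSupport(n_yes, len(evaluable), frac, round_percent(frac))


# ---------------------------------------------------------------------------
# packaged mutation catalogue
# ---------------------------------------------------------------------------

_EFFECT_ALIASES = {
    "missense": Effect.MISSENSE,
    "nonsense": Effect.NONSENSE,
    "synonymous": Effect.SYNONYMOUS,
    "frame shift": Effect.FRAMESHIFT,
    "frameshift": Effect.FRAMESHIFT,
    "splice intron": Effect.SPLICE,
    "splice": Effect.SPLICE,
}
_TYPE_ALIASES = {
    "transition": SubstitutionClass.TRANSITION,
    "transversion": SubstitutionClass.TRANSVERSION,
    "ins/del": SubstitutionClass.INDEL,
    "indel": SubstitutionClass.INDEL,
}
_RNA_ALIASES = {
    "yes": RnaStatus.YES,
    "no coverage": RnaStatus.NO_COVERAGE,
    "no_coverage": RnaStatus.NO_COVERAGE,
    "nd": RnaStatus.ND,
}


def load_mutation_table(
    path: str | Path | None = None, verify_checksum: bool = True
) -> list[MutationRecord]:
    """Load a mutation catalogue TSV (default: the packaged fixture).

    Effect and substitution class are re-derived from the printed codon
    change wherever a codon pair is available and cross-checked against the
    printed annotation columns; a mismatch raises ``ValidationError``.
    """
    if path is None:
        source = resources.files("somascape.data") / MUTATION_TABLE_RESOURCE
        raw = source.read_bytes()
        if verify_checksum:
            digest = hashlib.sha256(raw).hexdigest()
            if digest != MUTATION_TABLE_SHA256:
                raise ValidationError(
                    "packaged mutation table failed its integrity check"
                )
    else:
        raw = Path(path).read_bytes()

    lines = raw.decode("utf-8").splitlines()
    header = lines[0].rstrip("\n").split("\t")
    records: list[MutationRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        change = row["change"]
        printed_effect = _EFFECT_ALIASES[row["effect"].strip().lower()]
        printed_type = _TYPE_ALIASES[row["mutation_type"].strip().lower()]

        m = _CODON_RE.match(change)
        if m:
            effect = classify_effect(m.group(1), m.group(2))
        else:
            effect = printed_effect  # splice/indel descriptors pass through
        substitution = classify_substitution(change)
        if effect is not printed_effect or substitution is not printed_type:
            raise ValidationError(
                f"line {lineno}: derived classification ({effect.value}, "
                f"{substitution.value}) contradicts printed annotation"
            )

        def _score(key: str) -> float | None:
            value = row.get(key, "").strip()
            return float(value) if value and value != "." else None

        records.append(
            MutationRecord(
                gene=row["gene"],
                chromosome=row["chromosome"],
                change=change,
                effect=effect,
                substitution=substitution,
                protein_change=row.get("protein") or None,
                polyphen2=_score("polyphen2"),
                gerp=_score("gerp"),
                rna_expression=_RNA_ALIASES[row["rna_expression"].strip().lower()],
                n_cases=int(row["cases"]) if row.get("cases", "").strip() else None,
            )
        )
    return records
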