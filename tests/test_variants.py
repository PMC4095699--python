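from fractions import Fraction
from math import factorial

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somascape import (
    Effect,
    FilterThresholds,
    MutationRecord,
    PrioritizationRules,
    RnaStatus,
    SubstitutionClass,
    ValidationError,
    apply_filters,
    classify_deleterious,
    classify_effect,
    classify_substitution,
    expression_support,
    fisher_exact_2x2,
    gerp_bin,
    load_mutation_table,
    prioritize,
    summarize_mutations,
)
from somascape import variants as vmod


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------


def hypergeom_tail_oracle(tumor_ref, tumor_alt, normal_ref, normal_alt):
    """Enumerate every table with the observed margins; sum the upper tail."""
    n_tumor = tumor_ref + tumor_alt
    n_normal = normal_ref + normal_alt
    n_alt = tumor_alt + normal_alt
    total = n_tumor + n_normal

    def pmf(k):
        # P(tumor_alt = k) via the factorial form of the hypergeometric pmf
        if k < 0 or k > n_tumor or n_alt - k < 0 or n_alt - k > n_normal:
            return Fraction(0)
        return Fraction(
            factorial(n_tumor) * factorial(n_normal)
            * factorial(n_alt) * factorial(total - n_alt),
            factorial(k) * factorial(n_tumor - k)
            * factorial(n_alt - k) * factorial(n_normal - (n_alt - k))
            * factorial(total),
        )

    return float(sum(pmf(k) for k in range(tumor_alt, n_alt + 1)))


def test_balanced_table_matches_oracle_and_shows_no_enrichment():
    p = fisher_exact_2x2(5, 5, 5, 5)
    assert p == pytest.approx(hypergeom_tail_oracle(5, 5, 5, 5), abs=1e-12)
    assert p > 0.5  # no enrichment signal


def test_strong_enrichment_matches_oracle():
    p = fisher_exact_2x2(10, 10, 20, 0)
    assert p == pytest.approx(hypergeom_tail_oracle(10, 10, 20, 0), abs=1e-12)
    assert p < 0.001


def test_zero_alt_reads_gives_p_one():
    assert fisher_exact_2x2(30, 0, 25, 0) == 1.0
    assert fisher_exact_2x2(10, 0, 5, 3) == 1.0


def test_negative_counts_rejected():
    with pytest.raises(ValidationError):
        fisher_exact_2x2(-1, 2, 3, 4)
    with pytest.raises(ValidationError):
        fisher_exact_2x2(0, 0, 0, 0)


@given(
    tr=st.integers(0, 25), ta=st.integers(0, 25),
    nr=st.integers(0, 25), na=st.integers(0, 25),
)
@settings(max_examples=200, deadline=None)
def test_fisher_matches_enumeration_oracle(tr, ta, nr, na):
    if tr + ta + nr + na == 0:
        return
    assert fisher_exact_2x2(tr, ta, nr, na) == pytest.approx(
        hypergeom_tail_oracle(tr, ta, nr, na), abs=1e-12
    )


@given(
    tr=st.integers(0, 20), ta=st.integers(0, 20),
    nr=st.integers(0, 20), na=st.integers(0, 20),
)
@settings(max_examples=100, deadline=None)
def test_two_sided_matches_scipy(tr, ta, nr, na):
    if tr + ta + nr + na == 0:
        return
    from scipy.stats import fisher_exact

    ours = fisher_exact_2x2(tr, ta, nr, na, alternative="two-sided")
    ref = fisher_exact([[ta, tr], [na, nr]], alternative="two-sided")[1]
    assert ours == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------------------
# apply_filters
# ---------------------------------------------------------------------------


def test_clean_somatic_site_passes():
    v = apply_filters(30, 20, 50, 0, base_quality=30, hq_alt_reads=20)
    assert v.passed and v.failures == ()
    assert v.vaf == pytest.approx(0.4)
    assert v.p_value < 0.05


def test_vaf_threshold_is_inclusive_at_20_percent():
    # VAF exactly 0.20 passes; just below fails
    v = apply_filters(80, 20, 100, 0, base_quality=30, hq_alt_reads=20)
    assert "vaf" not in v.failures
    v = apply_filters(81, 19, 100, 0, base_quality=30, hq_alt_reads=19)
    assert "vaf" in v.failures and not v.passed


def test_coverage_nine_fails():
    v = apply_filters(5, 4, 50, 0, base_quality=30, hq_alt_reads=4)
    assert "coverage" in v.failures
    assert v.coverage == 9


def test_zero_coverage_fails_without_raising():
    v = apply_filters(0, 0, 50, 2, base_quality=30, hq_alt_reads=0)
    assert not v.passed
    assert "coverage" in v.failures and "vaf" in v.failures
    assert v.vaf is None


def test_each_criterion_is_named():
    v = apply_filters(100, 5, 100, 5, base_quality=10, hq_alt_reads=2)
    assert {"fisher_p", "base_quality", "vaf", "alt_reads"} <= set(v.failures)


def test_boundary_alt_reads_and_quality_inclusive():
    v = apply_filters(30, 20, 50, 0, base_quality=20.0, hq_alt_reads=4)
    assert "base_quality" not in v.failures
    assert "alt_reads" not in v.failures


@given(
    tr=st.integers(0, 40), ta=st.integers(0, 40),
    nr=st.integers(0, 40), na=st.integers(0, 10),
    bq=st.floats(10, 40), hq=st.integers(0, 40),
)
@settings(max_examples=150, deadline=None)
def test_filter_verdict_monotone_in_evidence(tr, ta, nr, na, bq, hq):
    if tr + ta + nr + na == 0:
        return
    base = apply_filters(tr, ta, nr, na, base_quality=bq, hq_alt_reads=hq)
    if not base.passed:
        return
    improvements = [
        (tr, ta + 1, nr, na, bq, hq + 1),  # one more hq alt-supporting read
        (tr, ta, nr, na, bq + 5, hq),  # better base quality
        (tr, ta, nr, na, bq, hq + 1),  # more high-quality support
    ]
    for args in improvements:
        assert apply_filters(*args[:4], base_quality=args[4], hq_alt_reads=args[5]).passed


# ---------------------------------------------------------------------------
# prioritisation
# ---------------------------------------------------------------------------


def _record(effect=Effect.MISSENSE, polyphen2=None, gerp=None, known=False):
    return MutationRecord(
        gene="X", chromosome="1", change="GAA>CAA",
        effect=effect, substitution=SubstitutionClass.TRANSVERSION,
        polyphen2=polyphen2, gerp=gerp, known_variant=known,
    )


def test_high_polyphen_missense_kept():
    assert prioritize(_record(polyphen2=1.00)).keep


def test_low_polyphen_missense_dropped():
    result = prioritize(_record(polyphen2=0.02))
    assert not result.keep and result.reason == "low_functional_score"


def test_known_variant_dropped():
    assert not prioritize(_record(polyphen2=1.0, known=True)).keep


def test_truncating_variant_kept_regardless_of_scores():
    assert prioritize(_record(effect=Effect.NONSENSE, gerp=0.1)).keep
    assert prioritize(_record(effect=Effect.FRAMESHIFT)).keep


def test_both_scores_must_pass_when_present():
    assert not prioritize(_record(polyphen2=0.9, gerp=2.0)).keep
    assert prioritize(_record(polyphen2=0.9, gerp=3.5)).keep


def test_scoreless_missense_kept():
    assert prioritize(_record()).reason == "no_scores"


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    ("ref", "alt", "expected"),
    [
        ("GAA", "CAA", Effect.MISSENSE),  # E>Q
        ("CAG", "TAG", Effect.NONSENSE),  # Q>stop
        ("GAA", "GAG", Effect.SYNONYMOUS),  # E>E
        ("ATG", "ATA", Effect.MISSENSE),  # M>I
    ],
)
def test_classify_effect(ref, alt, expected):
    assert classify_effect(ref, alt) is expected


def test_invalid_codon_rejected():
    with pytest.raises(ValidationError):
        classify_effect("GAN", "CAA")
    with pytest.raises(ValidationError):
        classify_effect("GA", "CAA")


@pytest.mark.parametrize(
    ("change", "expected"),
    [
        ("ATG>ACG", SubstitutionClass.TRANSITION),  # T>C
        ("GAA>CAA", SubstitutionClass.TRANSVERSION),  # G>C
        ("A>G", SubstitutionClass.TRANSITION),
        ("c.742_743insA", SubstitutionClass.INDEL),
        ("c.100delT", SubstitutionClass.INDEL),
    ],
)
def test_classify_substitution(change, expected):
    assert classify_substitution(change) is expected


def test_multi_position_codon_change_rejected():
    with pytest.raises(ValidationError):
        classify_substitution("AAA>CCA")


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@given(ref=st.sampled_from("ACGT"), alt=st.sampled_from("ACGT"))
def test_substitution_partition_and_complement_symmetry(ref, alt):
    if ref == alt:
        return
    cls = classify_substitution(f"{ref}>{alt}")
    assert cls in (SubstitutionClass.TRANSITION, SubstitutionClass.TRANSVERSION)
    comp = f"{ref.translate(_COMPLEMENT)}>{alt.translate(_COMPLEMENT)}"
    assert classify_substitution(comp) is cls


@pytest.mark.parametrize(
    ("polyphen", "gerp", "expected"),
    [
        (0.04, None, False),
        (None, 5.91, True),
        (None, 4.05, True),
        (1.00, None, True),
        (0.5, None, False),  # strict > 0.5
        (None, 4.0, False),  # strict > 4
        (0.3, 4.5, True),  # OR rule
    ],
)
def test_classify_deleterious(polyphen, gerp, expected):
    assert classify_deleterious(polyphen, gerp) is expected


def test_deleterious_needs_a_score():
    with pytest.raises(ValidationError):
        classify_deleterious(None, None)


@pytest.mark.parametrize(
    ("gerp", "band"),
    [
        (2.9, "benign"),
        (3.0, "possibly_damaging"),
        (4.05, "possibly_damaging"),
        (5.0, "possibly_damaging"),
        (5.91, "probably_damaging"),
    ],
)
def test_gerp_bands(gerp, band):
    assert gerp_bin(gerp) == band


# ---------------------------------------------------------------------------
# packaged catalogue and summaries
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def catalogue():
    return load_mutation_table()


def test_catalogue_integrity(catalogue):
    assert len(catalogue) == 36
    assert len({r.gene for r in catalogue}) == 23


def test_catalogue_checksum_enforced(monkeypatch):
    monkeypatch.setattr(vmod, "MUTATION_TABLE_SHA256", "0" * 64)
    with pytest.raises(ValidationError):
        load_mutation_table()


def test_catalogue_cross_check_rejects_bad_annotation(tmp_path):
    src = (tmp_path / "bad.tsv")
    header = "gene\tcases\tchromosome\tchange\tprotein\teffect\tmutation_type\tpolyphen2\tgerp\trna_expression\n"
    # GAA>CAA is missense, printed as Nonsense -> must be rejected
    src.write_text(header + "X\t1\t1\tGAA>CAA\tp.E1Q\tNonsense\tTransversion\t1.0\t.\tYes\n")
    with pytest.raises(ValidationError):
        load_mutation_table(src)


def test_summary_reproduces_catalogue_counts(catalogue):
    s = summarize_mutations(catalogue, n_cohort=50)
    assert s.n_variants == 36
    assert s.n_genes == 23
    assert (s.n_missense, s.pct_missense) == (32, 89)
    assert (s.n_transitions, s.pct_transitions) == (22, 61)
    assert (s.n_deleterious, s.pct_deleterious) == (26, 72)
    assert s.gene_pct["TP53"] == 10
    assert s.gene_pct["DNAH9"] == 8
    assert s.gene_pct["PIK3CA"] == 4


def test_summary_single_record():
    rec = _record(polyphen2=1.0)
    s = summarize_mutations([rec], n_cohort=50)
    assert s.n_variants == 1
    assert s.pct_missense == 100
    assert s.pct_deleterious == 100


def test_summary_rejects_bad_cohort_size(catalogue):
    with pytest.raises(ValidationError):
        summarize_mutations(catalogue, n_cohort=0)
    with pytest.raises(ValidationError):
        summarize_mutations([], n_cohort=50)


def test_expression_support_on_catalogue(catalogue):
    support = expression_support(catalogue)
    assert (support.n_expressed, support.n_evaluable) == (15, 22)
    assert support.pct == 68


def test_expression_support_edge_cases():
    nd = [_record()]  # default RNA status is ND
    support = expression_support(nd)
    assert support.fraction is None and support.n_evaluable == 0

    yes = [
        MutationRecord(
            gene="X", chromosome="1", change="A>G",
            effect=Effect.SPLICE, substitution=SubstitutionClass.TRANSITION,
            rna_expression=RnaStatus.YES,
        )
    ]
    assert expression_support(yes).pct == 100


def test_threshold_dataclasses_validate():
    with pytest.raises(ValidationError):
        FilterThresholds(min_vaf=0.0)
    with pytest.raises(ValidationError):
        PrioritizationRules(functional_score_min=1.5)
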