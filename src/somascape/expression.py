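"""Copy-number/expression integration and qPCR relative expression.

Gene-level copy number (the total copy number of the segment containing the
gene's representative position) is correlated with log2 expression using
Pearson's test; the significance gate is one-directional (r > 0.4 and
p <= 0.05).  Genes inside recurrently deleted territory are screened with a
Welch test plus a >= 1.5 fold-change rule, and qPCR Ct values are converted
to reference-relative expression by the delta-Ct method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import SegmentProfile
from .errors import ValidationError

R_GATE = 0.4
P_GATE = 0.05
FOLD_CHANGE_GATE = 1.5


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chromosome: str
    position: int  # representative bp


@dataclass(frozen=True)
class CorrelationResult:
    gene: str | None
    r: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class UnderexpressionResult:
    t_statistic: float
    p_value: float
    fold_change: float  # reference-group mean over case-group mean
    underexpressed: bool


def copy_number_at(profile: SegmentProfile, chrom: str, position: int) -> int:
    """Total copy number of the segment containing ``position``.

    Positions falling between segments resolve to the nearest segment on the
    left (profiles are piecewise-constant between probes); a position before
    every segment of the chromosome is an error.
    """
    best = None
    for seg in profile.segments:
        if seg.chrom != chrom:
            continue
        if seg.start <= position < seg.end:
            return seg.total
        if seg.end <= position and (best is None or seg.end > best.end):
            best = seg
    if best is not None:
        return best.total
    raise ValidationError(
        f"{profile.sample_id}: no segment at or before {chrom}:{position}"
    )


def cn_expression_correlation(
    cn_values: np.ndarray,
    expr_values: np.ndarray,
    gene: str | None = None,
    r_min: float = R_GATE,
    p_max: float = P_GATE,
) -> CorrelationResult:
    """Pearson correlation between per-sample copy number and expression.

    p-values come from the exact t transform with n-2 degrees of freedom.
    Zero variance in either vector yields an indeterminate, non-significant
    result (r = nan).
    """
    cn = np.asarray(cn_values, dtype=float)
    expr = np.asarray(expr_values, dtype=float)
    if cn.shape != expr.shape or cn.ndim != 1:
        raise ValidationError("copy-number and expression vectors must match")
    if cn.size < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.ptp(cn) == 0 or np.ptp(expr) == 0:
        return CorrelationResult(gene, float("nan"), float("nan"), False)
    r, p = stats.pearsonr(cn, expr)
    significant = bool(r > r_min and p <= p_max)
    return CorrelationResult(gene, float(r), float(p), significant)


def correlate_loci(
    profiles: list[SegmentProfile],
    expression: pd.DataFrame,
    loci: list[GeneLocus],
) -> pd.DataFrame:
    """Per-locus correlation report (genes x samples expression frame)."""
    sample_ids = [p.sample_id for p in profiles]
    missing = [s for s in sample_ids if s not in expression.columns]
    if missing:
        raise ValidationError(f"expression matrix lacks samples {missing}")
    rows = []
    for locus in loci:
        if locus.gene not in expression.index:
            raise ValidationError(f"no expression row for gene {locus.gene!r}")
        cn = np.array(
            [copy_number_at(p, locus.chromosome, locus.position) for p in profiles],
            dtype=float,
        )
        expr = expression.loc[locus.gene, sample_ids].to_numpy(dtype=float)
        res = cn_expression_correlation(cn, expr, gene=locus.gene)
        rows.append(
            {
                "gene": locus.gene,
                "chromosome": locus.chromosome,
                "position": locus.position,
                "r": res.r,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def underexpression_test(
    case_expr: np.ndarray,
    reference_expr: np.ndarray,
    p_max: float = P_GATE,
    fold_change_min: float = FOLD_CHANGE_GATE,
) -> UnderexpressionResult:
    """Welch two-sample test with a conjunctive fold-change rule.

    The fold change is the reference-group mean over the case-group mean on
    the linear scale, so a flag requires the case group to be at least
    ``fold_change_min``-fold lower with Welch p <= ``p_max`` (two-sided).
    """
    case = np.asarray(case_expr, dtype=float)
    ref = np.asarray(reference_expr, dtype=float)
    if case.size < 2 or ref.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(case, ref, equal_var=False)
    case_mean = case.mean()
    fold = float("inf") if case_mean == 0 else ref.mean() / case_mean
    flag = bool(p <= p_max and fold >= fold_change_min)
    return UnderexpressionResult(float(t), float(p), float(fold), flag)


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Delta-Ct relative expression: 2**-(Ct_target - Ct_reference).

    Assumes 100% amplification efficiency; no calibrator sample is used.
    """
    if ct_target <= 0 or ct_reference <= 0:
        raise ValidationError("Ct values must be positive")
    return float(2.0 ** -(ct_target - ct_reference))
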