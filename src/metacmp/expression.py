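"""Metatranscriptome expression quantification.

A gene's expression is the median per-base read coverage over the gene;
genes with >30% similarity to eukaryote sequences (host contamination) are
excluded; surviving genes' expression is summed per COG or pfam, and the
per-unit sums are compared between two samples with the same odds-ratio
machinery used for metagenome comparison.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Sequence, Union

import numpy as np

from .differential import compare_profiles
from .model import (
    AnnotatedMetagenome,
    ComparisonResult,
    ExpressionProfile,
    Gene,
    ValidationError,
)

EUK_THRESHOLD = 0.30


def median_coverage(per_base_coverage: Sequence[int]) -> float:
    """Median of a per-base coverage vector (even length: mean of the middle
    pair)."""
    vec = np.asarray(per_base_coverage)
    if vec.size == 0:
        raise ValidationError("empty coverage vector")
    return float(np.median(vec))


def filter_eukaryotic(
    genes: Iterable[Gene], threshold: float = EUK_THRESHOLD
) -> List[Gene]:
    """Drop genes whose eukaryote similarity strictly exceeds ``threshold``.

    A gene exactly at the threshold, or with no recorded similarity, is kept.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    return [g for g in genes if g.euk_fraction <= threshold]


def unit_expression(
    expression: Mapping[str, float], genes: Iterable[Gene], namespace: str
) -> Dict[str, float]:
    """Sum member genes' expression per functional unit.

    ``expression`` maps gene_id to its (median-coverage) expression; genes
    with no entry count as 0 so unit membership stays stable across samples.
    """
    out: Dict[str, float] = {}
    for gene in genes:
        value = expression.get(gene.gene_id, 0.0)
        for unit in gene.units_in(namespace):
            out[unit.id] = out.get(unit.id, 0.0) + value
    return out


def build_expression_profile(
    mg: AnnotatedMetagenome,
    coverage: Mapping[str, Union[np.ndarray, float]],
    namespace: str,
    euk_threshold: float = EUK_THRESHOLD,
) -> ExpressionProfile:
    """Assemble an ExpressionProfile from per-gene coverage.

    ``coverage`` values may be per-base vectors (median is taken) or
    precomputed medians. Eukaryote-like genes are removed before aggregation.
    """
    gene_expr: Dict[str, float] = {}
    for gid, cov in coverage.items():
        arr = np.atleast_1d(np.asarray(cov))
        gene_expr[gid] = median_coverage(arr) if arr.size > 1 else float(arr[0])
    retained = filter_eukaryotic(mg.genes.values(), euk_threshold)
    return ExpressionProfile(
        sample_id=mg.sample_id,
        namespace=namespace,
        gene_expression=gene_expr,
        unit_expression=unit_expression(gene_expr, retained, namespace),
    )


def compare_expression(
    expr_a: ExpressionProfile,
    expr_b: ExpressionProfile,
    alpha: float = 0.05,
    cc: float = 0.5,
) -> List[ComparisonResult]:
    """Differential expression between two samples via per-unit odds ratios."""
    if expr_a.namespace != expr_b.namespace:
        raise ValidationError("namespace mismatch between expression profiles")
    return compare_profiles(
        expr_a.as_abundance_profile(),
        expr_b.as_abundance_profile(),
        alpha=alpha,
        cc=cc,
    )
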