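"""OTU-level community statistics and weighted taxonomic profiles.

Covers the 16S amplicon side of the analysis — relative abundance and
major-OTU selection, Shannon diversity, analytic rarefaction, habitat
categorisation of OTUs — and the assembly side: a minimal lowest-common-
ancestor (LCA) assigner over precomputed hit lineages and depth- or
expression-weighted taxonomic composition profiles.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .model import Gene, OTUTable, UNCLASSIFIED, ValidationError

#: Habitat labels of an OTU's closest database relatives (input vocabulary).
HABITAT_LABELS = (
    "higher_termite",
    "lower_termite",
    "animal_gut_or_feces",
    "other_anoxic",
)

#: Output habitat categories, ordered from most restricted to most cosmopolitan.
HABITAT_CATEGORIES = (
    "higher_termite_only",
    "termite_only",
    "animal_gut",
    "other_anoxic",
)

#: Lineage prefix length per rank (lineages run domain -> phylum -> class -> ...).
_RANK_DEPTH = {"domain": 1, "phylum": 2, "class": 3}


def major_otus(
    table: OTUTable, sample: str, threshold_pct: float = 0.5
) -> List[str]:
    """OTUs comprising strictly more than ``threshold_pct`` % of the sample."""
    if sample not in table.counts.columns:
        raise ValidationError(f"sample {sample!r} not in OTU table")
    col = table.counts[sample]
    total = int(col.sum())
    if total <= 0:
        raise ValidationError(f"sample {sample!r} has zero total count")
    frac = col / total
    return [otu for otu in table.counts.index if frac[otu] > threshold_pct / 100.0]


def shannon(counts: Sequence[float]) -> float:
    """Shannon diversity H in nats; zero-count categories are ignored."""
    arr = np.asarray(list(counts), dtype=float)
    if arr.sum() <= 0:
        raise ValidationError("all counts are zero")
    if (arr < 0).any():
        raise ValidationError("negative counts")
    return float(stats.entropy(arr[arr > 0]))


def rarefaction(counts: Sequence[int], depths: Sequence[int]) -> List[float]:
    """Expected OTU richness at each subsampling depth (analytic, exact).

    E[S_n] = S - sum_i C(N - N_i, n) / C(N, n), evaluated with log-domain
    binomial coefficients; deterministic, no resampling.
    """
    arr = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    N = int(arr.sum())
    if N <= 0:
        raise ValidationError("all counts are zero")
    S = arr.size

    def log_choose(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = []
    for n in depths:
        n = int(n)
        if n < 0 or n > N:
            raise ValidationError(f"depth {n} exceeds total count {N}")
        missing = 0.0
        for Ni in arr:
            if N - Ni >= n:
                missing += math.exp(log_choose(N - Ni, n) - log_choose(N, n))
        out.append(S - missing)
    return out


def habitat_category(habitat_records: Iterable[str]) -> str:
    """Classify an OTU by the habitats of its closest relatives.

    Precedence runs from the most cosmopolitan observation down: a single
    relative from another anoxic environment makes the OTU ``other_anoxic``;
    otherwise any animal gut/feces record gives ``animal_gut``; otherwise any
    lower-termite record gives ``termite_only``; an OTU seen only in higher
    termites is ``higher_termite_only``. Order-independent.
    """
    labels = set(habitat_records)
    if not labels:
        raise ValidationError("empty habitat record list")
    unknown = labels - set(HABITAT_LABELS)
    if unknown:
        raise ValidationError(f"unknown habitat labels {sorted(unknown)}")
    if "other_anoxic" in labels:
        return "other_anoxic"
    if "animal_gut_or_feces" in labels:
        return "animal_gut"
    if "lower_termite" in labels:
        return "termite_only"
    return "higher_termite_only"


def lca_assign(hit_lineages: Sequence[Sequence[str]]) -> Tuple[str, ...]:
    """Lowest common ancestor = longest common prefix of the hit lineages.

    Returns an empty tuple (unclassified) when there are no hits or the hits
    disagree at the domain level.
    """
    lineages = [tuple(l) for l in hit_lineages if l]
    if not lineages:
        return ()
    prefix = lineages[0]
    for lin in lineages[1:]:
        k = 0
        for a, b in zip(prefix, lin):
            if a != b:
                break
            k += 1
        prefix = prefix[:k]
        if not prefix:
            break
    return prefix


def format_lineage(lineage: Sequence[str]) -> str:
    return ";".join(lineage) if lineage else UNCLASSIFIED


def weighted_taxonomy(
    genes: Iterable[Gene], weights: Mapping[str, float], rank: str = "phylum"
) -> Dict[str, float]:
    """Weight each gene's lineage (truncated at ``rank``) by its read depth or
    expression level and normalise to fractions summing to 1.

    Genes unresolved at the requested rank pool into ``unclassified``.
    """
    if rank not in _RANK_DEPTH:
        raise ValidationError(f"rank must be one of {sorted(_RANK_DEPTH)}")
    depth = _RANK_DEPTH[rank]
    acc: Dict[str, float] = {}
    for gene in genes:
        w = weights.get(gene.gene_id, 0.0)
        if w < 0:
            raise ValidationError(f"negative weight for gene {gene.gene_id}")
        if w == 0:
            continue
        taxon = gene.lineage[depth - 1] if len(gene.lineage) >= depth else UNCLASSIFIED
        acc[taxon] = acc.get(taxon, 0.0) + w
    total = sum(acc.values())
    if total <= 0:
        raise ValidationError("total weight is zero")
    return {t: v / total for t, v in acc.items()}
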