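"""Differential comparison of two functional profiles via the log odds ratio.

For each functional unit the two samples form a 2x2 table: unit mass vs
rest-of-namespace mass in sample A and sample B. The natural log of the odds
ratio (LOR) with Woolf's asymptotic standard error gives the Z-LOR statistic
``z = lor / se``; two-sided normal p-values are corrected with the
Benjamini–Hochberg step-up (FDR). Depth-weighted (non-integer) masses are used
directly in the cells — the weighting is the point of the method, and Woolf's
formula is defined for positive reals.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import AbundanceProfile, ComparisonResult, Unit, ValidationError


def log_odds_ratio(
    a: float, A: float, b: float, B: float, cc: float = 0.5
) -> Tuple[float, float]:
    """LOR and Woolf SE for the 2x2 table (a, A-a) vs (b, B-b).

    The Haldane–Anscombe continuity correction ``cc`` is added to all four
    cells, but only when at least one cell is exactly zero; otherwise the
    cells are used as given.
    """
    if A <= 0 or B <= 0:
        raise ValidationError("profile totals must be positive")
    if a < 0 or b < 0 or A - a < 0 or B - b < 0:
        raise ValidationError("cell outside [0, total]")
    if cc < 0:
        raise ValidationError("continuity correction must be >= 0")
    cells = [a, A - a, b, B - b]
    if cc > 0 and min(cells) == 0:
        cells = [c + cc for c in cells]
    a1, a2, b1, b2 = cells
    if min(cells) <= 0:
        raise ValidationError("zero cell with no continuity correction")
    # computed as a difference of per-sample log odds so that swapping the
    # samples negates the result bit-for-bit
    lor = math.log(a1 / a2) - math.log(b1 / b2)
    se = math.sqrt(1.0 / a1 + 1.0 / a2 + 1.0 / b1 + 1.0 / b2)
    return lor, se


def zlor_test(lor: float, se: float) -> Tuple[float, float]:
    """Z-LOR statistic and its two-sided standard-normal p-value."""
    if se <= 0:
        raise ValidationError("se must be positive")
    z = lor / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(p, 1.0)


def bh_fdr(pvalues: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return list(q)


def compare_profiles(
    profile_a: AbundanceProfile,
    profile_b: AbundanceProfile,
    alpha: float = 0.05,
    cc: float = 0.5,
) -> List[ComparisonResult]:
    """Unit-by-unit differential comparison of two profiles (A vs B).

    The union of unit keys is used; a unit absent from one sample has
    abundance 0 there. Results are ordered lexicographically by unit id.
    """
    if profile_a.namespace != profile_b.namespace:
        raise ValidationError(
            f"namespace mismatch: {profile_a.namespace} vs {profile_b.namespace}"
        )
    units = sorted(set(profile_a.abundance) | set(profile_b.abundance))
    if not units:
        return []
    A, B = profile_a.total, profile_b.total

    lors, ses, zs, ps = [], [], [], []
    for uid in units:
        a = profile_a.abundance.get(uid, 0.0)
        b = profile_b.abundance.get(uid, 0.0)
        lor, se = log_odds_ratio(a, A, b, B, cc=cc)
        z, p = zlor_test(lor, se)
        lors.append(lor)
        ses.append(se)
        zs.append(z)
        ps.append(p)
    qs = bh_fdr(ps)

    ns = profile_a.namespace
    return [
        ComparisonResult(
            unit=Unit(ns, uid),
            lor=lor,
            se=se,
            z=z,
            p=p,
            q=q,
            significant=bool(q < alpha),
        )
        for uid, lor, se, z, p, q in zip(units, lors, ses, zs, ps, qs)
    ]
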