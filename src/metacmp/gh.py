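"""CAZy glycoside hydrolase (GH) family inventories.

Maps pfam domain annotations to GH families of plant-cell-wall-degrading
enzymes, computes depth-weighted relative abundances among the total GHs in
the mapping, per-category subtotals, the >=min% heatmap matrix across samples,
and hierarchical clustering of profiles.

Families with no diagnostic pfam domain (GH44, GH51, GH74 — identified by
sequence search upstream) are consumed as explicit per-gene ``GH_family``
annotations rather than by running homology search here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .model import AnnotatedMetagenome, ValidationError

CATEGORIES = (
    "cellulases",
    "endohemicellulase",
    "cell_wall_elongation",
    "debranching",
    "oligosaccharide_degrading",
)

_DISTANCES = ("braycurtis", "euclidean", "correlation")
_LINKAGES = ("average", "complete")


@dataclass(frozen=True)
class GHMapping:
    """One GH family: its pfam domains (possibly none), category, activity."""

    gh_family: str
    pfam_ids: tuple
    category: str
    known_activity: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"{self.gh_family}: unknown category {self.category!r}"
            )


@dataclass
class GHInventory:
    """Per-sample GH-family relative abundances (% of total mapped GHs)."""

    sample_id: str
    percentages: Dict[str, float]  # gh_family -> % of total GHs
    subtotals: Dict[str, float]  # category -> %


def load_gh_mapping(path: Optional[Union[str, Path]] = None) -> List[GHMapping]:
    """Load the GH<->pfam mapping; the shipped resource covers the GH families
    of plant cell wall degradation profiled across termite-gut and other
    lignocellulolytic microbiomes."""
    if path is None:
        ref = resources.files("metacmp.data").joinpath("gh_mapping.tsv")
        with resources.as_file(ref) as p:
            return load_gh_mapping(p)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    out = []
    seen = set()
    for _, row in df.iterrows():
        fam = row["gh_family"]
        if fam in seen:
            raise ValidationError(f"duplicate GH family {fam!r} in mapping")
        seen.add(fam)
        pfams = tuple(p for p in row["pfam_ids"].split(",") if p)
        out.append(GHMapping(fam, pfams, row["category"], row.get("known_activity", "")))
    return out


def _pfam_to_family(mapping: Sequence[GHMapping]) -> Dict[str, str]:
    table: Dict[str, str] = {}
    for m in mapping:
        for pf in m.pfam_ids:
            if pf in table and table[pf] != m.gh_family:
                raise ValidationError(f"pfam {pf} maps to two GH families")
            table[pf] = m.gh_family
    return table


def gh_profile(
    mg: AnnotatedMetagenome, mapping: Sequence[GHMapping]
) -> GHInventory:
    """Depth-weighted GH family percentages for one sample.

    A gene carrying several pfam domains of the *same* family (e.g. the three
    GH2 domains) counts once; a gene genuinely annotated to two families
    counts in both. Percentages are normalised by the total mass of all
    families in the mapping.
    """
    pfam_map = _pfam_to_family(mapping)
    known = {m.gh_family for m in mapping}
    mass: Dict[str, float] = {m.gh_family: 0.0 for m in mapping}
    for gene in mg.genes.values():
        fams = {pfam_map[u.id] for u in gene.units_in("pfam") if u.id in pfam_map}
        fams |= {u.id for u in gene.units_in("GH_family") if u.id in known}
        if not fams:
            continue
        depth = mg.depth_of(gene)
        for fam in fams:
            mass[fam] += depth
    total = sum(mass.values())
    if total <= 0:
        raise ValidationError("no GH genes")
    pct = {fam: 100.0 * v / total for fam, v in mass.items()}
    return GHInventory(
        sample_id=mg.sample_id,
        percentages=pct,
        subtotals=category_subtotals(pct, mapping),
    )


def category_subtotals(
    percentages: Union[GHInventory, Mapping[str, float]],
    mapping: Sequence[GHMapping],
) -> Dict[str, float]:
    """Sum member-family percentages per functional category.

    Accepts a computed :class:`GHInventory` or a plain ``family -> %`` map
    (e.g. published table values)."""
    if isinstance(percentages, GHInventory):
        percentages = percentages.percentages
    out = {cat: 0.0 for cat in CATEGORIES}
    for m in mapping:
        out[m.category] += percentages.get(m.gh_family, 0.0)
    return out


def inventory_table(
    inventories: Sequence[GHInventory], mapping: Sequence[GHMapping]
) -> pd.DataFrame:
    """GH families x samples percentage matrix in mapping (category) order."""
    fams = [m.gh_family for m in mapping]
    data = {
        inv.sample_id: [inv.percentages.get(f, 0.0) for f in fams]
        for inv in inventories
    }
    return pd.DataFrame(data, index=fams)


def heatmap_matrix(matrix: pd.DataFrame, min_pct: float = 2.0) -> pd.DataFrame:
    """Restrict a families x samples matrix to families reaching ``min_pct``
    (inclusive) in at least one sample."""
    if matrix.shape[1] < 2:
        raise ValidationError("heatmap needs at least two samples")
    keep = matrix.max(axis=1) >= min_pct
    if not keep.any():
        raise ValidationError("filter removed all GH families")
    return matrix.loc[keep]


def cluster_profiles(
    matrix: pd.DataFrame, distance: str = "braycurtis", linkage: str = "average"
):
    """Agglomerative clustering of the sample columns of a profile matrix.

    Returns ``(Z, labels)`` where ``Z`` is a scipy linkage matrix (merge order
    and heights) over the columns in their input (label) order, which also
    fixes tie-breaking.
    """
    if distance not in _DISTANCES:
        raise ValidationError(f"distance must be one of {_DISTANCES}")
    if linkage not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")
    if matrix.shape[1] < 2:
        raise ValidationError("need at least two columns to cluster")
    X = matrix.to_numpy(dtype=float).T
    d = pdist(X, metric=distance)
    if np.any(np.isnan(d)):
        raise ValidationError("undefined distance (constant profile?)")
    Z = hierarchy.linkage(d, method=linkage)
    return Z, list(matrix.columns)


def dendrogram_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage matrix as a Newick-style nested string with heights."""
    n = len(labels)
    nodes = {i: (labels[i], 0.0) for i in range(n)}
    for k, (i, j, h, _) in enumerate(Z):
        li, hi = nodes.pop(int(i))
        lj, hj = nodes.pop(int(j))
        nodes[n + k] = (f"({li}:{h - hi:g},{lj}:{h - hj:g})", float(h))
    (tree, _), = nodes.values()
    return tree + ";"
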