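"""Depth-weighted functional-unit abundance and average genome size.

The abundance of a functional unit in a sample is the total count of genes
annotated to that unit, with each gene weighted by the mean read depth of its
contig — depth standing in for the abundance of the population the contig was
assembled from. A gene annotated to several units of the same namespace
contributes its full weight to each of them.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence

from .model import AbundanceProfile, AnnotatedMetagenome, ValidationError


def weighted_abundance(mg: AnnotatedMetagenome, namespace: str) -> AbundanceProfile:
    """Depth-weighted abundance profile of ``mg`` for one annotation namespace.

    ``abundance[u] = sum over genes g annotated to u of depth(contig(g))``.
    A namespace with no annotated genes yields an empty profile (total 0).
    """
    abundance: Dict[str, float] = {}
    for gene in mg.genes.values():
        units = gene.units_in(namespace)
        if not units:
            continue
        depth = mg.depth_of(gene)
        for unit in units:
            abundance[unit.id] = abundance.get(unit.id, 0.0) + depth
    return AbundanceProfile.from_abundance(mg.sample_id, namespace, abundance)


def relative_profile(profile: AbundanceProfile) -> Dict[str, float]:
    """Normalise a profile to fractions of the namespace total (sum to 1)."""
    if profile.total <= 0:
        raise ValidationError("empty profile")
    return {u: v / profile.total for u, v in profile.abundance.items()}


def cog_category_profile(
    cog_profile: AbundanceProfile, cog_to_categories: Mapping[str, Sequence[str]]
) -> AbundanceProfile:
    """Re-aggregate a COG profile into COG functional categories.

    A COG assigned to two categories counts fully in both. COGs absent from
    the mapping are dropped.
    """
    if cog_profile.namespace != "COG":
        raise ValidationError("cog_category_profile needs a COG-namespace profile")
    out: Dict[str, float] = {}
    for cog, mass in cog_profile.abundance.items():
        for cat in cog_to_categories.get(cog, ()):
            out[cat] = out.get(cat, 0.0) + mass
    return AbundanceProfile.from_abundance(
        cog_profile.sample_id, "COG_category", out
    )


def average_genome_size(
    mg: AnnotatedMetagenome, markers: Sequence[str]
) -> float:
    """Average genome size (bp) from single-copy phylogenetic marker COGs.

    AGS = total depth-weighted assembly mass divided by the mean depth-weighted
    abundance of the marker families:

        AGS = [sum_c length(c) * depth(c)] / [(1/|M|) * sum_{m in M} a_m]

    For markers present exactly once per genome this equals the depth-weighted
    mean genome length of the community.
    """
    markers = list(markers)
    if not markers:
        raise ValidationError("marker set is empty")
    if len(set(markers)) != len(markers):
        raise ValidationError("marker set contains duplicates")

    cog = weighted_abundance(mg, "COG")
    marker_mass = sum(cog.abundance.get(m, 0.0) for m in markers)
    if marker_mass <= 0:
        raise ValidationError("no marker genes found in metagenome")
    assembly_mass = sum(c.length * c.mean_depth for c in mg.contigs.values())
    return assembly_mass / (marker_mass / len(markers))
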