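"""Domain types for gene-centric metagenome comparison.

The unit of analysis is an annotated (meta)genome assembly: contigs carrying a
mean read depth — used throughout as a proxy for the abundance of the population
the contig derives from — and genes annotated with functional units (COGs, pfam
domains, COG functional categories, or CAZy glycoside-hydrolase families) and,
optionally, a taxonomic lineage and a eukaryote-similarity fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

#: Recognised functional-unit namespaces.
NAMESPACES = ("COG", "pfam", "COG_category", "GH_family")

#: Sentinel lineage for genes without taxonomic resolution.
UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    """Raised when an input table or object violates a model invariant."""


class Unit(NamedTuple):
    """A functional unit identifier, e.g. ``Unit('pfam', 'PF00150')``."""

    namespace: str
    id: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.namespace}:{self.id}"

    @classmethod
    def parse(cls, text: str) -> "Unit":
        ns, _, uid = text.partition(":")
        if not uid or ns not in NAMESPACES:
            raise ValidationError(f"malformed functional unit {text!r}")
        return cls(ns, uid)


@dataclass(frozen=True)
class Contig:
    contig_id: str
    length: int
    mean_depth: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"contig {self.contig_id}: length must be >= 1")
        if not (self.mean_depth >= 0) or math.isnan(self.mean_depth):
            raise ValidationError(
                f"contig {self.contig_id}: mean_depth must be non-negative"
            )


@dataclass(frozen=True)
class Gene:
    """A called gene. ``euk_similarity`` is the precomputed fraction of identity
    to the best eukaryote hit; ``None`` (absent) is treated as no evidence of
    eukaryotic origin, i.e. 0."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    units: frozenset = frozenset()
    lineage: tuple = ()
    euk_similarity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.euk_similarity is not None and not (0.0 <= self.euk_similarity <= 1.0):
            raise ValidationError(
                f"gene {self.gene_id}: euk_similarity outside [0, 1]"
            )

    def units_in(self, namespace: str) -> set:
        return {u for u in self.units if u.namespace == namespace}

    @property
    def euk_fraction(self) -> float:
        return 0.0 if self.euk_similarity is None else self.euk_similarity


@dataclass
class AnnotatedMetagenome:
    """Contigs plus genes for one sample; the input to all profiling stages."""

    sample_id: str
    contigs: dict = field(default_factory=dict)  # contig_id -> Contig
    genes: dict = field(default_factory=dict)  # gene_id -> Gene

    def __post_init__(self) -> None:
        dangling = [
            g.gene_id for g in self.genes.values() if g.contig_id not in self.contigs
        ]
        if dangling:
            raise ValidationError(
                "genes reference absent contigs: " + ", ".join(sorted(dangling))
            )

    def depth_of(self, gene: Gene) -> float:
        return self.contigs[gene.contig_id].mean_depth

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class AbundanceProfile:
    """Depth-weighted functional-unit abundances for one sample and namespace.

    ``abundance`` maps the unit id (without namespace prefix) to its total
    depth-weighted gene mass; ``total`` is the namespace-wide sum."""

    sample_id: str
    namespace: str
    abundance: dict  # unit id -> float
    total: float

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValidationError(f"unknown namespace {self.namespace!r}")
        neg = [u for u, v in self.abundance.items() if v < 0]
        if neg:
            raise ValidationError(f"negative abundance for {neg}")
        s = sum(self.abundance.values())
        if abs(s - self.total) > 1e-9 * max(1.0, abs(s)):
            raise ValidationError("total does not equal the sum of abundances")

    @classmethod
    def from_abundance(
        cls, sample_id: str, namespace: str, abundance: Mapping[str, float]
    ) -> "AbundanceProfile":
        ab = dict(abundance)
        return cls(sample_id, namespace, ab, float(sum(ab.values())))


@dataclass(frozen=True)
class ComparisonResult:
    """Per-unit differential result between two samples (A vs B)."""

    unit: Unit
    lor: float
    se: float
    z: float
    p: float
    q: float
    significant: bool

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.unit}: se must be positive")
        if abs(self.z - self.lor / self.se) > 1e-9 * max(1.0, abs(self.z)):
            raise ValidationError(f"{self.unit}: z != lor/se")
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValidationError(f"{self.unit}: p/q outside [0, 1]")
        if self.q < self.p - 1e-12:
            raise ValidationError(f"{self.unit}: q < p violates BH monotonicity")


@dataclass
class ExpressionProfile:
    """Per-gene and per-unit expression (median read coverage) for one sample."""

    sample_id: str
    namespace: str
    gene_expression: dict  # gene_id -> float
    unit_expression: dict  # unit id -> float

    def as_abundance_profile(self) -> AbundanceProfile:
        return AbundanceProfile.from_abundance(
            self.sample_id, self.namespace, self.unit_expression
        )


@dataclass
class OTUTable:
    """OTU counts per sample with representative lineages and the habitat
    labels of each OTU's closest database relatives."""

    counts: pd.DataFrame  # index: otu_id, columns: sample ids, integer counts
    lineages: dict = field(default_factory=dict)  # otu_id -> tuple of taxa
    habitat_records: dict = field(default_factory=dict)  # otu_id -> list of labels

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 1:
            raise ValidationError("OTU table needs at least one sample column")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("OTU counts must be non-negative")

    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)
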