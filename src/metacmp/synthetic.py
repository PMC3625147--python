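"""Synthetic annotated meta-omes with known ground truth.

Emulates the inputs of a two-sample gene-centric comparison: two communities
of genome models with per-sample relative abundances, contigs whose mean read
depths are the genome's abundance times lognormal noise, genes with
functional-unit copy numbers (optionally spiked with known between-sample
fold changes), single-copy marker genes, per-gene expression with known
differential effects, and multinomial OTU tables. Every generator is a pure
function of its parameters and an explicit seed.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    AnnotatedMetagenome,
    Contig,
    Gene,
    OTUTable,
    Unit,
    ValidationError,
)
from . import diversity


@dataclass(frozen=True)
class GenomeModel:
    """One community member: taxonomy, genome length, functional-unit copy
    numbers, single-copy marker COGs and per-sample relative abundance."""

    name: str
    lineage: tuple
    genome_length: int
    unit_copy_number: dict  # Unit -> int copies
    marker_units: tuple  # COG ids, exactly one copy each
    relative_abundance: dict  # sample label -> float

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValidationError(f"{self.name}: genome_length must be positive")
        for u, c in self.unit_copy_number.items():
            if int(c) != c or c < 0:
                raise ValidationError(f"{self.name}: copies of {u} must be int >= 0")
        for m in self.marker_units:
            marker = Unit("COG", m)
            if self.unit_copy_number.get(marker, 1) != 1:
                raise ValidationError(f"{self.name}: marker {m} must be single-copy")


@dataclass(frozen=True)
class SpikeDesign:
    """Known between-sample fold changes (sample A relative to B); units not
    listed default to fold 1."""

    folds: dict = field(default_factory=dict)  # Unit -> positive float

    def __post_init__(self) -> None:
        for u, f in self.folds.items():
            if not f > 0:
                raise ValidationError(f"fold change for {u} must be > 0")

    def fold(self, unit: Unit) -> float:
        return self.folds.get(unit, 1.0)


class PairedMetagenomes(NamedTuple):
    sample_a: AnnotatedMetagenome
    sample_b: AnnotatedMetagenome
    truth: pd.DataFrame  # namespace, unit, fold_change, expected_lor


class ExpressionSim(NamedTuple):
    metagenome: AnnotatedMetagenome  # genes carry the euk_similarity assignment
    coverage_a: dict  # gene_id -> per-base coverage vector
    coverage_b: dict
    truth: pd.DataFrame


class OTUSim(NamedTuple):
    table: OTUTable
    proportions: np.ndarray  # generative community proportions


def _check_composition(genomes: Sequence[GenomeModel], samples: Sequence[str]) -> None:
    if len(genomes) < 2:
        raise ValidationError("need at least two genomes")
    for s in samples:
        total = sum(g.relative_abundance.get(s, 0.0) for g in genomes)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"relative abundances in sample {s!r} sum to {total}, not 1"
            )


def _contig_lengths(rng: np.random.Generator, genome_length: int, n: int,
                    length_range: Tuple[int, int]) -> List[int]:
    # uniform raw draws rescaled so the contigs partition the genome exactly
    raw = rng.uniform(length_range[0], length_range[1], size=n)
    lengths = np.maximum(1, np.floor(raw / raw.sum() * genome_length)).astype(int)
    lengths[-1] += genome_length - int(lengths.sum())
    return [int(l) for l in lengths]


def generate_paired_metagenomes(
    genomes: Sequence[GenomeModel],
    spike: Optional[SpikeDesign] = None,
    *,
    depth_mu: float = math.log(10.0),
    depth_sigma: float = 0.5,
    n_contigs_per_genome: int = 5,
    contig_length_range: Tuple[int, int] = (5_000, 50_000),
    sample_ids: Tuple[str, str] = ("A", "B"),
    seed: int,
) -> PairedMetagenomes:
    """Generate two annotated metagenomes plus a ground-truth table.

    Contig depths are ``relative_abundance[sample] * LogNormal(depth_mu,
    depth_sigma)``; sample A's gene copy numbers are scaled by the spike's
    fold changes (``round(copies * fold)``; pick copy numbers that make the
    product integral for exact folds). The truth table records, per unit, the
    odds-based expected LOR computed from expected depth masses — exactly
    ``ln(fold)`` at sigma 0 with equal compositions and a single spiked unit.
    """
    if seed is None:
        raise ValidationError("a seed is required (reproducibility contract)")
    if depth_sigma < 0:
        raise ValidationError("depth_sigma must be >= 0")
    spike = spike or SpikeDesign()
    _check_composition(genomes, sample_ids)
    rng = np.random.default_rng(seed)

    def copies_for(g: GenomeModel, unit: Unit, sample_idx: int) -> int:
        c = g.unit_copy_number.get(unit, 0)
        if sample_idx == 0:
            return int(round(c * spike.fold(unit)))
        return int(c)

    metagenomes = []
    realized: List[Dict[Unit, float]] = [dict(), dict()]  # expected masses
    mean_depth_factor = math.exp(depth_mu + depth_sigma**2 / 2.0)

    for si, sample in enumerate(sample_ids):
        contigs, genes = {}, {}
        for g in genomes:
            rel = g.relative_abundance.get(sample, 0.0)
            lengths = _contig_lengths(
                rng, g.genome_length, n_contigs_per_genome, contig_length_range
            )
            cids = []
            for i, length in enumerate(lengths):
                cid = f"{sample}|{g.name}|c{i}"
                depth = rel * rng.lognormal(depth_mu, depth_sigma)
                contigs[cid] = Contig(cid, length, depth, sample)
                cids.append(cid)
            all_units = dict(g.unit_copy_number)
            for m in g.marker_units:
                all_units.setdefault(Unit("COG", m), 1)
            for unit, _ in sorted(all_units.items(), key=lambda kv: str(kv[0])):
                n_copies = (
                    1
                    if unit.namespace == "COG" and unit.id in g.marker_units
                    else copies_for(g, unit, si)
                )
                for k in range(n_copies):
                    gid = f"{sample}|{g.name}|{unit.namespace}:{unit.id}|{k}"
                    cid = cids[int(rng.integers(0, len(cids)))]
                    genes[gid] = Gene(
                        gene_id=gid,
                        contig_id=cid,
                        start=1,
                        end=999,
                        units=frozenset({unit}),
                        lineage=g.lineage,
                    )
                exp_copies = 1 if unit.namespace == "COG" and unit.id in g.marker_units else n_copies
                realized[si][unit] = (
                    realized[si].get(unit, 0.0)
                    + exp_copies * rel * mean_depth_factor
                )
        metagenomes.append(
            AnnotatedMetagenome(sample_id=sample, contigs=contigs, genes=genes)
        )

    truth = _truth_table(realized, spike)
    return PairedMetagenomes(metagenomes[0], metagenomes[1], truth)


def _truth_table(
    realized: Sequence[Mapping[Unit, float]], spike: SpikeDesign
) -> pd.DataFrame:
    units = sorted(set(realized[0]) | set(realized[1]), key=str)
    totals = [
        {ns: sum(v for u, v in r.items() if u.namespace == ns)
         for ns in {u.namespace for u in r}}
        for r in realized
    ]
    rows = []
    for u in units:
        a = realized[0].get(u, 0.0)
        b = realized[1].get(u, 0.0)
        A = totals[0].get(u.namespace, 0.0)
        B = totals[1].get(u.namespace, 0.0)
        if min(a, A - a, b, B - b) > 0:
            lor = math.log((a / (A - a)) / (b / (B - b)))
        else:
            lor = math.nan
        rows.append(
            {
                "namespace": u.namespace,
                "unit": u.id,
                "fold_change": spike.fold(u),
                "expected_lor": lor,
            }
        )
    return pd.DataFrame(rows)


def generate_expression(
    mg: AnnotatedMetagenome,
    de_design: Optional[Mapping[Unit, float]] = None,
    *,
    dispersion: float = 0.3,
    euk_fraction: float = 0.0,
    base_mean: float = 20.0,
    vector_length: int = 50,
    seed: int,
) -> ExpressionSim:
    """Per-gene per-base coverage vectors for two samples with unit-level
    expression fold changes (sample A relative to B).

    Coverage counts are negative-binomial with variance ``mu + dispersion *
    mu**2``; ``dispersion=0`` gives deterministic coverage equal to the mean
    (the no-noise limit). A fraction ``euk_fraction`` of genes is assigned a
    eukaryote similarity above the 0.30 exclusion threshold.
    """
    if seed is None:
        raise ValidationError("a seed is required (reproducibility contract)")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    if not (0.0 <= euk_fraction <= 1.0):
        raise ValidationError("euk_fraction must lie in [0, 1]")
    de_design = dict(de_design or {})
    rng = np.random.default_rng(seed)

    present = {u for g in mg.genes.values() for u in g.units}
    for u in set(de_design) - present:
        warnings.warn(f"de_design unit {u} absent from metagenome; ignored")
        del de_design[u]

    gene_ids = sorted(mg.genes)
    n_euk = int(round(euk_fraction * len(gene_ids)))
    euk_ids = set(rng.choice(gene_ids, size=n_euk, replace=False)) if n_euk else set()
    genes = {}
    for gid in gene_ids:
        g = mg.genes[gid]
        if gid in euk_ids:
            g = dataclasses.replace(
                g, euk_similarity=float(rng.uniform(0.31, 1.0))
            )
        genes[gid] = g
    mg_out = AnnotatedMetagenome(mg.sample_id, dict(mg.contigs), genes)

    def draw(mean: float) -> np.ndarray:
        if dispersion == 0:
            return np.full(vector_length, int(round(mean)), dtype=int)
        r = 1.0 / dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=vector_length)

    cov_a, cov_b = {}, {}
    expected = [dict(), dict()]  # per-unit expected expression sums
    for gid in gene_ids:
        g = genes[gid]
        fold = 1.0
        for u in g.units:
            fold *= de_design.get(u, 1.0)
        cov_a[gid] = draw(base_mean * fold)
        cov_b[gid] = draw(base_mean)
        if g.euk_fraction <= 0.30:
            for u in g.units:
                expected[0][u] = expected[0].get(u, 0.0) + base_mean * fold
                expected[1][u] = expected[1].get(u, 0.0) + base_mean
    spike = SpikeDesign(dict(de_design))
    return ExpressionSim(mg_out, cov_a, cov_b, _truth_table(expected, spike))


def generate_otu_table(
    alpha: Sequence[float],
    n_reads: int,
    habitat_pool: Sequence[str] = diversity.HABITAT_LABELS,
    *,
    n_samples: int = 2,
    seed: int,
) -> OTUSim:
    """Multinomial OTU counts from a Dirichlet community draw.

    One community proportion vector is drawn from Dirichlet(alpha) and shared
    by all samples; per-OTU habitat records are sampled from ``habitat_pool``.
    """
    if seed is None:
        raise ValidationError("a seed is required (reproducibility contract)")
    if n_reads < 1:
        raise ValidationError("n_reads must be >= 1")
    alpha = np.asarray(list(alpha), dtype=float)
    if alpha.size < 1 or (alpha <= 0).any():
        raise ValidationError("alpha must be positive")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(alpha) if alpha.size > 1 else np.array([1.0])
    S = alpha.size
    otu_ids = [f"OTU{i:04d}" for i in range(S)]
    counts = pd.DataFrame(
        {f"S{j}": rng.multinomial(n_reads, p) for j in range(n_samples)},
        index=otu_ids,
    )
    lineages = {
        oid: ("Bacteria", f"Phylum{i % 6}", f"Class{i % 17}") for i, oid in enumerate(otu_ids)
    }
    habitats = {
        oid: list(rng.choice(habitat_pool, size=int(rng.integers(1, 4)), replace=True))
        for oid in otu_ids
    }
    return OTUSim(OTUTable(counts, lineages, habitats), p)


def example_community(
    n_genomes: int = 20,
    n_units: int = 100,
    *,
    n_markers: int = 15,
    namespace: str = "pfam",
    composition: str = "equal",
    fixed_copy_units: Optional[Mapping[str, int]] = None,
    carry_prob: float = 0.6,
    genome_length_range: Tuple[int, int] = (2_000_000, 5_000_000),
    seed: int,
) -> List[GenomeModel]:
    """A ready-made community of genome models for simulations.

    Each genome carries each of ``n_units`` namespace units with probability
    ``carry_prob`` at 1–3 copies; ``fixed_copy_units`` pins chosen units to an
    exact copy number in every genome (useful to make spike folds integral).
    ``composition`` is ``"equal"`` (both samples 1/n per genome — balanced
    design, spike folds map to LOR exactly in expectation) or ``"distinct"``
    (two independent Dirichlet compositions — emulates two communities of
    differing taxonomic makeup).
    """
    if composition not in ("equal", "distinct"):
        raise ValidationError("composition must be 'equal' or 'distinct'")
    rng = np.random.default_rng(seed)
    unit_ids = [f"U{i:04d}" for i in range(n_units)]
    markers = tuple(f"COG{i:04d}" for i in range(n_markers))
    if composition == "equal":
        rel_a = rel_b = np.full(n_genomes, 1.0 / n_genomes)
    else:
        rel_a = rng.dirichlet(np.full(n_genomes, 5.0))
        rel_b = rng.dirichlet(np.full(n_genomes, 5.0))
    phyla = [f"Phylum{i % 6}" for i in range(n_genomes)]
    genomes = []
    for i in range(n_genomes):
        copies: Dict[Unit, int] = {}
        for uid in unit_ids:
            if uid in (fixed_copy_units or {}):
                copies[Unit(namespace, uid)] = int(fixed_copy_units[uid])
            elif rng.random() < carry_prob:
                copies[Unit(namespace, uid)] = int(rng.integers(1, 4))
        genomes.append(
            GenomeModel(
                name=f"G{i:03d}",
                lineage=("Bacteria", phyla[i], f"Class{i}"),
                genome_length=int(rng.integers(*genome_length_range)),
                unit_copy_number=copies,
                marker_units=markers,
                relative_abundance={"A": float(rel_a[i]), "B": float(rel_b[i])},
            )
        )
    return genomes
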