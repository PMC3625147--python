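import numpy as np
import pytest

from metacmp.model import AnnotatedMetagenome, Contig, Gene, Unit


def make_metagenome(sample_id, contig_specs, gene_specs):
    """contig_specs: (cid, length, depth); gene_specs: (gid, cid, units, lineage, euk)."""
    contigs = {
        cid: Contig(cid, length, depth, sample_id)
        for cid, length, depth in contig_specs
    }
    genes = {}
    for spec in gene_specs:
        gid, cid, units = spec[0], spec[1], spec[2]
        lineage = spec[3] if len(spec) > 3 else ()
        euk = spec[4] if len(spec) > 4 else None
        genes[gid] = Gene(
            gene_id=gid,
            contig_id=cid,
            start=1,
            end=300,
            units=frozenset(Unit.parse(u) for u in units),
            lineage=tuple(lineage),
            euk_similarity=euk,
        )
    return AnnotatedMetagenome(sample_id=sample_id, contigs=contigs, genes=genes)


@pytest.fixture
def tiny_metagenome():
    """Two contigs (depths 3 and 5), three pfam-annotated genes."""
    return make_metagenome(
        "s1",
        [("c1", 10_000, 3.0), ("c2", 20_000, 5.0)],
        [
            ("g1", "c1", ["pfam:PF00001"]),
            ("g2", "c1", ["pfam:PF00001"]),
            ("g3", "c2", ["pfam:PF00001", "pfam:PF00002"]),
        ],
    )


def random_metagenome(rng, n_contigs=8, n_genes=40, n_units=6, namespace="pfam"):
    contig_specs = [
        (f"c{i}", int(rng.integers(5_000, 50_000)), float(rng.uniform(0.5, 20)))
        for i in range(n_contigs)
    ]
    unit_ids = [f"X{i:03d}" for i in range(n_units)]
    gene_specs = []
    for j in range(n_genes):
        k = int(rng.integers(1, 3))
        units = [f"{namespace}:{u}" for u in rng.choice(unit_ids, size=k, replace=False)]
        gene_specs.append((f"g{j}", f"c{int(rng.integers(0, n_contigs))}", units))
    return make_metagenome("rand", contig_specs, gene_specs)
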