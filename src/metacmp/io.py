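"""Tab-delimited readers and writers for the pipeline's tables.

All tables are UTF-8 TSV with a header row; lines starting with ``#`` are
skipped (and used to carry profile metadata). Floats are written with ``repr``
precision so every reader/writer pair round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    AbundanceProfile,
    AnnotatedMetagenome,
    ComparisonResult,
    Contig,
    Gene,
    OTUTable,
    Unit,
    ValidationError,
)

PathLike = Union[str, Path]

_CONTIG_COLS = ["sample_id", "contig_id", "length", "mean_depth"]
_GENE_COLS = ["gene_id", "contig_id", "start", "end", "units", "lineage", "euk_similarity"]


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def _parse_units(text: str) -> frozenset:
    if not text:
        return frozenset()
    return frozenset(Unit.parse(tok) for tok in text.split(";") if tok)


def _parse_lineage(text: str) -> tuple:
    return tuple(t for t in text.split(";") if t) if text else ()


def read_metagenome(contig_table: PathLike, gene_table: PathLike) -> AnnotatedMetagenome:
    """Read one sample's contig and gene tables into an AnnotatedMetagenome.

    Malformed rows (non-numeric depth, duplicate ids, genes pointing at absent
    contigs) raise :class:`ValidationError` naming the offending row.
    """
    cdf = _read_tsv(contig_table, _CONTIG_COLS)
    samples = set(cdf["sample_id"])
    if len(samples) > 1:
        raise ValidationError(f"{contig_table}: multiple sample_ids {sorted(samples)}")
    sample_id = samples.pop() if samples else "sample"

    contigs = {}
    for _, row in cdf.iterrows():
        cid = row["contig_id"]
        if cid in contigs:
            raise ValidationError(f"{contig_table}: duplicate contig_id {cid!r}")
        try:
            length = int(row["length"])
            depth = float(row["mean_depth"])
        except ValueError as exc:
            raise ValidationError(f"{contig_table}: contig {cid!r}: {exc}") from exc
        contigs[cid] = Contig(cid, length, depth, sample_id)

    gdf = _read_tsv(gene_table, _GENE_COLS[:4])
    genes = {}
    for _, row in gdf.iterrows():
        gid = row["gene_id"]
        if gid in genes:
            raise ValidationError(f"{gene_table}: duplicate gene_id {gid!r}")
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise ValidationError(f"{gene_table}: gene {gid!r}: {exc}") from exc
        euk_text = row.get("euk_similarity", "")
        euk = None if euk_text in ("", "NA") else float(euk_text)
        genes[gid] = Gene(
            gene_id=gid,
            contig_id=row["contig_id"],
            start=start,
            end=end,
            units=_parse_units(row.get("units", "")),
            lineage=_parse_lineage(row.get("lineage", "")),
            euk_similarity=euk,
        )
    return AnnotatedMetagenome(sample_id=sample_id, contigs=contigs, genes=genes)


def write_metagenome(
    mg: AnnotatedMetagenome, contig_table: PathLike, gene_table: PathLike
) -> None:
    with open(contig_table, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CONTIG_COLS) + "\n")
        for c in mg.contigs.values():
            fh.write(f"{c.sample_id}\t{c.contig_id}\t{c.length}\t{c.mean_depth!r}\n")
    with open(gene_table, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in mg.genes.values():
            units = ";".join(sorted(str(u) for u in g.units))
            lineage = ";".join(g.lineage)
            euk = "" if g.euk_similarity is None else repr(g.euk_similarity)
            fh.write(
                f"{g.gene_id}\t{g.contig_id}\t{g.start}\t{g.end}\t{units}\t{lineage}\t{euk}\n"
            )


def write_profile(profile: AbundanceProfile, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#sample_id={profile.sample_id}\n")
        fh.write(f"#namespace={profile.namespace}\n")
        fh.write("unit\tabundance\n")
        for uid in sorted(profile.abundance):
            fh.write(f"{uid}\t{profile.abundance[uid]!r}\n")


def read_profile(path: PathLike) -> AbundanceProfile:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") and "=" in line:
                key, _, val = line[1:].strip().partition("=")
                meta[key] = val
    df = _read_tsv(path, ["unit", "abundance"])
    abundance = {row["unit"]: float(row["abundance"]) for _, row in df.iterrows()}
    return AbundanceProfile.from_abundance(
        meta.get("sample_id", "sample"), meta.get("namespace", "pfam"), abundance
    )


_CMP_COLS = ["unit", "lor", "se", "z", "p", "q", "significant"]


def write_comparison(results: Sequence[ComparisonResult], path: PathLike) -> None:
    if results is None:
        raise ValidationError("results must not be None")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CMP_COLS) + "\n")
        for r in results:
            fh.write(
                f"{r.unit}\t{r.lor!r}\t{r.se!r}\t{r.z!r}\t{r.p!r}\t{r.q!r}\t{r.significant}\n"
            )


def read_comparison(path: PathLike) -> List[ComparisonResult]:
    df = _read_tsv(path, _CMP_COLS)
    out = []
    for _, row in df.iterrows():
        out.append(
            ComparisonResult(
                unit=Unit.parse(row["unit"]),
                lor=float(row["lor"]),
                se=float(row["se"]),
                z=float(row["z"]),
                p=float(row["p"]),
                q=float(row["q"]),
                significant=row["significant"] == "True",
            )
        )
    return out


def write_comparison_json(results: Sequence[ComparisonResult], path: PathLike) -> None:
    payload = [
        {
            "unit": str(r.unit),
            "lor": r.lor,
            "se": r.se,
            "z": r.z,
            "p": r.p,
            "q": r.q,
            "significant": r.significant,
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def write_coverage(coverage: Mapping[str, np.ndarray], path: PathLike) -> None:
    """Per-gene per-base coverage vectors, comma-packed in a single column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tcoverage\n")
        for gid in sorted(coverage):
            vec = np.asarray(coverage[gid])
            fh.write(gid + "\t" + ",".join(str(int(v)) for v in vec) + "\n")


def read_coverage(path: PathLike) -> dict:
    """Read coverage as ``gene_id -> np.ndarray`` (comma-packed ``coverage``
    column) or ``gene_id -> float`` when only a ``median`` column is present."""
    df = _read_tsv(path, ["gene_id"])
    if "coverage" in df.columns:
        return {
            row["gene_id"]: np.array(
                [int(v) for v in row["coverage"].split(",")] if row["coverage"] else [],
                dtype=int,
            )
            for _, row in df.iterrows()
        }
    if "median" in df.columns:
        return {row["gene_id"]: float(row["median"]) for _, row in df.iterrows()}
    raise ValidationError(f"{path}: need a 'coverage' or 'median' column")


def write_otu_table(table: OTUTable, counts_path: PathLike, habitat_path: Optional[PathLike] = None) -> None:
    df = table.counts.copy()
    df.insert(0, "lineage", [";".join(table.lineages.get(o, ())) for o in df.index])
    df.index.name = "otu_id"
    df.to_csv(counts_path, sep="\t")
    if habitat_path is not None:
        with open(habitat_path, "w", encoding="utf-8") as fh:
            fh.write("otu_id\thabitat_label\n")
            for otu in table.counts.index:
                for label in table.habitat_records.get(otu, []):
                    fh.write(f"{otu}\t{label}\n")


def read_otu_table(counts_path: PathLike, habitat_path: Optional[PathLike] = None) -> OTUTable:
    df = pd.read_csv(counts_path, sep="\t", comment="#", index_col="otu_id")
    lineages = {}
    if "lineage" in df.columns:
        lineages = {
            o: tuple(t for t in str(l).split(";") if t and t != "nan")
            for o, l in df["lineage"].items()
        }
        df = df.drop(columns=["lineage"])
    counts = df.astype(int)
    habitats: dict = {}
    if habitat_path is not None:
        hdf = _read_tsv(habitat_path, ["otu_id", "habitat_label"])
        for _, row in hdf.iterrows():
            habitats.setdefault(row["otu_id"], []).append(row["habitat_label"])
    return OTUTable(counts=counts, lineages=lineages, habitat_records=habitats)
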