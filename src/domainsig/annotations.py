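"""Gene and protein-domain annotation records and their file formats.

Internal coordinate convention is 0-based half-open throughout; GFF3
(1-based inclusive) and the domain TSV (1-based inclusive) are converted on
read and write, BED passes through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import InputError

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GeneRecord:
    """A gene's genomic span. Coordinates are 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise InputError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in _STRANDS:
            raise InputError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class DomainRecord:
    """One occurrence of a protein-family domain.

    Located either by a host ``gene_id`` or by genomic coordinates
    (0-based half-open) — exactly one of the two forms.
    """

    domain_id: str
    gene_id: Optional[str] = None
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self):
        by_gene = self.gene_id is not None
        by_coord = self.chrom is not None or self.start is not None or self.end is not None
        if by_gene == by_coord:
            raise InputError(
                f"domain {self.domain_id}: exactly one of gene_id or coordinates required"
            )
        if by_coord:
            if self.chrom is None or self.start is None or self.end is None:
                raise InputError(f"domain {self.domain_id}: incomplete coordinates")
            if self.start >= self.end:
                raise InputError(f"domain {self.domain_id}: start must be < end")

    @property
    def has_coordinates(self) -> bool:
        return self.chrom is not None


def _check_unique_gene_ids(genes: list[GeneRecord]) -> None:
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise InputError(f"duplicate gene id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)


# ----------------------------------------------------------------- GFF3

def write_gff3(genes: list[GeneRecord], path) -> None:
    """Write gene features as GFF3 (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tdomainsig\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path, feature_type: str = "gene") -> list[GeneRecord]:
    """Read gene features from a GFF3 file.

    Only rows of ``feature_type`` carrying an ``ID`` (or ``gene_id``)
    attribute are used; coordinates are converted to 0-based half-open.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise InputError(f"{path}: malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            attr_map = {}
            for item in attrs.strip().rstrip(";").split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            gene_id = attr_map.get("ID") or attr_map.get("gene_id")
            if gene_id is None:
                raise InputError(f"{path}: {feature_type} feature without ID attribute")
            genes.append(
                GeneRecord(gene_id, chrom, int(start) - 1, int(end),
                           strand if strand in _STRANDS else ".")
            )
    _check_unique_gene_ids(genes)
    return genes


# ------------------------------------------------------------------ BED

def read_bed(path) -> list[GeneRecord]:
    """Read genes from BED (>=4 columns; already 0-based half-open)."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise InputError(f"{path}: BED needs >=4 columns for gene ids")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else "."
            genes.append(GeneRecord(name, chrom, int(start), int(end), strand))
    _check_unique_gene_ids(genes)
    return genes


# ----------------------------------------------------------- domain TSV

def write_domain_tsv(domains: list[DomainRecord], path) -> None:
    """Write domain records as TSV.

    Coordinate form uses columns (domain_id, chrom, start, end) with 1-based
    inclusive coordinates; identifier form uses (domain_id, gene_id). Mixing
    forms in one table is rejected.
    """
    if not domains:
        pd.DataFrame(columns=["domain_id", "chrom", "start", "end"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )
        return
    forms = {d.has_coordinates for d in domains}
    if len(forms) > 1:
        raise InputError("cannot write a domain table mixing coordinate and gene_id forms")
    if forms.pop():
        df = pd.DataFrame(
            [(d.domain_id, d.chrom, d.start + 1, d.end) for d in domains],
            columns=["domain_id", "chrom", "start", "end"],
        )
    else:
        df = pd.DataFrame(
            [(d.domain_id, d.gene_id) for d in domains],
            columns=["domain_id", "gene_id"],
        )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_domain_tsv(path) -> list[DomainRecord]:
    """Read a domain TSV in either the coordinate or the gene_id form."""
    df = pd.read_csv(path, sep="\t", dtype={"domain_id": str})
    cols = set(df.columns)
    if {"domain_id", "chrom", "start", "end"}.issubset(cols):
        return [
            DomainRecord(str(r.domain_id), chrom=str(r.chrom),
                         start=int(r.start) - 1, end=int(r.end))
            for r in df.itertuples()
        ]
    if {"domain_id", "gene_id"}.issubset(cols):
        return [DomainRecord(str(r.domain_id), gene_id=str(r.gene_id)) for r in df.itertuples()]
    raise InputError(
        f"{path}: domain TSV needs columns (domain_id, chrom, start, end) or (domain_id, gene_id)"
    )
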