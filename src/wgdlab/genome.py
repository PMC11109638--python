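"""Genome containers: ordered gene lists per chromosome, with CDS and coordinates.

Collinearity works in gene-order rank space; base-pair coordinates are kept
only so that genomes round-trip through the standard interchange formats
(CDS FASTA, gene-table TSV, BED).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_TABLE_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "order_index"]


@dataclass
class Gene:
    """One protein-coding gene: identity, position and (optionally) its CDS."""

    id: str
    chromosome: str
    order: int  # 0-based rank along its chromosome
    start: int
    end: int
    strand: str = "+"
    cds: str | None = None
    family: str | None = None  # ancestral-gene id, when known from simulation


@dataclass
class Genome:
    """A genome as ordered gene lists keyed by chromosome name."""

    species: str
    chromosomes: dict[str, list[Gene]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, Gene] = {}
        self.reindex()

    def reindex(self) -> None:
        """Rebuild rank indices and the id lookup after structural edits."""
        self._index = {}
        for chrom, genes in self.chromosomes.items():
            for rank, g in enumerate(genes):
                g.chromosome = chrom
                g.order = rank
                if g.id in self._index:
                    raise ValueError(f"duplicate gene id {g.id!r} in genome {self.species!r}")
                self._index[g.id] = g

    def genes(self):
        for genes in self.chromosomes.values():
            yield from genes

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def get(self, gene_id: str) -> Gene | None:
        return self._index.get(gene_id)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._index[gene_id]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_cds_fasta(genome: Genome, path, meta: dict | None = None) -> None:
    records = [
        SeqRecord(Seq(g.cds), id=g.id, description=f"{g.chromosome}:{g.start}-{g.end}({g.strand})")
        for g in genome.genes()
        if g.cds is not None
    ]
    with open(path, "w") as fh:
        fh.write(_header_lines(meta).replace("# ", "; "))
        SeqIO.write(records, fh, "fasta")


def read_cds_fasta(path) -> dict[str, str]:
    """Gene id -> CDS string; comment lines (';') tolerated."""
    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith(";"))
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(io.StringIO(text), "fasta")}


def write_gene_table(genome: Genome, path, meta: dict | None = None) -> None:
    rows = [
        (g.id, g.chromosome, g.start, g.end, g.strand, g.order) for g in genome.genes()
    ]
    df = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_gene_table(path, species: str, cds: dict[str, str] | None = None) -> Genome:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} lacks columns {sorted(missing)}")
    chroms: dict[str, list[Gene]] = {}
    for row in df.sort_values(["chromosome", "order_index"]).itertuples(index=False):
        g = Gene(
            id=str(row.gene_id),
            chromosome=str(row.chromosome),
            order=int(row.order_index),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            cds=None if cds is None else cds.get(str(row.gene_id)),
        )
        chroms.setdefault(g.chromosome, []).append(g)
    return Genome(species=species, chromosomes=chroms)


def write_bed(genome: Genome, path, meta: dict | None = None) -> None:
    """0-based half-open BED6 with the order index in the score column."""
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        for g in genome.genes():
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.id}\t{g.order}\t{g.strand}\n")
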