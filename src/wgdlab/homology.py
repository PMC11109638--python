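"""Homologous gene pairs that seed synteny anchors.

Three sources: the simulator's ground truth, BLAST tabular files (the common
12-column ``-outfmt 6`` dialect), and a light built-in shared-k-mer search
for small inputs where running BLASTP is out of proportion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from .codons import translate
from .genome import Genome
from .simulate import TruthLog

log = logging.getLogger(__name__)

BLAST_TAB_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HomologPair:
    gene_a: str
    gene_b: str
    score: float
    source: str  # truth | blast_tab | builtin


class HomologyMismatchError(ValueError):
    """Genomes do not belong to the truth log they are compared against."""


def _canonical(a: str, b: str, score: float, source: str) -> HomologPair:
    if b < a:
        a, b = b, a
    return HomologPair(a, b, score, source)


def pairs_from_truth(truth: TruthLog, genome_a: Genome, genome_b: Genome) -> list[HomologPair]:
    """One pair per extant gene pair sharing an ancestral gene.

    Intragenomic mode (``genome_a is genome_b`` or same species) emits each
    unordered pair exactly once. Symmetric in its genome arguments up to
    id ordering.
    """
    for g in (genome_a, genome_b):
        unknown = [x.id for x in g.genes() if x.id not in truth.gene_genealogy]
        if unknown:
            raise HomologyMismatchError(
                f"genome {g.species!r} has genes absent from the truth log "
                f"(e.g. {unknown[0]!r}); genomes must come from the same simulation"
            )
    intra = genome_a.species == genome_b.species
    fam_a: dict[str, list[str]] = {}
    for g in genome_a.genes():
        fam_a.setdefault(truth.gene_genealogy[g.id][0], []).append(g.id)
    pairs: list[HomologPair] = []
    if intra:
        for fam in sorted(fam_a):
            members = sorted(fam_a[fam])
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.append(_canonical(members[i], members[j], 1.0, "truth"))
    else:
        fam_b: dict[str, list[str]] = {}
        for g in genome_b.genes():
            fam_b.setdefault(truth.gene_genealogy[g.id][0], []).append(g.id)
        for fam in sorted(fam_a):
            if fam not in fam_b:
                continue
            for a in sorted(fam_a[fam]):
                for b in sorted(fam_b[fam]):
                    pairs.append(_canonical(a, b, 1.0, "truth"))
    return pairs


def ortholog_pairs_from_truth(
    truth: TruthLog, genome_a: Genome, genome_b: Genome
) -> list[HomologPair]:
    """Cross-genome pairs that diverged at the species split itself.

    Emulates reciprocal-best-hit ortholog identification: of all homologous
    pairs between two genomes, those whose divergence event is the speciation
    (the minimum expected divergence over the comparison) are the orthologs;
    pairs split at WGDs predating the speciation are excluded.
    """
    if genome_a.species == genome_b.species:
        raise ValueError("ortholog extraction needs two different genomes")
    pairs = pairs_from_truth(truth, genome_a, genome_b)
    if not pairs:
        return []
    div = {p: truth.true_pair_ks[(p.gene_a, p.gene_b)] for p in pairs}
    t_min = min(div.values())
    return [p for p in pairs if div[p] <= t_min * (1 + 1e-9)]


class BlastTabParseError(ValueError):
    pass


def read_blast_tab(path, evalue_max: float = 1e-5) -> list[HomologPair]:
    """Parse 12-column BLAST tabular output into homolog pairs.

    Hits with E-value above ``evalue_max`` and self-hits are dropped; the
    best (max bitscore) hit per unordered gene pair is kept. Extra trailing
    columns are ignored.
    """
    best: dict[tuple[str, str], float] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastTabParseError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise BlastTabParseError(f"{path}:{lineno}: {exc}") from exc
            n_lines += 1
            if q == s or evalue > evalue_max:
                continue
            key = (q, s) if q <= s else (s, q)
            if bitscore > best.get(key, -1.0):
                best[key] = bitscore
    if n_lines == 0:
        warnings.warn(f"BLAST tabular file {path} contains no hits", stacklevel=2)
    return [HomologPair(a, b, sc, "blast_tab") for (a, b), sc in sorted(best.items())]


def _kmer_set(protein: str, k: int) -> frozenset[str]:
    return frozenset(protein[i : i + k] for i in range(len(protein) - k + 1))


def builtin_similarity(
    genome_a: Genome,
    genome_b: Genome,
    k: int = 6,
    score_min: int = 30,
) -> list[HomologPair]:
    """Shared amino-acid k-mer search for toy-scale inputs (<= ~10^4 genes).

    CDS are translated and scored by the number of shared k-mers; a pair is
    kept when it is a reciprocal best hit or its score reaches ``score_min``.
    Genes whose protein is shorter than ``k`` are skipped with a warning.
    """
    intra = genome_a.species == genome_b.species

    def _kmers(genome: Genome) -> dict[str, frozenset[str]]:
        out = {}
        n_short = 0
        for g in genome.genes():
            if g.cds is None:
                raise ValueError(f"gene {g.id} has no CDS; builtin similarity needs sequences")
            prot = translate(g.cds)
            if len(prot) < k:
                n_short += 1
                continue
            out[g.id] = _kmer_set(prot, k)
        if n_short:
            warnings.warn(f"{n_short} genes shorter than k={k} skipped", stacklevel=3)
        return out

    km_a = _kmers(genome_a)
    km_b = km_a if intra else _kmers(genome_b)

    # inverted index over genome_b k-mers
    index: dict[str, list[str]] = {}
    for gid, kms in km_b.items():
        for m in kms:
            index.setdefault(m, []).append(gid)

    scores: dict[tuple[str, str], int] = {}
    for gid, kms in km_a.items():
        counts: dict[str, int] = {}
        for m in kms:
            for other in index.get(m, ()):
                if other == gid:
                    continue
                counts[other] = counts.get(other, 0) + 1
        for other, sc in counts.items():
            key = (gid, other) if not intra or gid <= other else (other, gid)
            if sc > scores.get(key, -1):
                scores[key] = sc

    best_a: dict[str, tuple[int, str]] = {}
    best_b: dict[str, tuple[int, str]] = {}
    for (a, b), sc in scores.items():
        if sc > best_a.get(a, (-1, ""))[0]:
            best_a[a] = (sc, b)
        if sc > best_b.get(b, (-1, ""))[0]:
            best_b[b] = (sc, a)

    kept: list[HomologPair] = []
    for (a, b), sc in sorted(scores.items()):
        reciprocal = best_a.get(a, (None, None))[1] == b and best_b.get(b, (None, None))[1] == a
        if reciprocal or sc >= score_min:
            kept.append(_canonical(a, b, float(sc), "builtin"))
    return kept


def write_pairs_tsv(pairs: list[HomologPair], path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("gene_a\tgene_b\tscore\tsource\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.score}\t{p.source}\n")


def read_pairs_tsv(path) -> list[HomologPair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("gene_a\t"):
                continue
            a, b, score, source = line.rstrip("\n").split("\t")
            pairs.append(HomologPair(a, b, float(score), source))
    return pairs
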