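"""Ancestral-karyotype analysis: chromosome painting, fusion/fission counts,
homeolog pairing and ancestral-gene retention.

Painting labels each descendant chromosome interval by the ancestral
chromosome its collinear blocks trace back to (the style of the classical
ancestral-eudicot-karyotype figures). A chromosome painted with s segments
records s − 1 fusion events; an ancestral chromosome scattered over d
descendant chromosomes records d − 1 fissions. Homeologous chromosome pairs
descending from one pre-WGD chromosome are recovered by maximum-weight
matching on the graph of interchromosomal self-collinearity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

from scipy import stats as _scipy_stats

from .genome import Genome
from .synteny import CollinearBlock

log = logging.getLogger(__name__)

DEFAULT_MIN_SEGMENT_ANCHORS = 5


@dataclass
class Segment:
    start: int  # rank interval, closed
    end: int
    label: str  # ancestral chromosome
    n_anchors: int


@dataclass
class KaryotypePainting:
    segments: dict[str, list[Segment]]  # descendant chromosome -> ordered segments

    def labels_of(self, chromosome: str) -> list[str]:
        return [s.label for s in self.segments.get(chromosome, [])]


@dataclass
class FusionReport:
    per_chromosome: dict[str, int]
    total_fusions: int
    fission_count: int


@dataclass
class HomeologGroups:
    groups: list[tuple[str, str]]
    unassigned: list[str]
    linkage_weights: dict[tuple[str, str], int]


@dataclass
class RetentionTable:
    """Ancestral genes retained per syntenic block, grouped by species."""

    counts: dict[str, list[int]]  # species -> per-block retained-anchor counts

    def totals(self) -> dict[str, int]:
        return {sp: sum(v) for sp, v in self.counts.items()}


def paint_chromosomes(
    blocks_vs_ancestor: list[CollinearBlock],
    genome: Genome,
    min_segment_anchors: int = DEFAULT_MIN_SEGMENT_ANCHORS,
) -> KaryotypePainting:
    """Label chromosome intervals of ``genome`` by ancestral chromosome.

    Blocks must have the descendant genome on their a-axis and the ancestral
    gene order on the b-axis. Overlapping same-label intervals are merged
    (anchor counts summed), intervals below ``min_segment_anchors`` dropped,
    and adjacent same-label segments merged.
    """
    if not blocks_vs_ancestor:
        warnings.warn("no blocks: empty painting", stacklevel=2)
        return KaryotypePainting(segments={c: [] for c in genome.chromosomes})

    per_chrom: dict[str, list[Segment]] = {c: [] for c in genome.chromosomes}
    for b in blocks_vs_ancestor:
        if b.chrom_a not in per_chrom:
            continue
        lo, hi = b.span_a
        per_chrom[b.chrom_a].append(Segment(lo, hi, b.chrom_b, b.n_anchors))

    painting: dict[str, list[Segment]] = {}
    for chrom, segs in per_chrom.items():
        # merge overlapping same-label intervals
        merged: list[Segment] = []
        for s in sorted(segs, key=lambda s: (s.label, s.start)):
            if merged and merged[-1].label == s.label and s.start <= merged[-1].end:
                merged[-1].end = max(merged[-1].end, s.end)
                merged[-1].n_anchors += s.n_anchors
            else:
                merged.append(Segment(s.start, s.end, s.label, s.n_anchors))
        merged = [s for s in merged if s.n_anchors >= min_segment_anchors]
        merged.sort(key=lambda s: (s.start, s.end))
        # merge adjacent same-label segments
        out: list[Segment] = []
        for s in merged:
            if out and out[-1].label == s.label:
                out[-1].end = max(out[-1].end, s.end)
                out[-1].n_anchors += s.n_anchors
            else:
                out.append(s)
        painting[chrom] = out
    return KaryotypePainting(segments=painting)


def count_fusions(painting: KaryotypePainting) -> FusionReport:
    """Fusions = extra segments per chromosome; fissions = extra chromosomes per label."""
    per_chrom = {
        chrom: max(0, len(segs) - 1) for chrom, segs in painting.segments.items()
    }
    label_homes: dict[str, set[str]] = {}
    for chrom, segs in painting.segments.items():
        for s in segs:
            label_homes.setdefault(s.label, set()).add(chrom)
    fissions = sum(len(homes) - 1 for homes in label_homes.values())
    return FusionReport(
        per_chromosome=per_chrom,
        total_fusions=sum(per_chrom.values()),
        fission_count=fissions,
    )


def pair_homeologs(self_blocks: list[CollinearBlock], genome: Genome) -> HomeologGroups:
    """Pair chromosomes descending from one pre-WGD chromosome.

    Chromosomes are nodes; the weight of an edge is the total anchor count
    of interchromosomal self-collinearity blocks between the pair. A greedy
    maximum-weight matching (heaviest edge first, deterministic tie-break on
    chromosome names) yields the homeolog pairs; unmatched chromosomes are
    reported as unassigned.
    """
    weights: dict[tuple[str, str], int] = {}
    for b in self_blocks:
        if b.chrom_a == b.chrom_b:
            continue
        key = tuple(sorted((b.chrom_a, b.chrom_b)))
        weights[key] = weights.get(key, 0) + b.n_anchors

    chroms = sorted(genome.chromosomes)
    if not weights:
        warnings.warn("no interchromosomal self blocks: all chromosomes unassigned", stacklevel=2)
        return HomeologGroups(groups=[], unassigned=chroms, linkage_weights={})

    edges = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    used: set[str] = set()
    groups: list[tuple[str, str]] = []
    for (a, b), _w in edges:
        if a in used or b in used:
            continue
        groups.append((a, b))
        used.update((a, b))
    unassigned = [c for c in chroms if c not in used]
    return HomeologGroups(groups=sorted(groups), unassigned=unassigned, linkage_weights=weights)


def retention_table(blocks_by_species: dict[str, list[CollinearBlock]]) -> RetentionTable:
    """Per-block retained ancestral-gene (anchor) counts, grouped by species.

    Every species must be painted against the same ancestral gene order;
    species with zero blocks are excluded with a warning.
    """
    counts: dict[str, list[int]] = {}
    for sp in sorted(blocks_by_species):
        blocks = blocks_by_species[sp]
        if not blocks:
            warnings.warn(f"species {sp!r} has no blocks; excluded from retention table", stacklevel=2)
            continue
        counts[sp] = [b.n_anchors for b in blocks]
    return RetentionTable(counts=counts)


def retention_anova(table: RetentionTable) -> tuple[float, float]:
    """One-way ANOVA of per-block retention counts across species.

    Returns the classical F statistic and the upper-tail p-value from the
    F(k−1, N−k) distribution. Identical groups give F = 0, p = 1.
    """
    groups = [v for v in table.counts.values() if len(v) >= 2]
    if len(table.counts) < 2 or len(groups) < 2 or len(groups) != len(table.counts):
        raise ValueError("ANOVA needs >= 2 species groups with >= 2 blocks each")
    f, p = _scipy_stats.f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# I/O


def write_painting_tsv(painting: KaryotypePainting, path, genome: Genome | None = None, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("chromosome\tseg_start_rank\tseg_end_rank\tancestral_chromosome\tn_anchors\n")
        for chrom in sorted(painting.segments):
            for s in painting.segments[chrom]:
                fh.write(f"{chrom}\t{s.start}\t{s.end}\t{s.label}\t{s.n_anchors}\n")


def write_painting_bed(painting: KaryotypePainting, genome: Genome, path, meta: dict | None = None) -> None:
    """BED-like bp export using the genome's gene coordinates."""
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        for chrom in sorted(painting.segments):
            genes = genome.chromosomes.get(chrom, [])
            for s in painting.segments[chrom]:
                if not genes:
                    continue
                bp_start = genes[min(s.start, len(genes) - 1)].start
                bp_end = genes[min(s.end, len(genes) - 1)].end
                fh.write(f"{chrom}\t{bp_start}\t{bp_end}\t{s.label}\t{s.n_anchors}\t+\n")


def write_fusion_report(report: FusionReport, groups: HomeologGroups | None, path, meta: dict | None = None) -> None:
    payload = {
        "per_chromosome_fusions": report.per_chromosome,
        "total_fusions": report.total_fusions,
        "fission_count": report.fission_count,
    }
    if groups is not None:
        payload["homeolog_groups"] = [list(g) for g in groups.groups]
        payload["unassigned"] = groups.unassigned
    if meta:
        payload["_meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_retention_tsv(table: RetentionTable, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("species\tblock_index\tancestral_genes_retained\n")
        for sp in sorted(table.counts):
            for i, c in enumerate(table.counts[sp]):
                fh.write(f"{sp}\t{i}\t{c}\n")
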