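"""Collinearity: anchors in gene-rank space, chained blocks, syntenic depth.

All coordinates here are 0-based gene-order ranks; base pairs appear only in
I/O. Chaining is a longest-chain dynamic programme with a gap constraint,
applied greedily (best chain extracted, its anchors removed, repeat), which
is the scheme the common collinearity tools (MCScanX, WGDI) build on.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .genome import Genome
from .homology import HomologPair

log = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 25
DEFAULT_MIN_BLOCK_ANCHORS = 5
TANDEM_GAP = 2


@dataclass(frozen=True)
class Anchor:
    """A homologous gene pair placed in rank coordinates."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float = 0.0


@dataclass
class AnchorStats:
    n_input_pairs: int = 0
    n_unresolved: int = 0
    n_tandem_dropped: int = 0


@dataclass
class CollinearBlock:
    anchors: list[Anchor]
    chrom_a: str
    chrom_b: str
    orientation: str  # "+" | "-"
    # explicit metadata for blocks reloaded from TSV (no anchor list)
    meta_n_anchors: int | None = None
    meta_span_a: tuple[int, int] | None = None
    meta_span_b: tuple[int, int] | None = None

    @property
    def n_anchors(self) -> int:
        return self.meta_n_anchors if self.meta_n_anchors is not None else len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        if self.meta_span_a is not None:
            return self.meta_span_a
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        if self.meta_span_b is not None:
            return self.meta_span_b
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)


@dataclass
class DepthProfile:
    """Per-gene collinear coverage on the reference (b-axis) genome."""

    coverage: dict[str, list[int]]  # chromosome -> per-rank block count
    modal_depth: int | None
    histogram: dict[int, int]


def build_anchors(
    pairs: list[HomologPair],
    genome_a: Genome,
    genome_b: Genome,
) -> tuple[list[Anchor], AnchorStats]:
    """Place homolog pairs in rank coordinates.

    Pairs naming genes absent from the genomes are dropped (counted in the
    returned stats); intragenomic pairs closer than ``TANDEM_GAP`` ranks on
    one chromosome are treated as tandem duplicates, not anchors, and
    dropped as well.
    """
    stats = AnchorStats(n_input_pairs=len(pairs))
    intra = genome_a.species == genome_b.species
    anchors: list[Anchor] = []
    for p in pairs:
        ga = genome_a.get(p.gene_a)
        gb = genome_b.get(p.gene_b)
        if ga is None or gb is None:
            # pair ids are stored in canonical order, not genome order
            ga2, gb2 = genome_a.get(p.gene_b), genome_b.get(p.gene_a)
            if ga2 is not None and gb2 is not None:
                ga, gb = ga2, gb2
        if ga is None or gb is None:
            stats.n_unresolved += 1
            continue
        if intra and ga.chromosome == gb.chromosome and abs(ga.order - gb.order) <= TANDEM_GAP:
            stats.n_tandem_dropped += 1
            continue
        anchors.append(
            Anchor(ga.id, gb.id, ga.chromosome, gb.chromosome, ga.order, gb.order, p.score)
        )
    if pairs and not anchors and stats.n_unresolved == len(pairs):
        raise ValueError("no pair could be placed: genomes do not match the pair list")
    if stats.n_unresolved:
        log.warning("%d/%d pairs unresolvable, dropped", stats.n_unresolved, len(pairs))
    return anchors, stats


def _best_chain(anchors: list[Anchor], orientation: str, max_gap: int) -> list[int]:
    """Longest gap-constrained chain (indices into ``anchors``), DP O(n^2).

    Anchors must share one chromosome pair. Ties broken toward the chain
    whose first anchor has the smaller (rank_a, rank_b).
    """
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].rank_a, anchors[i].rank_b),
    )
    best_len = [1] * len(order)
    prev = [-1] * len(order)
    sign = 1 if orientation == "+" else -1
    for ii in range(len(order)):
        ai = anchors[order[ii]]
        for jj in range(ii):
            aj = anchors[order[jj]]
            da = ai.rank_a - aj.rank_a
            db = sign * (ai.rank_b - aj.rank_b)
            if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                continue
            if best_len[jj] + 1 > best_len[ii]:
                best_len[ii] = best_len[jj] + 1
                prev[ii] = jj
    if not order:
        return []
    end = max(range(len(order)), key=lambda i: (best_len[i], -anchors[order[i]].rank_a))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    chain.reverse()
    return chain


def chain_anchors(
    anchors: list[Anchor],
    max_gap: int = DEFAULT_MAX_GAP,
    min_block_anchors: int = DEFAULT_MIN_BLOCK_ANCHORS,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks, greedily per chromosome pair.

    Per chromosome pair the highest-scoring chain over both orientations is
    extracted, its anchors removed from the pool, and the process repeats
    until no chain reaches ``min_block_anchors``. Every anchor ends up in at
    most one block.
    """
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(by_pair):
        pool = list(by_pair[(ca, cb)])
        while True:
            candidates = []
            for orientation in ("+", "-"):
                idx = _best_chain(pool, orientation, max_gap)
                if len(idx) >= min_block_anchors:
                    first = pool[idx[0]]
                    candidates.append(
                        (len(idx), orientation == "+", -first.rank_a, -first.rank_b, orientation, idx)
                    )
            if not candidates:
                break
            candidates.sort(reverse=True)
            _, _, _, _, orientation, idx = candidates[0]
            chosen = [pool[i] for i in idx]
            blocks.append(CollinearBlock(chosen, ca, cb, orientation))
            taken = set(idx)
            pool = [a for i, a in enumerate(pool) if i not in taken]
    return blocks


def syntenic_depth(blocks: list[CollinearBlock], reference_genome: Genome) -> DepthProfile:
    """Per-gene block coverage on the reference genome (the blocks' b-axis)."""
    coverage = {
        chrom: [0] * len(genes) for chrom, genes in reference_genome.chromosomes.items()
    }
    for b in blocks:
        if b.chrom_b not in coverage:
            continue
        lo, hi = b.span_b
        arr = coverage[b.chrom_b]
        for r in range(max(0, lo), min(len(arr) - 1, hi) + 1):
            arr[r] += 1
    hist = Counter()
    for arr in coverage.values():
        hist.update(arr)
    nonzero = {d: c for d, c in hist.items() if d > 0}
    if not nonzero:
        log.warning("empty block list: all-zero depth profile, modal depth undefined")
        modal = None
    else:
        modal = min(nonzero, key=lambda d: (-nonzero[d], d))
    return DepthProfile(coverage=coverage, modal_depth=modal, histogram=dict(hist))


@dataclass
class ParalogyCluster:
    """Mutually paralogous reference segments plus their counterpart regions."""

    segments: list[tuple[str, int, int]]  # (chrom_a, start, end) merged A regions
    counterpart_count: int

    @property
    def size(self) -> int:
        return len(self.segments)


def _overlaps(lo1: int, hi1: int, lo2: int, hi2: int) -> bool:
    return lo1 <= hi2 and lo2 <= hi1


def _merge_intervals(iv: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[list] = []
    for chrom, lo, hi in sorted(iv):
        if out and out[-1][0] == chrom and lo <= out[-1][2] + 1:
            out[-1][2] = max(out[-1][2], hi)
        else:
            out.append([chrom, lo, hi])
    return [tuple(x) for x in out]


def paralogy_clusters(
    self_blocks: list[CollinearBlock],
    cross_blocks: list[CollinearBlock],
) -> list[ParalogyCluster]:
    """Group reference segments into paralogy clusters with counterpart counts.

    The a-side segments of ``cross_blocks`` are the nodes; two segments are
    joined when their rank intervals overlap (same region seen by several
    blocks) or when a ``self_blocks`` entry links the regions they occupy.
    Each connected component is one cluster; its size counts distinct
    (overlap-merged) reference regions and its counterpart count the merged
    b-side regions its cross blocks hit.
    """
    segs = [(b.chrom_a, *b.span_a) for b in cross_blocks]
    G = nx.Graph()
    G.add_nodes_from(range(len(segs)))

    # overlap edges (flagged so cluster size can count distinct regions)
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if segs[i][0] == segs[j][0] and _overlaps(segs[i][1], segs[i][2], segs[j][1], segs[j][2]):
                G.add_edge(i, j, kind="overlap")

    for sb in self_blocks:
        side1 = (sb.chrom_a, *sb.span_a)
        side2 = (sb.chrom_b, *sb.span_b)
        hit1 = [i for i, s in enumerate(segs) if s[0] == side1[0] and _overlaps(s[1], s[2], side1[1], side1[2])]
        hit2 = [i for i, s in enumerate(segs) if s[0] == side2[0] and _overlaps(s[1], s[2], side2[1], side2[2])]
        for i in hit1:
            for j in hit2:
                if i != j and not G.has_edge(i, j):
                    G.add_edge(i, j, kind="link")

    clusters: list[ParalogyCluster] = []
    for comp in nx.connected_components(G):
        comp = sorted(comp)
        overlap_sub = nx.Graph()
        overlap_sub.add_nodes_from(comp)
        overlap_sub.add_edges_from(
            (u, v) for u, v, d in G.edges(comp, data=True) if d["kind"] == "overlap" and u in comp and v in comp
        )
        merged_segments = []
        for region_nodes in nx.connected_components(overlap_sub):
            ivs = [segs[i] for i in region_nodes]
            chrom = ivs[0][0]
            merged_segments.append((chrom, min(x[1] for x in ivs), max(x[2] for x in ivs)))
        counterparts = _merge_intervals([(cross_blocks[i].chrom_b, *cross_blocks[i].span_b) for i in comp])
        clusters.append(
            ParalogyCluster(segments=sorted(merged_segments), counterpart_count=len(counterparts))
        )
    clusters.sort(key=lambda c: c.segments)
    return clusters


# ---------------------------------------------------------------------------
# I/O


def write_blocks_tsv(blocks: list[CollinearBlock], path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(
            "block_id\tchrom_a\tspan_a_start\tspan_a_end\tchrom_b\tspan_b_start\tspan_b_end\torientation\tn_anchors\n"
        )
        for i, b in enumerate(blocks):
            sa, sb = b.span_a, b.span_b
            fh.write(
                f"{i}\t{b.chrom_a}\t{sa[0]}\t{sa[1]}\t{b.chrom_b}\t{sb[0]}\t{sb[1]}\t{b.orientation}\t{b.n_anchors}\n"
            )


def read_blocks_tsv(path) -> list[CollinearBlock]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("block_id\t"):
                continue
            (_bid, ca, sa0, sa1, cb, sb0, sb1, orientation, n) = line.rstrip("\n").split("\t")
            blocks.append(
                CollinearBlock(
                    anchors=[],
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                    meta_n_anchors=int(n),
                    meta_span_a=(int(sa0), int(sa1)),
                    meta_span_b=(int(sb0), int(sb1)),
                )
            )
    return blocks


def write_anchors_tsv(blocks: list[CollinearBlock], path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("block_id\tgene_a\tgene_b\tchrom_a\tchrom_b\trank_a\trank_b\n")
        for i, b in enumerate(blocks):
            for a in b.anchors:
                fh.write(f"{i}\t{a.gene_a}\t{a.gene_b}\t{a.chrom_a}\t{a.chrom_b}\t{a.rank_a}\t{a.rank_b}\n")


def write_dotplot_tsv(blocks: list[CollinearBlock], path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("rank_a\trank_b\tchrom_a\tchrom_b\tblock_id\n")
        for i, b in enumerate(blocks):
            for a in b.anchors:
                fh.write(f"{a.rank_a}\t{a.rank_b}\t{a.chrom_a}\t{a.chrom_b}\t{i}\n")
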