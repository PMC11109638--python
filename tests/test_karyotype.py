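"""Painting, fusion/fission counting, homeolog matching and retention ANOVA."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import blocks_between
from wgdlab import homology, karyotype, simulate, synteny
from wgdlab.simulate import SimConfig, TimedEvent
from wgdlab.synteny import Anchor, CollinearBlock


def _block(chrom_a, chrom_b, ranks_a, ranks_b):
    anchors = [
        Anchor(f"{chrom_a}:{ra}", f"{chrom_b}:{rb}", chrom_a, chrom_b, ra, rb)
        for ra, rb in zip(ranks_a, ranks_b)
    ]
    return CollinearBlock(anchors, chrom_a, chrom_b, "+")


def _speciation_sim(extra_events=(), seed=0, n_chrom=4, genes=40):
    """Ancestor frozen as 'ref'; 'desc' optionally rearranged afterwards."""
    sched = [TimedEvent(60.0, "anc", "speciation", {"children": ["desc", "ref"]})]
    sched += list(extra_events)
    cfg = SimConfig(
        n_chromosomes=n_chrom, genes_per_chromosome=genes, codons_per_gene=60,
        schedule=sched, seed=seed, mode="ks_level",
    )
    return simulate.simulate_evolution(cfg)


class TestPainting:
    def test_unrearranged_descendant_paints_one_segment_per_chromosome(self):
        genomes, truth = _speciation_sim()
        blocks = blocks_between(truth, genomes["desc"], genomes["ref"])
        painting = karyotype.paint_chromosomes(blocks, genomes["desc"])
        for chrom, segs in painting.segments.items():
            assert len(segs) == 1
            assert segs[0].label == chrom  # same naming on both sides, no rearrangement

    def test_fused_chromosome_shows_two_segments_in_order(self):
        genomes, truth = _speciation_sim(
            [TimedEvent(30.0, "desc", "fusion", {"chrom_a": 0, "chrom_b": 1})]
        )
        desc = genomes["desc"]
        assert desc.n_chromosomes == 3
        blocks = blocks_between(truth, desc, genomes["ref"])
        painting = karyotype.paint_chromosomes(blocks, desc)
        fused = painting.segments["chr01"]
        assert [s.label for s in fused] == ["chr01", "chr02"]

    def test_segments_below_anchor_threshold_dropped(self):
        good = _block("c1", "A1", range(10), range(10))
        spurious = [
            _block("c1", f"A{i}", range(50 + 5 * i, 52 + 5 * i), range(2)) for i in (2, 3, 4)
        ]
        from conftest import make_genome

        g = make_genome("s", {"c1": 80})
        painting = karyotype.paint_chromosomes([good] + spurious, g, min_segment_anchors=5)
        assert [s.label for s in painting.segments["c1"]] == ["A1"]

    def test_empty_blocks_warn(self):
        from conftest import make_genome

        g = make_genome("s", {"c1": 10})
        with pytest.warns(UserWarning):
            painting = karyotype.paint_chromosomes([], g)
        assert painting.segments == {"c1": []}


class TestFusionCounts:
    def test_single_segment_chromosomes_have_zero_fusions(self):
        painting = karyotype.KaryotypePainting(
            {"c1": [karyotype.Segment(0, 10, "A1", 11)], "c2": [karyotype.Segment(0, 8, "A2", 9)]}
        )
        report = karyotype.count_fusions(painting)
        assert report.total_fusions == 0
        assert report.fission_count == 0

    def test_two_segment_chromosome_counts_one_fusion(self):
        painting = karyotype.KaryotypePainting(
            {"c1": [karyotype.Segment(0, 10, "A1", 11), karyotype.Segment(11, 20, "A2", 10)]}
        )
        assert karyotype.count_fusions(painting).total_fusions == 1

    def test_label_split_across_chromosomes_counts_fission(self):
        painting = karyotype.KaryotypePainting(
            {
                "c1": [karyotype.Segment(0, 10, "A1", 11)],
                "c2": [karyotype.Segment(0, 10, "A1", 11)],
            }
        )
        report = karyotype.count_fusions(painting)
        assert report.fission_count == 1
        assert report.total_fusions == 0


def _random_rearrangement_schedule(rng, n_chrom, genes):
    """Label-distinct fusions (recent) after single-label fissions (older)."""
    state = [({i}, genes) for i in range(n_chrom)]
    events = []
    t = 50.0
    j = int(rng.integers(0, 3))
    for _ in range(j):
        candidates = [i for i, (labels, ln) in enumerate(state) if len(labels) == 1 and ln >= 12]
        i = int(rng.choice(candidates))
        labels, ln = state[i]
        at = ln // 2
        events.append(TimedEvent(t, "desc", "fission", {"chromosome": i, "at_rank": at}))
        state[i] = (labels, at)
        state.append((labels, ln - at))
        t -= 1.0
    k = int(rng.integers(1, 6))
    for _ in range(k):
        while True:
            ia, ib = sorted(rng.choice(len(state), size=2, replace=False))
            la, lb = state[int(ia)][0], state[int(ib)][0]
            if not (la & lb):
                break
        state[int(ia)] = (la | lb, state[int(ia)][1] + state[int(ib)][1])
        del state[int(ib)]
        events.append(TimedEvent(t, "desc", "fusion", {"chrom_a": int(ia), "chrom_b": int(ib)}))
        t -= 1.0
    return events, k, j


def test_scheduled_fusions_and_fissions_recovered_from_painting():
    """Known rearrangement schedules are recovered exactly in >=95% of 20 replicates."""
    successes = 0
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        events, k, j = _random_rearrangement_schedule(rng, n_chrom=8, genes=40)
        genomes, truth = _speciation_sim(events, seed=rep, n_chrom=8)
        blocks = blocks_between(truth, genomes["desc"], genomes["ref"])
        painting = karyotype.paint_chromosomes(blocks, genomes["desc"])
        report = karyotype.count_fusions(painting)
        if report.total_fusions == k and report.fission_count == j:
            successes += 1
        # chromosome-count bookkeeping holds regardless
        assert genomes["desc"].n_chromosomes == 8 - k + j
    assert successes >= 19


def test_painting_labels_agree_with_genealogy_majority():
    genomes, truth = _speciation_sim(
        [TimedEvent(30.0, "desc", "fusion", {"chrom_a": 0, "chrom_b": 2})], seed=3
    )
    desc, ref = genomes["desc"], genomes["ref"]
    # map each ref chromosome to the ancestral chromosome its genes carry
    ref_label_to_anc = {}
    for g in ref.genes():
        ref_label_to_anc.setdefault(g.chromosome, truth.gene_genealogy[g.id][1])
    blocks = blocks_between(truth, desc, ref)
    painting = karyotype.paint_chromosomes(blocks, desc)
    for chrom, segs in painting.segments.items():
        genes = desc.chromosomes[chrom]
        for s in segs:
            anc = [truth.gene_genealogy[g.id][1] for g in genes[s.start : s.end + 1]]
            majority = max(set(anc), key=anc.count)
            assert ref_label_to_anc[s.label] == majority


# ---------------------------------------------------------------------------
# homeolog pairing


def oracle_matching_weight(weights: dict, nodes: list[str]) -> int:
    """Exhaustive maximum-weight matching total (for <=8 nodes)."""
    best = 0

    def rec(remaining, total):
        nonlocal best
        best = max(best, total)
        if len(remaining) < 2:
            return
        a = remaining[0]
        rec(remaining[1:], total)
        for b in remaining[1:]:
            w = weights.get(tuple(sorted((a, b))), 0)
            if w:
                rec([x for x in remaining[1:] if x != b], total + w)

    rec(nodes, 0)
    return best


class TestHomeologPairing:
    def test_wgd_genome_pairs_into_halved_chromosome_count(self):
        cfg = SimConfig(
            n_chromosomes=13, genes_per_chromosome=40, codons_per_gene=60,
            schedule=[TimedEvent(15.14, "anc", "wgd", {"loss": 0.1})],
            seed=11, mode="ks_level",
        )
        genomes, truth = simulate.simulate_evolution(cfg)
        g = genomes["anc"]
        blocks = blocks_between(truth, g, g)
        groups = karyotype.pair_homeologs(blocks, g)
        assert len(groups.groups) == 13
        assert groups.unassigned == []

    def test_partial_linkage_leaves_unassigned(self):
        from conftest import make_genome

        g = make_genome("s", {"c1": 20, "c2": 20, "c3": 20})
        blocks = [_block("c1", "c2", range(6), range(6))]
        groups = karyotype.pair_homeologs(blocks, g)
        assert groups.groups == [("c1", "c2")]
        assert groups.unassigned == ["c3"]

    def test_no_interchromosomal_blocks_warns(self):
        from conftest import make_genome

        g = make_genome("s", {"c1": 10})
        with pytest.warns(UserWarning):
            groups = karyotype.pair_homeologs([], g)
        assert groups.groups == [] and groups.unassigned == ["c1"]

    def test_invariant_under_chromosome_order(self, one_wgd_fast):
        _, genome, truth = one_wgd_fast
        blocks = blocks_between(truth, genome, genome)
        from wgdlab.genome import Genome

        reordered = Genome(
            species=genome.species,
            chromosomes={c: genome.chromosomes[c] for c in reversed(list(genome.chromosomes))},
        )
        g1 = karyotype.pair_homeologs(blocks, genome)
        g2 = karyotype.pair_homeologs(blocks, reordered)
        assert g1.groups == g2.groups

    def test_greedy_matching_equals_exhaustive_on_small_genomes(self, one_wgd_fast):
        """<=8 chromosomes: greedy matching reaches the brute-force optimum."""
        _, genome, truth = one_wgd_fast
        blocks = blocks_between(truth, genome, genome)
        groups = karyotype.pair_homeologs(blocks, genome)
        greedy_weight = sum(groups.linkage_weights[g] for g in groups.groups)
        optimum = oracle_matching_weight(groups.linkage_weights, sorted(genome.chromosomes))
        assert greedy_weight == optimum


# ---------------------------------------------------------------------------
# retention


class TestRetention:
    def test_identical_species_blocks_count_full_chromosomes(self):
        genomes, truth = _speciation_sim()
        blocks = blocks_between(truth, genomes["desc"], genomes["ref"])
        table = karyotype.retention_table({"desc": blocks})
        assert sorted(table.counts["desc"]) == [40, 40, 40, 40]

    def test_rearranged_lineage_has_smaller_blocks(self):
        sched = [
            TimedEvent(60.0, "anc", "speciation", {"children": ["x", "ref"]}),
            TimedEvent(50.0, "x", "speciation", {"children": ["calm", "shuffled"]}),
            TimedEvent(30.0, "shuffled", "fission", {"chromosome": 0, "at_rank": 20}),
            TimedEvent(29.0, "shuffled", "fission", {"chromosome": 1, "at_rank": 20}),
            TimedEvent(28.0, "shuffled", "inversion", {"chromosome": 2, "start": 5, "end": 30}),
            TimedEvent(27.0, "shuffled", "fission", {"chromosome": 2, "at_rank": 15}),
        ]
        cfg = SimConfig(
            n_chromosomes=4, genes_per_chromosome=40, codons_per_gene=60,
            schedule=sched, seed=2, mode="ks_level",
        )
        genomes, truth = simulate.simulate_evolution(cfg)
        table = karyotype.retention_table({
            "calm": blocks_between(truth, genomes["calm"], genomes["ref"]),
            "shuffled": blocks_between(truth, genomes["shuffled"], genomes["ref"]),
        })
        assert np.mean(table.counts["calm"]) > np.mean(table.counts["shuffled"])

    def test_species_without_blocks_excluded_with_warning(self):
        genomes, truth = _speciation_sim()
        blocks = blocks_between(truth, genomes["desc"], genomes["ref"])
        with pytest.warns(UserWarning, match="no blocks"):
            table = karyotype.retention_table({"desc": blocks, "ghost": []})
        assert list(table.counts) == ["desc"]

    def test_anova_matches_hand_computation(self):
        """{10,11,12} vs {20,21,22}: SSB=150 (df 1), MSW=1 (df 4) -> F=150."""
        table = karyotype.RetentionTable({"a": [10, 11, 12], "b": [20, 21, 22]})
        f, p = karyotype.retention_anova(table)
        assert f == pytest.approx(150.0)
        assert p == pytest.approx(2.552167e-4, rel=1e-4)

    def test_identical_groups_give_f_zero(self):
        table = karyotype.RetentionTable({"a": [10, 11, 12], "b": [10, 11, 12]})
        f, p = karyotype.retention_anova(table)
        assert f == 0.0
        assert p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            karyotype.retention_anova(karyotype.RetentionTable({"a": [1, 2, 3]}))
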