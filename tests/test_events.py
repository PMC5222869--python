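import dataclasses

import numpy as np
import pytest

from asflow.errors import InvalidInputError
from asflow.events import (
    ReadIndex,
    build_exon_clusters,
    call_events,
    count_isoform_support,
    coverage_test,
    detect_events,
    enumerate_events,
    junction_test,
)
from asflow.genome import GenomeAnnotation
from asflow.junctions import (
    AlignedRead,
    Junction,
    JunctionObservation,
    JunctionTable,
)
from asflow.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_reads,
    to_aligned_reads,
    truth_table,
)
from asflow.stats import CombinationWeights
from conftest import make_gene
from oracles import events_from_transcript_pair, fisher_two_sided_bruteforce


def table_with(junction_counts, chrom="chr1"):
    """JunctionTable with given {(d, a): {group: nr}} synthetic NR support."""
    table = JunctionTable(anchor_pass=True, redundancy_pass=True)
    for (d, a), by_group in junction_counts.items():
        j = Junction(chrom, d, a)
        for group, nr in by_group.items():
            j.support[group] = [JunctionObservation(d - 20 - i, 20, 20) for i in range(nr)]
        table.junctions[(chrom, d, a)] = j
    return table


def event_shapes(gene, jtable=None, include_mxe=True):
    ann = GenomeAnnotation({gene.id: gene})
    (cluster,) = build_exon_clusters(ann, jtable or JunctionTable())
    events = enumerate_events(cluster, include_mxe=include_mxe)
    return {(e.type, e.alt_region) for e in events}, events


class TestBuildExonClusters:
    def test_single_transcript_identity(self, single_transcript_annotation):
        (cluster,) = build_exon_clusters(single_transcript_annotation, JunctionTable())
        assert cluster.exons == [(100, 250), (400, 550)]
        assert cluster.junctions == {(250, 400)}

    def test_cassette_cluster(self, cassette_gene):
        ann = GenomeAnnotation({cassette_gene.id: cassette_gene})
        (cluster,) = build_exon_clusters(ann, JunctionTable())
        assert cluster.exons == [(100, 300), (400, 600), (700, 900)]
        assert cluster.junctions == {(300, 400), (600, 700), (300, 700)}

    def test_observed_junction_splits_exon(self):
        # junction landing mid-exon on both sides splits it (reannotation)
        gene = make_gene("g", [[(0, 1000)]])
        table = table_with({(200, 800): {"CK": 5, "S": 5}})
        (cluster,) = build_exon_clusters(GenomeAnnotation({"g": gene}), table)
        assert cluster.exons == [(0, 200), (200, 800), (800, 1000)]
        assert (200, 800) in cluster.junctions

    def test_junction_outside_all_spans_skipped(self, single_transcript_annotation):
        table = table_with({(5000, 6000): {"CK": 5, "S": 5}})
        (cluster,) = build_exon_clusters(single_transcript_annotation, table)
        assert (5000, 6000) not in cluster.junctions


class TestEnumerateEvents:
    def test_cassette_yields_one_se(self, cassette_gene):
        shapes, events = event_shapes(cassette_gene)
        assert shapes == {("SE", (400, 600))}
        (e,) = events
        assert e.inclusion_junctions == frozenset({(300, 400), (600, 700)})
        assert e.exclusion_junctions == frozenset({(300, 700)})

    def test_shared_donor_pair_is_a3ss_on_plus(self):
        gene = make_gene("g", [[(0, 100), (200, 300)], [(0, 100), (230, 330)]])
        shapes, events = event_shapes(gene)
        assert shapes == {("A3SS", (200, 230))}
        (e,) = events
        assert e.inclusion_junctions == frozenset({(100, 200)})
        assert e.exclusion_junctions == frozenset({(100, 230)})

    def test_shared_donor_pair_is_a5ss_on_minus(self):
        gene = make_gene("g", [[(0, 100), (200, 300)], [(0, 100), (230, 330)]], strand="-")
        shapes, _ = event_shapes(gene)
        assert shapes == {("A5SS", (200, 230))}

    def test_shared_acceptor_pair_is_a5ss_on_plus(self):
        gene = make_gene("g", [[(0, 130), (200, 300)], [(0, 100), (200, 300)]])
        shapes, events = event_shapes(gene)
        assert shapes == {("A5SS", (100, 130))}
        (e,) = events
        assert e.inclusion_junctions == frozenset({(130, 200)})
        assert e.exclusion_junctions == frozenset({(100, 200)})

    def test_retained_intron(self):
        gene = make_gene("g", [[(0, 500)], [(0, 200), (300, 500)]])
        shapes, events = event_shapes(gene)
        assert shapes == {("RI", (200, 300))}
        (e,) = events
        assert e.inclusion_junctions == frozenset()
        assert e.exclusion_junctions == frozenset({(200, 300)})

    def test_mutually_exclusive_exons(self):
        gene = make_gene(
            "g",
            [
                [(0, 100), (200, 300), (600, 700)],
                [(0, 100), (400, 500), (600, 700)],
            ],
        )
        shapes, _ = event_shapes(gene)
        assert shapes == {("MXE", (200, 300))}

    def test_mxe_flag_off(self):
        gene = make_gene(
            "g",
            [
                [(0, 100), (200, 300), (600, 700)],
                [(0, 100), (400, 500), (600, 700)],
            ],
        )
        shapes, _ = event_shapes(gene, include_mxe=False)
        assert shapes == set()

    def test_single_transcript_no_events(self):
        gene = make_gene("g", [[(0, 100), (200, 300), (400, 500)]])
        shapes, _ = event_shapes(gene)
        assert shapes == set()

    def test_novel_observed_junction_creates_event(self):
        # exon-skipping junction seen only in the reads, not the annotation
        gene = make_gene("g", [[(0, 100), (200, 300), (400, 500)]])
        table = table_with({(100, 400): {"CK": 5, "S": 5}})
        ann = GenomeAnnotation({"g": gene})
        (cluster,) = build_exon_clusters(ann, table)
        events = enumerate_events(cluster)
        assert {(e.type, e.alt_region) for e in events} == {("SE", (200, 300))}


class TestCounting:
    def _se_event(self, cassette_gene, table):
        ann = GenomeAnnotation({cassette_gene.id: cassette_gene})
        (cluster,) = build_exon_clusters(ann, table)
        (event,) = enumerate_events(cluster)
        return event

    def test_se_summation_rule(self, cassette_gene):
        table = table_with(
            {
                (300, 400): {"CK": 10, "S": 2},
                (600, 700): {"CK": 10, "S": 2},
                (300, 700): {"CK": 5, "S": 9},
            }
        )
        event = self._se_event(cassette_gene, table)
        count_isoform_support(event, table, ReadIndex([]), cassette_gene)
        assert event.inclusion_counts == {"CK": 20, "S": 4}
        assert event.exclusion_counts == {"CK": 5, "S": 9}

    def test_missing_junction_counts_zero(self, cassette_gene):
        table = table_with({(300, 700): {"CK": 5, "S": 5}})
        event = self._se_event(cassette_gene, table)
        count_isoform_support(event, table, ReadIndex([]), cassette_gene)
        assert event.inclusion_counts == {"CK": 0, "S": 0}

    def test_group_without_reads_all_zero(self, cassette_gene):
        table = table_with(
            {
                (300, 400): {"CK": 4},
                (600, 700): {"CK": 4},
                (300, 700): {"CK": 4},
            }
        )
        event = self._se_event(cassette_gene, table)
        reads = [AlignedRead("r1", "chr1", ((150, 225),), "CK", 1)]
        count_isoform_support(event, table, ReadIndex(reads), cassette_gene)
        assert event.inclusion_counts["S"] == 0
        assert event.exclusion_counts["S"] == 0
        assert event.alt_coverage["S"] == 0 and event.gene_coverage["S"] == 0
        assert event.gene_coverage["CK"] == 1

    def test_ri_inclusion_requires_intron_overlap(self):
        gene = make_gene("g", [[(0, 500)], [(0, 200), (300, 500)]])
        ann = GenomeAnnotation({"g": gene})
        table = table_with({(200, 300): {"CK": 5, "S": 5}})
        (cluster,) = build_exon_clusters(ann, table)
        (event,) = enumerate_events(cluster)
        reads = [
            # spliced read: no intron overlap
            AlignedRead("r1", "chr1", ((150, 200), (300, 350)), "CK", 1),
            # 5 bases inside the intron: below the 7-base floor
            AlignedRead("r2", "chr1", ((130, 205),), "CK", 1),
            # deep inside the intron
            AlignedRead("r3", "chr1", ((180, 255),), "S", 1),
        ]
        count_isoform_support(event, table, ReadIndex(reads), gene, min_anchor=7)
        assert event.inclusion_counts == {"CK": 0, "S": 1}
        assert event.exclusion_counts == {"CK": 5, "S": 5}

    def test_alt_and_gene_coverage(self, cassette_gene):
        table = table_with({(300, 700): {"CK": 4, "S": 4}})
        event = self._se_event(cassette_gene, table)
        reads = [
            AlignedRead("r1", "chr1", ((450, 525),), "CK", 1),  # inside cassette
            AlignedRead("r2", "chr1", ((120, 195),), "CK", 1),  # upstream exon
            AlignedRead("r3", "chr1", ((1200, 1275),), "CK", 1),  # outside gene
        ]
        count_isoform_support(event, table, ReadIndex(reads), cassette_gene)
        assert event.alt_coverage["CK"] == 1
        assert event.gene_coverage["CK"] == 2


class TestEventTests:
    def _event_with_counts(self, incl, excl, alt=None, gene_cov=None):
        from asflow.events import ASEvent

        e = ASEvent(
            event_id="e",
            gene_id="g",
            type="SE",
            chrom="chr1",
            strand="+",
            alt_region=(0, 10),
            inclusion_junctions=frozenset(),
            exclusion_junctions=frozenset(),
        )
        e.inclusion_counts = dict(incl)
        e.exclusion_counts = dict(excl)
        e.alt_coverage = dict(alt or {"CK": 0, "S": 0})
        e.gene_coverage = dict(gene_cov or {"CK": 0, "S": 0})
        return e

    def test_junction_test_matches_oracle(self):
        e = self._event_with_counts({"CK": 20, "S": 5}, {"CK": 5, "S": 20})
        assert junction_test(e) == pytest.approx(
            fisher_two_sided_bruteforce(20, 5, 5, 20), abs=1e-12
        )

    def test_junction_test_equal_proportions(self):
        e = self._event_with_counts({"CK": 10, "S": 10}, {"CK": 10, "S": 10})
        assert junction_test(e) == 1.0

    def test_junction_test_no_evidence(self):
        e = self._event_with_counts({"CK": 0, "S": 0}, {"CK": 0, "S": 0})
        assert junction_test(e) == 1.0

    def test_coverage_test_matches_oracle(self):
        e = self._event_with_counts(
            {}, {}, alt={"CK": 30, "S": 10}, gene_cov={"CK": 100, "S": 100}
        )
        assert coverage_test(e) == pytest.approx(
            fisher_two_sided_bruteforce(30, 70, 10, 90), abs=1e-12
        )

    def test_coverage_test_proportional(self):
        e = self._event_with_counts(
            {}, {}, alt={"CK": 10, "S": 20}, gene_cov={"CK": 100, "S": 200}
        )
        assert coverage_test(e) == pytest.approx(
            fisher_two_sided_bruteforce(10, 90, 20, 180), abs=1e-12
        )

    def test_coverage_test_zero_gene_coverage(self):
        e = self._event_with_counts({}, {}, alt={"CK": 0, "S": 0}, gene_cov={"CK": 0, "S": 0})
        assert coverage_test(e) == 1.0

    def test_coverage_floor_at_zero(self):
        # a read overlapping the alt region but counted once for the gene can
        # push alt above gene coverage; the complement is floored at 0
        e = self._event_with_counts({}, {}, alt={"CK": 5, "S": 1}, gene_cov={"CK": 3, "S": 2})
        assert 0.0 <= coverage_test(e) <= 1.0

    def test_label_swap_symmetry(self):
        e1 = self._event_with_counts(
            {"CK": 20, "S": 5}, {"CK": 5, "S": 20},
            alt={"CK": 30, "S": 10}, gene_cov={"CK": 100, "S": 90},
        )
        e2 = self._event_with_counts(
            {"CK": 5, "S": 20}, {"CK": 20, "S": 5},
            alt={"CK": 10, "S": 30}, gene_cov={"CK": 90, "S": 100},
        )
        assert junction_test(e1) == pytest.approx(junction_test(e2), abs=1e-12)
        assert coverage_test(e1) == pytest.approx(coverage_test(e2), abs=1e-12)


class TestCallEvents:
    def _events(self, pvals):
        out = []
        for i, (p1, p2) in enumerate(pvals):
            e = TestEventTests()._event_with_counts({"CK": 0, "S": 0}, {"CK": 0, "S": 0})
            e.event_id = f"e{i}"
            e.p1, e.p2 = p1, p2
            out.append(e)
        return out

    def test_all_null_events_not_significant(self):
        result = call_events(self._events([(1.0, 1.0)] * 5))
        assert result.significant_events() == []

    def test_single_event_arithmetic(self):
        result = call_events(self._events([(0.02, 0.04)]))
        (e,) = result.events
        assert e.p_combined == pytest.approx(0.03)
        assert e.q == pytest.approx(0.03)
        assert e.significant

    def test_empty_collection(self):
        result = call_events([])
        assert result.events == []

    def test_sorted_by_q_then_id(self):
        result = call_events(self._events([(0.5, 0.5), (0.01, 0.01), (0.5, 0.5)]))
        assert [e.event_id for e in result.events] == ["e1", "e0", "e2"]

    def test_weights_respected(self):
        result = call_events(
            self._events([(0.1, 0.9)]), weights=CombinationWeights(1.0, 0.0)
        )
        assert result.events[0].p_combined == pytest.approx(0.1)

    def test_bad_threshold_rejected(self):
        with pytest.raises(InvalidInputError):
            call_events([], fdr_threshold=0.0)


class TestEnumerationOracle:
    """Detector enumeration vs direct transcript-pair structural comparison."""

    @pytest.mark.parametrize("seed", range(4))
    def test_random_two_transcript_genes(self, seed):
        from asflow.simulate import _gene_structure

        rng = np.random.default_rng(seed)
        for i in range(50):
            etype = ("SE", "A5SS", "A3SS", "RI", "MXE")[int(rng.integers(0, 5))]
            strand = "+" if rng.random() < 0.5 else "-"
            gene, _, _ = _gene_structure(
                f"g{i}", "chr1", strand, 100, etype, rng, 75
            )
            shapes, _ = event_shapes(gene)
            t1, t2 = gene.transcripts
            oracle = events_from_transcript_pair(
                [e.interval for e in t1.exons],
                [e.interval for e in t2.exons],
                strand,
            )
            assert shapes == oracle, f"{etype} gene, strand {strand}"


class TestDetectEvents:
    def test_full_pipeline_recovers_planted_shift(self):
        config = SimulationConfig(
            seed=5, n_genes=40, depth_per_condition=40_000,
            frac_de_genes=0.0, frac_as_genes=0.4, psi_ck=0.8, psi_s=0.2,
        )
        ann = simulate_annotation(config)
        truth = truth_table(config)
        reads = []
        for cond in ("CK", "S"):
            for rep in (1, 2):
                reads += to_aligned_reads(
                    simulate_reads(ann, truth, config, cond, rep), cond, rep
                )
        result, stats = detect_events(ann, reads)
        assert stats["clusters"] == 40
        planted = {(e.gene_id, e.event_type) for e in truth.events}
        called = {(e.gene_id, e.type) for e in result.significant_events()}
        # strong shift at high depth: most planted events must be recovered
        assert len(called & planted) >= 0.7 * len(planted)

    def test_label_swap_leaves_pvalues_unchanged(self):
        config = SimulationConfig(
            seed=9, n_genes=20, depth_per_condition=15_000, frac_as_genes=0.5,
            psi_ck=0.7, psi_s=0.3,
        )
        ann = simulate_annotation(config)
        truth = truth_table(config)
        reads, swapped = [], []
        for cond in ("CK", "S"):
            flip = {"CK": "S", "S": "CK"}[cond]
            for rep in (1, 2):
                sim = simulate_reads(ann, truth, config, cond, rep)
                reads += to_aligned_reads(sim, cond, rep)
                swapped += to_aligned_reads(sim, flip, rep)
        res_a, _ = detect_events(ann, reads)
        res_b, _ = detect_events(ann, swapped)
        pa = {e.event_id: (e.p1, e.p2, e.p_combined, e.q) for e in res_a.events}
        pb = {e.event_id: (e.p1, e.p2, e.p_combined, e.q) for e in res_b.events}
        assert pa.keys() == pb.keys()
        for key in pa:
            assert pa[key] == pytest.approx(pb[key], abs=1e-12)

    def test_to_dataframe_columns(self):
        result = call_events([])
        df = result.to_dataframe()
        assert list(df.columns)[:3] == ["event_id", "gene_id", "type"]
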