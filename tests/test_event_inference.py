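import itertools

import pytest

from spliceshift import (
    Intron,
    JunctionRecord,
    TranscriptModel,
    build_count_matrix,
    attach_counts,
    infer_annotation_events,
    infer_de_novo_alt_ends,
)


def _matrix(junction_counts, samples=("s1",)):
    """junction_counts: list of ((chrom,start,end,strand), {sample: count})."""
    records = []
    for key, per_sample in junction_counts:
        for sample, count in per_sample.items():
            records.append(
                JunctionRecord(Intron(*key), 1, 1, count, 0, 30, sample)
            )
    return build_count_matrix(records, list(samples))


class TestDeNovoAltEnds:
    def test_boundary_support_and_span(self):
        # two donors 1 nt apart sharing an acceptor, 5 total reads: passes both filters
        m = _matrix([(("c", 100, 200, "+"), {"s1": 3}), (("c", 101, 200, "+"), {"s1": 2})])
        assert len(infer_de_novo_alt_ends(m, "A5")) == 1

    def test_support_four_fails(self):
        m = _matrix([(("c", 100, 200, "+"), {"s1": 2}), (("c", 101, 200, "+"), {"s1": 2})])
        assert infer_de_novo_alt_ends(m, "A5") == []

    def test_span_fifty_passes_fifty_one_fails(self):
        at_50 = _matrix(
            [(("c", 100, 200, "+"), {"s1": 10}), (("c", 150, 200, "+"), {"s1": 10})]
        )
        at_51 = _matrix(
            [(("c", 100, 200, "+"), {"s1": 10}), (("c", 151, 200, "+"), {"s1": 10})]
        )
        assert len(infer_de_novo_alt_ends(at_50, "A5")) == 1
        assert infer_de_novo_alt_ends(at_51, "A5") == []

    def test_support_totals_across_samples_and_junctions(self):
        m = _matrix(
            [
                (("c", 100, 200, "+"), {"s1": 1, "s2": 2}),
                (("c", 101, 200, "+"), {"s1": 1, "s2": 1}),
            ],
            samples=("s1", "s2"),
        )
        assert len(infer_de_novo_alt_ends(m, "A5")) == 1

    def test_four_donors_yield_all_pairs(self):
        donors = [100, 110, 120, 130]
        m = _matrix([(("c", d, 300, "+"), {"s1": 20}) for d in donors])
        events = infer_de_novo_alt_ends(m, "A5")
        # brute-force oracle: every unordered pair within span and support
        expected = {
            frozenset({d1, d2})
            for d1, d2 in itertools.combinations(donors, 2)
            if abs(d1 - d2) <= 50 and 40 >= 5
        }
        got = {
            frozenset({next(iter(e.form1_junctions)).start,
                       next(iter(e.form2_junctions)).start})
            for e in events
        }
        assert got == expected and len(events) == 6

    def test_a3_groups_by_donor(self):
        m = _matrix([(("c", 100, 200, "+"), {"s1": 10}), (("c", 100, 210, "+"), {"s1": 10})])
        (event,) = infer_de_novo_alt_ends(m, "A3")
        assert event.event_type == "A3"
        assert event.shared_end == 100

    def test_minus_strand_a5_shares_genomic_start(self):
        m = _matrix([(("c", 100, 200, "-"), {"s1": 10}), (("c", 100, 210, "-"), {"s1": 10})])
        (event,) = infer_de_novo_alt_ends(m, "A5")
        assert event.shared_end == 100  # acceptor of a minus-strand intron

    def test_form1_is_higher_support(self):
        m = _matrix([(("c", 100, 200, "+"), {"s1": 3}), (("c", 101, 200, "+"), {"s1": 30})])
        (event,) = infer_de_novo_alt_ends(m, "A5")
        assert next(iter(event.form1_junctions)).start == 101

    def test_monotonicity_in_thresholds(self):
        rng_pairs = [
            (("c", 100 + i, 300, "+"), {"s1": 2 + i}) for i in range(5)
        ]
        m = _matrix(rng_pairs)
        loose = infer_de_novo_alt_ends(m, "A5", min_support=3, max_span=60)
        strict = infer_de_novo_alt_ends(m, "A5", min_support=8, max_span=2)
        loose_keys = {e.forms_key() for e in loose}
        assert {e.forms_key() for e in strict} <= loose_keys

    def test_commutes_with_chromosome_partition(self):
        m_all = _matrix(
            [
                (("c1", 100, 200, "+"), {"s1": 10}),
                (("c1", 105, 200, "+"), {"s1": 10}),
                (("c2", 100, 200, "+"), {"s1": 10}),
                (("c2", 103, 200, "+"), {"s1": 10}),
            ]
        )
        global_keys = {e.forms_key() for e in infer_de_novo_alt_ends(m_all, "A5")}
        per_chrom = set()
        for chrom in ("c1", "c2"):
            sub = _matrix(
                [
                    ((chrom, 100, 200, "+"), {"s1": 10}),
                    ((chrom, 105 if chrom == "c1" else 103, 200, "+"), {"s1": 10}),
                ]
            )
            per_chrom |= {e.forms_key() for e in infer_de_novo_alt_ends(sub, "A5")}
        assert global_keys == per_chrom

    def test_strand_undefined_junctions_skipped(self):
        m = _matrix([(("c", 100, 200, "."), {"s1": 10}), (("c", 101, 200, "."), {"s1": 10})])
        assert infer_de_novo_alt_ends(m, "A5") == []


def _t(tid, exons, gene="g", strand="+"):
    return TranscriptModel(tid, gene, "c", strand, exons)


class TestAnnotationEvents:
    def test_skipped_exon(self):
        t1 = _t("t1", [(1, 10), (21, 30), (41, 50)])
        t2 = _t("t2", [(1, 10), (41, 50)])
        (event,) = infer_annotation_events([t1, t2])
        assert event.event_type == "SE"
        assert {(i.start, i.end) for i in event.form1_junctions} == {(11, 20), (31, 40)}
        assert {(i.start, i.end) for i in event.form2_junctions} == {(11, 40)}

    def test_annotated_a5(self):
        t1 = _t("t1", [(1, 10), (21, 30)])
        t2 = _t("t2", [(1, 12), (21, 30)])
        (event,) = infer_annotation_events([t1, t2])
        assert event.event_type == "A5"

    def test_annotated_a3_minus_strand(self):
        # on the minus strand a differing genomic start is the acceptor side
        t1 = _t("t1", [(1, 10), (21, 30)], strand="-")
        t2 = _t("t2", [(1, 12), (21, 30)], strand="-")
        (event,) = infer_annotation_events([t1, t2])
        assert event.event_type == "A3"

    def test_alternative_first_exon(self):
        t1 = _t("t1", [(1, 10), (51, 100)])
        t2 = _t("t2", [(21, 30), (51, 100)])
        (event,) = infer_annotation_events([t1, t2])
        assert event.event_type == "AF"

    def test_alternative_last_exon(self):
        t1 = _t("t1", [(1, 50), (101, 110)])
        t2 = _t("t2", [(1, 50), (131, 140)])
        (event,) = infer_annotation_events([t1, t2])
        assert event.event_type == "AL"

    def test_retained_intron(self):
        t1 = _t("t1", [(1, 10), (21, 30)])
        t2 = _t("t2", [(1, 30)])
        (event,) = infer_annotation_events([t1, t2])
        assert event.event_type == "RI"
        assert event.form1_retention_intron == Intron("c", 11, 20, "+")

    def test_single_transcript_gene_emits_nothing(self):
        assert infer_annotation_events([_t("t1", [(1, 10), (21, 30)])]) == []

    def six_isoform_gene(self):
        # exon universe E1..E5 with one donor extension, one skip chain and
        # one retained intron; expected event set derived by hand from the
        # pairwise templates.
        t1 = _t("t1", [(1, 10), (21, 30), (41, 50), (61, 70), (81, 90)])
        t2 = _t("t2", [(1, 10), (41, 50), (61, 70), (81, 90)])  # skip E2
        t3 = _t("t3", [(1, 10), (61, 70), (81, 90)])  # skip E2+E3
        t4 = _t("t4", [(1, 10), (21, 30), (41, 50), (61, 72), (81, 90)])  # E4 donor +2
        t5 = _t("t5", [(1, 10), (21, 30), (61, 70), (81, 90)])  # skip E3
        t6 = _t("t6", [(1, 10), (21, 30), (41, 50), (61, 90)])  # retain last intron
        return [t1, t2, t3, t4, t5, t6]

    def test_six_isoform_gene_matches_hand_enumeration(self):
        events = infer_annotation_events(self.six_isoform_gene())
        by_type = {}
        for e in events:
            by_type[e.event_type] = by_type.get(e.event_type, 0) + 1
        assert by_type == {"SE": 4, "MS": 1, "MX": 1, "A5": 1, "RI": 2}

    def test_input_order_invariance(self):
        ts = self.six_isoform_gene()
        keys_fwd = {e.forms_key() for e in infer_annotation_events(ts)}
        keys_rev = {e.forms_key() for e in infer_annotation_events(ts[::-1])}
        assert keys_fwd == keys_rev


class TestAttachCounts:
    def test_a5_counts_attached(self):
        m = _matrix([(("c", 100, 200, "+"), {"s1": 10}), (("c", 101, 200, "+"), {"s1": 30})])
        (event,) = infer_de_novo_alt_ends(m, "A5")
        (q,) = attach_counts([event], m)
        assert q.form1_counts["s1"] == (30,)
        assert q.form2_counts["s1"] == (10,)

    def test_absent_junction_counts_zero(self):
        m = _matrix([(("c", 100, 200, "+"), {"s1": 10}), (("c", 101, 200, "+"), {"s1": 30})])
        (event,) = infer_de_novo_alt_ends(m, "A5")
        other = _matrix([(("c", 999, 1100, "+"), {"s1": 5})])
        (q,) = attach_counts([event], other)
        assert q.form1_counts["s1"] == (0,)

    def test_ri_without_retention_dropped(self):
        t1 = _t("t1", [(1, 10), (21, 30)])
        t2 = _t("t2", [(1, 30)])
        (event,) = infer_annotation_events([t1, t2])
        m = _matrix([(("c", 11, 20, "+"), {"s1": 10})])
        assert attach_counts([event], m, retention=None) == []
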