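"""Operon start/end point selection, linkage, and OP/NOP/POP/EGP labelling."""

import pytest

from condop.confirm import (
    AdjacentPair,
    ConfirmConfig,
    OspAnchor,
    adjacent_same_strand_pairs,
    confirm_operons,
    igr_feature_id,
    label_pairs,
    link_operon,
    select_oep,
    select_osp,
)
from condop.coverage import Breakpoint, ExpressionRecord
from condop.genome_io import Gene, ReferenceOperon

CDS_MIN, IGR_MIN = 1.0, 0.5


def bp(pos, kind, fc=10.0, strand="."):
    r = 0.95 if kind == "increase" else -0.95
    return Breakpoint(pos, kind, r, 1e-12, fc, strand)


def rec(fid, kind, log2):
    return ExpressionRecord(fid, kind, 2.0**log2 - 1, log2)


@pytest.fixture
def genes():
    return [
        Gene("gA", 1001, 1600, "+"),
        Gene("gB", 1651, 2250, "+"),
        Gene("gC", 2301, 2900, "+"),
        Gene("gD", 3500, 4000, "+"),
        Gene("gE", 5001, 5600, "-"),
        Gene("gF", 5701, 6300, "-"),
    ]


@pytest.fixture
def operons():
    # opB is '-' strand: transcription order is right-to-left
    return [
        ReferenceOperon("opA", ("gA", "gB", "gC")),
        ReferenceOperon("opB", ("gF", "gE")),
    ]


@pytest.fixture
def expression(genes):
    expr = {g.id: rec(g.id, "CDS", 5.0) for g in genes}
    for a, b in (("gA", "gB"), ("gB", "gC"), ("gC", "gD"), ("gE", "gF")):
        fid = igr_feature_id(a, b)
        expr[fid] = rec(fid, "IGR", 2.0)
    return expr


class TestSelectOsp:
    def test_anchor_upstream_of_expressed_operon_gene(self, genes, operons, expression):
        anchors = select_osp([bp(950, "increase")], expression, genes, operons, CDS_MIN)
        assert [(a.gene.id, a.operon.id) for a in anchors] == [("gA", "opA")]

    def test_low_fold_change_rejected(self, genes, operons, expression):
        assert select_osp([bp(950, "increase", fc=1.5)], expression, genes, operons, CDS_MIN) == []

    def test_gene_outside_reference_operons_rejected(self, genes, operons, expression):
        assert select_osp([bp(3450, "increase")], expression, genes, operons, CDS_MIN) == []

    def test_unexpressed_downstream_gene_rejected(self, genes, operons, expression):
        expr = dict(expression)
        expr["gA"] = rec("gA", "CDS", 0.2)
        assert select_osp([bp(950, "increase")], expr, genes, operons, CDS_MIN) == []

    def test_gap_beyond_max_utr_rejected(self, genes, operons, expression):
        assert select_osp([bp(600, "increase")], expression, genes, operons, CDS_MIN) == []
        cfg = ConfirmConfig(max_utr=500)
        assert len(select_osp([bp(600, "increase")], expression, genes, operons, CDS_MIN, cfg)) == 1

    def test_minus_strand_start_is_a_genomic_decrease(self, genes, operons, expression):
        anchors = select_osp([bp(6350, "decrease")], expression, genes, operons, CDS_MIN)
        assert [(a.gene.id, a.operon.id) for a in anchors] == [("gF", "opB")]

    def test_first_gene_only_mode(self, genes, operons, expression):
        cfg = ConfirmConfig(first_gene_only=True)
        internal = select_osp([bp(1630, "increase")], expression, genes, operons, CDS_MIN, cfg)
        assert internal == []  # gB anchor suppressed
        head = select_osp([bp(950, "increase")], expression, genes, operons, CDS_MIN, cfg)
        assert len(head) == 1


class TestSelectOep:
    def test_decrease_after_last_expressed_gene(self, genes, operons, expression):
        anchors = select_oep([bp(2950, "decrease")], expression, genes, operons, CDS_MIN)
        assert [(a.gene.id, a.operon.id) for a in anchors] == [("gC", "opA")]

    def test_increase_is_never_an_oep_for_plus_strand(self, genes, operons, expression):
        anchors = select_oep([bp(2950, "increase")], expression, genes, operons, CDS_MIN)
        assert all(a.gene.strand == "-" for a in anchors)

    def test_low_fold_change_rejected(self, genes, operons, expression):
        assert select_oep([bp(2950, "decrease", fc=1.2)], expression, genes, operons, CDS_MIN) == []


class TestLinkage:
    def anchor(self, genes, operons, which="gA"):
        by_id = {g.id: g for g in genes}
        op = operons[0] if which in operons[0].gene_ids else operons[1]
        pos = 950 if which == "gA" else 6350
        kind = "increase" if which == "gA" else "decrease"
        return OspAnchor(bp(pos, kind), by_id[which], op)

    def test_full_operon_linked(self, genes, operons, expression):
        conf = link_operon(self.anchor(genes, operons), expression, [], CDS_MIN, IGR_MIN, genes=genes)
        assert conf.gene_ids == ("gA", "gB", "gC")
        assert conf.osp_position == 950

    def test_silent_igr_stops_linkage(self, genes, operons, expression):
        expr = dict(expression)
        fid = igr_feature_id("gB", "gC")
        expr[fid] = rec(fid, "IGR", 0.1)
        conf = link_operon(self.anchor(genes, operons), expr, [], CDS_MIN, IGR_MIN, genes=genes)
        assert conf.gene_ids == ("gA", "gB")

    def test_unexpressed_second_gene_yields_none(self, genes, operons, expression):
        expr = dict(expression)
        expr["gB"] = rec("gB", "CDS", 0.0)
        conf = link_operon(self.anchor(genes, operons), expr, [], CDS_MIN, IGR_MIN, genes=genes)
        assert conf is None

    def test_breakpoint_in_igr_stops_linkage(self, genes, operons, expression):
        inside = [bp(2270, "decrease")]  # IGR gB|gC spans 2251..2300
        conf = link_operon(self.anchor(genes, operons), expression, inside, CDS_MIN, IGR_MIN, genes=genes)
        assert conf.gene_ids == ("gA", "gB")

    def test_minus_strand_linkage(self, genes, operons, expression):
        conf = link_operon(self.anchor(genes, operons, "gF"), expression, [], CDS_MIN, IGR_MIN, genes=genes)
        assert conf.gene_ids == ("gF", "gE")

    def test_confirm_operons_keeps_longest_per_reference(self, genes, operons, expression):
        anchors = [self.anchor(genes, operons), OspAnchor(bp(1630, "increase"),
                   {g.id: g for g in genes}["gB"], operons[0])]
        confirmed = confirm_operons(anchors, expression, [], CDS_MIN, IGR_MIN, genes)
        assert [c.gene_ids for c in confirmed] == [("gA", "gB", "gC")]


class TestLabelPairs:
    def run(self, genes, operons, expression, breakpoints, confirmed):
        return {
            (p.upstream_gene, p.downstream_gene): p.label
            for p in label_pairs(genes, confirmed, operons, breakpoints, expression, CDS_MIN)
        }

    def test_confirmed_junctions_are_op(self, genes, operons, expression):
        conf = link_operon(
            TestLinkage().anchor(genes, operons), expression, [], CDS_MIN, IGR_MIN, genes=genes
        )
        labels = self.run(genes, operons, expression, [], [conf])
        assert labels[("gA", "gB")] == "OP" and labels[("gB", "gC")] == "OP"

    def test_breakpoint_in_igr_makes_nop(self, genes, operons, expression):
        labels = self.run(genes, operons, expression, [bp(3100, "decrease")], [])
        assert labels[("gC", "gD")] == "NOP"

    def test_nop_does_not_require_expression(self, genes, operons, expression):
        expr = dict(expression)
        expr["gC"] = rec("gC", "CDS", 0.0)
        expr["gD"] = rec("gD", "CDS", 0.0)
        labels = self.run(genes, operons, expr, [bp(3100, "decrease")], [])
        assert labels[("gC", "gD")] == "NOP"

    def test_expressed_non_cooperonic_pair_is_pop(self, genes, operons, expression):
        labels = self.run(genes, operons, expression, [], [])
        assert labels[("gC", "gD")] == "POP"

    def test_expressed_cooperonic_unconfirmed_pair_is_egp(self, genes, operons, expression):
        labels = self.run(genes, operons, expression, [], [])
        assert labels[("gA", "gB")] == "EGP"
        assert labels[("gF", "gE")] == "EGP"

    def test_unexpressed_pair_unlabeled(self, genes, operons, expression):
        expr = dict(expression)
        expr["gD"] = rec("gD", "CDS", 0.0)
        labels = self.run(genes, operons, expr, [], [])
        assert labels[("gC", "gD")] == "unlabeled"

    def test_deleting_breakpoints_removes_all_nops(self, genes, operons, expression):
        with_bp = self.run(genes, operons, expression, [bp(3100, "decrease")], [])
        without = self.run(genes, operons, expression, [], [])
        assert "NOP" in with_bp.values() and "NOP" not in without.values()

    def test_labels_partition_the_pairs(self, genes, operons, expression):
        labels = self.run(genes, operons, expression, [bp(3100, "decrease")], [])
        assert set(labels.values()) <= {"OP", "NOP", "POP", "EGP", "unlabeled"}
        assert len(labels) == len(adjacent_same_strand_pairs(genes))


class TestAdjacentPairs:
    def test_opposite_strand_neighbours_are_not_paired(self, genes):
        pairs = adjacent_same_strand_pairs(genes)
        ids = {(p.upstream_gene, p.downstream_gene) for p in pairs}
        assert ("gD", "gE") not in ids and ("gE", "gD") not in ids

    def test_minus_pair_upstream_is_rightmost(self, genes):
        pairs = adjacent_same_strand_pairs(genes)
        minus = [p for p in pairs if p.strand == "-"]
        assert [(p.upstream_gene, p.downstream_gene) for p in minus] == [("gF", "gE")]
        assert (minus[0].igr_start, minus[0].igr_end) == (5601, 5700)
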