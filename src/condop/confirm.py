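"""Operon confirmation: OSP/OEP selection, linkage, and pair labelling.

Terminology (transcription order, strand-aware):

* OSP — operon start point: an increase-type breakpoint (on the genomic axis
  a coverage *decrease* plays this role for '-' strand genes) anchored just
  upstream of a structural gene of a reference operon.
* OEP — operon end point: the mirror image at the 3' side.
* The linkage process walks a reference operon downstream from the anchored
  gene, appending the next structural gene while the intergenic region is
  expressed, the next gene is expressed, and no breakpoint falls inside the
  intergenic region.  A confirmed operon needs >= 2 linked genes.

Adjacent same-strand gene pairs are then labelled:

* OP  — consecutive members of a confirmed operon (co-transcribed here);
* NOP — a transcription start/end point lies inside the pair's IGR
  (expression of the two genes is not required);
* POP — both genes expressed, pair not co-operonic in the reference
  (candidate novel operon or extension);
* EGP — both genes expressed and reference-co-operonic, but not linked to a
  detected operon start under the measured condition;
* unlabeled otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from condop.coverage import Breakpoint, ExpressionRecord
from condop.genome_io import Gene, ReferenceOperon

logger = logging.getLogger(__name__)

__all__ = [
    "ConfirmConfig",
    "AdjacentPair",
    "ConfirmedOperon",
    "OspAnchor",
    "adjacent_same_strand_pairs",
    "select_osp",
    "select_oep",
    "link_operon",
    "confirm_operons",
    "label_pairs",
    "igr_feature_id",
    "igr_intervals",
]


@dataclass
class ConfirmConfig:
    """Parameters of the confirmation stage.

    max_utr bounds the gap between a breakpoint and the anchored gene ("enough
    space for the 5'UTR"); anchoring may use any structural gene of the
    reference operon (condition-dependent internal starts) unless
    ``first_gene_only`` is set.
    """

    max_utr: int = 300
    fold_change_min: float = 2.0
    first_gene_only: bool = False


@dataclass
class AdjacentPair:
    """Two chromosomally consecutive genes on the same strand.

    ``upstream_gene``/``downstream_gene`` are in transcription order; the IGR
    coordinates are genomic (igr_start > igr_end means the genes abut or
    overlap, i.e. no intergenic region exists).
    """

    upstream_gene: str
    downstream_gene: str
    strand: str
    igr_start: int
    igr_end: int
    label: str = "unlabeled"

    @property
    def pair_id(self) -> str:
        return f"{self.upstream_gene}|{self.downstream_gene}"

    @property
    def has_igr(self) -> bool:
        return self.igr_end >= self.igr_start


@dataclass(frozen=True)
class OspAnchor:
    breakpoint: Breakpoint
    gene: Gene
    operon: ReferenceOperon


@dataclass(frozen=True)
class ConfirmedOperon:
    """A reference operon (suffix, in transcription order) confirmed by the
    measured coverage profile."""

    reference_operon_id: str
    gene_ids: tuple[str, ...]
    osp_position: int
    linked_through: tuple[str, ...] = ()

    def junctions(self) -> list[tuple[str, str]]:
        return list(zip(self.gene_ids[:-1], self.gene_ids[1:]))


def igr_feature_id(left_gene_id: str, right_gene_id: str) -> str:
    """Expression-record id for the IGR between two genes (genomic order)."""
    return f"IGR:{left_gene_id}|{right_gene_id}"


def adjacent_same_strand_pairs(genes: Sequence[Gene]) -> list[AdjacentPair]:
    """All chromosomally consecutive same-strand gene pairs (genomic sort)."""
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    pairs: list[AdjacentPair] = []
    for left, right in zip(ordered[:-1], ordered[1:]):
        if left.strand != right.strand:
            continue
        igr_start, igr_end = left.end + 1, right.start - 1
        if left.strand == "+":
            up, down = left, right
        else:
            up, down = right, left
        pairs.append(
            AdjacentPair(up.id, down.id, left.strand, igr_start, igr_end)
        )
    return pairs


def igr_intervals(genes: Sequence[Gene]) -> list[tuple[str, str, int, int]]:
    """(id, 'IGR', start, end) for every positive-length same-strand IGR."""
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    out = []
    for left, right in zip(ordered[:-1], ordered[1:]):
        if left.strand == right.strand and right.start - left.end > 1:
            out.append(
                (igr_feature_id(left.id, right.id), "IGR", left.end + 1, right.start - 1)
            )
    return out


def _membership(reference_operons: Sequence[ReferenceOperon]) -> dict[str, ReferenceOperon]:
    member_of: dict[str, ReferenceOperon] = {}
    for op in reference_operons:
        for gid in op.gene_ids:
            member_of[gid] = op
    return member_of


def _strand_matches(bp: Breakpoint, strand: str) -> bool:
    return bp.strand == "." or bp.strand == strand


def _nearest_start_gene(
    bp: Breakpoint, genes: Sequence[Gene], strand: str, max_utr: int
) -> Gene | None:
    """Nearest gene whose transcription 5' end lies just downstream of the
    breakpoint, within [0, max_utr]."""
    best: Gene | None = None
    best_gap = max_utr + 1
    for g in genes:
        if g.strand != strand:
            continue
        if strand == "+":
            gap = g.start - bp.position
        else:
            gap = bp.position - 1 - g.end
        if 0 <= gap < best_gap:
            best, best_gap = g, gap
    return best


def _nearest_end_gene(
    bp: Breakpoint, genes: Sequence[Gene], strand: str, max_utr: int
) -> Gene | None:
    """Nearest gene whose transcription 3' end lies just upstream of the
    breakpoint, within [0, max_utr]."""
    best: Gene | None = None
    best_gap = max_utr + 1
    for g in genes:
        if g.strand != strand:
            continue
        if strand == "+":
            gap = bp.position - 1 - g.end
        else:
            gap = g.start - bp.position
        if 0 <= gap < best_gap:
            best, best_gap = g, gap
    return best


def select_osp(
    breakpoints: Sequence[Breakpoint],
    expression: Mapping[str, ExpressionRecord],
    genes: Sequence[Gene],
    reference_operons: Sequence[ReferenceOperon],
    cds_min: float,
    cfg: ConfirmConfig | None = None,
) -> list[OspAnchor]:
    """Operon start points: breakpoints that anchor a reference operon.

    A breakpoint qualifies iff (i) its coverage fold change exceeds
    ``fold_change_min``; (ii) the nearest downstream gene (transcription
    order) is expressed above the CDS threshold; (iii) that gene is a
    structural gene of a reference operon; (iv) the breakpoint-to-gene gap
    leaves room for a 5'UTR of at most ``max_utr`` nt.
    """
    cfg = cfg or ConfirmConfig()
    member_of = _membership(reference_operons)
    anchors: list[OspAnchor] = []
    for bp in breakpoints:
        if bp.fold_change <= cfg.fold_change_min:
            continue
        # a genomic increase is TSP-like for '+' genes; a genomic decrease is
        # TSP-like for '-' genes (transcription runs right-to-left there)
        for strand in ("+", "-"):
            tsp_like = (bp.kind == "increase") == (strand == "+")
            if not tsp_like or not _strand_matches(bp, strand):
                continue
            gene = _nearest_start_gene(bp, genes, strand, cfg.max_utr)
            if gene is None:
                continue
            rec = expression.get(gene.id)
            if rec is None or rec.log2_rpkm <= cds_min:
                continue
            operon = member_of.get(gene.id)
            if operon is None:
                continue
            if cfg.first_gene_only and operon.gene_ids[0] != gene.id:
                continue
            anchors.append(OspAnchor(bp, gene, operon))
    return anchors


def select_oep(
    breakpoints: Sequence[Breakpoint],
    expression: Mapping[str, ExpressionRecord],
    genes: Sequence[Gene],
    reference_operons: Sequence[ReferenceOperon],
    cds_min: float,
    cfg: ConfirmConfig | None = None,
) -> list[OspAnchor]:
    """Operon end points: the 3'-side mirror image of :func:`select_osp`."""
    cfg = cfg or ConfirmConfig()
    member_of = _membership(reference_operons)
    anchors: list[OspAnchor] = []
    for bp in breakpoints:
        if bp.fold_change <= cfg.fold_change_min:
            continue
        for strand in ("+", "-"):
            tep_like = (bp.kind == "decrease") == (strand == "+")
            if not tep_like or not _strand_matches(bp, strand):
                continue
            gene = _nearest_end_gene(bp, genes, strand, cfg.max_utr)
            if gene is None:
                continue
            rec = expression.get(gene.id)
            if rec is None or rec.log2_rpkm <= cds_min:
                continue
            operon = member_of.get(gene.id)
            if operon is None:
                continue
            anchors.append(OspAnchor(bp, gene, operon))
    return anchors


def _junction_igr(prev: Gene, nxt: Gene) -> tuple[int, int]:
    """Genomic IGR coordinates between two transcription-consecutive genes."""
    if prev.strand == "+":
        return prev.end + 1, nxt.start - 1
    return nxt.end + 1, prev.start - 1


def link_operon(
    anchor: OspAnchor,
    expression: Mapping[str, ExpressionRecord],
    breakpoints: Sequence[Breakpoint],
    cds_min: float,
    igr_min: float,
    genes_by_id: Mapping[str, Gene] | None = None,
    genes: Sequence[Gene] | None = None,
) -> ConfirmedOperon | None:
    """Link structural genes downstream of an operon start point.

    Starting from the anchored gene, the next gene of the reference operon
    (transcription order) is appended while (1) the intergenic region is
    expressed above the IGR threshold, (2) the next gene is expressed above
    the CDS threshold, and (3) no breakpoint falls inside the intergenic
    region.  Junctions with no IGR (abutting/overlapping genes) satisfy
    rules 1 and 3 vacuously.  No end point is required after the last linked
    gene.  Returns None when fewer than 2 genes link.
    """
    if genes_by_id is None:
        if genes is None:
            raise ValueError("need genes_by_id or genes")
        genes_by_id = {g.id: g for g in genes}
    op = anchor.operon
    start_idx = op.gene_ids.index(anchor.gene.id)
    linked = [op.gene_ids[start_idx]]
    evidence: list[str] = []
    strand = anchor.gene.strand
    bps = [b for b in breakpoints if _strand_matches(b, strand)]
    for gid in op.gene_ids[start_idx + 1 :]:
        prev = genes_by_id[linked[-1]]
        nxt = genes_by_id[gid]
        igr_start, igr_end = _junction_igr(prev, nxt)
        if igr_end >= igr_start:
            lo = prev.id if strand == "+" else nxt.id
            hi = nxt.id if strand == "+" else prev.id
            rec = expression.get(igr_feature_id(lo, hi))
            if rec is None or rec.log2_rpkm <= igr_min:
                break
            if any(igr_start <= b.position <= igr_end for b in bps):
                break
            igr_note = f"igr_log2={rec.log2_rpkm:.3f}"
        else:
            igr_note = "no-igr"
        nxt_rec = expression.get(gid)
        if nxt_rec is None or nxt_rec.log2_rpkm <= cds_min:
            break
        linked.append(gid)
        evidence.append(f"{prev.id}->{gid}:{igr_note}")
    if len(linked) < 2:
        return None
    return ConfirmedOperon(op.id, tuple(linked), anchor.breakpoint.position, tuple(evidence))


def confirm_operons(
    anchors: Sequence[OspAnchor],
    expression: Mapping[str, ExpressionRecord],
    breakpoints: Sequence[Breakpoint],
    cds_min: float,
    igr_min: float,
    genes: Sequence[Gene],
) -> list[ConfirmedOperon]:
    """Run linkage from every anchor; keep the longest confirmation per
    reference operon (earliest anchored gene on ties)."""
    genes_by_id = {g.id: g for g in genes}
    best: dict[str, ConfirmedOperon] = {}
    for anchor in anchors:
        conf = link_operon(
            anchor, expression, breakpoints, cds_min, igr_min, genes_by_id=genes_by_id
        )
        if conf is None:
            continue
        cur = best.get(conf.reference_operon_id)
        if cur is None or len(conf.gene_ids) > len(cur.gene_ids):
            best[conf.reference_operon_id] = conf
    return sorted(best.values(), key=lambda c: c.osp_position)


def label_pairs(
    genes: Sequence[Gene],
    confirmed: Sequence[ConfirmedOperon],
    reference_operons: Sequence[ReferenceOperon],
    breakpoints: Sequence[Breakpoint],
    expression: Mapping[str, ExpressionRecord],
    cds_min: float,
) -> list[AdjacentPair]:
    """Assign OP/NOP/POP/EGP/unlabeled to every adjacent same-strand pair."""
    pairs = adjacent_same_strand_pairs(genes)
    op_junctions = {j for c in confirmed for j in c.junctions()}
    ref_junctions = {
        j for op in reference_operons for j in zip(op.gene_ids[:-1], op.gene_ids[1:])
    }

    def expressed(gid: str) -> bool:
        rec = expression.get(gid)
        return rec is not None and rec.log2_rpkm > cds_min

    for pair in pairs:
        key = (pair.upstream_gene, pair.downstream_gene)
        bp_in_igr = pair.has_igr and any(
            pair.igr_start <= b.position <= pair.igr_end
            for b in breakpoints
            if _strand_matches(b, pair.strand)
        )
        if key in op_junctions:
            if bp_in_igr:
                logger.warning(
                    "pair %s is a confirmed OP junction but contains a breakpoint; "
                    "keeping OP",
                    pair.pair_id,
                )
            pair.label = "OP"
        elif bp_in_igr:
            pair.label = "NOP"
        elif expressed(pair.upstream_gene) and expressed(pair.downstream_gene):
            pair.label = "EGP" if key in ref_junctions else "POP"
        else:
            pair.label = "unlabeled"
    return pairs


def write_confirmed(confirmed: Sequence[ConfirmedOperon], path) -> None:
    with open(path, "w") as fh:
        fh.write("# reference_operon_id\tgene_ids\tosp_position\n")
        for c in confirmed:
            fh.write(f"{c.reference_operon_id}\t{','.join(c.gene_ids)}\t{c.osp_position}\n")


def read_confirmed(path) -> list[ConfirmedOperon]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            op_id, gene_field, pos = line.rstrip("\n").split("\t")
            out.append(ConfirmedOperon(op_id, tuple(gene_field.split(",")), int(pos)))
    return out


def read_pairs(path) -> list[AdjacentPair]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            up, down, strand, label, s, e = line.rstrip("\n").split("\t")
            out.append(AdjacentPair(up, down, strand, int(s), int(e), label))
    return out


def write_pairs(pairs: Sequence[AdjacentPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("# upstream_gene\tdownstream_gene\tstrand\tlabel\tigr_start\tigr_end\n")
        for p in pairs:
            fh.write(
                f"{p.upstream_gene}\t{p.downstream_gene}\t{p.strand}\t{p.label}\t"
                f"{p.igr_start}\t{p.igr_end}\n"
            )
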