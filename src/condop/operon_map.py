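"""Assemble the condition-dependent operon map and check control signals.

Adjacent gene pairs that ended up OP — either confirmed by the linkage
process or voted OP by the classifier ensemble — are chained into maximal
operon calls.  Intergenic regions of the called junctions are then screened
for predicted promoter/terminator intervals: genes co-transcribed under the
measured condition should have none, so a signal-free junction adds
confidence.  Flagged junctions are reported but not removed.  Flanking
regions of an operon are deliberately not screened (the call may be part of
a larger unit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from condop.confirm import AdjacentPair, ConfirmedOperon
from condop.genome_io import Gene, SignalInterval

__all__ = ["OperonCall", "assemble_map", "check_signals", "summarize_map"]


@dataclass
class OperonCall:
    """A maximal chain of OP junctions (gene ids in transcription order)."""

    gene_ids: tuple[str, ...]
    strand: str
    status: str  # confirmed | putative | mixed
    source_pairs: tuple[tuple[str, str], ...]  # (pair_id, provenance)
    signal_clean: tuple[bool, ...] = ()  # per junction, set by check_signals

    @property
    def call_id(self) -> str:
        return f"{self.gene_ids[0]}..{self.gene_ids[-1]}"

    def junctions(self) -> list[tuple[str, str]]:
        return list(zip(self.gene_ids[:-1], self.gene_ids[1:]))


def assemble_map(
    pairs: Sequence[AdjacentPair],
    confirmed: Sequence[ConfirmedOperon],
    votes: Mapping[str, str] | None = None,
) -> list[OperonCall]:
    """Chain OP junctions into maximal operon calls.

    A junction is an OP junction when its pair label is OP (provenance
    ``confirmed-OP``) or when the voting scheme classified it OP (provenance
    ``voted-OP``; ``votes`` maps pair_id -> final class for POP/EGP pairs).
    Output is independent of the input pair order.
    """
    votes = votes or {}
    confirmed_junctions = {j for c in confirmed for j in c.junctions()}
    op_pairs: dict[tuple[str, str], tuple[AdjacentPair, str]] = {}
    for p in pairs:
        key = (p.upstream_gene, p.downstream_gene)
        if p.label == "OP" or key in confirmed_junctions:
            op_pairs[key] = (p, "confirmed-OP")
        elif votes.get(p.pair_id) == "OP":
            op_pairs[key] = (p, "voted-OP")

    # chain junctions that share a gene: successor of junction (a, b) is (b, c)
    by_upstream = {k[0]: k for k in op_pairs}
    has_predecessor = {k[1] for k in op_pairs}
    calls: list[OperonCall] = []
    for key in sorted(op_pairs, key=lambda k: op_pairs[k][0].pair_id):
        if key[0] in has_predecessor:
            continue  # not a chain head
        chain = [key]
        while chain[-1][1] in by_upstream:
            chain.append(by_upstream[chain[-1][1]])
        genes = [chain[0][0]] + [j[1] for j in chain]
        provs = [op_pairs[j][1] for j in chain]
        if all(p == "confirmed-OP" for p in provs):
            status = "confirmed"
        elif all(p == "voted-OP" for p in provs):
            status = "putative"
        else:
            status = "mixed"
        calls.append(
            OperonCall(
                gene_ids=tuple(genes),
                strand=op_pairs[chain[0]][0].strand,
                status=status,
                source_pairs=tuple(
                    (op_pairs[j][0].pair_id, op_pairs[j][1]) for j in chain
                ),
            )
        )
    calls.sort(key=lambda c: c.call_id)
    return calls


def check_signals(
    calls: Sequence[OperonCall],
    signals: Sequence[SignalInterval],
    genes: Sequence[Gene],
) -> tuple[list[OperonCall], dict[str, float]]:
    """Flag junctions whose IGR overlaps a predicted promoter/terminator.

    A stranded signal must match the operon strand; unstranded signals match
    both.  Any overlap of >= 1 bp flags the junction.  Returns the annotated
    calls and, per signal source tag (plus ``"any"``), the percentage of
    junctions with no signal.
    """
    genes_by_id = {g.id: g for g in genes}
    sources = sorted({s.source or s.kind for s in signals})

    def junction_hits(call: OperonCall, up_id: str, down_id: str) -> set[str]:
        up, down = genes_by_id[up_id], genes_by_id[down_id]
        lo = min(up.end, down.end) + 1
        hi = max(up.start, down.start) - 1
        if hi < lo:  # abutting/overlapping genes: no IGR to screen
            return set()
        return {
            s.source or s.kind
            for s in signals
            if s.strand in (".", call.strand) and s.start <= hi and s.end >= lo
        }

    annotated: list[OperonCall] = []
    clean_by_source = {src: 0 for src in sources}
    clean_any = 0
    n_junctions = 0
    for call in calls:
        flags: list[bool] = []
        for up_id, down_id in call.junctions():
            hits = junction_hits(call, up_id, down_id)
            n_junctions += 1
            flags.append(not hits)
            clean_any += not hits
            for src in sources:
                clean_by_source[src] += src not in hits
        annotated.append(
            OperonCall(
                call.gene_ids, call.strand, call.status, call.source_pairs,
                tuple(flags),
            )
        )
    denom = n_junctions if n_junctions else 1
    summary = {src: 100.0 * clean_by_source[src] / denom for src in sources}
    summary["any"] = 100.0 * clean_any / denom if n_junctions else 100.0
    return annotated, summary


def summarize_map(
    calls: Sequence[OperonCall], pairs: Sequence[AdjacentPair]
) -> dict[str, float]:
    """Map summary: confirmed / putative OP junction counts, number of operon
    calls, and percentages over all same-strand adjacent pairs."""
    confirmed = sum(
        1 for c in calls for _, prov in c.source_pairs if prov == "confirmed-OP"
    )
    putative = sum(
        1 for c in calls for _, prov in c.source_pairs if prov == "voted-OP"
    )
    n_pairs = len(pairs)
    pct = (lambda x: 100.0 * x / n_pairs) if n_pairs else (lambda x: 0.0)
    return {
        "confirmed_junctions": confirmed,
        "putative_junctions": putative,
        "total_junctions": confirmed + putative,
        "n_operon_calls": len(calls),
        "confirmed_pct": pct(confirmed),
        "putative_pct": pct(putative),
        "total_pct": pct(confirmed + putative),
    }


def write_map(calls: Sequence[OperonCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("# operon_id\tgene_ids\tstrand\tstatus\tjunction_provenance\tsignal_clean\n")
        for c in calls:
            prov = ",".join(p for _, p in c.source_pairs)
            clean = ",".join("1" if f else "0" for f in c.signal_clean) or "NA"
            fh.write(
                f"{c.call_id}\t{','.join(c.gene_ids)}\t{c.strand}\t{c.status}\t"
                f"{prov}\t{clean}\n"
            )
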