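"""Readers and writers for the external formats the pipeline touches.

Internal coordinate convention: 1-based, inclusive on both ends (the GFF3 /
pileup convention).  BED input/output is converted on the fly.  Only
single-replicon genomes are accepted: the sequence-name column is checked for
consistency and multi-chromosome input is rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from gffutils.iterators import DataIterator

logger = logging.getLogger(__name__)


class GenomeIOError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """An annotated CDS with 1-based inclusive coordinates."""

    id: str
    start: int
    end: int
    strand: str
    cds_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"gene {self.id}: end < start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.cds_sequence is not None:
            if len(self.cds_sequence) != self.length:
                raise ValueError(
                    f"gene {self.id}: CDS length {len(self.cds_sequence)} != "
                    f"span {self.length}"
                )
            if self.length % 3 != 0:
                raise ValueError(f"gene {self.id}: CDS length not divisible by 3")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_sequence(self, seq: str) -> "Gene":
        return Gene(self.id, self.start, self.end, self.strand, seq)


@dataclass(frozen=True)
class ReferenceOperon:
    """A reference (static) operon: >= 2 same-strand consecutive genes.

    ``gene_ids`` is stored in transcription order (for '-' strand operons this
    is descending genomic order).
    """

    id: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError(f"operon {self.id}: needs >= 2 genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"operon {self.id}: duplicate gene ids")


@dataclass(frozen=True)
class SignalInterval:
    """A predicted promoter or terminator (internal 1-based inclusive)."""

    kind: str  # promoter | terminator
    start: int
    end: int
    strand: str = "."  # '+', '-', or '.' for unstranded
    source: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("signal interval: end < start")
        if self.kind not in ("promoter", "terminator"):
            raise ValueError(f"signal kind must be promoter/terminator, got {self.kind!r}")


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

_GENE_FEATURE_TYPES = ("CDS", "gene")


def read_annotation(path: str | Path) -> list[Gene]:
    """Read gene/CDS features from a GFF3 file, sorted by genomic start.

    Features of type ``gene`` or ``CDS`` are accepted; each must carry a
    unique ``ID`` (or ``locus_tag``) attribute and an explicit strand.
    """
    path = Path(path)
    genes: list[Gene] = []
    seen: set[str] = set()
    seqids: set[str] = set()
    try:
        features = list(DataIterator(str(path)))
    except Exception as exc:  # pragma: no cover - gffutils internal variety
        raise GenomeIOError(f"{path}: failed to parse as GFF3: {exc}") from exc
    for feat in features:
        if feat.featuretype not in _GENE_FEATURE_TYPES:
            continue
        attrs = dict(feat.attributes)
        gid = (attrs.get("ID") or attrs.get("locus_tag") or [None])[0]
        if gid is None:
            raise GenomeIOError(f"{path}: feature at {feat.start}-{feat.end} has no ID")
        if gid in seen:
            raise GenomeIOError(f"{path}: duplicate gene ID {gid!r}")
        if feat.strand not in ("+", "-"):
            raise GenomeIOError(f"{path}: gene {gid!r} has missing/invalid strand")
        seen.add(gid)
        seqids.add(feat.seqid)
        genes.append(Gene(gid, int(feat.start), int(feat.end), feat.strand))
    if len(seqids) > 1:
        raise GenomeIOError(
            f"{path}: multiple sequence names {sorted(seqids)}; "
            "only single-replicon genomes are supported"
        )
    genes.sort(key=lambda g: (g.start, g.end, g.id))
    return genes


def write_annotation(genes: Sequence[Gene], path: str | Path, seqid: str = "chr") -> None:
    """Write genes as a minimal GFF3 file (one CDS feature per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{seqid}\tcondop\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.id}\n"
            )


# ---------------------------------------------------------------------------
# CDS FASTA
# ---------------------------------------------------------------------------

def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read CDS sequences keyed by gene id."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise GenomeIOError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def attach_sequences(genes: Sequence[Gene], seqs: dict[str, str]) -> list[Gene]:
    """Attach CDS sequences to genes; genes without a sequence are kept bare."""
    out = []
    for g in genes:
        seq = seqs.get(g.id)
        out.append(g.with_sequence(seq) if seq is not None else g)
    return out


def write_cds_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, seq in seqs.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# reference operon table (2-column DOOR projection)
# ---------------------------------------------------------------------------

def read_operon_table(path: str | Path, genes: Sequence[Gene]) -> list[ReferenceOperon]:
    """Read a tab-delimited reference operon map (operon_id TAB gene,gene,...).

    This is a minimal two-column projection of a DOOR-style flat file (see
    docs).  Rows referencing unknown genes raise; singleton rows are dropped
    with a warning; mixed-strand rows are rejected.
    """
    by_id = {g.id: g for g in genes}
    claimed: dict[str, str] = {}
    operons: list[ReferenceOperon] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenomeIOError(f"{path}:{lineno}: expected 2 tab-separated columns")
            op_id, gene_field = parts
            gene_ids = [g.strip() for g in gene_field.split(",") if g.strip()]
            for gid in gene_ids:
                if gid not in by_id:
                    raise GenomeIOError(f"{path}:{lineno}: unknown gene id {gid!r}")
            if len(gene_ids) < 2:
                warnings.warn(
                    f"{path}:{lineno}: operon {op_id!r} has fewer than 2 genes; dropped",
                    stacklevel=2,
                )
                continue
            strands = {by_id[g].strand for g in gene_ids}
            if len(strands) > 1:
                raise GenomeIOError(f"{path}:{lineno}: operon {op_id!r} mixes strands")
            for gid in gene_ids:
                if gid in claimed:
                    raise GenomeIOError(
                        f"{path}:{lineno}: gene {gid!r} already in operon {claimed[gid]!r}"
                    )
                claimed[gid] = op_id
            # normalize to transcription order
            strand = strands.pop()
            ordered = sorted(gene_ids, key=lambda g: by_id[g].start, reverse=(strand == "-"))
            operons.append(ReferenceOperon(op_id, tuple(ordered)))
    return operons


def write_operon_table(operons: Sequence[ReferenceOperon], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# operon_id\tgene_ids\n")
        for op in operons:
            fh.write(f"{op.id}\t{','.join(op.gene_ids)}\n")


# ---------------------------------------------------------------------------
# coverage (pileup or position/depth track)
# ---------------------------------------------------------------------------

def read_coverage(
    path: str | Path,
    genome_length: int,
    read_length: int = 50,
):
    """Read per-base coverage into a dense :class:`~condop.coverage.CoverageTrack`.

    Accepted dialects (detected per line width):

    * samtools pileup: ``ref  pos  base  depth  ...`` (columns 2 and 4 used)
    * 2-column TSV: ``pos  depth`` (unstranded)
    * 3-column numeric TSV: ``pos  depth_fwd  depth_rev`` (strand-specific)

    Positions absent from the file get depth 0.
    """
    from condop.coverage import CoverageTrack  # local import to avoid a cycle

    path = Path(path)
    depth = np.zeros(genome_length, dtype=np.int64)
    fwd = np.zeros(genome_length, dtype=np.int64)
    rev = np.zeros(genome_length, dtype=np.int64)
    stranded = False
    refs: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if len(parts) >= 4 and not _is_int(parts[2]):
                    # pileup: ref pos base depth ...
                    refs.add(parts[0])
                    pos, d = int(parts[1]), int(parts[3])
                    df = dr = None
                elif len(parts) == 3:
                    pos, df, dr = int(parts[0]), int(parts[1]), int(parts[2])
                    d = df + dr
                elif len(parts) == 2:
                    pos, d = int(parts[0]), int(parts[1])
                    df = dr = None
                else:
                    raise ValueError("unrecognized column layout")
            except ValueError as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from exc
            if not (1 <= pos <= genome_length):
                raise GenomeIOError(
                    f"{path}:{lineno}: position {pos} outside [1, {genome_length}]"
                )
            if d < 0 or (df is not None and (df < 0 or dr < 0)):
                raise GenomeIOError(f"{path}:{lineno}: negative depth")
            depth[pos - 1] = d
            if df is not None:
                stranded = True
                fwd[pos - 1] = df
                rev[pos - 1] = dr
    if len(refs) > 1:
        raise GenomeIOError(f"{path}: multiple reference names {sorted(refs)}")
    return CoverageTrack(
        depth=depth,
        read_length=read_length,
        fwd=fwd if stranded else None,
        rev=rev if stranded else None,
    )


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_coverage(track, path: str | Path) -> None:
    """Write a coverage track as position/depth TSV (3 columns if stranded)."""
    with open(path, "w") as fh:
        if track.stranded:
            fh.write("# pos\tdepth_fwd\tdepth_rev\n")
            for i in range(track.genome_length):
                f, r = int(track.fwd[i]), int(track.rev[i])
                if f or r:
                    fh.write(f"{i + 1}\t{f}\t{r}\n")
        else:
            fh.write("# pos\tdepth\n")
            for i, d in enumerate(track.depth):
                if d:
                    fh.write(f"{i + 1}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# BED signal intervals
# ---------------------------------------------------------------------------

_BED_KIND = {"promoter": "promoter", "terminator": "terminator",
             "term": "terminator", "prom": "promoter"}


def read_signals(path: str | Path) -> list[SignalInterval]:
    """Read predicted promoter/terminator intervals from BED.

    BED is 0-based half-open; internal coordinates are 1-based inclusive, so
    an interval ``(start, end)`` maps to ``(start+1, end)``.  The BED name
    column encodes ``kind`` optionally followed by a source tag, e.g.
    ``terminator:tt`` or ``promoter:pp``.
    """
    out: list[SignalInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GenomeIOError(f"{path}:{lineno}: BED needs >= 4 columns")
            start0, end0 = int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise GenomeIOError(f"{path}:{lineno}: end <= start in BED interval")
            name = parts[3]
            kind, _, source = name.partition(":")
            kind = _BED_KIND.get(kind.lower())
            if kind is None:
                raise GenomeIOError(f"{path}:{lineno}: unknown signal kind {parts[3]!r}")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            out.append(SignalInterval(kind, start0 + 1, end0, strand, source))
    return out


def write_signals(signals: Iterable[SignalInterval], path: str | Path,
                  seqid: str = "chr") -> None:
    with open(path, "w") as fh:
        for s in signals:
            name = f"{s.kind}:{s.source}" if s.source else s.kind
            fh.write(f"{seqid}\t{s.start - 1}\t{s.end}\t{name}\t0\t{s.strand}\n")
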