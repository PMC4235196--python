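"""Per-pair genomic and transcriptomic features.

Four features are computed for each adjacent same-strand gene pair:

* ``igr_length`` — intergenic distance ``start_{i+1} - end_i - 1`` (negative
  for overlapping genes);
* ``cu_score`` — similarity of the two genes' relative synonymous codon
  usage (RSCU) bias vectors, ``sum_c RSCU_c(g_i) * RSCU_c(g_{i+1})`` over the
  61 sense codons (genes in the same operon tend to share codon bias);
* ``diff_expr`` — ``|log2RPKM(g_i) - log2RPKM(g_{i+1})|`` (co-transcribed
  genes have similar levels);
* ``igr_expr`` — log2RPKM of the intergenic region (co-transcribed pairs
  have expressed IGRs).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from condop.confirm import AdjacentPair, igr_feature_id
from condop.coverage import ExpressionRecord
from condop.genome_io import Gene

__all__ = [
    "FEATURE_NAMES",
    "igr_length",
    "rscu_vector",
    "cu_score",
    "diff_expr",
    "igr_expr",
    "build_feature_table",
    "SENSE_CODONS",
    "SYNONYMOUS_FAMILIES",
]

FEATURE_NAMES = ("igr_length", "cu_score", "diff_expr", "igr_expr")

# bacterial genetic code (NCBI table 11); identical sense-codon table to the
# standard code
_TABLE = CodonTable.unambiguous_dna_by_id[11]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
_AA_OF = dict(_TABLE.forward_table)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _AA_OF.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
SYNONYMOUS_FAMILIES = {
    aa: tuple(sorted(c for c, a in _AA_OF.items() if a == aa))
    for aa in SYNONYMOUS_FAMILIES
}
_STOPS = set(_TABLE.stop_codons)


def igr_length(g_i: Gene, g_j: Gene) -> int:
    """Number of base pairs separating two consecutive genes.

    ``g_i`` must be the genomically upstream gene (lower coordinates);
    overlapping genes give a negative length.
    """
    if g_j.start <= g_i.start:
        raise ValueError(
            f"{g_i.id} must be genomically upstream of {g_j.id}"
        )
    if g_i.strand != g_j.strand:
        raise ValueError("igr_length is defined for same-strand adjacent pairs")
    return g_j.start - g_i.end - 1


def rscu_vector(cds: str, gene_id: str = "") -> dict[str, float]:
    """Relative synonymous codon usage of a coding sequence.

    ``RSCU_c = n_c * k_a / n_a`` for codon ``c`` of amino acid ``a``, where
    ``n_c`` is the codon count, ``n_a`` the family total and ``k_a`` the
    family size.  Stop codons are excluded; codons of amino acids absent from
    the gene get RSCU 0 by convention.  Internal stop codons and codons with
    ambiguous bases are skipped with a warning.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    counts: dict[str, int] = {}
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _STOPS:
            if i < n_codons - 1:
                warnings.warn(
                    f"internal stop codon {codon} at codon {i} in {gene_id or 'CDS'}; skipped",
                    stacklevel=2,
                )
            continue
        if codon not in _AA_OF:
            warnings.warn(
                f"ambiguous codon {codon!r} in {gene_id or 'CDS'}; skipped",
                stacklevel=2,
            )
            continue
        counts[codon] = counts.get(codon, 0) + 1
    rscu = dict.fromkeys(SENSE_CODONS, 0.0)
    for aa, family in SYNONYMOUS_FAMILIES.items():
        n_a = sum(counts.get(c, 0) for c in family)
        if n_a == 0:
            continue
        k_a = len(family)
        for c in family:
            rscu[c] = counts.get(c, 0) * k_a / n_a
    return rscu


def cu_score(
    u: Mapping[str, float], v: Mapping[str, float], level: str = "codon"
) -> float:
    """Codon-usage similarity of two RSCU vectors.

    Default sums the RSCU product over the 61 sense codons; ``level="aa"``
    first averages RSCU within each synonymous family and sums over amino
    acids.  Symmetric in its arguments.
    """
    if level == "codon":
        return float(sum(u[c] * v[c] for c in SENSE_CODONS))
    if level == "aa":
        total = 0.0
        for family in SYNONYMOUS_FAMILIES.values():
            mu = sum(u[c] for c in family) / len(family)
            mv = sum(v[c] for c in family) / len(family)
            total += mu * mv
        return float(total)
    raise ValueError(f"unknown level {level!r}")


def diff_expr(e_i: ExpressionRecord, e_j: ExpressionRecord) -> float:
    """Absolute difference of log2RPKM between two consecutive genes."""
    if e_i.kind != "CDS" or e_j.kind != "CDS":
        raise ValueError("diff_expr takes two CDS expression records")
    return abs(e_i.log2_rpkm - e_j.log2_rpkm)


def igr_expr(
    pair: AdjacentPair, expression: Mapping[str, ExpressionRecord]
) -> float:
    """log2RPKM of the pair's intergenic region.

    When the genes abut or overlap (no region exists) the minimum of the two
    gene levels is returned as a conservative stand-in.
    """
    if pair.has_igr:
        left, right = (
            (pair.upstream_gene, pair.downstream_gene)
            if pair.strand == "+"
            else (pair.downstream_gene, pair.upstream_gene)
        )
        rec = expression.get(igr_feature_id(left, right))
        if rec is None:
            raise KeyError(f"missing IGR expression record for pair {pair.pair_id}")
        return rec.log2_rpkm
    up = expression[pair.upstream_gene]
    down = expression[pair.downstream_gene]
    return min(up.log2_rpkm, down.log2_rpkm)


def build_feature_table(
    pairs: Sequence[AdjacentPair],
    genes: Sequence[Gene],
    expression: Mapping[str, ExpressionRecord],
    cds_sequences: Mapping[str, str],
) -> pd.DataFrame:
    """One row per adjacent pair: pair id, label and the four features.

    Rows are in genomic order; pairs whose CDS sequence is missing are
    dropped with a warning.
    """
    genes_by_id = {g.id: g for g in genes}
    rscu_cache: dict[str, dict[str, float]] = {}

    def rscu_of(gid: str) -> dict[str, float] | None:
        if gid not in rscu_cache:
            seq = cds_sequences.get(gid)
            if seq is None and genes_by_id[gid].cds_sequence is not None:
                seq = genes_by_id[gid].cds_sequence
            rscu_cache[gid] = rscu_vector(seq, gid) if seq is not None else None
        return rscu_cache[gid]

    rows = []
    for pair in pairs:
        up = genes_by_id[pair.upstream_gene]
        down = genes_by_id[pair.downstream_gene]
        left, right = (up, down) if pair.strand == "+" else (down, up)
        u, v = rscu_of(up.id), rscu_of(down.id)
        if u is None or v is None:
            warnings.warn(
                f"pair {pair.pair_id}: missing CDS sequence; dropped", stacklevel=2
            )
            continue
        rows.append(
            {
                "pair_id": pair.pair_id,
                "gene_i": pair.upstream_gene,
                "gene_j": pair.downstream_gene,
                "strand": pair.strand,
                "label": pair.label,
                "igr_length": igr_length(left, right),
                "cu_score": cu_score(u, v),
                "diff_expr": diff_expr(expression[up.id], expression[down.id]),
                "igr_expr": igr_expr(pair, expression),
            }
        )
    columns = ["pair_id", "gene_i", "gene_j", "strand", "label", *FEATURE_NAMES]
    df = pd.DataFrame(rows, columns=columns)
    order = {g.id: i for i, g in enumerate(sorted(genes, key=lambda g: g.start))}
    if len(df):
        df = (
            df.assign(_k=[min(order[a], order[b]) for a, b in zip(df.gene_i, df.gene_j)])
            .sort_values("_k", kind="stable")
            .drop(columns="_k")
            .reset_index(drop=True)
        )
    return df
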