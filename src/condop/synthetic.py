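"""Synthetic prokaryotic transcriptome fixtures with full ground truth.

The generator emulates the data regime the prediction method assumes:

* genes laid out in transcription units (TUs) on both strands, with short
  (often overlapping) intra-operon spacers and longer between-TU gaps;
* step-shaped per-base coverage over each expressed TU (plus a short 5'/3'
  UTR), Poisson noise around the TU's depth, and a low background depth
  elsewhere, so intra-operon intergenic regions are expressed;
* per-condition dynamics: the silent-TU set, expression levels and internal
  transcription starts are re-drawn per condition from the same genome;
* shared codon bias within operons: all CDSs of a TU are sampled from one
  per-family codon preference vector drawn from a Dirichlet;
* a corrupted reference operon map (random splits and merges at
  ``annotation_error_rate``) mimicking static-annotation errors, creating
  POP/EGP/NOP opportunities downstream.

The between-TU gap floor (60 nt) keeps neighbouring coverage steps farther
apart than half the 100-nt detector window, the detector's intrinsic
resolution; closer boundaries would be unresolvable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from condop.coverage import Breakpoint, CoverageTrack
from condop.genome_io import (
    Gene,
    ReferenceOperon,
    write_annotation,
    write_cds_fasta,
    write_coverage,
    write_operon_table,
)

__all__ = [
    "SimConfig",
    "TrueTU",
    "SynGenome",
    "Condition",
    "SimResult",
    "draw_genome",
    "draw_condition",
    "simulate",
    "simulate_to_dir",
    "truth_compare",
]

_AA_FAMILIES: dict[str, tuple[str, ...]] | None = None


def _families() -> dict[str, tuple[str, ...]]:
    global _AA_FAMILIES
    if _AA_FAMILIES is None:
        from condop.features import SYNONYMOUS_FAMILIES

        _AA_FAMILIES = SYNONYMOUS_FAMILIES
    return _AA_FAMILIES


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the shipped study conditions."""

    seed: int = 0
    n_operons: int = 300  # number of TUs (sizes 1..8; >= 2 makes an operon)
    operon_size_p: float = 0.5  # geometric(p), truncated to [1, 8]
    within_operon_igr_mean: float = 20.0
    within_operon_igr_sd: float = 15.0
    within_operon_igr_floor: float = -20.0  # negative = gene overlap allowed
    between_tu_igr_mean: float = 150.0
    between_tu_igr_sd: float = 60.0
    between_tu_igr_floor: float = 60.0  # > detector half-window (see module doc)
    expression_mean: float = 6.0  # per-TU log2 depth level
    expression_sd: float = 2.0
    fraction_silent_tus: float = 0.15
    internal_start_rate: float = 0.10
    background_depth: float = 0.2
    depth_scale: float = 1.0  # per-base mean depth of a TU = scale * 2**level
    noise: str = "poisson"  # "poisson" | "none"
    stranded: bool = False  # emit a strand-specific library (fwd/rev tracks)
    dispersion: float = 0.0  # > 0 switches to negative binomial
    read_length: int = 50
    boundary_sharpness: int = 0  # nt of linear ramp at each plateau edge
    annotation_error_rate: float = 0.10
    codon_bias_concentration: float = 0.5  # Dirichlet alpha per family
    gene_length_min: int = 300  # multiples of 3
    gene_length_max: int = 900
    utr_min: int = 10
    utr_max: int = 40
    margin: int = 300
    genome_length: int | None = None  # optional hard cap

    def __post_init__(self) -> None:
        for name in ("fraction_silent_tus", "internal_start_rate", "annotation_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_operons < 1:
            raise ValueError("n_operons must be positive")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")


@dataclass
class TrueTU:
    id: str
    strand: str
    gene_ids: tuple[str, ...]  # transcription order


@dataclass
class SynGenome:
    genes: list[Gene]
    cds: dict[str, str]
    true_tus: list[TrueTU]
    reference_operons: list[ReferenceOperon]
    genome_length: int
    genes_by_id: dict[str, Gene] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes_by_id:
            self.genes_by_id = {g.id: g for g in self.genes}


@dataclass
class Condition:
    """Per-condition ground truth plus the emitted coverage track."""

    track: CoverageTrack
    expressed: dict[str, bool]  # per TU
    start_index: dict[str, int]  # first transcribed gene (transcription order)
    tu_level: dict[str, float]  # log2 depth level
    tu_depth: dict[str, float]  # per-base mean depth of the plateau
    boundaries: list[tuple[int, str]]  # (position, increase|decrease), genomic
    operons: list[tuple[str, ...]]  # per-condition operons (>= 2 genes)
    co_pairs: set[tuple[str, str]]  # co-transcribed (upstream, downstream)


@dataclass
class SimResult:
    config: SimConfig
    genome: SynGenome
    condition: Condition


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _truncated_geometric(rng: np.random.Generator, p: float, lo: int, hi: int) -> int:
    while True:
        v = int(rng.geometric(p))
        if lo <= v <= hi:
            return v


def _gene_sequence(
    rng: np.random.Generator, n_codons: int, pref: dict[str, np.ndarray]
) -> str:
    families = _families()
    aas = list(families)
    codons = ["ATG"]
    aa_idx = rng.integers(0, len(aas), size=n_codons - 1)
    for i in aa_idx:
        aa = aas[i]
        fam = families[aa]
        codons.append(fam[rng.choice(len(fam), p=pref[aa])])
    return "".join(codons)


def _codon_preference(rng: np.random.Generator, concentration: float) -> dict[str, np.ndarray]:
    return {
        aa: rng.dirichlet(np.full(len(fam), concentration))
        for aa, fam in _families().items()
    }


def draw_genome(cfg: SimConfig) -> SynGenome:
    """Lay out TUs, draw CDS sequences and the (corrupted) reference map."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes: list[Gene] = []
    cds: dict[str, str] = {}
    tus: list[TrueTU] = []
    cursor = cfg.margin  # last used coordinate
    for t in range(cfg.n_operons):
        size = _truncated_geometric(rng, cfg.operon_size_p, 1, 8)
        strand = "+" if rng.random() < 0.5 else "-"
        pref = _codon_preference(rng, cfg.codon_bias_concentration)
        if t > 0:
            gap = max(
                cfg.between_tu_igr_floor,
                rng.normal(cfg.between_tu_igr_mean, cfg.between_tu_igr_sd),
            )
            cursor += int(round(gap))
        gene_ids: list[str] = []
        for k in range(size):
            if k > 0:
                gap = max(
                    cfg.within_operon_igr_floor,
                    rng.normal(cfg.within_operon_igr_mean, cfg.within_operon_igr_sd),
                )
                cursor += int(round(gap))
            length = 3 * int(rng.integers(cfg.gene_length_min // 3, cfg.gene_length_max // 3 + 1))
            start, end = cursor + 1, cursor + length
            gid = f"g{len(genes):04d}"
            seq = _gene_sequence(rng, length // 3, pref)
            genes.append(Gene(gid, start, end, strand, seq))
            cds[gid] = seq
            gene_ids.append(gid)
            cursor = end
        if strand == "-":
            gene_ids = gene_ids[::-1]  # transcription order
        tus.append(TrueTU(f"tu{t:04d}", strand, tuple(gene_ids)))
    genome_length = cursor + cfg.margin
    if cfg.genome_length is not None:
        if genome_length > cfg.genome_length:
            raise ValueError(
                f"layout needs {genome_length} bp; increase genome_length "
                f"to at least {genome_length}"
            )
        genome_length = cfg.genome_length
    reference = _corrupt_reference(rng, tus, cfg)
    return SynGenome(genes, cds, tus, reference, genome_length)


def _corrupt_reference(
    rng: np.random.Generator, tus: Sequence[TrueTU], cfg: SimConfig
) -> list[ReferenceOperon]:
    """True operons -> DOOR-style reference with split/merge errors.

    A split drops one junction from a multi-gene operon (halves of size 1
    disappear from the map, as DOOR lists no singletons); a merge joins a TU
    with its genomic successor when strands agree.  Merges create
    reference-co-operonic pairs that the condition splits (NOP/EGP cases);
    splits create POP cases.
    """
    out: list[ReferenceOperon] = []
    merged_into_prev: set[int] = set()
    i = 0
    counter = 0
    while i < len(tus):
        tu = tus[i]
        corrupt = rng.random() < cfg.annotation_error_rate
        action = None
        if corrupt:
            can_merge = i + 1 < len(tus) and tus[i + 1].strand == tu.strand
            can_split = len(tu.gene_ids) >= 2
            options = [a for a, ok in (("merge", can_merge), ("split", can_split)) if ok]
            action = options[int(rng.integers(0, len(options)))] if options else None
        if action == "merge":
            nxt = tus[i + 1]
            combined = (
                tu.gene_ids + nxt.gene_ids
                if tu.strand == "+"
                else nxt.gene_ids + tu.gene_ids
            )
            out.append(ReferenceOperon(f"rop{counter:04d}", combined))
            counter += 1
            i += 2
            continue
        if action == "split":
            cut = int(rng.integers(1, len(tu.gene_ids)))
            for part in (tu.gene_ids[:cut], tu.gene_ids[cut:]):
                if len(part) >= 2:
                    out.append(ReferenceOperon(f"rop{counter:04d}", part))
                    counter += 1
            i += 1
            continue
        if len(tu.gene_ids) >= 2:
            out.append(ReferenceOperon(f"rop{counter:04d}", tu.gene_ids))
            counter += 1
        i += 1
    return out


# ---------------------------------------------------------------------------
# condition
# ---------------------------------------------------------------------------

def draw_condition(
    genome: SynGenome, cfg: SimConfig, condition_seed: int = 0
) -> Condition:
    """Draw one measured condition: silent set, levels, internal starts,
    UTRs and the noisy coverage track."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, condition_seed]))
    if cfg.stranded:
        # background split evenly between strands
        lam_by_strand = {
            s: np.full(genome.genome_length, cfg.background_depth / 2, dtype=float)
            for s in "+-"
        }
    else:
        lam_by_strand = None
    lam = np.full(genome.genome_length, cfg.background_depth, dtype=float)
    expressed: dict[str, bool] = {}
    start_index: dict[str, int] = {}
    tu_level: dict[str, float] = {}
    tu_depth: dict[str, float] = {}
    boundaries: list[tuple[int, str]] = []
    operons: list[tuple[str, ...]] = []
    co_pairs: set[tuple[str, str]] = set()

    for tu in genome.true_tus:
        is_expr = rng.random() >= cfg.fraction_silent_tus
        level = float(rng.normal(cfg.expression_mean, cfg.expression_sd))
        k = 0
        if is_expr and len(tu.gene_ids) >= 2 and rng.random() < cfg.internal_start_rate:
            # an internal start needs intergenic space upstream, so that the
            # transcript (and its breakpoint) stays clear of the upstream gene
            eligible = [
                j
                for j in range(1, len(tu.gene_ids))
                if _intra_igr(genome, tu, j) >= 2
            ]
            if eligible:
                k = int(eligible[int(rng.integers(0, len(eligible)))])
        expressed[tu.id] = is_expr
        start_index[tu.id] = k
        tu_level[tu.id] = level
        if not is_expr:
            tu_depth[tu.id] = 0.0
            continue
        depth = cfg.depth_scale * 2.0**level
        tu_depth[tu.id] = depth
        tx_genes = tu.gene_ids[k:]
        first = genome.genes_by_id[tx_genes[0]]
        last = genome.genes_by_id[tx_genes[-1]]
        utr5 = int(rng.integers(cfg.utr_min, cfg.utr_max + 1))
        utr3 = int(rng.integers(cfg.utr_min, cfg.utr_max + 1))
        utr5, utr3 = _clamp_utrs(genome, tu, k, utr5, utr3, cfg)
        if tu.strand == "+":
            lo, hi = first.start - utr5, last.end + utr3
        else:
            lo, hi = last.start - utr3, first.end + utr5
        lo, hi = max(1, lo), min(genome.genome_length, hi)
        _paint(lam, lo, hi, depth, cfg.boundary_sharpness)
        if lam_by_strand is not None:
            _paint(lam_by_strand[tu.strand], lo, hi, depth, cfg.boundary_sharpness)
        boundaries.append((lo, "increase"))
        boundaries.append((hi + 1, "decrease"))
        if len(tx_genes) >= 2:
            operons.append(tuple(tx_genes))
            co_pairs.update(zip(tx_genes[:-1], tx_genes[1:]))

    if lam_by_strand is not None:
        fwd = _noisify(rng, lam_by_strand["+"], cfg)
        rev = _noisify(rng, lam_by_strand["-"], cfg)
        track = CoverageTrack(
            depth=fwd + rev, read_length=cfg.read_length, fwd=fwd, rev=rev
        )
    else:
        track = CoverageTrack(depth=_noisify(rng, lam, cfg), read_length=cfg.read_length)
    boundaries.sort()
    return Condition(
        track, expressed, start_index, tu_level, tu_depth, boundaries, operons, co_pairs
    )


def _intra_igr(genome: SynGenome, tu: TrueTU, k: int) -> int:
    """Intra-operon IGR length upstream of the k-th gene (transcription order)."""
    prev = genome.genes_by_id[tu.gene_ids[k - 1]]
    cur = genome.genes_by_id[tu.gene_ids[k]]
    if tu.strand == "+":
        return cur.start - prev.end - 1
    return prev.start - cur.end - 1


def _clamp_utrs(
    genome: SynGenome, tu: TrueTU, k: int, utr5: int, utr3: int, cfg: SimConfig
) -> tuple[int, int]:
    """Keep the transcript's UTRs clear of neighbouring plateaus.

    Between-TU gaps reserve at least 60 nt of background (half the detector
    window plus margin), so each side may consume at most (gap - 60) / 2.
    An internal start's 5'UTR is confined to its upstream intra-operon IGR so
    the resulting breakpoint falls inside that intergenic region.
    """
    tx = tu.gene_ids[k:]
    first = genome.genes_by_id[tx[0]]
    last = genome.genes_by_id[tx[-1]]
    ordered = sorted(genome.genes, key=lambda g: g.start)
    idx = {g.id: i for i, g in enumerate(ordered)}
    left_gene = first if tu.strand == "+" else last
    right_gene = last if tu.strand == "+" else first
    i_left, i_right = idx[left_gene.id], idx[right_gene.id]
    gap_left = (
        left_gene.start - ordered[i_left - 1].end - 1 if i_left > 0 else cfg.margin
    )
    gap_right = (
        ordered[i_right + 1].start - right_gene.end - 1
        if i_right + 1 < len(ordered)
        else cfg.margin
    )
    allow_left = max(0, (gap_left - 60) // 2)
    allow_right = max(0, (gap_right - 60) // 2)
    if tu.strand == "+":
        utr5, utr3 = min(utr5, allow_left), min(utr3, allow_right)
    else:
        utr5, utr3 = min(utr5, allow_right), min(utr3, allow_left)
    if k > 0:  # internal start: 5'UTR stays inside the upstream intra-TU IGR
        prev_gene = genome.genes_by_id[tu.gene_ids[k - 1]]
        if tu.strand == "+":
            igr = first.start - prev_gene.end - 1
        else:
            igr = prev_gene.start - first.end - 1
        utr5 = min(utr5, max(0, igr - 1))
    return utr5, utr3


def _paint(lam: np.ndarray, lo: int, hi: int, depth: float, sharpness: int) -> None:
    lam[lo - 1 : hi] = depth
    if sharpness > 0:
        ramp = np.linspace(0.0, depth, sharpness + 2)[1:-1]
        left = slice(max(0, lo - 1 - sharpness), lo - 1)
        lam[left] = np.maximum(lam[left], ramp[-(lo - 1 - left.start) :])
        right = slice(hi, min(lam.size, hi + sharpness))
        lam[right] = np.maximum(lam[right], ramp[::-1][: right.stop - hi])


def _noisify(rng: np.random.Generator, lam: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.noise == "none":
        return np.round(lam).astype(np.int64)
    if cfg.dispersion > 0:
        # negative binomial with mean lam and variance lam * (1 + dispersion*lam)
        r = 1.0 / cfg.dispersion
        p = r / (r + lam)
        return rng.negative_binomial(r, p).astype(np.int64)
    return rng.poisson(lam).astype(np.int64)


def simulate(cfg: SimConfig, condition_seed: int = 0) -> SimResult:
    """Draw a genome and one measured condition."""
    genome = draw_genome(cfg)
    condition = draw_condition(genome, cfg, condition_seed)
    return SimResult(cfg, genome, condition)


def simulate_to_dir(cfg: SimConfig, outdir: str | Path, condition_seed: int = 0) -> SimResult:
    """Simulate and write the standard-format fixture files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = simulate(cfg, condition_seed)
    write_annotation(res.genome.genes, outdir / "genes.gff3")
    write_cds_fasta(res.genome.cds, outdir / "cds.fasta")
    write_coverage(res.condition.track, outdir / "coverage.tsv")
    write_operon_table(res.genome.reference_operons, outdir / "reference_operons.tsv")
    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("# record_type\tfield1\tfield2\n")
        fh.write(f"genome_length\t{res.genome.genome_length}\t.\n")
        for tu in res.genome.true_tus:
            fh.write(f"tu\t{tu.id}\t{','.join(tu.gene_ids)}\n")
        for tu_id, ex in res.condition.expressed.items():
            fh.write(f"expressed\t{tu_id}\t{int(ex)}\n")
        for pos, kind in res.condition.boundaries:
            fh.write(f"boundary\t{pos}\t{kind}\n")
        for up, down in sorted(res.condition.co_pairs):
            fh.write(f"co_pair\t{up}\t{down}\n")
    return res


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------

def truth_compare(
    predicted_junctions: Sequence[tuple[str, str]],
    condition: Condition,
    genome: SynGenome,
    breakpoints: Sequence[Breakpoint] | None = None,
) -> dict:
    """Junction-level precision/recall plus boundary-distance summary.

    ``predicted_junctions`` are (upstream, downstream) gene-id pairs in
    transcription order (e.g. collected from OperonCall.junctions()).
    Precision is NaN (flagged) when nothing was predicted.
    """
    pred = set(predicted_junctions)
    for up, down in pred:
        if up not in genome.genes_by_id or down not in genome.genes_by_id:
            raise ValueError(f"unknown gene id in predicted junction {up}|{down}")
    truth = condition.co_pairs
    tp = len(pred & truth)
    precision = tp / len(pred) if pred else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    out = {
        "junction_precision": precision,
        "junction_recall": recall,
        "n_predicted": len(pred),
        "n_truth": len(truth),
    }
    if breakpoints is not None:
        errors = []
        for pos, kind in condition.boundaries:
            dists = [abs(b.position - pos) for b in breakpoints if b.kind == kind]
            errors.append(min(dists) if dists else float("inf"))
        errors = np.asarray(errors, dtype=float)
        out["boundary_errors"] = errors
        finite = errors[np.isfinite(errors)]
        out["boundary_error_quantiles"] = (
            np.quantile(finite, [0.5, 0.9, 1.0]).tolist() if finite.size else None
        )
    return out
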