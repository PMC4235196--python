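"""Transcription breakpoint detection and RPKM expression estimation.

The detector slides a fixed window (default 100 nt, stride 1) across the
per-base coverage profile and correlates each depth segment with a step
template ``x = [0]*50 + [1]*50`` modelling a sharp increase in transcription.
Windows with Pearson r above ``r_threshold`` (increases) or below its
negative (decreases) and a correlation-test p-value below ``p_threshold``
are candidate breakpoints; maximal runs of consecutive significant same-sign
windows are merged and the centre point of the run's best window (maximal
|r|, leftmost on ties) is reported.

The reported position is the first base of the window's right half: for an
ideal step ``...a a a b b b...`` the breakpoint position is the first base at
depth ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CoverageTrack",
    "DetectorConfig",
    "Breakpoint",
    "ExpressionRecord",
    "detect_breakpoints",
    "correlation_pvalue",
    "compute_rpkm",
    "expression_thresholds",
]


@dataclass
class CoverageTrack:
    """Dense per-base read depth for a single replicon.

    ``depth`` is the combined track; strand-specific libraries additionally
    carry ``fwd``/``rev`` arrays whose sum equals ``depth``.
    """

    depth: np.ndarray
    read_length: int = 50
    fwd: np.ndarray | None = None
    rev: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("coverage depths must be non-negative")
        if (self.fwd is None) != (self.rev is None):
            raise ValueError("stranded track needs both fwd and rev arrays")
        if self.fwd is not None:
            self.fwd = np.asarray(self.fwd, dtype=np.int64)
            self.rev = np.asarray(self.rev, dtype=np.int64)

    @property
    def genome_length(self) -> int:
        return int(self.depth.size)

    @property
    def total_mapped_bases(self) -> int:
        return int(self.depth.sum())

    @property
    def stranded(self) -> bool:
        return self.fwd is not None

    def strand_depth(self, strand: str | None = None) -> np.ndarray:
        """Depth array for one strand ('+'/'-') or the combined track."""
        if strand is None or not self.stranded:
            return self.depth
        return self.fwd if strand == "+" else self.rev


def default_template(window_length: int = 100) -> np.ndarray:
    half = window_length // 2
    return np.concatenate([np.zeros(half), np.ones(half)])


@dataclass
class DetectorConfig:
    """Sliding-window detector parameters (defaults follow the method)."""

    window_length: int = 100
    r_threshold: float = 0.7
    p_threshold: float = 1e-7
    fold_change_min: float = 2.0
    template: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.template is None:
            self.template = default_template(self.window_length)
        self.template = np.asarray(self.template, dtype=float)
        if self.window_length % 2 != 0 or self.template.size != self.window_length:
            raise ValueError("window_length must be even and equal template length")
        if not (0.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class Breakpoint:
    """A putative transcription start (increase) or end (decrease) point."""

    position: int  # 1-based genome position (window centre)
    kind: str  # "increase" | "decrease"
    r: float
    p_value: float
    fold_change: float
    strand: str = "."  # '+', '-', '.' (unstranded)


@dataclass(frozen=True)
class ExpressionRecord:
    """log2(RPKM + 1) expression of a CDS or intergenic region."""

    feature_id: str
    kind: str  # "CDS" | "IGR"
    rpkm: float
    log2_rpkm: float


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation.

    Uses the exact t-statistic ``t = r*sqrt((n-2)/(1-r^2))`` with ``n-2``
    degrees of freedom; |r| = 1 maps to p = 0.
    """
    if n < 3:
        raise ValueError("correlation test needs n >= 3")
    r = float(r)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _window_correlations(depth: np.ndarray, template: np.ndarray):
    """Pearson r of every length-w window (stride 1) against the template.

    Returns (r, valid) where ``valid`` is False for zero-variance windows.
    Computed with cumulative sums + one cross-correlation, O(n·w).
    """
    w = template.size
    y = depth.astype(np.float64)
    n_win = y.size - w + 1
    if n_win <= 0:
        raise ValueError("window longer than genome")
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y * y)])
    s_y = csum[w:] - csum[:-w]
    s_yy = csum2[w:] - csum2[:-w]
    s_xy = np.correlate(y, template, mode="valid")
    x = template
    s_x, s_xx = x.sum(), (x * x).sum()
    var_x = s_xx - s_x * s_x / w
    var_y = s_yy - s_y * s_y / w
    cov = s_xy - s_x * s_y / w
    # guard zero variance: undefined correlation
    tol = 1e-9 * np.maximum(s_yy, 1.0)
    valid = var_y > tol
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_x * np.where(valid, var_y, 1.0))
    r = np.clip(np.where(valid, r, 0.0), -1.0, 1.0)
    return r, valid


def _pvalues(r: np.ndarray, n: int) -> np.ndarray:
    p = np.zeros_like(r)
    interior = np.abs(r) < 1.0
    ri = r[interior]
    t = ri * np.sqrt((n - 2) / (1.0 - ri * ri))
    p[interior] = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return p


def _merge_runs(indices: np.ndarray, r: np.ndarray) -> list[int]:
    """Split significant window start-indices into maximal consecutive runs,
    returning the best window index per run (max |r|, leftmost tie-break)."""
    best: list[int] = []
    if indices.size == 0:
        return best
    splits = np.where(np.diff(indices) > 1)[0] + 1
    for run in np.split(indices, splits):
        best.append(int(run[np.argmax(np.abs(r[run]))]))
    return best


def detect_breakpoints(
    track: CoverageTrack, cfg: DetectorConfig | None = None, strand: str | None = None
) -> list[Breakpoint]:
    """Detect transcription start/end points on a coverage track.

    For strand-specific tracks pass ``strand`` to scan one strand's depth;
    the returned breakpoints then carry that strand label.
    """
    cfg = cfg or DetectorConfig()
    depth = track.strand_depth(strand)
    w = cfg.window_length
    if depth.size < w:
        raise ValueError("window longer than genome")
    r, valid = _window_correlations(depth, cfg.template)
    p = _pvalues(r, w)
    sig_pos = np.where(valid & (r > cfg.r_threshold) & (p < cfg.p_threshold))[0]
    sig_neg = np.where(valid & (r < -cfg.r_threshold) & (p < cfg.p_threshold))[0]

    half = w // 2
    out: list[Breakpoint] = []
    label = strand if strand is not None else "."
    for kind, sig in (("increase", sig_pos), ("decrease", sig_neg)):
        for i in _merge_runs(sig, r):
            left = depth[i : i + half].mean()
            right = depth[i + half : i + w].mean()
            if kind == "increase":
                fc = (right + 1.0) / (left + 1.0)
            else:
                fc = (left + 1.0) / (right + 1.0)
            out.append(
                Breakpoint(
                    position=i + half + 1,
                    kind=kind,
                    r=float(r[i]),
                    p_value=float(p[i]),
                    fold_change=float(fc),
                    strand=label,
                )
            )
    out.sort(key=lambda b: (b.position, b.kind))
    return out


def compute_rpkm(
    track: CoverageTrack,
    intervals: Sequence[tuple[str, str, int, int]],
    strand: str | None = None,
) -> list[ExpressionRecord]:
    """RPKM (and log2(RPKM+1)) for (id, kind, start, end) intervals.

    Read counts are estimated from per-base depth: C = sum(depth)/read_length
    over the interval, N = total_mapped_bases/read_length for the library,
    RPKM = C / ((L/1000) * (N/1e6)).
    """
    depth = track.strand_depth(strand)
    total = int(depth.sum()) if strand is not None and track.stranded else track.total_mapped_bases
    if total == 0:
        raise ValueError("empty library: total mapped bases is zero")
    n_reads = total / track.read_length
    csum = np.concatenate([[0], np.cumsum(depth)])
    out: list[ExpressionRecord] = []
    for fid, kind, start, end in intervals:
        if not (1 <= start <= end <= track.genome_length):
            raise ValueError(f"interval {fid}: [{start}, {end}] outside genome")
        c = (csum[end] - csum[start - 1]) / track.read_length
        length = end - start + 1
        rpkm = c / ((length / 1000.0) * (n_reads / 1e6))
        out.append(ExpressionRecord(fid, kind, float(rpkm), float(np.log2(rpkm + 1.0))))
    return out


def expression_thresholds(
    records: Sequence[ExpressionRecord], percentile: float = 10.0
) -> tuple[float, float]:
    """Minimum-expression thresholds: the given percentile (linear
    interpolation) of the log2(RPKM+1) distributions of CDS and IGR records.
    """
    cds = [r.log2_rpkm for r in records if r.kind == "CDS"]
    igr = [r.log2_rpkm for r in records if r.kind == "IGR"]
    if not cds or not igr:
        raise ValueError("need at least one CDS and one IGR expression record")
    cds_min = float(np.percentile(cds, percentile, method="linear"))
    igr_min = float(np.percentile(igr, percentile, method="linear"))
    return cds_min, igr_min


def write_breakpoints(breakpoints: Sequence[Breakpoint], path) -> None:
    with open(path, "w") as fh:
        fh.write("# position\tkind\tr\tp_value\tfold_change\tstrand\n")
        for b in breakpoints:
            fh.write(
                f"{b.position}\t{b.kind}\t{b.r:.6f}\t{b.p_value:.6e}\t"
                f"{b.fold_change:.4f}\t{b.strand}\n"
            )


def read_breakpoints(path) -> list[Breakpoint]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            pos, kind, r, p, fc, strand = line.rstrip("\n").split("\t")
            out.append(Breakpoint(int(pos), kind, float(r), float(p), float(fc), strand))
    return out


def read_expression(path) -> list[ExpressionRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fid, kind, rpkm, log2 = line.rstrip("\n").split("\t")
            out.append(ExpressionRecord(fid, kind, float(rpkm), float(log2)))
    return out


def write_expression(records: Sequence[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("# feature_id\tkind\trpkm\tlog2_rpkm\n")
        for r in records:
            fh.write(f"{r.feature_id}\t{r.kind}\t{r.rpkm:.6f}\t{r.log2_rpkm:.6f}\n")
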