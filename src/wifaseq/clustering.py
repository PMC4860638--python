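"""Multi-sample aggregation and distance-based clustering of altered runs.

Per-sample sign-filtered high-frequency signals are summed bin-wise into a
recurrence signal; its maximal same-sign nonzero runs are grouped when the
genomic gap between runs of the same sign is at most ``d`` bp, subgrouped at
distance ``r``, and each group's highest-|score| subgroup is reported as a
focal cluster.  A subgroup's score is the sum of the recurrence signal over
its runs, so high scores need either many affected samples or large
amplitude — the same trade-off GISTIC's G-score encodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .masking import MaskedSignal
from .wavelet import HighFreqSignal

logger = logging.getLogger(__name__)


@dataclass
class SumSignal:
    """Bin-wise sum of sign-filtered per-sample signals plus, per bin, the
    number of samples contributing a nonzero value (patient support)."""

    values: np.ndarray
    support: np.ndarray
    n_samples: int
    masked: MaskedSignal


@dataclass
class Run:
    """One maximal same-sign nonzero stretch of the recurrence signal."""

    chrom: str
    start_idx: int      # concatenated coordinates, inclusive
    end_idx: int
    start_bp: int       # genomic, 0-based
    end_bp: int         # genomic, half-open
    sign: int
    score: float
    max_support: int
    spans_junction: bool = False


@dataclass
class FocalCluster:
    """A candidate recurrent focal region (1-based inclusive coordinates)."""

    chromosome: str
    start: int
    end: int
    score: float
    n_patients: int
    sign: int
    p_values: dict[int, float] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)
    spans_junction: bool = False

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def sum_samples(signals: list[HighFreqSignal]) -> SumSignal:
    """Element-wise sum of the samples' sign-filtered signals."""
    if not signals:
        raise ValueError("no signals to sum")
    first = signals[0].masked
    total = np.zeros(len(first), dtype=np.float64)
    support = np.zeros(len(first), dtype=np.int32)
    for sig in signals:
        if len(sig.masked) != len(first) or not np.array_equal(
            sig.masked.kept_bins, first.kept_bins
        ):
            raise ValueError("signals do not share the same layout/mask")
        v = sig.y_high_filtered
        total += v
        support += v != 0
    return SumSignal(values=total, support=support, n_samples=len(signals), masked=first)


def extract_runs(sum_signal: SumSignal) -> list[Run]:
    """Maximal consecutive same-sign nonzero runs, split at chromosome
    boundaries.  Runs may cross an intra-chromosome junction (removed
    region); such runs are flagged rather than split, since concatenation
    deliberately treats flanks of a removed region as neighbors."""
    v = sum_signal.values
    m = sum_signal.masked
    if len(v) == 0:
        return []
    sgn = np.sign(v).astype(np.int8)
    breaks = np.zeros(len(v) + 1, dtype=bool)
    breaks[0] = breaks[-1] = True
    breaks[1:-1] = (sgn[1:] != sgn[:-1]) | (m.chrom_index[1:] != m.chrom_index[:-1])
    pts = np.flatnonzero(breaks)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    bs = m.layout.bin_size
    junc = m.junctions
    runs: list[Run] = []
    for a, b in zip(pts[:-1], pts[1:]):
        if sgn[a] == 0:
            continue
        end = b - 1
        chrom = m.layout.names[int(m.chrom_index[a])]
        runs.append(
            Run(
                chrom=chrom,
                start_idx=int(a),
                end_idx=int(end),
                start_bp=int(m.start_bp[a]),
                end_bp=int(m.start_bp[end]) + bs,
                sign=int(sgn[a]),
                score=float(csum[b] - csum[a]),
                max_support=int(sum_signal.support[a:b].max()),
                spans_junction=bool(((junc > a) & (junc <= end)).any()),
            )
        )
    return runs


def count_sign_segments(signal: np.ndarray) -> int:
    """Number of maximal same-sign nonzero runs in a bare signal."""
    sgn = np.sign(np.asarray(signal))
    nz = sgn != 0
    if not nz.any():
        return 0
    new_run = np.concatenate([[True], (sgn[1:] != sgn[:-1])])
    return int((new_run & nz).sum())


@dataclass
class RunArrays:
    """Column-oriented run records (fast path shared with the permutation
    null, where building one object per run would dominate the runtime)."""

    chrom_code: np.ndarray
    start_bp: np.ndarray
    end_bp: np.ndarray       # half-open
    sign: np.ndarray
    score: np.ndarray
    max_support: np.ndarray
    spans_junction: np.ndarray
    chrom_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.score)


def extract_run_arrays(
    values: np.ndarray, masked: MaskedSignal, support: np.ndarray | None = None
) -> RunArrays:
    """Vectorized :func:`extract_runs` returning columns instead of objects."""
    v = np.asarray(values)
    names = masked.layout.names
    if len(v) == 0:
        z = np.zeros(0, dtype=np.int64)
        return RunArrays(z, z, z, z, z.astype(float), z, z.astype(bool), names)
    sgn = np.sign(v).astype(np.int8)
    breaks = np.zeros(len(v) + 1, dtype=bool)
    breaks[0] = breaks[-1] = True
    breaks[1:-1] = (sgn[1:] != sgn[:-1]) | (masked.chrom_index[1:] != masked.chrom_index[:-1])
    pts = np.flatnonzero(breaks)
    a, b = pts[:-1], pts[1:]          # candidate segments [a, b)
    keep = sgn[a] != 0
    a, b = a[keep], b[keep]
    csum = np.concatenate([[0.0], np.cumsum(v)])
    bs = masked.layout.bin_size
    if support is None or len(a) == 0:
        max_support = np.zeros(len(a), dtype=np.int64)
    else:
        # interleaved reduceat: even slots reduce over [a_i, b_i)
        idx = np.empty(2 * len(a), dtype=np.int64)
        idx[0::2] = a
        idx[1::2] = b
        if idx[-1] == len(v):  # reduceat indices must be < len(v)
            idx = idx[:-1]
        max_support = np.maximum.reduceat(np.asarray(support), idx)[0::2].astype(
            np.int64
        )
    junc = masked.junctions
    if len(junc) and len(a):
        # a junction at index j separates positions j-1 and j
        cnt = np.searchsorted(junc, b, side="left") - np.searchsorted(
            junc, a + 1, side="left"
        )
        spans = cnt > 0
    else:
        spans = np.zeros(len(a), dtype=bool)
    return RunArrays(
        chrom_code=masked.chrom_index[a].astype(np.int64),
        start_bp=masked.start_bp[a].astype(np.int64),
        end_bp=(masked.start_bp[b - 1] + bs).astype(np.int64),
        sign=sgn[a].astype(np.int64),
        score=csum[b] - csum[a],
        max_support=max_support,
        spans_junction=spans,
        chrom_names=names,
    )


@dataclass
class ClusterArrays:
    """Column-oriented cluster records (output of the array fast path)."""

    chrom_code: np.ndarray
    start_bp: np.ndarray     # 0-based
    end_bp: np.ndarray       # half-open
    score: np.ndarray
    n_patients: np.ndarray
    sign: np.ndarray
    spans_junction: np.ndarray
    chrom_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.score)


def cluster_arrays(runs: RunArrays, d: float, r: float) -> ClusterArrays:
    """Array implementation of grouping/subgrouping/cluster selection.

    Runs sharing chromosome and sign merge into a group when the exclusive
    genomic gap is <= d, into a subgroup when <= r; each group's
    maximum-|score| subgroup (leftmost on ties) becomes a cluster.
    """
    if d < 0 or r < 0:
        raise ValueError("d and r must be >= 0")
    n = len(runs)
    names = runs.chrom_names
    if n == 0:
        z = np.zeros(0, dtype=np.int64)
        return ClusterArrays(z, z, z, z.astype(float), z, z, z.astype(bool), names)
    order = np.lexsort((runs.start_bp, runs.sign, runs.chrom_code))
    cc = runs.chrom_code[order]
    sg = runs.sign[order]
    start = runs.start_bp[order]
    end = runs.end_bp[order]
    score = runs.score[order]
    npat = runs.max_support[order]
    junc = runs.spans_junction[order]
    new_block = np.ones(n, dtype=bool)
    new_block[1:] = (cc[1:] != cc[:-1]) | (sg[1:] != sg[:-1])
    gap = np.empty(n, dtype=np.int64)
    gap[0] = 0
    gap[1:] = start[1:] - end[:-1]
    new_group = new_block | (gap > d)
    new_sub = new_group | (gap > r)
    gid = np.cumsum(new_group) - 1
    sub_first = np.flatnonzero(new_sub)
    sub_last = np.r_[sub_first[1:] - 1, n - 1]
    sub_score = np.add.reduceat(score, sub_first)
    sub_npat = np.maximum.reduceat(npat, sub_first)
    sub_junc = np.bitwise_or.reduceat(junc, sub_first)
    sub_gid = gid[sub_first]
    pos = np.arange(len(sub_first))
    sel_order = np.lexsort((pos, -np.abs(sub_score), sub_gid))
    _, first_of_group = np.unique(sub_gid[sel_order], return_index=True)
    best = sel_order[first_of_group]
    out_order = np.argsort(-np.abs(sub_score[best]), kind="stable")
    best = best[out_order]
    return ClusterArrays(
        chrom_code=cc[sub_first[best]],
        start_bp=start[sub_first[best]],
        end_bp=end[sub_last[best]],
        score=sub_score[best],
        n_patients=sub_npat[best],
        sign=sg[sub_first[best]],
        spans_junction=sub_junc[best],
        chrom_names=names,
    )


def _runs_to_arrays(runs: list[Run], chrom_names: tuple[str, ...]) -> RunArrays:
    code = {name: i for i, name in enumerate(chrom_names)}
    return RunArrays(
        chrom_code=np.array([code[x.chrom] for x in runs], dtype=np.int64),
        start_bp=np.array([x.start_bp for x in runs], dtype=np.int64),
        end_bp=np.array([x.end_bp for x in runs], dtype=np.int64),
        sign=np.array([x.sign for x in runs], dtype=np.int64),
        score=np.array([x.score for x in runs], dtype=np.float64),
        max_support=np.array([x.max_support for x in runs], dtype=np.int64),
        spans_junction=np.array([x.spans_junction for x in runs], dtype=bool),
        chrom_names=chrom_names,
    )


def clusters_from_arrays(ca: ClusterArrays) -> list[FocalCluster]:
    return [
        FocalCluster(
            chromosome=ca.chrom_names[int(ca.chrom_code[i])],
            start=int(ca.start_bp[i]) + 1,
            end=int(ca.end_bp[i]),
            score=float(ca.score[i]),
            n_patients=int(ca.n_patients[i]),
            sign=int(ca.sign[i]),
            spans_junction=bool(ca.spans_junction[i]),
        )
        for i in range(len(ca))
    ]


def group_and_cluster(
    runs: list[Run], d: float = 300_000, r: float = 300_000
) -> list[FocalCluster]:
    """Group same-sign runs at distance ``d``, subgroup at ``r``, and emit
    each group's maximum-|score| subgroup as a cluster.

    Opposite-sign runs never share a group; gaps are genomic end-to-start
    distances (exclusive), so runs on different chromosomes never merge.
    Ties on |score| go to the leftmost subgroup.  Reported coordinates are
    1-based inclusive at bin boundaries; output is |score|-descending.
    """
    if not runs:
        return []
    chrom_names = tuple(sorted({x.chrom for x in runs}))
    ca = cluster_arrays(_runs_to_arrays(runs, chrom_names), d, r)
    return clusters_from_arrays(ca)


def annotate_clusters(
    clusters: list[FocalCluster], genes: list[tuple[str, int, int, str]]
) -> list[FocalCluster]:
    """Attach names of genes overlapping each cluster by >= 1 bp.

    ``genes`` holds (chrom, start, end, name) with 0-based half-open
    coordinates (BED discipline); input order is preserved.
    """
    out = []
    for c in clusters:
        lo, hi = c.start - 1, c.end  # back to half-open
        hits = [
            name
            for chrom, s, e, name in genes
            if chrom == c.chromosome and s < hi and e > lo
        ]
        out.append(replace(c, genes=hits, p_values=dict(c.p_values)))
    return out
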