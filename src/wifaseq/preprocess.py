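"""Read counting, outlier winsorization, binning and log2-ratio tracks.

The depth-of-coverage proxy is deliberately simple: each aligned read
increments exactly one position, its leftmost mapped base.  Per-base counts
are winsorized inside a sliding window (spikes from collapsed repeats and
mapping artifacts), summed into fixed-width bins, and turned into a
chromosome-normalized tumor/normal log2 ratio

    y_i = log2( (Tumor_i / Tumor_chr) / (Normal_i / Normal_chr) )

which is invariant to per-chromosome library size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .genome import GenomeLayout

logger = logging.getLogger(__name__)


@dataclass
class BinnedCoverage:
    """Per-bin nonnegative read counts for one sample, aligned to a layout."""

    sample_id: str
    role: str  # "tumor" | "normal"
    counts: np.ndarray
    layout: GenomeLayout

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (self.layout.total_bins,):
            raise ValueError(
                f"counts length {self.counts.shape} does not match layout "
                f"({self.layout.total_bins} bins)"
            )
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        if self.role not in ("tumor", "normal"):
            raise ValueError(f"role must be tumor|normal, got {self.role!r}")

    @property
    def per_chromosome_totals(self) -> np.ndarray:
        """Total reads per chromosome, recomputed from the bin counts."""
        offs = self.layout.bin_offsets
        return np.add.reduceat(self.counts, offs[:-1])


@dataclass
class CopyRatioTrack:
    """Chromosome-normalized per-bin log2 tumor/normal ratio y_i.

    ``valid_mask`` is False where the ratio is undefined (zero tumor or
    normal count, zero chromosome totals) or where the bin falls in a masked
    region; ``log2_ratio`` is 0.0 at such bins so the array stays finite.
    """

    sample_id: str
    log2_ratio: np.ndarray
    valid_mask: np.ndarray
    layout: GenomeLayout

    def __post_init__(self) -> None:
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.log2_ratio.shape != self.valid_mask.shape:
            raise ValueError("ratio/mask length mismatch")
        if not np.isfinite(self.log2_ratio[self.valid_mask]).all():
            raise ValueError("non-finite ratio at a valid bin")


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def count_reads_per_base(
    alignment_source, layout: GenomeLayout
) -> dict[str, np.ndarray]:
    """Tally read starts per base, one vector per chromosome.

    ``alignment_source`` may be a path to a SAM/BAM file, an open
    :class:`pysam.AlignmentFile`, or an iterable of ``(chrom, pos0)`` pairs.
    Unmapped, secondary, supplementary and duplicate-flagged reads are
    skipped (tally logged); an unknown reference name is a hard error.
    """
    counts = {
        name: np.zeros(length, dtype=np.int64) for name, length in layout.chromosomes
    }
    skipped = 0
    if isinstance(alignment_source, str):
        import pysam

        with pysam.AlignmentFile(alignment_source, check_sq=False) as af:
            skipped = _count_pysam(af, counts)
    elif hasattr(alignment_source, "fetch") or hasattr(alignment_source, "head"):
        skipped = _count_pysam(alignment_source, counts)
    else:
        for chrom, pos in alignment_source:
            if chrom not in counts:
                raise ValueError(f"unknown reference name {chrom!r}")
            counts[chrom][pos] += 1
    if skipped:
        logger.info("count_reads_per_base: skipped %d reads", skipped)
    return counts


def _count_pysam(af, counts: dict[str, np.ndarray]) -> int:
    skipped = 0
    for read in af:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
        ):
            skipped += 1
            continue
        chrom = read.reference_name
        if chrom not in counts:
            raise ValueError(f"unknown reference name {chrom!r}")
        counts[chrom][read.reference_start] += 1
    return skipped


# ---------------------------------------------------------------------------
# outlier winsorization
# ---------------------------------------------------------------------------

def _window_quantiles(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Per-position quantile of the centered window [i-w//2, i-w//2+w) ∩ [0,n).

    The ``lower`` order-statistic quantile is used so that winsorizing is
    idempotent (the cap is an actual data value; capping never moves it).
    """
    n = len(x)
    half = window // 2
    out = np.empty(n, dtype=np.float64)
    lo_edge = half
    hi_edge = n - (window - half)  # last i with a full window
    # full interior windows, chunked to bound memory
    if hi_edge >= lo_edge:
        from numpy.lib.stride_tricks import sliding_window_view

        view = sliding_window_view(x, window)
        chunk = max(1, 20_000_000 // window)
        for a in range(0, hi_edge - lo_edge + 1, chunk):
            b = min(a + chunk, hi_edge - lo_edge + 1)
            out[lo_edge + a : lo_edge + b] = np.quantile(
                view[a:b], q, axis=1, method="lower"
            )
    for i in range(0, min(lo_edge, n)):
        out[i] = np.quantile(x[: min(n, i - half + window)], q, method="lower")
    for i in range(max(hi_edge + 1, 0), n):
        out[i] = np.quantile(x[max(0, i - half):], q, method="lower")
    return out


def remove_outliers(
    per_base_counts: np.ndarray | Mapping[str, np.ndarray],
    window: int = 200,
    quantile: float = 0.95,
) -> np.ndarray | dict[str, np.ndarray]:
    """Winsorize positions exceeding their sliding-window quantile.

    Values above the window's empirical quantile are replaced by that
    quantile (never deleted), so track length and count order are preserved
    and no count increases.  Capping one position can lower a neighboring
    window's quantile, so the pass is repeated until the track is a fixed
    point; the operation is therefore idempotent.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if isinstance(per_base_counts, Mapping):
        return {
            k: remove_outliers(v, window, quantile)
            for k, v in per_base_counts.items()
        }
    x = np.asarray(per_base_counts, dtype=np.float64)
    if len(x) == 0:
        return x.copy()
    if window > len(x):
        logger.warning(
            "outlier window (%d) longer than sequence (%d); using one window",
            window,
            len(x),
        )
        cap = np.quantile(x, quantile, method="lower")
        return np.minimum(x, cap)
    for _pass in range(20):
        capped = np.minimum(x, _window_quantiles(x, window, quantile))
        if np.array_equal(capped, x):
            break
        x = capped
    else:  # pragma: no cover - caps are data values, so this terminates fast
        logger.warning("winsorization did not stabilize after 20 passes")
    return x


# ---------------------------------------------------------------------------
# binning and log2 ratio
# ---------------------------------------------------------------------------

def bin_counts(
    per_base_counts: Mapping[str, np.ndarray],
    layout: GenomeLayout,
    sample_id: str = "sample",
    role: str = "tumor",
) -> BinnedCoverage:
    """Sum per-base counts into the layout's bins (mass-conserving)."""
    binned = np.zeros(layout.total_bins, dtype=np.float64)
    offs = layout.bin_offsets
    for ci, (name, length) in enumerate(layout.chromosomes):
        x = np.asarray(per_base_counts[name])
        if len(x) != length:
            raise ValueError(
                f"per-base counts for {name} have length {len(x)}, expected {length}"
            )
        edges = np.arange(0, length, layout.bin_size)
        binned[offs[ci] : offs[ci + 1]] = np.add.reduceat(
            x.astype(np.float64), edges
        )
    return BinnedCoverage(sample_id=sample_id, role=role, counts=binned, layout=layout)


def compute_log2_ratio(tumor: BinnedCoverage, normal: BinnedCoverage) -> CopyRatioTrack:
    """Chromosome-normalized log2 ratio track for one tumor/normal pair.

    Bins with a zero tumor or normal count are marked invalid rather than
    pseudocounted; extended sparse regions are the masking stage's job.
    """
    if tumor.layout is not normal.layout and tumor.layout != normal.layout:
        raise ValueError("tumor and normal must share the same layout")
    layout = tumor.layout
    t, n = tumor.counts, normal.counts
    t_chr = tumor.per_chromosome_totals
    n_chr = normal.per_chromosome_totals
    ratio = np.zeros(layout.total_bins)
    valid = (t > 0) & (n > 0)
    offs = layout.bin_offsets
    for ci, (name, _) in enumerate(layout.chromosomes):
        sl = slice(int(offs[ci]), int(offs[ci + 1]))
        if n_chr[ci] == 0 or t_chr[ci] == 0:
            logger.warning("chromosome %s has zero total reads; all bins invalid", name)
            valid[sl] = False
            continue
        v = valid[sl]
        ratio[sl][v] = np.log2(
            (t[sl][v] / t_chr[ci]) / (n[sl][v] / n_chr[ci])
        )
    valid &= layout.keep_mask()
    ratio[~valid] = 0.0
    return CopyRatioTrack(
        sample_id=tumor.sample_id, log2_ratio=ratio, valid_mask=valid, layout=layout
    )
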