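"""Masked concatenation and low-mapping region removal.

Reference 'N' gaps and regions where normal reads map only sparsely create
spurious apparent deletions.  Both are excluded from the analysis signal by
concatenating the remaining bins in genome order; positions that become
neighbors across a removed region are recorded as junctions so downstream
reports can flag clusters spanning one.

Low-mapping regions are found from the normal sample itself: the same
high-frequency wavelet procedure is run on the (median-centered) normal
count signal, maximal nonzero segments are collected, and a 1-D 2-means on
mean mapped reads per bp separates well-mapped from sparsely mapped
segments (the distribution is bimodal when the artifact is present).
Segments in the lower-mean class at least ``min_len`` bp long are masked,
and the analysis is repeated on the cleaned signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout, Interval

logger = logging.getLogger(__name__)


@dataclass
class MaskedSignal:
    """A per-bin signal over unmasked bins only, concatenated genome-wide.

    ``kept_bins`` are the global bin indices retained (strictly increasing),
    giving the exact bijection concatenated index <-> genomic bin.
    """

    values: np.ndarray
    kept_bins: np.ndarray      # global bin index per concatenated position
    chrom_index: np.ndarray    # chromosome ordinal per concatenated position
    start_bp: np.ndarray       # genomic bin start per concatenated position
    junctions: np.ndarray      # indices i>0 where position i-1, i not adjacent
    layout: GenomeLayout

    def __len__(self) -> int:
        return len(self.values)

    def to_genomic(self, idx: int) -> tuple[str, int]:
        """(chromosome, bin start bp) of concatenated position ``idx``."""
        return self.layout.names[int(self.chrom_index[idx])], int(self.start_bp[idx])

    def chrom_slice(self, chrom: str) -> slice:
        """Concatenated index range of one chromosome (contiguous by
        construction since concatenation preserves genome order)."""
        ci = self.layout.chrom_index(chrom)
        lo, hi = np.searchsorted(self.chrom_index, [ci, ci + 1])
        return slice(int(lo), int(hi))

    def with_values(self, values: np.ndarray) -> "MaskedSignal":
        if len(values) != len(self.values):
            raise ValueError("length mismatch")
        return MaskedSignal(
            values=np.asarray(values, dtype=np.float64),
            kept_bins=self.kept_bins,
            chrom_index=self.chrom_index,
            start_bp=self.start_bp,
            junctions=self.junctions,
            layout=self.layout,
        )


_GEOMETRY_CACHE: dict[tuple, tuple] = {}


def _geometry(layout: GenomeLayout) -> tuple:
    """Concatenation geometry, cached by layout content (the same layout is
    concatenated once per patient in a cohort run)."""
    key = (
        layout.chromosomes,
        layout.bin_size,
        tuple(sorted(layout.n_gaps.items())),
        tuple(sorted(layout.low_map_mask.items())),
    )
    if key not in _GEOMETRY_CACHE:
        keep = layout.keep_mask()
        kept = np.flatnonzero(keep)
        if len(kept) == 0:
            raise ValueError("all bins are masked; nothing to analyse")
        offs = layout.bin_offsets
        chrom_index = (np.searchsorted(offs, kept, side="right") - 1).astype(np.int32)
        start_bp = ((kept - offs[chrom_index]) * layout.bin_size).astype(np.int64)
        adjacent = (np.diff(kept) == 1) & (np.diff(chrom_index) == 0)
        junctions = np.flatnonzero(~adjacent) + 1
        if len(_GEOMETRY_CACHE) > 8:
            _GEOMETRY_CACHE.clear()
        _GEOMETRY_CACHE[key] = (kept, chrom_index, start_bp, junctions)
    return _GEOMETRY_CACHE[key]


def _concatenate(values: np.ndarray, layout: GenomeLayout) -> MaskedSignal:
    kept, chrom_index, start_bp, junctions = _geometry(layout)
    return MaskedSignal(
        values=np.asarray(values, dtype=np.float64)[kept],
        kept_bins=kept,
        chrom_index=chrom_index,
        start_bp=start_bp,
        junctions=junctions,
        layout=layout,
    )


def concatenate_unmasked(track, layout: GenomeLayout) -> MaskedSignal:
    """Concatenate a :class:`~wifaseq.preprocess.CopyRatioTrack` over
    unmasked bins.  Invalid bins that are not masked contribute 0 (neutral);
    extended invalid stretches are what the low-mapping mask removes."""
    vals = np.where(track.valid_mask, track.log2_ratio, 0.0)
    return _concatenate(vals, layout)


# ---------------------------------------------------------------------------
# low-mapping detection
# ---------------------------------------------------------------------------

def _kmeans_1d_two(x: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D 2-means: centers start at min/max, ties assign to
    the lower class.  Returns 0 for the lower-mean class, 1 for the upper."""
    c = np.array([x.min(), x.max()], dtype=float)
    labels = np.full(len(x), -1, dtype=np.int8)
    for _iteration in range(max_iter):
        # strict comparison: ties (equidistant points) go to the lower class
        new = (np.abs(x - c[1]) < np.abs(x - c[0])).astype(np.int8)
        if (new == labels).all():
            break
        labels = new
        for k in (0, 1):
            if (labels == k).any():
                c[k] = x[labels == k].mean()
    if c[0] > c[1]:
        labels = 1 - labels
    return labels


def signal_segments(masked: MaskedSignal) -> list[tuple[int, int]]:
    """Maximal runs of nonzero values, split at junctions and chromosome
    boundaries so every segment is genomically contiguous.  Returns
    (start, end) concatenated index pairs, end inclusive."""
    nz = masked.values != 0
    breaks = np.zeros(len(masked.values) + 1, dtype=bool)
    breaks[0] = breaks[-1] = True
    breaks[1:-1] = nz[1:] != nz[:-1]
    breaks[masked.junctions] = True
    pts = np.flatnonzero(breaks)
    return [
        (int(a), int(b - 1))
        for a, b in zip(pts[:-1], pts[1:])
        if nz[a]
    ]


def detect_low_mapping_segments(
    normal,
    params=None,
    k: int = 2,
    min_len: int = 3000,
) -> dict[str, list[Interval]]:
    """Find sparsely mapped regions from the normal sample's bin counts.

    Runs the high-frequency wavelet procedure on the median-centered normal
    count signal, collects maximal nonzero segments, clusters their mean
    mapped reads per bp with 2-means, and returns segments of the
    lower-mean class at least ``min_len`` bp long as genomic intervals.
    """
    from . import wavelet  # deferred: wavelet imports this module

    if k != 2:
        raise ValueError("only k=2 is supported")
    params = params or wavelet.WaveletParams()
    layout = normal.layout
    masked = _concatenate(normal.counts, layout)
    centered = masked.values - np.median(masked.values)
    y = wavelet.high_freq_values(centered, params)
    y_hat = wavelet.sign_filter(y, centered)
    segs = signal_segments(masked.with_values(y_hat))
    if not segs:
        return {}
    bs = layout.bin_size
    reads_per_bp = np.array(
        [masked.values[a : b + 1].sum() / ((b - a + 1) * bs) for a, b in segs]
    )
    if len(np.unique(reads_per_bp)) < 2:
        logger.warning("no bimodality in segment coverage; nothing masked")
        return {}
    labels = _kmeans_1d_two(reads_per_bp)
    out: dict[str, list[Interval]] = {}
    for (a, b), lab in zip(segs, labels):
        if lab != 0:
            continue
        length_bp = (b - a + 1) * bs
        if length_bp < min_len:
            continue
        chrom = layout.names[int(masked.chrom_index[a])]
        start = int(masked.start_bp[a])
        end = int(masked.start_bp[b]) + bs
        out.setdefault(chrom, []).append((start, min(end, layout.lengths[chrom])))
    return out


def two_pass_mask(
    track, normal, layout: GenomeLayout, params=None, min_len: int = 3000
) -> tuple[GenomeLayout, MaskedSignal]:
    """Detect low-mapping segments (pass 1), union them into the layout's
    mask, and re-concatenate the ratio track (pass 2).  The caller re-runs
    the wavelet transform on the returned signal."""
    segs = detect_low_mapping_segments(normal, params=params, min_len=min_len)
    layout2 = layout.with_low_map(segs) if segs else layout
    track2_valid = track.valid_mask & layout2.keep_mask()
    from .preprocess import CopyRatioTrack

    track2 = CopyRatioTrack(
        sample_id=track.sample_id,
        log2_ratio=np.where(track2_valid, track.log2_ratio, 0.0),
        valid_mask=track2_valid,
        layout=layout2,
    )
    return layout2, concatenate_unmasked(track2, layout2)
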