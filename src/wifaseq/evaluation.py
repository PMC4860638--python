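"""Evaluation constructs: the altered-segment filter and inspection-length
curves.

``classify_altered_segments`` is the "silver standard" filter applied to a
segmentation: a segment counts as a focal alteration when its mean |log2
ratio| is at least 0.4 and it spans at most 25% of its chromosome arm.
``inspection_length_curve`` quantifies how much genome a reviewer must walk
through, in score order, before each known driver gene is first hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentCall:
    """One segmented region with its mean log2 ratio (bp inclusive)."""

    chrom: str
    start: int
    end: int
    mean_log2: float
    arm: str = "p"
    arm_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")
        if self.arm_length is not None and self.arm_length <= 0:
            raise ValueError("arm_length must be > 0")


def classify_altered_segments(
    segments: Sequence[SegmentCall],
    min_abs_log2: float = 0.4,
    max_arm_fraction: float = 0.25,
) -> list[Optional[bool]]:
    """Flag segments that are focal alterations; ``None`` where the arm
    length is missing (segment skipped, with a warning)."""
    flags: list[Optional[bool]] = []
    for seg in segments:
        if seg.arm_length is None:
            logger.warning("segment %s:%d-%d has no arm length; skipped",
                           seg.chrom, seg.start, seg.end)
            flags.append(None)
            continue
        length = seg.end - seg.start + 1
        flags.append(
            abs(seg.mean_log2) >= min_abs_log2
            and length <= max_arm_fraction * seg.arm_length
        )
    return flags


def inspection_length_curve(
    regions: Sequence[tuple[str, int, int, float]],
    target_genes: Sequence[tuple[str, int, int, str]],
) -> pd.DataFrame:
    """Cumulative genome length inspected before each target gene is found.

    ``regions`` are (chrom, start, end, score) with 1-based inclusive
    coordinates; they are walked in |score|-descending order, accumulating
    lengths.  ``target_genes`` are BED-style (chrom, start, end, name),
    0-based half-open.  A gene is found at the first region overlapping it
    by >= 1 bp; duplicates count once.  Returns a frame with one row per
    newly found gene: gene, genes_found (running count), cumulative_bp.
    """
    order = sorted(regions, key=lambda x: -abs(x[3]))
    found: dict[str, int] = {}
    rows = []
    cum = 0
    for chrom, start, end, _score in order:
        cum += end - start + 1
        lo, hi = start - 1, end
        for gchrom, gs, ge, name in target_genes:
            if name in found:
                continue
            if gchrom == chrom and gs < hi and ge > lo:
                found[name] = cum
                rows.append({"gene": name, "genes_found": len(found), "cumulative_bp": cum})
    return pd.DataFrame(rows, columns=["gene", "genes_found", "cumulative_bp"])
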