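"""Genome layout: chromosome tiling into fixed-width bins and region masks.

The whole analysis runs on a concatenated, binned coordinate system.  A
:class:`GenomeLayout` owns the chromosome order, the bin width, and two sets
of masked genomic intervals: reference ``N`` gaps (centromeres,
heterochromatin) and low-mapping regions discovered by the masking stage.
Bins tile each chromosome left to right; a final partial bin is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based half-open bp


def _normalize_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosomes, bin size and masks, plus the bin-index coordinate system.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.  Order defines the concatenated
        genome order used everywhere downstream.
    bin_size
        Bin width in bp (default 100).
    n_gaps
        Per-chromosome reference 'N' intervals, 0-based half-open bp.
    low_map_mask
        Per-chromosome low-mapping intervals (filled by the masking stage).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = 100
    n_gaps: Mapping[str, Sequence[Interval]] = field(default_factory=dict)
    low_map_mask: Mapping[str, Sequence[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        if not chroms:
            raise ValueError("layout needs at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, l in chroms:
            if l <= 0:
                raise ValueError(f"chromosome {n} has non-positive length")
        object.__setattr__(self, "chromosomes", chroms)
        for attr in ("n_gaps", "low_map_mask"):
            raw = getattr(self, attr)
            norm = {}
            for name, ivs in raw.items():
                if name not in names:
                    raise ValueError(f"{attr} references unknown chromosome {name!r}")
                length = dict(chroms)[name]
                merged = _normalize_intervals(ivs)
                if merged and (merged[0][0] < 0 or merged[-1][1] > length):
                    raise ValueError(f"{attr} interval outside chromosome {name}")
                norm[name] = tuple(merged)
            object.__setattr__(self, attr, norm)

    # -- derived geometry ---------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def n_bins(self) -> np.ndarray:
        """Bins per chromosome (final partial bin kept)."""
        return np.array(
            [-(-l // self.bin_size) for _, l in self.chromosomes], dtype=np.int64
        )

    @property
    def bin_offsets(self) -> np.ndarray:
        """Global bin index of each chromosome's first bin, plus total."""
        return np.concatenate([[0], np.cumsum(self.n_bins)])

    @property
    def total_bins(self) -> int:
        return int(self.n_bins.sum())

    def chrom_index(self, name: str) -> int:
        return self.names.index(name)

    def bin_index(self, chrom: str, pos_bp: int) -> int:
        """Global bin index of the bin containing ``pos_bp`` on ``chrom``."""
        ci = self.chrom_index(chrom)
        if not 0 <= pos_bp < self.chromosomes[ci][1]:
            raise ValueError(f"position {pos_bp} outside {chrom}")
        return int(self.bin_offsets[ci] + pos_bp // self.bin_size)

    def bin_coords(self, global_idx: int) -> tuple[str, int]:
        """(chromosome, bin start bp) of a global bin index; round-trips
        exactly with :meth:`bin_index` for every bin."""
        offs = self.bin_offsets
        if not 0 <= global_idx < offs[-1]:
            raise IndexError(global_idx)
        ci = int(np.searchsorted(offs, global_idx, side="right") - 1)
        return self.names[ci], int((global_idx - offs[ci]) * self.bin_size)

    # -- masks --------------------------------------------------------------

    def _mask_bins(self, intervals: Mapping[str, Sequence[Interval]], out: np.ndarray) -> None:
        offs = self.bin_offsets
        nb = self.n_bins
        for name, ivs in intervals.items():
            ci = self.chrom_index(name)
            for s, e in ivs:
                first = s // self.bin_size
                last = (e - 1) // self.bin_size  # bins overlapping [s, e)
                last = min(last, int(nb[ci]) - 1)
                out[offs[ci] + first : offs[ci] + last + 1] = False

    def keep_mask(self) -> np.ndarray:
        """Boolean per-bin array: True for bins overlapping no masked interval."""
        keep = np.ones(self.total_bins, dtype=bool)
        self._mask_bins(self.n_gaps, keep)
        self._mask_bins(self.low_map_mask, keep)
        return keep

    def with_low_map(self, intervals: Mapping[str, Sequence[Interval]]) -> "GenomeLayout":
        """New layout with ``intervals`` unioned into the low-mapping mask.

        Masking is monotone: existing masked intervals are never removed.
        """
        merged = {k: list(v) for k, v in self.low_map_mask.items()}
        for name, ivs in intervals.items():
            merged.setdefault(name, []).extend(ivs)
        merged = {k: _normalize_intervals(v) for k, v in merged.items() if v}
        return replace(self, low_map_mask=merged)

    @classmethod
    def from_chrom_sizes(
        cls,
        path: str,
        bin_size: int = 100,
        n_gaps: Mapping[str, Sequence[Interval]] | None = None,
    ) -> "GenomeLayout":
        """Build a layout from a 2-column ``chrom<TAB>length`` text file."""
        chroms = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                name, length = line.split()[:2]
                chroms.append((name, int(length)))
        return cls(tuple(chroms), bin_size=bin_size, n_gaps=n_gaps or {})
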