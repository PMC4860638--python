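"""Text-format input/output: bedGraph, BED, chrom-sizes, cluster reports.

All genomic intervals in files are 0-based half-open (BED/bedGraph
discipline); coordinates are converted to 1-based inclusive only in the
final cluster report table.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import FocalCluster
from .genome import GenomeLayout, Interval
from .preprocess import BinnedCoverage

logger = logging.getLogger(__name__)


def read_bed(path: str, named: bool = False):
    """BED intervals; returns {chrom: [(start, end)]} or, with ``named``,
    a list of (chrom, start, end, name)."""
    out_map: dict[str, list[Interval]] = {}
    out_named: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {ln}") from exc
            if named:
                if len(parts) < 4:
                    raise ValueError(f"{path}: BED line {ln} lacks a name field")
                out_named.append((chrom, start, end, parts[3]))
            else:
                out_map.setdefault(chrom, []).append((start, end))
    return out_named if named else out_map


def write_bed(intervals: dict[str, Sequence[Interval]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in intervals.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bedgraph_counts(
    path: str, layout: GenomeLayout, sample_id: str, role: str
) -> BinnedCoverage:
    """Load a 4-column bedGraph of read counts into layout bins.

    Interval counts are assigned to bins by bp-overlap fraction, which is
    exact when intervals align with bin boundaries.
    """
    counts = np.zeros(layout.total_bins, dtype=np.float64)
    bs = layout.bin_size
    offs = layout.bin_offsets
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["chrom", "start", "end", "count"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "count": float},
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in layout.names:
            raise ValueError(f"{path}: unknown chromosome {chrom!r}")
        ci = layout.chrom_index(chrom)
        off = int(offs[ci])
        for start, end, value in zip(sub["start"], sub["end"], sub["count"]):
            first, last = start // bs, (end - 1) // bs
            if first == last:
                counts[off + first] += value
            else:
                for b in range(first, last + 1):
                    lo = max(start, b * bs)
                    hi = min(end, (b + 1) * bs)
                    counts[off + b] += value * (hi - lo) / (end - start)
    return BinnedCoverage(sample_id=sample_id, role=role, counts=counts, layout=layout)


def write_bedgraph(
    layout: GenomeLayout, values: np.ndarray, path: str, skip_zero: bool = True
) -> None:
    """Write one value per bin as bedGraph (0-based half-open)."""
    bs = layout.bin_size
    offs = layout.bin_offsets
    with open(path, "w") as fh:
        for ci, (name, length) in enumerate(layout.chromosomes):
            v = values[offs[ci] : offs[ci + 1]]
            for b in np.flatnonzero(v != 0) if skip_zero else range(len(v)):
                fh.write(
                    f"{name}\t{b * bs}\t{min((b + 1) * bs, length)}\t{v[b]:g}\n"
                )


def clusters_to_frame(clusters: Sequence[FocalCluster]) -> pd.DataFrame:
    """Cluster report table (1-based inclusive coordinates, |score| order)."""
    rows = []
    for c in sorted(clusters, key=lambda c: -abs(c.score)):
        row = {
            "Chr": c.chromosome,
            "Start": c.start,
            "End": c.end,
            "Score": round(c.score, 2),
            "Patients": c.n_patients,
        }
        for mode in sorted(c.p_values):
            row[f"P_FDC{mode}"] = round(c.p_values[mode], 4)
        row["Genes"] = "|".join(c.genes)
        row["SpansJunction"] = int(c.spans_junction)
        rows.append(row)
    return pd.DataFrame(rows)


def write_clusters_tsv(clusters: Sequence[FocalCluster], path: str) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def write_clusters_bed9(clusters: Sequence[FocalCluster], path: str) -> None:
    """BED9 with gains red, losses blue."""
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: -abs(c.score)):
            color = "200,0,0" if c.sign > 0 else "0,0,200"
            s, e = c.start - 1, c.end
            fh.write(
                f"{c.chromosome}\t{s}\t{e}\tscore={c.score:.2f}\t0\t.\t{s}\t{e}\t{color}\n"
            )
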