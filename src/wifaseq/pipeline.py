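"""End-to-end orchestration: ratio tracks -> masking -> per-sample wavelet
signals -> recurrence clustering -> permutation p-values."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import (
    FocalCluster,
    SumSignal,
    annotate_clusters,
    extract_runs,
    group_and_cluster,
    sum_samples,
)
from .genome import GenomeLayout
from .masking import detect_low_mapping_segments
from .preprocess import BinnedCoverage, compute_log2_ratio
from .significance import NullDistribution, attach_pvalues, build_null
from .wavelet import HighFreqSignal, WaveletParams, compute_sample_signal

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    layout: GenomeLayout
    signals: list[HighFreqSignal]
    sum_signal: SumSignal
    clusters: list[FocalCluster]
    null: NullDistribution | None = None


def run_pipeline(
    pairs: list[tuple[BinnedCoverage, BinnedCoverage]],
    params: WaveletParams | None = None,
    d: float = 300_000,
    r: float = 300_000,
    B: int = 1000,
    seed: int = 0,
    low_map_removal: bool = True,
    low_map_min_len: int = 3000,
    fdc_modes: tuple[int, ...] = (1, 2, 3, 4, 5),
    genes: list[tuple[str, int, int, str]] | None = None,
) -> PipelineResult:
    """Run the whole method on a cohort of (tumor, normal) coverage pairs.

    With ``low_map_removal`` the normal samples are first screened for
    sparse-mapping segments (wavelet pass on the normal counts + 2-means),
    the union over patients is masked, and the analysis re-runs on the
    cleaned layout.  Set ``B=0`` to skip significance testing.
    """
    if not pairs:
        raise ValueError("empty cohort")
    params = params or WaveletParams()
    layout = pairs[0][0].layout

    if low_map_removal:
        merged: dict[str, list] = {}
        for _, normal in pairs:
            for chrom, ivs in detect_low_mapping_segments(
                normal, params=params, min_len=low_map_min_len
            ).items():
                merged.setdefault(chrom, []).extend(ivs)
        if merged:
            logger.info(
                "low-mapping mask: %d intervals on %d chromosomes",
                sum(len(v) for v in merged.values()),
                len(merged),
            )
            layout = layout.with_low_map(merged)
            pairs = [
                (
                    BinnedCoverage(t.sample_id, "tumor", t.counts, layout),
                    BinnedCoverage(n.sample_id, "normal", n.counts, layout),
                )
                for t, n in pairs
            ]

    signals = [
        compute_sample_signal(compute_log2_ratio(t, n), layout, params)
        for t, n in pairs
    ]
    total = sum_samples(signals)
    clusters = group_and_cluster(extract_runs(total), d=d, r=r)
    null = None
    if B > 0 and clusters:
        null = build_null(signals, d=d, r=r, B=B, seed=seed)
        attach_pvalues(clusters, null, modes=fdc_modes)
    if genes:
        clusters = annotate_clusters(clusters, genes)
    return PipelineResult(
        layout=layout,
        signals=signals,
        sum_signal=total,
        clusters=clusters,
        null=null,
    )
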