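"""Permutation null and the five false-discovery-control p-value schemes.

The null hypothesis is that alterations arise independently across
patients: each patient's maximal nonzero runs (values kept intact, in
order) are reallocated uniformly at random, without overlap, within the
unmasked territory of their own chromosome; the relocated signals are
summed and clustered with the same distances ``d`` and ``r``, and this is
repeated ``B`` times (default 1000).  Observed clusters are then scored
against the resulting random clusters of the same sign on absolute score:

* FDC1 - exceedance of the per-permutation maximum |score|;
* FDC2 - as FDC1, restricted to random clusters no longer than the
  observed one;
* FDC3 - as FDC2, additionally restricted to random clusters supported by
  no more patients than the observed one;
* FDC4 - residual exceedance after a least-squares fit of |score| on
  length over all pooled random clusters;
* FDC5 - as FDC4 with patient count as a second covariate.

FDC1 is the most conservative; FDC2/3 discount long random clusters and
FDC4/5 regress score on its covariates, so the schemes are increasingly
permissive.

Placement uses the gap method: with runs kept in order, the free territory
is split by sorted uniform draws into random inter-run gaps.  This samples
a uniformly random non-overlapping arrangement in O(n) and stays exact at
realistic run counts (a single sample can carry thousands of runs), where
per-run rejection sampling degenerates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clustering import (
    FocalCluster,
    cluster_arrays,
    extract_run_arrays,
)
from .masking import MaskedSignal
from .wavelet import HighFreqSignal

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Random clusters from ``B`` independent reallocations."""

    B: int
    seed: int
    d: float
    r: float
    perm: np.ndarray       # permutation index per random cluster
    score: np.ndarray      # signed score
    length: np.ndarray     # bp
    n_patients: np.ndarray
    sign: np.ndarray


def _runs_of(values: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """(start, values) of each maximal nonzero run."""
    nz = values != 0
    if not nz.any():
        return []
    edges = np.flatnonzero(np.diff(np.r_[False, nz, False]))
    return [(int(a), values[a:b].copy()) for a, b in zip(edges[::2], edges[1::2])]


@dataclass
class _PackedRuns:
    """One patient's runs on one chromosome, flattened for fast placement."""

    offset: int            # concatenated index of the chromosome's start
    territory: int         # number of unmasked bins on the chromosome
    lengths: np.ndarray    # run lengths, genome order
    values: np.ndarray     # concatenated run values
    rel: np.ndarray        # within-flat offset of each value from its run start
    free: int              # territory - total run length

    @classmethod
    def pack(cls, values: np.ndarray, offset: int) -> "_PackedRuns | None":
        runs = _runs_of(values)
        if not runs:
            return None
        lengths = np.array([len(v) for _, v in runs], dtype=np.int32)
        flat = np.concatenate([v for _, v in runs])
        rel = np.arange(len(flat), dtype=np.int32) - np.repeat(
            np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int32), lengths
        )
        free = len(values) - int(lengths.sum())
        if free < 0:
            raise ValueError("runs exceed territory")
        return cls(
            offset=offset,
            territory=len(values),
            lengths=lengths,
            values=flat,
            rel=rel,
            free=free,
        )

    def random_indices(self, rng: np.random.Generator) -> np.ndarray:
        """Concatenated target index of every run value after reallocation.

        Placed runs keep at least one empty bin between them whenever the
        territory allows, so the multiset of runs (lengths and value sums)
        is conserved exactly rather than merging on adjacent placement.
        int32 indices: concatenated genomes stay far below 2^31 bins."""
        k = len(self.lengths)
        spacing = 1 if self.free >= k - 1 else 0
        slack = self.free - spacing * (k - 1)
        gaps_at = np.sort(rng.integers(0, slack + 1, size=k).astype(np.int32))
        base = np.concatenate([[0], np.cumsum(self.lengths)[:-1]]).astype(np.int32)
        starts = gaps_at + base + spacing * np.arange(k, dtype=np.int32)
        return np.int32(self.offset) + np.repeat(starts, self.lengths) + self.rel


def permute_patient(
    signal: HighFreqSignal | np.ndarray,
    rng: np.random.Generator,
    masked: MaskedSignal | None = None,
) -> np.ndarray:
    """Randomly reallocate one patient's nonzero runs within each
    chromosome's unmasked territory; all other positions are zero.  The
    multiset of run lengths and run value sums is conserved per
    chromosome."""
    if isinstance(signal, HighFreqSignal):
        values, masked = signal.y_high_filtered, signal.masked
    else:
        values = np.asarray(signal)
        if masked is None:
            raise ValueError("masked coordinates required for a bare array")
    out = np.zeros_like(values, dtype=np.float64)
    for chrom in masked.layout.names:
        sl = masked.chrom_slice(chrom)
        packed = _PackedRuns.pack(values[sl], sl.start)
        if packed is None:
            continue
        out[packed.random_indices(rng)] = packed.values
    return out


def build_null(
    signals: list[HighFreqSignal],
    d: float = 300_000,
    r: float = 300_000,
    B: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """B independent reallocations of every patient, summed and clustered
    with the observed ``d``/``r``; a pure function of its arguments."""
    if not signals:
        raise ValueError("no signals")
    masked = signals[0].masked
    n = len(masked)
    per_patient: list[list[_PackedRuns]] = []
    for sig in signals:
        entries = []
        for chrom in masked.layout.names:
            sl = masked.chrom_slice(chrom)
            packed = _PackedRuns.pack(sig.y_high_filtered[sl], sl.start)
            if packed is not None:
                entries.append(packed)
        per_patient.append(entries)
    rng = np.random.default_rng(seed)
    perm_l, score_l, len_l, npat_l, sign_l = [], [], [], [], []
    for b in range(B):
        total = np.zeros(n)
        support = np.zeros(n, dtype=np.int32)
        for entries in per_patient:
            for packed in entries:
                idx = packed.random_indices(rng)
                total[idx] += packed.values
                support[idx] += 1
        ca = cluster_arrays(extract_run_arrays(total, masked, support), d=d, r=r)
        k = len(ca)
        if k:
            perm_l.append(np.full(k, b, dtype=np.int64))
            score_l.append(ca.score)
            len_l.append(ca.end_bp - ca.start_bp)
            npat_l.append(ca.n_patients)
            sign_l.append(ca.sign)

    def cat(parts, dtype):
        return (
            np.concatenate(parts).astype(dtype)
            if parts
            else np.zeros(0, dtype=dtype)
        )

    return NullDistribution(
        B=B,
        seed=seed,
        d=d,
        r=r,
        perm=cat(perm_l, np.int64),
        score=cat(score_l, np.float64),
        length=cat(len_l, np.int64),
        n_patients=cat(npat_l, np.int64),
        sign=cat(sign_l, np.int64),
    )


def _perm_max_exceedance(
    null: NullDistribution, mask: np.ndarray, s_obs: float
) -> float:
    """Fraction of permutations whose max |score| over ``mask`` >= s_obs;
    permutations with no qualifying cluster count as non-exceedances."""
    maxima = np.full(null.B, -np.inf)
    np.maximum.at(maxima, null.perm[mask], np.abs(null.score[mask]))
    return float((maxima >= s_obs).sum() / null.B)


def fdc_pvalue(cluster: FocalCluster, null: NullDistribution, mode: int) -> float:
    """p-value of one observed cluster under one FDC scheme (1..5).

    Comparisons use random clusters of the same sign only, on absolute
    score.  FDC4/5 with fewer than 3 qualifying random clusters return NaN.
    """
    if mode not in (1, 2, 3, 4, 5):
        raise ValueError(f"mode must be 1..5, got {mode}")
    s_obs = abs(cluster.score)
    same_sign = null.sign == cluster.sign
    if mode == 1:
        return _perm_max_exceedance(null, same_sign, s_obs)
    if mode == 2:
        return _perm_max_exceedance(
            null, same_sign & (null.length <= cluster.length_bp), s_obs
        )
    if mode == 3:
        return _perm_max_exceedance(
            null,
            same_sign
            & (null.length <= cluster.length_bp)
            & (null.n_patients <= cluster.n_patients),
            s_obs,
        )
    # FDC4/5: residual exceedance over pooled same-sign random clusters
    idx = np.flatnonzero(same_sign)
    if len(idx) < 3:
        logger.warning("fewer than 3 random clusters; FDC%d undefined", mode)
        return float("nan")
    y = np.abs(null.score[idx])
    cols = [np.ones(len(idx)), null.length[idx].astype(float)]
    x_obs = [1.0, float(cluster.length_bp)]
    if mode == 5:
        cols.append(null.n_patients[idx].astype(float))
        x_obs.append(float(cluster.n_patients))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    e_obs = s_obs - float(np.asarray(x_obs) @ beta)
    return float((resid >= e_obs).sum() / len(idx))


def attach_pvalues(
    clusters: list[FocalCluster],
    null: NullDistribution,
    modes: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> list[FocalCluster]:
    for c in clusters:
        for mode in modes:
            c.p_values[mode] = fdc_pvalue(c, null, mode)
    return clusters


def significant_clusters(
    clusters: list[FocalCluster],
    null: NullDistribution | None = None,
    mode: int = 1,
    alpha: float = 0.1,
) -> list[FocalCluster]:
    """Clusters with p <= alpha under the chosen scheme, by |score| desc."""
    out = []
    for c in clusters:
        p = c.p_values.get(mode)
        if p is None:
            if null is None:
                raise ValueError("p-values absent and no null supplied")
            p = fdc_pvalue(c, null, mode)
            c.p_values[mode] = p
        if not np.isnan(p) and p <= alpha:
            out.append(c)
    out.sort(key=lambda c: -abs(c.score))
    return out
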