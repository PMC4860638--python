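"""Stationary Haar wavelet analysis of one sample's copy-ratio signal.

The transform is the undecimated (à trous) Haar analysis written with
average / half-difference filters: at step ``t`` with dilation ``h = 2^(t-1)``
and circular indexing over the extended signal,

    s_t[i] = (s_{t-1}[i] + s_{t-1}[i+h]) / 2
    w_t[i] = (s_{t-1}[i] - s_{t-1}[i+h]) / 2

so ``s_t[i]`` is the mean of ``2^t`` consecutive input values and ``w_t[i]``
is half the difference of two adjacent block means.  Detail coefficients are
hard-thresholded level by level with the universal threshold

    lambda_j = C * sigma_j * sqrt(2 ln n_j),    sigma_j = MAD(|w_j|) / 0.6745

and the high-frequency reconstruction ``y_HIGH`` is the branch-averaged
inverse with the coarsest scaling coefficients zeroed: it measures how a bin
differs from its neighborhood up to ``2^(J-M)`` bins, which is what makes a
focal alteration visible inside a broad arm-level one.  Because a step edge
always produces an opposite-signed lobe on its far side, positions whose
``y_HIGH`` sign disagrees with the local log2 ratio are zeroed, giving the
sign-consistent signal used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout
from .masking import MaskedSignal, concatenate_unmasked

MAD_TO_SIGMA = 0.6745  # Phi^{-1}(0.75): MAD of a Gaussian in sigma units

try:  # fused kernels; the numpy implementations below remain the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _analysis_kernel_into(x: np.ndarray, W: np.ndarray) -> None:
        n_levels, n = W.shape
        s = x.copy()
        sn = np.empty(n)
        for t in range(n_levels):
            h = 1 << t
            for i in range(n):
                j = i + h
                if j >= n:
                    j -= n
                a = s[i]
                b = s[j]
                W[t, i] = 0.5 * (a - b)
                sn[i] = 0.5 * (a + b)
            s, sn = sn, s

    @_njit(cache=True)
    def _threshold_level(W: np.ndarray, t: int, lam: float) -> None:
        for i in range(W.shape[1]):
            if abs(W[t, i]) <= lam:
                W[t, i] = 0.0

    @_njit(cache=True)
    def _inverse_kernel(scaling: np.ndarray, W: np.ndarray) -> np.ndarray:
        n_levels, n = W.shape
        s = scaling.copy()
        sn = np.empty(n)
        for t in range(n_levels - 1, -1, -1):
            h = 1 << t
            for i in range(n):
                j = i - h
                if j < 0:
                    j += n
                sn[i] = 0.5 * (s[i] + W[t, i]) + 0.5 * (s[j] - W[t, j])
            s, sn = sn, s
        return s.copy()

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class WaveletParams:
    """Decomposition depth and threshold settings.

    ``J`` is the exponent of the (extended) signal length, ``M`` the
    coarsest retained level, so ``J - M`` analysis steps are applied and the
    neighborhood scale is ``2^(J-M)`` bins (defaults 25/10: 32768 bins,
    ~3.3 Mb at 100-bp bins).  ``C`` multiplies the universal threshold.
    """

    J: int = 25
    M: int = 10
    C: float = 2.0

    def __post_init__(self) -> None:
        if not self.J > self.M >= 1:
            raise ValueError("require J > M >= 1")
        if self.C < 0:
            raise ValueError("C must be >= 0")

    @property
    def n_levels(self) -> int:
        return self.J - self.M


def params_for_genome(
    genome_bp: float,
    bin_size: int = 100,
    neighbor_bp: float = 3_000_000,
    C: float = 2.0,
) -> WaveletParams:
    """Derive (J, M) from genome size and the desired neighbor scale.

    ``J = ceil(log2(#bins))``; the number of analysis levels is
    ``ceil(log2(neighbor_bp / bin_size))`` and ``M = J - levels``.  For a
    3.2 Gbp genome at 100-bp bins and a 3 Mb neighborhood this gives
    J = 25, 15 levels, M = 10.
    """
    n_bins = math.ceil(genome_bp / bin_size)
    J = math.ceil(math.log2(n_bins))
    levels = math.ceil(math.log2(neighbor_bp / bin_size))
    return WaveletParams(J=J, M=J - levels, C=C)


@dataclass
class SWTCoefficients:
    """Per-level stationary-transform coefficients over the extended signal."""

    detail: list[np.ndarray]          # w_1 .. w_L (finest to coarsest step)
    scaling: np.ndarray               # s_L after the last step
    thresholds: list[float] = field(default_factory=list)
    thresholded: list[np.ndarray] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.detail)


@dataclass
class HighFreqSignal:
    """Per-bin y_HIGH and sign-filtered signal for one sample, in
    concatenated (masked) coordinates."""

    sample_id: str
    y_high: np.ndarray
    y_high_filtered: np.ndarray
    masked: MaskedSignal
    params: WaveletParams


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def symmetric_extend(signal: np.ndarray, target_length: int) -> np.ndarray:
    """Extend to ``target_length`` by tiling mirror-reflected copies.

    ``[1,2,3] -> [1,2,3, 3,2,1, 1,2]`` for target 8.  The original occupies
    offset 0, so cropping to ``len(signal)`` undoes the extension.
    """
    x = np.asarray(signal, dtype=np.float64)
    n = len(x)
    if target_length < n:
        raise ValueError("target_length shorter than signal")
    if target_length & (target_length - 1):
        raise ValueError("target_length must be a power of two")
    if target_length == n:
        return x.copy()
    reps = -(-target_length // n)
    tiles = [x if i % 2 == 0 else x[::-1] for i in range(reps)]
    return np.concatenate(tiles)[:target_length]


def haar_swt(signal: np.ndarray, n_levels: int) -> SWTCoefficients:
    """Stationary Haar analysis: ``n_levels`` average/half-difference steps
    with circular indexing.  Requires a power-of-two length >= 2^n_levels."""
    x = np.asarray(signal, dtype=np.float64)
    n = len(x)
    if n < 2 or n & (n - 1):
        raise ValueError("signal length must be a power of two >= 2")
    if 2 ** n_levels > n:
        raise ValueError(f"{n_levels} levels need length >= {2 ** n_levels}")
    s = x.copy()
    details: list[np.ndarray] = []
    for t in range(1, n_levels + 1):
        h = 1 << (t - 1)
        sr = np.roll(s, -h)
        details.append(0.5 * (s - sr))
        s = 0.5 * (s + sr)
    return SWTCoefficients(detail=details, scaling=s)


def inverse_swt(scaling: np.ndarray, details: list[np.ndarray]) -> np.ndarray:
    """Branch-averaged inverse of :func:`haar_swt`.

    Each coarse position yields two estimates of the finer scaling signal
    (from the branch starting at ``i`` and the one starting at ``i - h``);
    averaging them is the shift-correction of the à trous inverse and gives
    exact reconstruction when the coefficients are untouched.
    """
    s = np.asarray(scaling, dtype=np.float64).copy()
    for t in range(len(details), 0, -1):
        h = 1 << (t - 1)
        w = details[t - 1]
        est_a = s + w
        est_b = np.roll(s - w, h)
        s = 0.5 * (est_a + est_b)
    return s


def estimate_level_threshold(detail_level: np.ndarray, C: float) -> float:
    """Universal threshold ``C * sigma * sqrt(2 ln n)`` with a MAD noise
    scale estimated from the level's own coefficients."""
    w = np.asarray(detail_level)
    n = len(w)
    if n < 1:
        raise ValueError("empty coefficient level")
    sigma = np.median(np.abs(w)) / MAD_TO_SIGMA
    if sigma == 0.0:
        return 0.0
    return float(C * sigma * math.sqrt(2.0 * math.log(n)))


def hard_threshold(detail: np.ndarray, lam: float) -> np.ndarray:
    """Zero coefficients with ``|w| <= lam`` (non-strict); pass the rest."""
    if lam < 0:
        raise ValueError("threshold must be >= 0")
    w = np.asarray(detail)
    return np.where(np.abs(w) > lam, w, 0.0)


def reconstruct_y_high(coeffs: SWTCoefficients) -> np.ndarray:
    """Inverse transform with the coarsest scaling zeroed and thresholded
    details retained; the low-frequency trend is discarded so only
    neighborhood differences up to ``2^L`` bins survive."""
    details = coeffs.thresholded if coeffs.thresholded else coeffs.detail
    return inverse_swt(np.zeros_like(coeffs.scaling), details)


def sign_filter(y_high: np.ndarray, log2_ratio: np.ndarray) -> np.ndarray:
    """Zero positions where y_HIGH and the log2 ratio disagree in sign.

    A true copy-number step always throws an opposite-signed y_HIGH lobe
    onto its unaltered side; requiring sign agreement with the raw ratio
    removes those artifacts.
    """
    y = np.asarray(y_high, dtype=np.float64)
    r = np.asarray(log2_ratio, dtype=np.float64)
    if y.shape != r.shape:
        raise ValueError("length mismatch")
    return np.where(y * r > 0, y, 0.0)


# ---------------------------------------------------------------------------
# per-sample orchestration
# ---------------------------------------------------------------------------

def threshold_coefficients(coeffs: SWTCoefficients, C: float) -> SWTCoefficients:
    """Hard-threshold every level with its own universal threshold."""
    coeffs.thresholds = [estimate_level_threshold(w, C) for w in coeffs.detail]
    coeffs.thresholded = [
        hard_threshold(w, lam) for w, lam in zip(coeffs.detail, coeffs.thresholds)
    ]
    return coeffs


def high_freq_values(values: np.ndarray, params: WaveletParams) -> np.ndarray:
    """y_HIGH for a bare concatenated signal: extend to the next power of
    two, analyse, threshold, reconstruct, crop to the original range.

    Uses fused kernels when numba is importable; numerically identical to
    the :func:`haar_swt` / :func:`reconstruct_y_high` reference path.
    """
    n = len(values)
    if n < 2:
        raise ValueError("signal too short")
    target = 1 << math.ceil(math.log2(n))
    ext = symmetric_extend(values, target)
    n_levels = min(params.n_levels, int(math.log2(target)))
    if not _HAVE_NUMBA:  # pragma: no cover
        coeffs = haar_swt(ext, n_levels)
        threshold_coefficients(coeffs, params.C)
        return reconstruct_y_high(coeffs)[:n]
    W = _coeff_buffer(n_levels, target)
    _analysis_kernel_into(ext, W)
    ln_term = math.sqrt(2.0 * math.log(target))
    buf = np.empty(target)
    mid = target // 2
    for t in range(n_levels):
        np.abs(W[t], out=buf)
        buf.partition([mid - 1, mid])
        med = 0.5 * (buf[mid - 1] + buf[mid])
        lam = params.C * (med / MAD_TO_SIGMA) * ln_term
        _threshold_level(W, t, lam)
    return _inverse_kernel(np.zeros(target), W)[:n]


_BUFFERS: dict[tuple[int, int], np.ndarray] = {}


def _coeff_buffer(n_levels: int, n: int) -> np.ndarray:
    """Reusable detail-coefficient workspace (large and short-lived)."""
    key = (n_levels, n)
    if key not in _BUFFERS:
        _BUFFERS.clear()  # keep at most one large workspace alive
        _BUFFERS[key] = np.empty((n_levels, n))
    return _BUFFERS[key]


def compute_sample_signal(
    track, layout: GenomeLayout, params: WaveletParams | None = None
) -> HighFreqSignal:
    """Full per-sample chain: concatenate unmasked bins, transform,
    threshold, reconstruct and sign-filter against the log2 ratio."""
    params = params or WaveletParams()
    masked = concatenate_unmasked(track, layout)
    y = high_freq_values(masked.values, params)
    y_hat = sign_filter(y, masked.values)
    return HighFreqSignal(
        sample_id=track.sample_id,
        y_high=y,
        y_high_filtered=y_hat,
        masked=masked,
        params=params,
    )
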