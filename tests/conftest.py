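"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from wifaseq.genome import GenomeLayout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_layout():
    """Two tiny chromosomes, bin 100 bp, one N-gap on chr1."""
    return GenomeLayout(
        chromosomes=(("chr1", 2000), ("chr2", 1500)),
        bin_size=100,
        n_gaps={"chr1": [(800, 1000)]},
    )


# ---------------------------------------------------------------------------
# oracles (deliberately naive, independent of the package's implementations)
# ---------------------------------------------------------------------------

def sliding_quantile_oracle(x, window, q):
    """Per-position 'lower' quantile of the centered truncated window."""
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i - half + window)
        out[i] = np.quantile(x[lo:hi], q, method="lower")
    return out


def block_mean_oracle(x, t):
    """Stationary Haar scaling signal at step t: circular mean of 2^t
    consecutive values."""
    n = len(x)
    return np.array([np.mean([x[(i + k) % n] for k in range(2**t)]) for i in range(n)])


def swt_detail_oracle(x, t):
    """Detail coefficients at step t: half the difference of adjacent
    block means."""
    s_prev = block_mean_oracle(x, t - 1)
    h = 2 ** (t - 1)
    return 0.5 * (s_prev - np.roll(s_prev, -h))


def brute_force_clusters(runs, d, r):
    """Exhaustive grouping oracle on (chrom, start, end, sign, score,
    support) tuples; end half-open.  Returns a set of cluster summaries
    (chrom, start, end, round(score, 6), n_patients, sign)."""
    out = set()
    keys = {(c, s) for c, _, _, s, _, _ in runs}
    for chrom, sign in keys:
        part = sorted(x for x in runs if x[0] == chrom and x[3] == sign)
        # transitive closure of "gap <= d" by pairwise merging
        groups = [[x] for x in part]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if any(
                        max(a[1], b[1]) - min(a[2], b[2]) <= d
                        for a in groups[i]
                        for b in groups[j]
                    ):
                        groups[i] += groups.pop(j)
                        changed = True
                        break
                if changed:
                    break
        for group in groups:
            group.sort()
            subs = [[group[0]]]
            for x in group[1:]:
                if x[1] - subs[-1][-1][2] <= r:
                    subs[-1].append(x)
                else:
                    subs.append([x])
            scores = [sum(x[4] for x in sg) for sg in subs]
            best = int(np.argmax(np.abs(scores)))
            sg = subs[best]
            out.add(
                (
                    chrom,
                    sg[0][1],
                    sg[-1][2],
                    round(scores[best], 6),
                    max(x[5] for x in sg),
                    sign,
                )
            )
    return out
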