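import numpy as np
import pytest

from wifaseq.clustering import (
    Run,
    count_sign_segments,
    annotate_clusters,
    cluster_arrays,
    extract_run_arrays,
    extract_runs,
    group_and_cluster,
    sum_samples,
    SumSignal,
    _runs_to_arrays,
    clusters_from_arrays,
)
from wifaseq.genome import GenomeLayout
from wifaseq.masking import _concatenate
from wifaseq.wavelet import HighFreqSignal, WaveletParams

from conftest import brute_force_clusters


def _masked(n_bins_per_chrom=(50,), bin_size=100):
    chroms = tuple(
        (f"chr{i+1}", n * bin_size) for i, n in enumerate(n_bins_per_chrom)
    )
    lay = GenomeLayout(chroms, bin_size=bin_size)
    return _concatenate(np.zeros(lay.total_bins), lay)


def _signal(values, masked):
    return HighFreqSignal(
        sample_id="s",
        y_high=np.asarray(values, float),
        y_high_filtered=np.asarray(values, float),
        masked=masked,
        params=WaveletParams(),
    )


def _sum(values, masked, support=None):
    v = np.asarray(values, float)
    if support is None:
        support = (v != 0).astype(np.int32)
    return SumSignal(values=v, support=np.asarray(support, np.int32), n_samples=1, masked=masked)


class TestSumSamples:
    def test_single_sample_identity(self):
        m = _masked((10,))
        v = np.r_[np.zeros(3), [1.0, 2.0], np.zeros(5)]
        s = sum_samples([_signal(v, m)])
        assert np.array_equal(s.values, v)
        assert np.array_equal(s.support, v != 0)

    def test_two_identical_samples_double(self):
        m = _masked((10,))
        v = np.r_[np.zeros(3), [1.0, -2.0], np.zeros(5)]
        s = sum_samples([_signal(v, m), _signal(v, m)])
        assert np.array_equal(s.values, 2 * v)
        assert s.support.max() == 2

    def test_order_invariant(self, rng):
        m = _masked((20,))
        sigs = [_signal(rng.choice([0, 0, 1, -1], 20) * rng.random(20), m) for _ in range(4)]
        a = sum_samples(sigs)
        b = sum_samples(sigs[::-1])
        assert np.allclose(a.values, b.values, atol=1e-12)
        assert np.array_equal(a.support, b.support)

    def test_layout_mismatch_is_hard_error(self):
        a, b = _masked((10,)), _masked((12,))
        with pytest.raises(ValueError):
            sum_samples([_signal(np.zeros(10), a), _signal(np.zeros(12), b)])


class TestExtractRuns:
    def test_example(self):
        m = _masked((6,))
        runs = extract_runs(_sum([0, 1, 1, -1, 0, 2], m))
        assert [(x.start_idx, x.end_idx, x.sign) for x in runs] == [
            (1, 2, 1),
            (3, 3, -1),
            (5, 5, 1),
        ]
        assert runs[0].score == 2.0
        assert runs[0].start_bp == 100 and runs[0].end_bp == 300

    def test_all_zeros(self):
        m = _masked((6,))
        assert extract_runs(_sum(np.zeros(6), m)) == []

    def test_runs_split_at_chromosome_boundary(self):
        m = _masked((3, 3))
        runs = extract_runs(_sum([0, 1, 1, 1, 1, 0], m))
        assert len(runs) == 2
        assert runs[0].chrom == "chr1" and runs[1].chrom == "chr2"

    def test_object_and_array_paths_agree(self, rng):
        m = _masked((40, 30))
        v = rng.choice([0.0, 0, 1, -1], 70) * rng.random(70)
        support = rng.integers(0, 5, 70).astype(np.int32)
        ss = _sum(v, m, support)
        runs = extract_runs(ss)
        ra = extract_run_arrays(v, m, support)
        assert len(runs) == len(ra)
        for i, x in enumerate(runs):
            assert x.start_bp == ra.start_bp[i]
            assert x.end_bp == ra.end_bp[i]
            assert x.sign == ra.sign[i]
            assert x.score == pytest.approx(ra.score[i])
            assert x.max_support == ra.max_support[i]


class TestCountSignSegments:
    @pytest.mark.parametrize(
        "sig,n",
        [([0, 1, 1, -1, 0, 2], 3), ([0, 0], 0), ([1, -1, 1, -1], 4), ([], 0)],
    )
    def test_examples(self, sig, n):
        assert count_sign_segments(np.array(sig, float)) == n

    def test_concatenation_additivity(self, rng):
        a = rng.choice([0.0, 1, -1], 30)
        b = rng.choice([0.0, 1, -1], 30)
        joined = np.r_[a, [0.0], b]
        assert count_sign_segments(joined) == count_sign_segments(a) + count_sign_segments(b)


def _mk_run(chrom, start_bp, end_bp, sign, score, support=1):
    return Run(
        chrom=chrom,
        start_idx=0,
        end_idx=0,
        start_bp=start_bp,
        end_bp=end_bp,
        sign=sign,
        score=score,
        max_support=support,
    )


class TestGroupAndCluster:
    def test_single_isolated_run(self):
        runs = [_mk_run("c", 1000, 2000, 1, 5.0, 3)]
        (c,) = group_and_cluster(runs, d=500, r=500)
        assert (c.start, c.end, c.score, c.n_patients) == (1001, 2000, 5.0, 3)

    def test_two_distant_runs_two_clusters(self):
        runs = [
            _mk_run("c", 0, 1000, 1, 5.0),
            _mk_run("c", 10_000, 11_000, 1, 3.0),
        ]
        assert len(group_and_cluster(runs, d=500, r=500)) == 2

    def test_opposite_signs_never_merge(self):
        runs = [
            _mk_run("c", 0, 1000, 1, 5.0),
            _mk_run("c", 1100, 2000, -1, -3.0),
        ]
        assert len(group_and_cluster(runs, d=5000, r=5000)) == 2

    def test_subgroup_with_max_abs_score_wins(self):
        # one group (gaps <= d) with two subgroups (gap > r between them)
        runs = [
            _mk_run("c", 0, 1000, 1, 2.0, 1),
            _mk_run("c", 1100, 2000, 1, 2.5, 2),
            _mk_run("c", 4000, 5000, 1, 3.0, 1),
        ]
        (c,) = group_and_cluster(runs, d=3000, r=500)
        assert (c.start, c.end) == (1, 2000)
        assert c.score == pytest.approx(4.5)
        assert c.n_patients == 2

    def test_leftmost_wins_score_ties(self):
        runs = [
            _mk_run("c", 0, 1000, 1, 3.0),
            _mk_run("c", 5000, 6000, 1, 3.0),
        ]
        (c,) = group_and_cluster(runs, d=10_000, r=500)
        assert c.start == 1

    def test_zero_distances_degenerate_to_runs(self):
        runs = [
            _mk_run("c", 0, 1000, 1, 5.0),
            _mk_run("c", 1001, 2000, 1, 3.0),
            _mk_run("c", 3000, 4000, -1, -4.0),
        ]
        out = group_and_cluster(runs, d=0, r=0)
        assert len(out) == 3

    def test_score_recomputable_from_sum_signal(self, rng):
        m = _masked((100,))
        v = rng.choice([0.0, 0, 1, -1], 100) * rng.random(100)
        ss = _sum(v, m)
        for c in group_and_cluster(extract_runs(ss), d=300, r=300):
            span = v[(c.start - 1) // 100 : c.end // 100]
            same_sign = span[np.sign(span) == c.sign]
            assert c.score == pytest.approx(same_sign.sum())

    def test_monotone_in_d(self, rng):
        runs = [
            _mk_run("c", s, s + 50, 1, float(sc))
            for s, sc in zip(sorted(rng.choice(10_000, 30, replace=False) * 10), rng.random(30) + 0.1)
        ]
        counts = [len(group_and_cluster(runs, d=d, r=0)) for d in (0, 100, 1000, 10_000)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_matches_brute_force_oracle(self, rng):
        """Randomized instances against an exhaustive O(n^2) grouping
        oracle."""
        for _ in range(50):
            n = rng.integers(1, 30)
            starts = np.sort(rng.choice(100_000, n, replace=False))
            runs = []
            tuples = []
            prev_end = -1
            for s in starts:
                start = max(int(s), prev_end + 1)
                end = start + int(rng.integers(1, 500))
                prev_end = end
                sign = int(rng.choice([-1, 1]))
                score = sign * float(rng.random() + 0.05)
                supp = int(rng.integers(1, 6))
                runs.append(_mk_run("c", start, end, sign, score, supp))
                tuples.append(("c", start, end, sign, score, supp))
            d = float(rng.choice([0, 100, 1000, 5000]))
            r = float(rng.choice([0, 100, 1000, 5000]))
            got = {
                (c.chromosome, c.start - 1, c.end, round(c.score, 6), c.n_patients, c.sign)
                for c in group_and_cluster(runs, d=d, r=r)
            }
            assert got == brute_force_clusters(tuples, d, r)


class TestAnnotate:
    def _cluster(self, start, end):
        runs = [_mk_run("c", start - 1, end, 1, 1.0)]
        return group_and_cluster(runs, d=0, r=0)

    def test_exact_cover(self):
        out = annotate_clusters(self._cluster(101, 200), [("c", 100, 200, "GENE")])
        assert out[0].genes == ["GENE"]

    def test_no_overlap(self):
        out = annotate_clusters(self._cluster(101, 200), [("c", 300, 400, "GENE")])
        assert out[0].genes == []

    def test_adjacent_not_overlapping(self):
        # gene ends exactly where the cluster starts (half-open discipline)
        out = annotate_clusters(self._cluster(101, 200), [("c", 0, 100, "GENE")])
        assert out[0].genes == []
        out = annotate_clusters(self._cluster(101, 200), [("c", 0, 101, "GENE")])
        assert out[0].genes == ["GENE"]
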