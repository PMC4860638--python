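import numpy as np
import pytest

from wifaseq.clustering import FocalCluster
from wifaseq.genome import GenomeLayout
from wifaseq.masking import _concatenate
from wifaseq.pipeline import run_pipeline
from wifaseq.significance import (
    NullDistribution,
    build_null,
    fdc_pvalue,
    permute_patient,
    significant_clusters,
)
from wifaseq.simulate import CNAEvent, SimulationSpec, simulate_cohort
from wifaseq.wavelet import HighFreqSignal, WaveletParams


def _masked(n_bins_per_chrom=(50,), bin_size=100):
    chroms = tuple((f"chr{i+1}", n * bin_size) for i, n in enumerate(n_bins_per_chrom))
    lay = GenomeLayout(chroms, bin_size=bin_size)
    return _concatenate(np.zeros(lay.total_bins), lay)


def _signal(values, masked):
    return HighFreqSignal("s", np.asarray(values, float), np.asarray(values, float), masked, WaveletParams())


def _cluster(score, length_bp=1000, n_patients=2):
    sign = 1 if score > 0 else -1
    return FocalCluster("chr1", 1, length_bp, score, n_patients, sign)


def _null(scores, lengths, npats, B=1000, perms=None):
    scores = np.asarray(scores, float)
    return NullDistribution(
        B=B,
        seed=0,
        d=0,
        r=0,
        perm=np.asarray(perms if perms is not None else np.arange(len(scores))),
        score=scores,
        length=np.asarray(lengths),
        n_patients=np.asarray(npats),
        sign=np.sign(scores).astype(int),
    )


class TestPermutePatient:
    def test_all_zero_stays_zero(self, rng):
        m = _masked((30,))
        out = permute_patient(_signal(np.zeros(30), m), rng)
        assert not out.any()

    def test_full_chromosome_run_is_identity(self, rng):
        m = _masked((10,))
        v = np.arange(1.0, 11.0)
        out = permute_patient(_signal(v, m), rng)
        assert np.array_equal(out, v)

    def test_conservation_over_seeded_permutations(self, rng):
        """Multiset of run lengths and run value sums is conserved per
        chromosome across 100 seeded reallocations."""
        m = _masked((60, 40))
        v = np.zeros(100)
        v[3:10] = 1.5
        v[20:22] = -0.5
        v[45:52] = 2.0
        v[70:75] = -1.0  # chr2
        sig = _signal(v, m)

        def run_summary(values, lo, hi):
            x = values[lo:hi]
            nz = x != 0
            edges = np.flatnonzero(np.diff(np.r_[False, nz, False]))
            return sorted(
                (b - a, round(x[a:b].sum(), 9)) for a, b in zip(edges[::2], edges[1::2])
            )

        expected_chr1 = run_summary(v, 0, 60)
        expected_chr2 = run_summary(v, 60, 100)
        for seed in range(100):
            out = permute_patient(sig, np.random.default_rng(seed))
            assert run_summary(out, 0, 60) == expected_chr1
            assert run_summary(out, 60, 100) == expected_chr2

    def test_runs_never_cross_chromosomes(self):
        m = _masked((20, 20))
        v = np.zeros(40)
        v[5:15] = 1.0
        for seed in range(20):
            out = permute_patient(_signal(v, m), np.random.default_rng(seed))
            assert not out[20:].any()


class TestBuildNull:
    def test_all_zero_patients_give_empty_null(self):
        m = _masked((30,))
        null = build_null([_signal(np.zeros(30), m)], B=5, seed=0)
        assert len(null.score) == 0

    def test_same_seed_reproduces_exactly(self):
        m = _masked((200,))
        v = np.zeros(200)
        v[10:30] = 1.0
        v[100:105] = -2.0
        sigs = [_signal(v, m), _signal(np.roll(v, 7), m)]
        a = build_null(sigs, B=20, seed=42)
        b = build_null(sigs, B=20, seed=42)
        for field in ("perm", "score", "length", "n_patients", "sign"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_shared_locus_beats_null(self):
        """A run shared by many patients at one locus scores above the
        null's maxima when each patient carries little else."""
        m = _masked((500,))
        v = np.zeros(500)
        v[200:210] = 1.0
        sigs = [_signal(v, m) for _ in range(8)]
        null = build_null(sigs, B=100, seed=1, d=0, r=0)
        obs = _cluster(8.0 * 10, length_bp=1000, n_patients=8)
        assert fdc_pvalue(obs, null, 1) <= 0.05


class TestFdcPvalues:
    def test_above_every_maximum(self):
        null = _null([1.0] * 10, [100] * 10, [1] * 10, B=10)
        assert fdc_pvalue(_cluster(5.0), null, 1) == 0.0

    def test_below_every_maximum(self):
        null = _null([10.0] * 10, [100] * 10, [1] * 10, B=10)
        assert fdc_pvalue(_cluster(5.0), null, 1) == 1.0

    def test_fifty_of_thousand(self):
        """50 permutation maxima exceeding the observed score give p=0.05."""
        scores = np.r_[np.full(50, 9.0), np.full(950, 1.0)]
        null = _null(scores, [100] * 1000, [1] * 1000, B=1000)
        assert fdc_pvalue(_cluster(5.0), null, 1) == pytest.approx(0.05)

    def test_sign_separation(self):
        null = _null([-9.0] * 10, [100] * 10, [1] * 10, B=10)
        # positive cluster compared only against positive random clusters
        assert fdc_pvalue(_cluster(5.0), null, 1) == 0.0

    def test_length_filter_counts_non_exceedance(self):
        null = _null([9.0] * 10, [5000] * 10, [1] * 10, B=10)
        c = _cluster(5.0, length_bp=1000)
        assert fdc_pvalue(c, null, 1) == 1.0
        assert fdc_pvalue(c, null, 2) == 0.0  # no short random clusters

    def test_mode45_needs_three_clusters(self):
        null = _null([1.0, 2.0], [100, 200], [1, 1], B=2)
        assert np.isnan(fdc_pvalue(_cluster(5.0), null, 4))

    def test_nesting_on_constructed_null(self, rng):
        scores = rng.random(500) * 10
        null = _null(
            scores,
            rng.integers(100, 10_000, 500),
            rng.integers(1, 10, 500),
            B=100,
            perms=rng.integers(0, 100, 500),
        )
        for _ in range(50):
            c = _cluster(
                float(rng.random() * 10),
                length_bp=int(rng.integers(100, 10_000)),
                n_patients=int(rng.integers(1, 10)),
            )
            p1, p2, p3 = (fdc_pvalue(c, null, m) for m in (1, 2, 3))
            assert p3 <= p2 <= p1

    def test_invalid_mode(self):
        null = _null([1.0], [100], [1], B=1)
        with pytest.raises(ValueError):
            fdc_pvalue(_cluster(1.0), null, 6)


class TestSignificantClusters:
    def test_alpha_bounds(self):
        null = _null([1.0] * 4, [100] * 4, [1] * 4, B=4)
        clusters = [_cluster(5.0), _cluster(0.5)]
        assert len(significant_clusters(clusters, null, 1, alpha=1.0)) == 2
        assert [c.score for c in significant_clusters(clusters, null, 1, alpha=0.0)] == [5.0]

    def test_sorted_by_abs_score(self):
        null = _null([0.1] * 4, [100] * 4, [1] * 4, B=4)
        clusters = [_cluster(-2.0), _cluster(5.0), _cluster(3.0)]
        out = significant_clusters(clusters, null, 1, alpha=1.0)
        assert [c.score for c in out] == [5.0, 3.0, -2.0]


class TestCohortLevel:
    def test_type_one_error_controlled_on_pure_noise(self):
        """Across 100 pure-noise cohorts (10 patients, no planted events)
        a cluster reaching FDC1 p <= 0.1 appears in at most 15% of runs."""
        chroms = (("chr1", 5_000_000), ("chr2", 5_000_000))
        hits = 0
        for seed in range(100):
            spec = SimulationSpec(chromosomes=chroms, n_patients=10, seed=seed)
            _, pairs, _ = simulate_cohort(spec)
            res = run_pipeline(
                pairs, B=200, seed=seed + 10_000, low_map_removal=False, fdc_modes=(1,)
            )
            if significant_clusters(res.clusters, res.null, 1, alpha=0.1):
                hits += 1
        assert hits <= 15

    def test_nesting_and_fdc5_leniency_on_planted_cohort(self):
        """On a cohort with a recurrent focal gain, FDC p-values nest
        (p3 <= p2 <= p1) and the FDC5 significant set contains the FDC1
        set, mirroring the increasing permissiveness of the schemes."""
        spec = SimulationSpec(
            chromosomes=(("chr1", 5_000_000), ("chr2", 5_000_000)),
            n_patients=10,
            events=(CNAEvent("chr1", 2_000_000, 2_600_000, 1.0, "focal", (0, 1, 2, 3)),),
            seed=5,
        )
        _, pairs, _ = simulate_cohort(spec)
        res = run_pipeline(pairs, B=200, seed=99, low_map_removal=False)
        assert res.clusters
        for c in res.clusters:
            assert c.p_values[3] <= c.p_values[2] <= c.p_values[1]
        sig1 = {(c.chromosome, c.start) for c in significant_clusters(res.clusters, mode=1, alpha=0.1)}
        sig5 = {(c.chromosome, c.start) for c in significant_clusters(res.clusters, mode=5, alpha=0.1)}
        assert sig1 <= sig5
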