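import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdfquant.io import PeakRecord
from tdfquant import peaks as P
from tdfquant.simulate import AflpSimConfig, simulate_aflp

from conftest import make_design, matrix_from_values


def peak(sample="s1", combo="pc1", size=100.0, height=100.0):
    return PeakRecord(sample_id=sample, primer_combo=combo, size=size, height=height)


class TestFilterPeaks:
    @pytest.mark.parametrize(
        "size,height,kept",
        [
            (100.0, 49.9, False),   # just under the detection floor
            (75.0, 50.0, True),     # inclusive on both boundaries
            (500.0, 50.0, True),
            (500.5, 5000.0, False),  # outside the sizing window
            (74.9, 5000.0, False),
        ],
    )
    def test_boundaries(self, size, height, kept):
        out = P.filter_peaks([peak(size=size, height=height)])
        assert (len(out) == 1) == kept


def brute_force_bins(sizes, tol):
    """Independent oracle: connected components of the |a-b| <= tol graph
    (single linkage = transitive closure of pairwise closeness)."""
    n = len(sizes)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if abs(sizes[i] - sizes[j]) <= tol:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestBinPeaks:
    def _design(self):
        return make_design(n_bio=1, n_tech=2, transects=("1",))

    def test_cross_sample_peaks_within_tolerance_merge(self):
        samples = self._design()
        ids = [s.sample_id for s in samples]
        peaks = [peak(sample=ids[0], size=100.0), peak(sample=ids[1], size=101.5)]
        m = P.bin_peaks(peaks, samples)
        assert m.n_transcripts == 1

    def test_gap_beyond_tolerance_separates(self):
        samples = self._design()
        ids = [s.sample_id for s in samples]
        peaks = [peak(sample=ids[0], size=100.0), peak(sample=ids[1], size=103.0)]
        m = P.bin_peaks(peaks, samples)
        assert m.n_transcripts == 2

    def test_within_sample_collision_keeps_taller(self):
        samples = self._design()
        sid = samples[0].sample_id
        peaks = [peak(sample=sid, size=100.0, height=80), peak(sample=sid, size=101.0, height=300)]
        m = P.bin_peaks(peaks, samples)
        assert m.n_transcripts == 1
        assert m.intensity.iloc[0][sid] == 300

    def test_matches_connected_components_oracle(self, rng):
        samples = self._design()
        ids = [s.sample_id for s in samples]
        for _ in range(25):
            sizes = np.sort(rng.uniform(75, 120, size=12)).round(2)
            peaks = [
                peak(sample=ids[i % len(ids)], size=float(s), height=60 + i)
                for i, s in enumerate(sizes)
            ]
            m = P.bin_peaks(peaks, samples)
            expected = brute_force_bins(list(sizes), 2.0)
            assert m.n_transcripts == len(expected)

    def test_row_order_invariance(self, rng):
        samples = self._design()
        ids = [s.sample_id for s in samples]
        sizes = rng.uniform(75, 200, size=20)
        peaks = [
            peak(sample=ids[i % 2], size=float(s), height=60 + i)
            for i, s in enumerate(sizes)
        ]
        m1 = P.bin_peaks(peaks, samples)
        m2 = P.bin_peaks(list(reversed(peaks)), samples)
        assert m1.intensity.equals(m2.intensity)

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="not in the sample sheet"):
            P.bin_peaks([peak(sample="ghost")], self._design())


class TestNormalizeSumOfSignal:
    def test_two_sample_arithmetic(self):
        samples = make_design(n_bio=1, n_tech=2, transects=("1",))[:2]
        m = matrix_from_values([[400.0, 800.0], [600.0, 1200.0]], samples)
        out = P.normalize_sum_of_signal(m)
        totals = out.intensity.sum(axis=0)
        assert totals.iloc[0] == pytest.approx(1500.0)
        assert totals.iloc[1] == pytest.approx(1500.0)
        # scale factors 1.5 and 0.75
        assert out.intensity.iloc[0, 0] == pytest.approx(600.0)
        assert out.intensity.iloc[0, 1] == pytest.approx(600.0)

    def test_equal_totals_identity(self, small_design, rng):
        vals = rng.uniform(100, 1000, size=(4, len(small_design)))
        vals = vals / vals.sum(axis=0, keepdims=True) * 5000
        m = matrix_from_values(vals, small_design)
        out = P.normalize_sum_of_signal(m)
        np.testing.assert_allclose(out.intensity.to_numpy(), vals, rtol=1e-12)

    def test_conserves_grand_total(self, small_design, rng):
        vals = rng.uniform(50, 5000, size=(6, len(small_design)))
        m = matrix_from_values(vals, small_design)
        out = P.normalize_sum_of_signal(m)
        assert out.intensity.to_numpy().sum() == pytest.approx(vals.sum(), rel=1e-9)

    def test_zero_total_names_sample(self, small_design):
        vals = np.full((2, len(small_design)), 100.0)
        vals[:, 3] = np.nan
        m = matrix_from_values(vals, small_design)
        with pytest.raises(ValueError, match=small_design[3].sample_id):
            P.normalize_sum_of_signal(m)


class TestSelectSharedTranscripts:
    @pytest.mark.parametrize("n_present,kept", [(29, True), (28, False)])
    def test_ceiling_threshold_at_32_runs(self, n_present, kept):
        design32 = make_design(n_bio=4, n_tech=2)  # 32 runs
        vals = np.full((1, 32), np.nan)
        vals[0, :n_present] = 100.0
        m = matrix_from_values(vals, design32)
        out = P.select_shared_transcripts(m, 0.90)
        assert out.n_transcripts == (1 if kept else 0)

    def test_zero_fraction_keeps_all(self, small_design):
        vals = np.full((3, len(small_design)), np.nan)
        vals[:, 0] = 60.0
        m = matrix_from_values(vals, small_design)
        assert P.select_shared_transcripts(m, 0.0).n_transcripts == 3

    def test_stricter_fraction_keeps_subset(self, paper_design, rng):
        vals = rng.uniform(50, 500, size=(40, 64))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        m = matrix_from_values(vals, paper_design)
        kept90 = set(P.select_shared_transcripts(m, 0.90).intensity.index)
        kept80 = set(P.select_shared_transcripts(m, 0.80).intensity.index)
        assert kept90 <= kept80


class TestImputeAndAverage:
    def test_partial_detection_uses_floor(self, small_design):
        vals = np.full((3, len(small_design)), np.nan)
        # first biological replicate: runs 0 and 1
        vals[0, 0], vals[0, 1] = 80.0, np.nan   # one missing -> mean(80, 50)
        vals[1, 0], vals[1, 1] = 60.0, 80.0     # both present -> mean
        # transcript 2 absent in both runs -> stays absent
        vals[:, 2:] = 100.0
        m = matrix_from_values(vals, small_design)
        out = P.impute_and_average_technical(m, floor=50.0)
        first = out.intensity.columns[0]
        assert out.intensity.at["t0", first] == pytest.approx(65.0)
        assert out.intensity.at["t1", first] == pytest.approx(70.0)
        assert np.isnan(out.intensity.at["t2", first])

    def test_wrong_replicate_count_rejected(self, small_design):
        vals = np.full((1, len(small_design)), 100.0)
        m = matrix_from_values(vals, small_design)
        broken = m.copy()
        broken.intensity = broken.intensity.iloc[:, :-1]
        broken.samples = broken.samples.iloc[:-1]
        with pytest.raises(ValueError, match="technical"):
            P.impute_and_average_technical(broken)

    def test_collapsed_matrix_has_one_column_per_pool(self, paper_design, rng):
        vals = rng.uniform(50, 500, size=(5, 64))
        m = matrix_from_values(vals, paper_design)
        out = P.impute_and_average_technical(m)
        assert out.n_samples == 32
        assert "technical_replicate" not in out.samples.columns


class TestSimpleMatching:
    def test_worked_example(self):
        assert P.simple_matching([1, 1, 0, 0], [1, 0, 0, 1]) == pytest.approx(0.5)

    def test_identical_and_complementary(self):
        a = [True, False, True]
        assert P.simple_matching(a, a) == 1.0
        assert P.simple_matching(a, [not v for v in a]) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=40).flatmap(
        lambda a: st.tuples(st.just(a), st.lists(st.booleans(), min_size=len(a), max_size=len(a)))
    ))
    def test_symmetry_and_hamming_identity(self, pair):
        a, b = pair
        s1 = P.simple_matching(a, b)
        s2 = P.simple_matching(b, a)
        assert s1 == s2
        hamming = sum(x != y for x, y in zip(a, b)) / len(a)
        assert s1 == pytest.approx(1.0 - hamming)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            P.simple_matching([1, 0], [1, 0, 1])


class TestReproducibility:
    def test_duplicated_technicals_are_perfect(self, small_design, rng):
        vals = rng.uniform(60, 600, size=(10, len(small_design)))
        vals[:, 1::2] = vals[:, 0::2]  # make run 2 identical to run 1
        m = matrix_from_values(vals, small_design)
        rep = P.reproducibility(m)
        assert rep.simple_matching_mean == 1.0
        assert rep.pearson_mean == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        samples = make_design(n_bio=1, n_tech=2, transects=("1",), ecotypes=("RB",))
        vals = np.array([[100.0, 300.0], [200.0, 200.0], [300.0, 100.0]])
        m = matrix_from_values(vals, samples)
        rep = P.reproducibility(m)
        assert rep.per_pair["pearson"].iloc[0] == pytest.approx(-1.0)

    def test_pair_with_too_few_joint_peaks_flagged(self):
        samples = make_design(n_bio=1, n_tech=2, transects=("1",), ecotypes=("RB",))
        vals = np.array([[100.0, np.nan], [np.nan, 50.0], [60.0, 70.0]])
        m = matrix_from_values(vals, samples)
        rep = P.reproducibility(m)
        assert np.isnan(rep.per_pair["pearson"].iloc[0])

    def test_pearson_decreases_with_technical_noise(self):
        means = []
        for sd_tech in (0.2, 0.6, 1.0):
            vals = []
            for seed in range(3):
                cfg = AflpSimConfig(seed=seed, sd_tech=sd_tech)
                pk, sm, _ = simulate_aflp(cfg)
                m = P.normalize_sum_of_signal(P.bin_peaks(P.filter_peaks(pk), sm))
                vals.append(P.reproducibility(P.select_shared_transcripts(m)).pearson_mean)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
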