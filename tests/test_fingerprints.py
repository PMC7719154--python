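"""Fingerprints, population maps, similarity, coherence, network shares."""

import numpy as np
import pytest
from scipy import stats

from cbparc.connectivity import ConnectivityMatrix
from cbparc.fingerprints import (
    coherence_with_tracer,
    compute_fingerprint,
    network_shares,
    population_map,
    similarity_analysis,
)


def _matrix(counts, column_labels, samples=100000, subject="S"):
    counts = np.asarray(counts)
    m = counts.shape[0]
    coords = np.column_stack([np.arange(m), np.zeros(m, int), np.zeros(m, int)])
    return ConnectivityMatrix(
        counts=counts,
        seed_coords=coords,
        samples_per_voxel=samples,
        column_labels=np.asarray(column_labels),
        subject_id=subject,
    )


class TestComputeFingerprint:
    def test_all_samples_into_one_target(self):
        m = _matrix([[100000, 0]], [1, 2])
        fp = compute_fingerprint(m, {1: np.array([True])})
        np.testing.assert_allclose(fp.strengths, [[1.0, 0.0]])

    def test_individual_level_threshold_zeroes_weak_connections(self):
        # 3.0 of 1e5 samples is below the 3.08e-5 probability cut
        m = _matrix([[3, 4]], [1, 2])
        fp = compute_fingerprint(m, {1: np.array([True])}, seed_threshold=3.08e-5)
        assert fp.strengths[0, 0] == 0.0
        assert fp.strengths[0, 1] == pytest.approx(4e-5)

    def test_hand_built_three_voxel_subarea(self):
        counts = np.array(
            [
                [1000, 2000, 500, 0],
                [500, 500, 1500, 500],
                [0, 3000, 0, 1000],
            ]
        )
        atlas = np.array([1, 1, 2, 2])  # two targets, two columns each
        m = _matrix(counts, atlas)
        fp = compute_fingerprint(m, {7: np.ones(3, bool)}, seed_threshold=0.0)
        # per voxel, per target summed probabilities (of 1e5 samples):
        # t1: .03, .01, .03 ; t2: .005, .02, .01 -> means (approx)
        assert fp.subarea_ids.tolist() == [7]
        np.testing.assert_allclose(
            fp.strengths[0], [np.mean([0.03, 0.01, 0.03]), np.mean([0.005, 0.02, 0.01])]
        )

    def test_empty_subarea_gives_flagged_zero_row(self):
        m = _matrix([[10, 10]], [1, 2])
        with pytest.warns(UserWarning, match="empty"):
            fp = compute_fingerprint(m, {1: np.array([False])})
        assert fp.empty_subareas[0]
        np.testing.assert_array_equal(fp.strengths, [[0.0, 0.0]])

    def test_invariant_to_target_order(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 5000, (4, 6))
        atlas = np.array([1, 2, 3, 1, 2, 3])
        masks = {1: np.array([True, True, False, False])}
        a = compute_fingerprint(_matrix(counts, atlas), masks)
        perm = [5, 0, 3, 2, 4, 1]
        b = compute_fingerprint(_matrix(counts[:, perm], atlas[perm]), masks)
        np.testing.assert_allclose(a.strengths, b.strengths)


class TestPopulationMap:
    def test_half_threshold_on_eight_subjects(self):
        maps = np.zeros((8, 3), dtype=int)
        maps[:4, 0] = 1  # 4 of 8 -> kept
        maps[:3, 1] = 1  # 3 of 8 -> dropped
        maps[:, 2] = 1
        out = population_map(maps, 0.5)
        assert out.tolist() == [True, False, True]

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(5)
        maps = (rng.random((8, 20)) > 0.5).astype(int)
        low = population_map(maps, 0.25)
        high = population_map(maps, 0.75)
        assert np.all(high <= low)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binar"):
            population_map(np.array([[0.5, 1.0]]), 0.5)


class TestSimilarity:
    def _fps(self, vectors):
        from cbparc.fingerprints import Fingerprint

        return [
            Fingerprint(
                strengths=np.atleast_2d(v),
                subarea_ids=np.array([1]),
                target_ids=np.arange(1, len(v) + 1),
                subject_id=f"s{i}",
            )
            for i, v in enumerate(vectors)
        ]

    def test_identical_fingerprints_correlate_perfectly(self):
        v = np.array([1.0, 2.0, 3.0, 1.0])
        df = similarity_analysis(self._fps([v, v]))
        assert df.r.iloc[0] == pytest.approx(1.0)

    def test_reversed_fingerprint_anticorrelates(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        df = similarity_analysis(self._fps([v, v.max() + v.min() - v]))
        assert df.r.iloc[0] == pytest.approx(-1.0)

    def test_matches_closed_form_t_statistic(self):
        rng = np.random.default_rng(6)
        a, b = rng.random(12), rng.random(12)
        df = similarity_analysis(self._fps([a, b]))
        r = df.r.iloc[0]
        n = 12
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert df.p.iloc[0] == pytest.approx(p, rel=1e-10)
        assert df.significant.iloc[0] == (p < 0.001)

    def test_constant_vector_reported_missing(self):
        df = similarity_analysis(self._fps([np.ones(5), np.arange(5.0)]))
        assert np.isnan(df.r.iloc[0])
        assert not df.significant.iloc[0]


class TestCoherence:
    def test_identical_sets_are_fully_coherent(self):
        rep = coherence_with_tracer({"A", "B"}, {"A", "B"})
        assert rep.coherence_percent == 100.0

    def test_three_of_four_regions_recovered(self):
        rep = coherence_with_tracer({"A", "B", "C", "D"}, {"A", "B", "C"})
        assert rep.coherence_percent == pytest.approx(75.0)
        assert rep.missing == {"D"}

    def test_extra_findings_do_not_penalize(self):
        rep = coherence_with_tracer({"A"}, {"A", "B", "C"})
        assert rep.coherence_percent == 100.0
        assert rep.extra == {"B", "C"}

    def test_empty_tracer_set_rejected(self):
        with pytest.raises(ValueError):
            coherence_with_tracer(set(), {"A"})


class TestNetworkShares:
    def _fp(self, strengths, targets):
        from cbparc.fingerprints import Fingerprint

        return Fingerprint(
            strengths=np.atleast_2d(strengths),
            subarea_ids=np.array([1]),
            target_ids=np.asarray(targets),
        )

    def test_exclusive_connection_gives_unit_share(self):
        fp = self._fp([0.2, 0.3, 0.0, 0.0], [1, 2, 3, 4])
        df = network_shares(fp, {"dmn": {1, 2}, "other": {3, 4}})
        shares = dict(zip(df.network, df.share))
        assert shares["dmn"] == pytest.approx(1.0)
        assert shares["other"] == 0.0

    def test_proportional_normalization(self):
        fp = self._fp([2.0, 1.0, 1.0], [1, 2, 3])
        df = network_shares(fp, {"a": {1}, "b": {2}, "c": {3}})
        assert dict(zip(df.network, df.share)) == pytest.approx(
            {"a": 0.5, "b": 0.25, "c": 0.25}
        )

    def test_network_order_irrelevant(self):
        fp = self._fp([2.0, 1.0, 1.0], [1, 2, 3])
        nets = {"a": {1}, "b": {2}, "c": {3}}
        rev = dict(reversed(list(nets.items())))
        d1 = dict(zip(*(network_shares(fp, nets)[c] for c in ("network", "share"))))
        d2 = dict(zip(*(network_shares(fp, rev)[c] for c in ("network", "share"))))
        assert d1 == pytest.approx(d2)

    def test_zero_total_flagged(self):
        fp = self._fp([0.0, 0.0], [1, 2])
        with pytest.warns(UserWarning, match="zero"):
            df = network_shares(fp, {"a": {1}, "b": {2}})
        assert df.undefined.all()
        assert df.share.isna().all()
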