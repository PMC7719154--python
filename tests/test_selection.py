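"""Validity indices (Cramer's V, TpD), PCA criteria, and the k decision."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbparc.parcellation import Parcellation
from cbparc.selection import (
    KSelection,
    ValidityProfile,
    cramers_v,
    mean_cramers_v,
    parcel_adjacency,
    pca_criteria,
    pca_criteria_from_eigenvalues,
    scree_inflexion,
    select_k,
    tpd,
)
from conftest import random_labels


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _cramers_v_oracle(a, b):
    """Plain-loop contingency chi-square, coded independently."""
    la, lb = sorted(set(a)), sorted(set(b))
    table = np.zeros((len(la), len(lb)))
    for x, y in zip(a, b):
        table[la.index(x), lb.index(y)] += 1
    n = table.sum()
    chi2 = 0.0
    for i in range(len(la)):
        for j in range(len(lb)):
            e = table[i].sum() * table[:, j].sum() / n
            if e > 0:
                chi2 += (table[i, j] - e) ** 2 / e
    return np.sqrt(chi2 / (n * (min(len(la), len(lb)) - 1)))


def _tpd_oracle(adj_a, adj_b):
    """Exhaustive search over all parcel correspondences."""
    k = adj_a.shape[0]
    best = np.inf
    for perm in itertools.permutations(range(k)):
        p = list(perm)
        mism = sum(
            adj_a[p[i], p[j]] != adj_b[i, j]
            for i in range(k)
            for j in range(k)
            if i != j
        )
        best = min(best, mism / (k * (k - 1)))
    return best


def _scree_oracle(eigenvalues):
    """Fit a*x^-b in log space, then brute-force the max point-to-chord
    distance over all ranks with the generic 2-D distance formula."""
    eig = np.asarray(eigenvalues, float)
    eig = eig[eig > 0]
    n = eig.size
    x = np.arange(1, n + 1, dtype=float)
    lx, ly = np.log(x), np.log(eig)
    b = -((lx - lx.mean()) * (ly - ly.mean())).sum() / ((lx - lx.mean()) ** 2).sum()
    a = np.exp(ly.mean() + b * lx.mean())
    f = a * x ** (-b)
    u = (x - 1) / (n - 1)
    v = (f - f[-1]) / (f[0] - f[-1])
    p1, p2 = np.array([0.0, 1.0]), np.array([1.0, 0.0])
    best_rank, best_d = None, -1.0
    for i in range(n):
        p = np.array([u[i], v[i]])
        e, q = p2 - p1, p - p1
        d = abs(e[0] * q[1] - e[1] * q[0]) / np.linalg.norm(e)
        if d > best_d:
            best_d, best_rank = d, i + 1
    return best_rank


def _parc(labels, coords=None, k=None):
    labels = np.asarray(labels)
    if coords is None:
        coords = np.column_stack(
            [np.arange(labels.size), np.zeros(labels.size, int), np.zeros(labels.size, int)]
        )
    return Parcellation(
        labels=labels, k=int(labels.max() if k is None else k), seed_coords=coords
    )


# ---------------------------------------------------------------------------
# Cramer's V
# ---------------------------------------------------------------------------

class TestCramersV:
    def test_identical_partitions_score_one(self):
        lab = [1, 1, 2, 3, 3, 2]
        assert cramers_v(_parc(lab), _parc(lab)) == pytest.approx(1.0)

    def test_label_permutation_still_scores_one(self):
        a = _parc([1, 1, 2, 2])
        b = _parc([2, 2, 1, 1])
        assert cramers_v(a, b) == pytest.approx(1.0)

    def test_independent_partitions_score_zero(self):
        # 2x2 contingency table is uniform, so chi-square vanishes
        assert cramers_v(_parc([1, 1, 2, 2]), _parc([1, 2, 1, 2])) == pytest.approx(0.0)

    def test_single_cluster_undefined(self):
        with pytest.raises(ValueError, match="single cluster"):
            cramers_v(_parc([1, 1, 1]), _parc([1, 1, 1]))

    def test_matches_contingency_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(10, 201))
            ka, kb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = random_labels(rng, n, ka)
            b = random_labels(rng, n, kb)
            assert cramers_v(_parc(a), _parc(b)) == pytest.approx(
                _cramers_v_oracle(a, b), abs=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_bounded_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 60))
        a = random_labels(rng, n, 3)
        b = random_labels(rng, n, 3)
        v = cramers_v(_parc(a), _parc(b))
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(cramers_v(_parc(b), _parc(a)))
        perm = np.array([0, 3, 1, 2])  # relabel 1..3 -> perm
        assert v == pytest.approx(cramers_v(_parc(perm[a]), _parc(b)))

    def test_mean_over_three_subjects_is_pair_average(self):
        a, b, c = _parc([1, 1, 2, 2]), _parc([1, 2, 1, 2]), _parc([1, 1, 2, 2])
        expected = np.mean(
            [cramers_v(a, b), cramers_v(a, c), cramers_v(b, c)]
        )
        assert mean_cramers_v([a, b, c]) == pytest.approx(expected)

    def test_mean_of_identical_cohort_is_one(self):
        p = _parc([1, 2, 2, 1, 3, 3])
        assert mean_cramers_v([p, p, p]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# TpD
# ---------------------------------------------------------------------------

def _line_parcellation(labels_along_line):
    """Parcels laid out on a 1-D voxel line: adjacency is a path graph."""
    return _parc(labels_along_line)


def _star_parcellation():
    """Center parcel 1 touching parcels 2, 3, 4 (star adjacency)."""
    coords = np.array([[1, 1, 0], [0, 1, 0], [2, 1, 0], [1, 0, 0]])
    return _parc([1, 2, 3, 4], coords=coords)


class TestTpD:
    def test_self_distance_is_zero(self):
        p = _line_parcellation([1, 1, 2, 2, 3, 3])
        assert tpd(p, p) == 0.0

    def test_path_vs_star_matches_exhaustive_oracle(self):
        path = _line_parcellation([1, 1, 2, 2, 3, 3, 4, 4])
        star = _star_parcellation()
        expected = _tpd_oracle(parcel_adjacency(path), parcel_adjacency(star))
        assert tpd(path, star) == pytest.approx(expected)
        # best matching shares 2 of each graph's 3 edges -> 2 mismatched
        # pairs out of 6 off-diagonal pairs (counted both ways)
        assert expected == pytest.approx(1.0 / 3.0)

    def test_unequal_k_is_maximally_dissimilar(self):
        a = _line_parcellation([1, 1, 2, 2])
        b = _line_parcellation([1, 2, 3, 3])
        assert tpd(a, b) == 1.0

    def test_matches_exhaustive_oracle_on_random_grids(self):
        rng = np.random.default_rng(23)
        for k in (3, 4, 5, 6):
            for _ in range(5):
                coords = np.argwhere(np.ones((3, 3, 2), dtype=bool))
                a = _parc(random_labels(rng, 18, k), coords=coords)
                b = _parc(random_labels(rng, 18, k), coords=coords)
                expected = _tpd_oracle(parcel_adjacency(a), parcel_adjacency(b))
                got = tpd(a, b)
                assert got == pytest.approx(expected)
                assert got == pytest.approx(tpd(b, a))
                assert 0.0 <= got <= 1.0

    def test_degenerate_parcellation_rejected(self):
        good = _line_parcellation([1, 1, 2, 2])
        bad = _parc([1, 1, 1, 1], k=2)
        with pytest.raises(ValueError, match="degenerate"):
            tpd(bad, good)


# ---------------------------------------------------------------------------
# PCA criteria
# ---------------------------------------------------------------------------

def _three_component_data(noise=0.05, seed=0):
    """30 variables driven by 3 orthogonal latent factors plus tiny noise."""
    rng = np.random.default_rng(seed)
    f = rng.normal(size=(120, 3))
    load = np.zeros((3, 30))
    for g in range(3):
        load[g, g * 10 : (g + 1) * 10] = 1.0
    return f @ load + noise * rng.normal(size=(120, 30))


class TestPcaCriteria:
    def test_worked_eigenvalue_example(self):
        c1, c2, _ = pca_criteria_from_eigenvalues(np.array([5, 3, 1.2, 0.4, 0.1]))
        # cumulative proportions 51.5%, 82.5% -> 2 components clear 80%;
        # three eigenvalues exceed 1 and 0.4 is not within 0.2 of 1
        assert c1 == 2
        assert c2 == 3

    def test_next_closest_to_one_extends_kaiser_count(self):
        c1, c2, _ = pca_criteria_from_eigenvalues(np.array([5, 3, 1.2, 0.9, 0.1]))
        assert c2 == 4

    def test_three_component_dataset_agrees_on_all_criteria(self):
        x = _three_component_data()
        from cbparc.connectivity import ConnectivityMatrix

        # correlations are shift-invariant, so offsetting to non-negative
        # "counts" preserves the exact 3-factor spectrum
        m = ConnectivityMatrix(
            counts=x.T - x.min(),  # seed voxels x columns
            seed_coords=np.column_stack(
                [np.arange(30), np.zeros(30, int), np.zeros(30, int)]
            ),
        )
        assert pca_criteria(m) == (3, 3, 3)

    def test_isotropic_spectrum_has_no_elbow(self):
        with pytest.warns(UserWarning, match="elbow"):
            c1, c2, c3 = pca_criteria_from_eigenvalues(np.ones(6))
        assert c3 is None


class TestScreeInflexion:
    def test_sharp_knee_found_and_matches_geometric_oracle(self):
        eig = np.sort(
            np.concatenate([np.linspace(10, 2, 4), np.linspace(1.8, 1.0, 8)])
        )[::-1]
        assert scree_inflexion(eig) == _scree_oracle(eig) == 4

    def test_geometric_decay_matches_brute_force(self):
        eig = 2.0 ** -np.arange(1, 13)
        assert scree_inflexion(eig) == _scree_oracle(eig)

    def test_flat_spectrum_rejected(self):
        with pytest.raises(ValueError, match="elbow"):
            scree_inflexion(np.ones(8))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4"):
            scree_inflexion(np.array([3.0, 2.0, 1.0]))


# ---------------------------------------------------------------------------
# k decision
# ---------------------------------------------------------------------------

class TestSelectK:
    def test_shared_extremum_is_selected(self):
        prof = ValidityProfile(
            k_values=[7, 8, 9],
            mean_cramers_v=[0.6, 0.8, 0.7],
            mean_tpd=[0.3, 0.1, 0.2],
        )
        sel = select_k(prof)
        assert sel.selected_k == 8
        assert sel.candidates == [8]
        assert not sel.used_fallback

    def test_monotone_series_fall_back_to_pca_mean(self):
        prof = ValidityProfile(
            k_values=[2, 3, 4, 5],
            mean_cramers_v=[0.9, 0.8, 0.7, 0.6],
            mean_tpd=[0.1, 0.2, 0.3, 0.4],
            pca_inflexions={"a": 4.0, "b": 4.0},
        )
        with pytest.warns(UserWarning, match="falling back"):
            sel = select_k(prof)
        assert sel.used_fallback
        assert sel.selected_k == 4

    def test_unstable_subject_excluded_from_pca_mean(self):
        prof = ValidityProfile(
            k_values=[2, 3, 4],
            mean_cramers_v=[0.5, 0.9, 0.6],
            mean_tpd=[0.3, 0.1, 0.2],
            pca_inflexions={"s1": 8.3, "s2": 8.2, "s3": 9.9, "s4": 8.1},
        )
        sel = select_k(prof, stability_delta=0.5)
        assert sel.excluded_subjects == ["s3"]
        # mean over the remaining subjects: (8.3 + 8.2 + 8.1) / 3
        assert sel.pca_mean == pytest.approx(8.2)

    def test_requires_three_k_values(self):
        prof = ValidityProfile(
            k_values=[2, 3], mean_cramers_v=[0.5, 0.6], mean_tpd=[0.2, 0.1]
        )
        with pytest.raises(ValueError):
            select_k(prof)
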