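"""Modified k-means, AAHC, two-level grand means, template sorting."""

import numpy as np
import pytest

import microstates as ms
from conftest import brute_force_best_gev, partition_gev
from microstates.clustering import TemplateSet
from microstates.errors import InvalidDataError


def noisy_group_maps(templates, counts, noise_sd, seed, scales=None):
    """Maps drawn around given templates with random signs and noise."""
    rng = np.random.default_rng(seed)
    X, truth = [], []
    for k, c in enumerate(counts):
        for _ in range(c):
            v = templates.maps[k] * rng.choice([-1, 1])
            v = v + rng.normal(0, noise_sd, v.shape)
            if scales is not None:
                v = v * rng.uniform(*scales)
            X.append(v)
            truth.append(k)
    return np.stack(X), np.array(truth)


class TestModifiedKmeans:
    def test_single_template_recovered(self, templates5, montage30):
        rng = np.random.default_rng(0)
        X = templates5.maps[0] * rng.choice([-1, 1], size=(20, 1)) * rng.uniform(1, 3, (20, 1))
        res = ms.modified_kmeans(X, 1, seed=0, montage=montage30)
        assert abs(res.templates.maps[0] @ templates5.maps[0]) == pytest.approx(1.0)
        assert res.gev == pytest.approx(1.0)

    def test_two_templates_recovered_noiseless(self, templates2, montage30):
        X, truth = noisy_group_maps(templates2, (25, 25), 0.0, seed=1, scales=(1, 3))
        res = ms.modified_kmeans(X, 2, seed=0, montage=montage30)
        assert res.gev == pytest.approx(1.0)
        cross = np.abs(res.templates.maps @ templates2.maps.T)
        assert np.allclose(np.sort(cross.max(axis=1)), 1.0)

    def test_matches_exhaustive_partition_oracle(self, templates2, montage30):
        X, _ = noisy_group_maps(templates2, (4, 4), 0.15, seed=2, scales=(1, 2))
        res = ms.modified_kmeans(X, 2, n_restarts=20, seed=0, montage=montage30)
        oracle = brute_force_best_gev(X, 2)
        assert res.gev >= oracle - 1e-9
        # converged k-means output is itself a partition, so it cannot beat it
        assert res.gev <= oracle + 1e-9

    def test_polarity_invariance(self, templates2, montage30):
        X, _ = noisy_group_maps(templates2, (10, 10), 0.1, seed=3)
        flip = np.random.default_rng(0).choice([-1.0, 1.0], size=(20, 1))
        a = ms.modified_kmeans(X, 2, seed=5, montage=montage30)
        b = ms.modified_kmeans(X * flip, 2, seed=5, montage=montage30)
        assert a.gev == pytest.approx(b.gev, abs=1e-12)
        assert np.array_equal(a.assignment, b.assignment)
        assert np.allclose(np.abs(a.templates.maps @ b.templates.maps.T).max(axis=1), 1.0)

    def test_gev_nondecreasing_in_restarts(self, templates5, montage30):
        X, _ = noisy_group_maps(templates5, (6, 6, 6, 6, 6), 0.4, seed=4)
        gevs = [ms.modified_kmeans(X, 5, n_restarts=r, seed=11, montage=montage30).gev
                for r in (1, 3, 10)]
        assert gevs[0] <= gevs[1] + 1e-12 <= gevs[2] + 2e-12

    def test_k_larger_than_n_maps_rejected(self, templates2, montage30):
        with pytest.raises(InvalidDataError):
            ms.modified_kmeans(templates2.maps, 3, montage=montage30)


class TestAAHC:
    def test_orthogonal_singletons_kept(self, montage30):
        ts = ms.make_templates(montage30, K=3, min_pairwise_sep=0.8, seed=6)
        res = ms.aahc(ts.maps, 3, montage=montage30)
        cross = np.abs(res.templates.maps @ ts.maps.T)
        assert np.all(cross.max(axis=1) > 0.999)
        assert res.gev == pytest.approx(1.0, abs=1e-9)

    def test_two_tight_groups(self, templates2, montage30):
        X, truth = noisy_group_maps(templates2, (10, 10), 0.05, seed=7)
        res = ms.aahc(X, 2, montage=montage30)
        # assignment pure: each cluster contains one group only
        for k in (0, 1):
            assert len(np.unique(truth[res.assignment == k])) == 1
        cross = np.abs(res.templates.maps @ templates2.maps.T)
        assert np.all(cross.max(axis=1) > 0.98)

    def test_deterministic(self, templates2, montage30):
        X, _ = noisy_group_maps(templates2, (8, 8), 0.2, seed=8)
        a = ms.aahc(X, 2, montage=montage30)
        b = ms.aahc(X, 2, montage=montage30)
        assert np.array_equal(a.assignment, b.assignment)
        assert a.gev == b.gev

    def test_reaches_partition_oracle_on_small_instance(self, templates2, montage30):
        X, _ = noisy_group_maps(templates2, (5, 5), 0.1, seed=9)
        res = ms.aahc(X, 2, montage=montage30)
        oracle = brute_force_best_gev(X, 2)
        shortfall = oracle - res.gev
        # AAHC is greedy; on these easy instances it should reach the oracle
        assert shortfall <= 1e-9


class TestTwoLevelGrandMean:
    def make_subject_sets(self, templates5, montage30, n_subjects, noise_sd, seed):
        rng = np.random.default_rng(seed)
        sets, perms = [], []
        for _ in range(n_subjects):
            perm = rng.permutation(5)
            signs = rng.choice([-1.0, 1.0], size=(5, 1))
            maps = templates5.maps[perm] * signs + rng.normal(0, noise_sd, (5, 30))
            sets.append(TemplateSet(maps, montage30, [f"MS{i+1}" for i in range(5)]))
            perms.append(perm)
        return sets, perms

    def test_identical_subjects_recovered_exactly(self, templates5, montage30):
        sets, _ = self.make_subject_sets(templates5, montage30, 6, 0.0, seed=0)
        gm, _ = ms.two_level_grand_mean(sets, seed=0)
        cross = np.abs(gm.maps @ templates5.maps.T)
        assert np.allclose(np.sort(cross.max(axis=1)), 1.0, atol=1e-9)
        assert gm.gev == pytest.approx(1.0, abs=1e-9)

    def test_single_subject_passthrough(self, templates5, montage30):
        sets, _ = self.make_subject_sets(templates5, montage30, 1, 0.0, seed=1)
        gm, perms = ms.two_level_grand_mean(sets, seed=0)
        cross = np.abs(gm.maps @ sets[0].maps.T)
        assert np.allclose(cross.max(axis=1), 1.0, atol=1e-9)

    def test_noisy_permuted_subjects_recovered(self, templates5, montage30):
        sets, true_perms = self.make_subject_sets(templates5, montage30, 12, 0.1, seed=2)
        gm, perms = ms.two_level_grand_mean(sets, seed=0)
        cross = np.abs(gm.maps @ templates5.maps.T)
        assert np.all(cross.max(axis=1) > 0.95)
        # recovered permutations must be mutually consistent with the truth:
        # slot j of every subject maps to the same true template
        slot_truth = np.array([[true_perms[s][perms[s, j]] for j in range(5)]
                               for s in range(12)])
        assert np.all(slot_truth == slot_truth[0])

    def test_subject_order_invariance(self, templates5, montage30):
        sets, _ = self.make_subject_sets(templates5, montage30, 8, 0.05, seed=3)
        gm1, _ = ms.two_level_grand_mean(sets, seed=0)
        gm2, _ = ms.two_level_grand_mean(sets[::-1], seed=0)
        cross = np.abs(gm1.maps @ gm2.maps.T)
        assert np.allclose(cross.max(axis=1), 1.0, atol=1e-6)

    def test_mixed_k_rejected(self, templates5, templates2, montage30):
        s5 = TemplateSet(templates5.maps, montage30, [f"M{i}" for i in range(5)])
        s2 = TemplateSet(templates2.maps, montage30, ["a", "b"])
        with pytest.raises(InvalidDataError):
            ms.two_level_grand_mean([s5, s2])


class TestGrandGrandMeanConsistency:
    def test_identical_sets_100(self, templates5):
        _, cons = ms.grand_grand_mean_consistency([templates5, templates5], seed=0)
        assert cons == pytest.approx(100.0, abs=1e-6)

    def test_two_sets_at_known_angle(self, templates5, montage30):
        # rotate every map by acos(r): the grand-grand mean is the bisector,
        # so each set correlates cos(acos(r)/2) with it -> mean r^2 = (1+r)/2
        r = 0.9
        rng = np.random.default_rng(5)
        rotated = []
        for u in templates5.maps:
            g = rng.normal(size=30)
            g -= g.mean()
            g -= (g @ u) * u
            g /= np.linalg.norm(g)
            rotated.append(r * u + np.sqrt(1 - r**2) * g)
        set2 = TemplateSet(np.stack(rotated), montage30, templates5.labels)
        _, cons = ms.grand_grand_mean_consistency([templates5, set2], seed=0)
        assert cons == pytest.approx(100 * (1 + r) / 2, abs=0.5)

    def test_single_set_flagged(self, templates5):
        with pytest.warns(UserWarning):
            _, cons = ms.grand_grand_mean_consistency([templates5])
        assert cons == 100.0


class TestSortAgainstReference:
    def test_shuffled_signflipped_restored(self, templates5, montage30):
        perm = [3, 0, 4, 1, 2]
        signs = np.array([1, -1, 1, -1, -1.0])[:, None]
        shuffled = TemplateSet(templates5.maps[perm] * signs, montage30,
                               [f"X{i}" for i in range(5)])
        out = ms.sort_against_reference(shuffled, templates5)
        assert out.labels == templates5.labels
        assert np.allclose(out.maps, templates5.maps, atol=1e-12)

    def test_identity(self, templates5):
        out = ms.sort_against_reference(templates5, templates5)
        assert np.allclose(out.maps, templates5.maps)

    def test_noisy_copies_labeled_correctly(self, templates5, montage30):
        rng = np.random.default_rng(6)
        noisy = TemplateSet(templates5.maps + rng.normal(0, 0.05, (5, 30)),
                            montage30, [f"X{i}" for i in range(5)])
        out = ms.sort_against_reference(noisy, templates5)
        diag = np.abs(np.einsum("ij,ij->i", out.maps, templates5.maps))
        assert np.all(diag > 0.9)
        assert out.labels == templates5.labels


class TestSerialization:
    def test_roundtrip(self, templates5, tmp_path):
        ms.save_template_set(templates5, tmp_path / "gm")
        back = ms.load_template_set(tmp_path / "gm")
        assert back.labels == templates5.labels
        assert np.allclose(back.maps, templates5.maps, atol=1e-9)
        assert back.montage == templates5.montage
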