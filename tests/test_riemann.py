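"""SPD geometry, shrinkage estimation, Tomek balancing, classifiers."""

import numpy as np
import pytest

from oddbci import (crossvalidate, mdm_fit_predict, riemann_distance,
                    riemann_mean, shrinkage_covariance, tangent_project,
                    tomek_links, tsc_fit_predict)
from oddbci.riemann import SPDSet, mdm_fit, mdm_predict, spd_expm, spd_logm

from conftest import random_spd


def brute_force_lambda(x):
    """Schaefer-Strimmer optimum from the defining sums, written as plain
    loops, independent of the vectorized implementation."""
    x = np.asarray(x, float)
    p, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    s = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            s[i, j] = np.sum(xc[i] * xc[j]) / (n - 1)
    num = den = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            w = xc[i] * xc[j]
            var_s = n / (n - 1) ** 3 * np.sum((w - w.mean()) ** 2)
            num += var_s
            den += s[i, j] ** 2
    return min(max(num / den, 0.0), 1.0)


class TestShrinkage:
    def test_lambda_matches_brute_force(self, rng):
        for _ in range(20):
            x = rng.standard_normal((5, 300)) * rng.uniform(0.5, 3.0)
            _, lam = shrinkage_covariance(x)
            assert lam == pytest.approx(brute_force_lambda(x), abs=1e-10)

    def test_lambda_vanishes_asymptotically(self, rng):
        mix = rng.standard_normal((4, 4))
        lams = []
        for n in (50, 500, 5000):
            x = mix @ rng.standard_normal((4, n))
            _, lam = shrinkage_covariance(x)
            lams.append(lam)
        assert lams[0] > lams[1] > lams[2]
        assert lams[2] < 0.01

    def test_output_always_spd(self, rng):
        for _ in range(200):
            n_ch = int(rng.integers(2, 9))
            x = rng.standard_normal((n_ch, int(rng.integers(20, 100))))
            c, lam = shrinkage_covariance(x)
            assert 0.0 <= lam <= 1.0
            assert np.linalg.eigvalsh(c).min() > 0
            assert np.allclose(c, c.T)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            shrinkage_covariance(rng.standard_normal((3, 1)))


class TestDistance:
    def test_identity_of_indiscernibles(self, rng):
        a = random_spd(rng, 4)
        assert riemann_distance(a, a) == pytest.approx(0.0, abs=1e-10)

    def test_commuting_closed_form(self):
        assert riemann_distance(np.eye(2), np.diag([1.0, 4.0])) == \
            pytest.approx(np.log(4.0), abs=1e-12)

    def test_metric_axioms_on_random_batch(self, rng):
        for _ in range(50):
            a, b = random_spd(rng, 5), random_spd(rng, 5)
            dab = riemann_distance(a, b)
            assert dab > 0
            assert dab == pytest.approx(riemann_distance(b, a), abs=1e-9)
            c = random_spd(rng, 5)
            assert dab <= (riemann_distance(a, c)
                           + riemann_distance(c, b) + 1e-9)

    def test_affine_and_inversion_invariance(self, rng):
        a, b = random_spd(rng, 4), random_spd(rng, 4)
        d = riemann_distance(a, b)
        w = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        assert riemann_distance(w.T @ a @ w, w.T @ b @ w) == \
            pytest.approx(d, abs=1e-8)
        assert riemann_distance(np.linalg.inv(a), np.linalg.inv(b)) == \
            pytest.approx(d, abs=1e-8)


class TestMean:
    def test_singleton(self, rng):
        a = random_spd(rng, 3)
        assert np.allclose(riemann_mean(a[None]), a)

    def test_commuting_closed_form(self, rng):
        # for commuting matrices the Frechet mean is exp(mean of logs)
        assert np.allclose(riemann_mean(np.stack([np.eye(2),
                                                  4.0 * np.eye(2)])),
                           2.0 * np.eye(2), atol=1e-8)
        d = [np.diag(rng.uniform(0.5, 4.0, 3)) for _ in range(5)]
        expect = spd_expm(np.mean([spd_logm(m) for m in d], axis=0))
        assert np.allclose(riemann_mean(np.stack(d)), expect, atol=1e-8)

    def test_congruence_equivariance(self, rng):
        mats = np.stack([random_spd(rng, 4) for _ in range(6)])
        w = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        lhs = riemann_mean(np.stack([w.T @ m @ w for m in mats]))
        rhs = w.T @ riemann_mean(mats) @ w
        assert np.allclose(lhs, rhs, atol=1e-6)

    def test_local_minimality_of_objective(self, rng):
        mats = np.stack([random_spd(rng, 3) for _ in range(8)])
        m = riemann_mean(mats)

        def objective(x):
            return sum(riemann_distance(x, a) ** 2 for a in mats)

        base = objective(m)
        sqrt_m = spd_expm(0.5 * spd_logm(m))
        for _ in range(10):
            step = rng.standard_normal((3, 3)) * 0.01
            step = 0.5 * (step + step.T)
            perturbed = sqrt_m @ spd_expm(step) @ sqrt_m
            assert objective(perturbed) >= base - 1e-9

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            riemann_mean(np.empty((0, 3, 3)))


class TestTangent:
    def test_reference_maps_to_zero(self, rng):
        r = random_spd(rng, 4)
        assert np.allclose(tangent_project(r, r), 0.0, atol=1e-10)

    @pytest.mark.parametrize("n", [1, 5, 8])
    def test_vector_dimension(self, rng, n):
        v = tangent_project(random_spd(rng, n), random_spd(rng, n))
        assert v.shape == (n * (n + 1) // 2,)

    def test_norm_equals_distance(self, rng):
        for _ in range(100):
            c, r = random_spd(rng, 5), random_spd(rng, 5)
            v = tangent_project(c, r)
            assert np.linalg.norm(v) == pytest.approx(
                riemann_distance(c, r), abs=1e-9)


def brute_force_tomek(vectors, labels, seed):
    """Naive loop re-implementation of iterative Tomek-link balancing."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels.tolist()))
    alive = list(range(len(labels)))
    while True:
        counts = {c: sum(labels[i] == c for i in alive) for c in classes}
        if counts[classes[0]] == counts[classes[1]]:
            return sorted(alive)
        maj = max(classes, key=lambda c: counts[c])
        nn = {}
        for i in alive:
            best, bestd = None, np.inf
            for j in alive:
                if j == i:
                    continue
                d = float(np.sum((vectors[i] - vectors[j]) ** 2))
                if d < bestd:
                    best, bestd = j, d
            nn[i] = best
        links = set()
        for i in alive:
            j = nn[i]
            if nn[j] == i and labels[i] != labels[j]:
                links.add(tuple(sorted((i, j))))
        if not links:
            break
        drop = {i if labels[i] == maj else j for i, j in links}
        excess = counts[maj] - min(counts.values())
        if len(drop) > excess:
            drop = set(sorted(drop)[:excess])
        alive = [i for i in alive if i not in drop]
    counts = {c: sum(labels[i] == c for i in alive) for c in classes}
    maj = max(classes, key=lambda c: counts[c])
    excess = counts[maj] - min(counts.values())
    if excess > 0:
        maj_alive = np.array([k for k, i in enumerate(alive)
                              if labels[i] == maj])
        drop_local = rng.choice(maj_alive, size=excess, replace=False)
        alive = [i for k, i in enumerate(alive)
                 if k not in set(np.sort(drop_local).tolist())]
    return sorted(alive)


class TestTomekLinks:
    def test_matches_exhaustive_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_maj = int(rng.integers(28, 35))
            v = np.concatenate([rng.normal(0, 1, (n_maj, 2)),
                                rng.normal(0.8, 1, (50 - n_maj, 2))])
            labels = np.array(["a"] * n_maj + ["b"] * (50 - n_maj),
                              dtype=object)
            got = tomek_links(v, labels, np.random.default_rng(seed + 1000))
            expect = brute_force_tomek(v, labels, seed + 1000)
            assert got.tolist() == expect

    def test_separated_classes_balanced_by_random_undersampling(self, rng):
        v = np.concatenate([rng.normal(0, 0.1, (30, 2)),
                            rng.normal(100, 0.1, (20, 2))])
        labels = np.array(["a"] * 30 + ["b"] * 20, dtype=object)
        keep = tomek_links(v, labels, np.random.default_rng(0))
        kept = labels[keep]
        assert (kept == "a").sum() == (kept == "b").sum() == 20
        # no boundary pairs: all minority retained
        assert set(np.flatnonzero(labels == "b")) <= set(keep.tolist())

    def test_balanced_input_unchanged(self, rng):
        v = rng.standard_normal((40, 3))
        labels = np.array(["a", "b"] * 20, dtype=object)
        keep = tomek_links(v, labels, np.random.default_rng(0))
        assert keep.tolist() == list(range(40))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            tomek_links(rng.standard_normal((10, 2)),
                        np.array(["a"] * 10, dtype=object))


def spd_cluster(rng, center, n, spread=0.05):
    sqrt_c = spd_expm(0.5 * spd_logm(center))
    out = []
    for _ in range(n):
        step = rng.standard_normal(center.shape) * spread
        out.append(sqrt_c @ spd_expm(0.5 * (step + step.T)) @ sqrt_c)
    return np.stack(out)


class TestClassifiers:
    def _clusters(self, rng, n_per=30, spread=0.05):
        ca = np.eye(3)
        cb = np.diag([6.0, 1.0, 0.2])
        mats = np.concatenate([spd_cluster(rng, ca, n_per, spread),
                               spd_cluster(rng, cb, n_per, spread)])
        labels = np.array(["a"] * n_per + ["b"] * n_per, dtype=object)
        return SPDSet(mats, labels, np.zeros(2 * n_per))

    def test_mdm_separable_clusters_perfect(self, rng):
        train = self._clusters(rng)
        test = self._clusters(rng)
        assert (mdm_fit_predict(train, test) == test.labels).all()

    def test_mdm_test_point_at_centroid(self, rng):
        train = self._clusters(rng)
        cents = mdm_fit(train)
        test = SPDSet(cents["b"][None], np.array(["?"], object), np.zeros(1))
        assert mdm_predict(cents, test)[0] == "b"

    def test_mdm_random_labels_at_chance(self, rng):
        mats = spd_cluster(rng, np.eye(3), 200, spread=0.3)
        labels = np.array(["a", "b"] * 100, dtype=object)
        spd = SPDSet(mats, labels, np.zeros(200))
        pred = mdm_fit_predict(spd.select(range(100)),
                               spd.select(range(100, 200)))
        acc = np.mean([(pred[spd.labels[100:] == c] == c).mean()
                       for c in ("a", "b")])
        assert 0.4 <= acc <= 0.6

    def test_tsc_separable_clusters_perfect(self, rng):
        train = self._clusters(rng)
        test = self._clusters(rng)
        pred, proba = tsc_fit_predict(train, test)
        assert (pred == test.labels).all()
        assert np.all((proba >= 0) & (proba <= 1))
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_predictions_independent_of_test_labels(self, rng):
        train = self._clusters(rng, spread=0.4)
        test = self._clusters(rng, spread=0.4)
        shuffled = SPDSet(test.mats, test.labels[::-1].copy(), test.lambdas)
        assert (mdm_fit_predict(train, test)
                == mdm_fit_predict(train, shuffled)).all()
        assert (tsc_fit_predict(train, test)[0]
                == tsc_fit_predict(train, shuffled)[0]).all()


class TestCrossValidation:
    def test_separable_data_perfect_balanced_accuracy(self, rng):
        mats = np.concatenate([spd_cluster(rng, np.eye(3), 40),
                               spd_cluster(rng, np.diag([6.0, 1.0, 0.2]), 25)])
        labels = np.array(["a"] * 40 + ["b"] * 25, dtype=object)
        spd = SPDSet(mats, labels, np.zeros(65))
        cv = crossvalidate(spd, "mdm", seed=0)
        assert cv.balanced_accuracy == pytest.approx(1.0)
        assert cv.fold_balanced.shape == (5,)

    def test_balanced_accuracy_is_mean_of_recalls(self, rng):
        mats = np.concatenate([spd_cluster(rng, np.eye(3), 40),
                               spd_cluster(rng, np.diag([6.0, 1.0, 0.2]), 25)])
        labels = np.array(["a"] * 40 + ["b"] * 25, dtype=object)
        cv = crossvalidate(SPDSet(mats, labels, np.zeros(65)), "tsc", seed=1)
        assert np.allclose(cv.fold_balanced,
                           cv.fold_class_recall.mean(axis=1))

    def test_seed_determinism(self, rng):
        mats = spd_cluster(rng, np.eye(3), 60, spread=0.3)
        labels = np.array(["a", "b"] * 30, dtype=object)
        spd = SPDSet(mats, labels, np.zeros(60))
        a = crossvalidate(spd, "tsc", seed=3)
        b = crossvalidate(spd, "tsc", seed=3)
        assert np.array_equal(a.fold_balanced, b.fold_balanced)

    def test_insufficient_trials_rejected(self, rng):
        mats = spd_cluster(rng, np.eye(3), 7)
        labels = np.array(["a"] * 4 + ["b"] * 3, dtype=object)
        with pytest.raises(ValueError):
            crossvalidate(SPDSet(mats, labels, np.zeros(7)), "mdm")
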