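"""CRF energies, exact enumeration posterior, MAP and mean-field inference."""

import itertools

import numpy as np
import pytest

from specseg.crf import (
    CRFParams,
    EnergyModel,
    LabelField,
    approximate_map,
    energy,
    exact_marginals,
    exact_posterior,
    map_refine,
    mean_field_refine,
    pairwise_potential,
)
from specseg.errors import CapacityError, ShapeError, ValidationError


def _random_instance(rng, h=2, w=2, k=2, beta1=0.5, beta2=1.0, d=3):
    probs = rng.dirichlet(np.ones(k), size=(h, w))
    feats = rng.normal(size=(h, w, d))
    params = CRFParams(beta1=beta1, beta2=beta2, n_iters=10)
    return probs, feats, params


def _oracle_energy(labels, unary, feats, params):
    """Independent term-by-term summation over 4-connected pairs."""
    h, w = labels.shape
    e = sum(unary[r, c, labels[r, c]] for r in range(h) for c in range(w))
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < h and c2 < w:
                    e += params.beta1 * np.sum((feats[r, c] - feats[r2, c2]) ** 2)
                    e += params.beta2 * (labels[r, c] != labels[r2, c2])
    return e


class TestPairwisePotential:
    def test_identical_features_equal_labels(self):
        p = CRFParams(beta1=1.0, beta2=1.0)
        assert pairwise_potential([1, 2], [1, 2], 0, 0, p) == 0.0

    def test_squared_feature_distance(self):
        p = CRFParams(beta1=1.0, beta2=0.0)
        assert pairwise_potential([0, 0], [3, 4], 1, 1, p) == 25.0

    def test_potts_term(self):
        p = CRFParams(beta1=0.0, beta2=2.0)
        assert pairwise_potential([5, 5], [0, 1], 0, 1, p) == 2.0

    def test_negative_betas_rejected(self):
        with pytest.raises(ValidationError):
            CRFParams(beta1=-1.0)


class TestEnergy:
    def test_all_zero_potentials(self):
        model = EnergyModel(unary=np.zeros((2, 2, 2)), features=np.zeros((2, 2, 1)),
                            params=CRFParams(beta1=0, beta2=0))
        assert energy(LabelField(np.zeros((2, 2), int), 2), model) == 0.0

    def test_two_pixel_potts(self):
        model = EnergyModel(unary=np.zeros((1, 2, 2)), features=np.zeros((1, 2, 1)),
                            params=CRFParams(beta1=0, beta2=1))
        assert energy(LabelField(np.array([[0, 0]]), 2), model) == 0.0
        assert energy(LabelField(np.array([[0, 1]]), 2), model) == 1.0

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(20):
            probs, feats, params = _random_instance(rng)
            model = EnergyModel.from_probabilities(probs, feats, params)
            labels = rng.integers(0, 2, size=(2, 2))
            e = energy(LabelField(labels, 2), model)
            assert e == pytest.approx(
                _oracle_energy(labels, model.unary, feats, params), rel=1e-12
            )

    def test_shape_mismatch(self):
        model = EnergyModel(unary=np.zeros((2, 2, 2)), features=np.zeros((2, 2, 1)),
                            params=CRFParams())
        with pytest.raises(ShapeError):
            energy(LabelField(np.zeros((3, 3), int), 2), model)


class TestExactPosterior:
    def test_uniform_two_pixel_case(self):
        model = EnergyModel(unary=np.zeros((2, 1, 2)), features=np.zeros((2, 1, 1)),
                            params=CRFParams(beta1=0, beta2=0))
        table, z = exact_posterior(model)
        assert z == pytest.approx(4.0)
        assert all(p == pytest.approx(0.25) for p in table.values())

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(10):
            probs, feats, params = _random_instance(rng)
            model = EnergyModel.from_probabilities(probs, feats, params)
            table, z = exact_posterior(model)
            assert sum(table.values()) == pytest.approx(1.0, abs=1e-12)
            assert z > 0

    def test_strong_potts_concentrates_on_constant_labelings(self):
        params = CRFParams(beta1=0.0, beta2=10.0)
        model = EnergyModel(unary=np.zeros((2, 2, 2)), features=np.zeros((2, 2, 1)),
                            params=params)
        table, _ = exact_posterior(model)
        best = sorted(table, key=table.get, reverse=True)[:2]
        assert set(best) == {(0, 0, 0, 0), (1, 1, 1, 1)}
        assert table[best[0]] == pytest.approx(table[best[1]])

    def test_oversize_instance_capacity_error(self):
        model = EnergyModel(unary=np.zeros((6, 6, 3)), features=np.zeros((6, 6, 1)),
                            params=CRFParams())
        with pytest.raises(CapacityError, match="mean_field"):
            exact_posterior(model)

    def test_marginals_match_brute_force(self, rng):
        probs, feats, params = _random_instance(rng)
        model = EnergyModel.from_probabilities(probs, feats, params)
        table, _ = exact_posterior(model)
        marg = exact_marginals(model)
        brute = np.zeros((2, 2, 2))
        for labeling, p in table.items():
            arr = np.array(labeling).reshape(2, 2)
            for c in range(2):
                brute[:, :, c] += p * (arr == c)
        assert np.allclose(marg, brute, atol=1e-12)


class TestMapRefine:
    def test_zero_pairwise_reduces_to_argmax(self, rng):
        probs, feats, _ = _random_instance(rng, h=3, w=3)
        params = CRFParams(beta1=0.0, beta2=0.0)
        out = map_refine(probs, feats, params)
        assert np.array_equal(out.labels, np.argmax(probs, axis=2))

    def test_single_pixel(self):
        probs = np.array([[[0.2, 0.8]]])
        out = map_refine(probs, np.zeros((1, 1, 1)), CRFParams(beta2=5.0))
        assert out.labels[0, 0] == 1

    def test_map_invariant_to_beta1(self, rng):
        """The feature term shifts all labelings equally, so MAP ignores it."""
        for _ in range(20):
            probs, feats, _ = _random_instance(rng)
            maps = [
                map_refine(probs, feats, CRFParams(beta1=b1, beta2=1.0)).labels
                for b1 in (0.0, 1.0, 10.0)
            ]
            assert np.array_equal(maps[0], maps[1])
            assert np.array_equal(maps[0], maps[2])

    def test_unnormalized_input_rejected(self):
        bad = np.full((2, 2, 2), 0.4)
        with pytest.raises(ValidationError):
            map_refine(bad, np.zeros((2, 2, 1)), CRFParams())

    def test_approximate_map_attains_exact_energy_on_small_instances(self, rng):
        """Mean field plus label polishing reaches the enumerated MAP energy
        on nearly every small instance, and never beats it."""
        hits = 0
        n = 100
        for _ in range(n):
            probs, feats, params = _random_instance(rng, beta1=0.0,
                                                    beta2=rng.uniform(0, 2))
            model = EnergyModel.from_probabilities(probs, feats, params)
            exact = map_refine(probs, feats, params)
            approx = approximate_map(probs, feats, params)
            e_exact = energy(exact, model)
            e_approx = energy(approx, model)
            assert e_approx >= e_exact - 1e-9
            hits += e_approx <= e_exact + 1e-9
        assert hits >= 90


class TestMeanField:
    def test_zero_pairwise_is_identity(self, rng):
        probs, feats, _ = _random_instance(rng, h=4, w=4)
        params = CRFParams(beta1=0.0, beta2=0.0, n_iters=7)
        out = mean_field_refine(probs, feats, params)
        assert np.allclose(out, probs, atol=1e-9)

    def test_normalization_preserved_every_iteration(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(8, 8))
        feats = rng.normal(size=(8, 8, 2))
        for n_iters in range(1, 6):
            out = mean_field_refine(probs, feats, CRFParams(beta2=2.0, n_iters=n_iters))
            assert np.allclose(out.sum(axis=2), 1.0, atol=1e-9)
            assert np.all(out >= 0)

    def test_strong_potts_removes_label_islands(self):
        rng = np.random.default_rng(42)
        base = np.zeros((12, 12), dtype=int)
        base[3:9, 3:9] = 1
        noisy = base.copy()
        flips = rng.random(base.shape) < 0.08
        noisy[flips] = 1 - noisy[flips]
        probs = np.where(noisy[..., None] == np.arange(2), 0.9, 0.1)
        feats = np.zeros((12, 12, 1))
        out = mean_field_refine(probs, feats, CRFParams(beta2=3.0, n_iters=10))
        refined = np.argmax(out, axis=2)

        from scipy import ndimage

        def islands(arr):
            total = 0
            for v in (0, 1):
                _, n = ndimage.label(arr == v)
                total += n
            return total

        assert islands(refined) < islands(noisy)

    def test_marginals_approach_exact_as_coupling_vanishes(self, rng):
        probs, feats, _ = _random_instance(rng)
        errs = []
        for beta2 in (1.0, 0.1, 0.01):
            params = CRFParams(beta1=0.0, beta2=beta2, n_iters=30)
            model = EnergyModel.from_probabilities(probs, feats, params)
            q = mean_field_refine(probs, feats, params)
            errs.append(np.abs(q - exact_marginals(model)).max())
        assert errs[-1] < 1e-3
        assert errs[2] <= errs[0] + 1e-9

    def test_n_iters_validation(self):
        with pytest.raises(ValidationError):
            CRFParams(n_iters=0)

    def test_dense_neighborhood_matches_pairwise_definition(self, rng):
        """Dense energy counts every unordered pixel pair exactly once."""
        probs, feats, _ = _random_instance(rng)
        params = CRFParams(beta1=0.3, beta2=0.7, neighborhood="dense")
        model = EnergyModel.from_probabilities(probs, feats, params)
        labels = rng.integers(0, 2, size=(2, 2))
        e = energy(LabelField(labels, 2), model)
        flat_l = labels.ravel()
        flat_f = feats.reshape(4, -1)
        expect = sum(model.unary.reshape(4, 2)[i, flat_l[i]] for i in range(4))
        for i, j in itertools.combinations(range(4), 2):
            expect += 0.3 * np.sum((flat_f[i] - flat_f[j]) ** 2)
            expect += 0.7 * (flat_l[i] != flat_l[j])
        assert e == pytest.approx(expect, rel=1e-12)
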