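"""Objective terms against closed forms and independent brute-force oracles."""

import numpy as np
import pytest

import specseg.autodiff as ad
from specseg import losses as L
from specseg.errors import DataError, DomainError, NumericError, ValidationError
from specseg.phantoms import AnatomicalPriorSet


@pytest.fixture
def weights():
    return L.LossWeights()


class TestSupervised:
    def test_perfect_onehot_is_near_zero(self):
        probs = np.zeros((4, 4, 2))
        probs[..., 1] = 1.0
        mask = np.ones((4, 4), dtype=int)
        assert L.seg_loss(probs, mask) <= 1e-6

    def test_uniform_binary_is_ln2(self):
        probs = np.full((5, 5, 2), 0.5)
        mask = np.zeros((5, 5), dtype=int)
        assert L.seg_loss(probs, mask) == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_per_pixel_summation_oracle(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(6, 5))
        mask = rng.integers(0, 3, size=(6, 5))
        expect = np.mean(
            [-np.log(probs[r, c, mask[r, c]]) for r in range(6) for c in range(5)]
        )
        assert L.seg_loss(probs, mask) == pytest.approx(expect, abs=1e-6)

    def test_composite_arithmetic(self, weights):
        w = L.LossWeights(lambda_cls=0.5)
        assert L.composite_supervised(1.0, 2.0, w) == pytest.approx(2.0)
        w0 = L.LossWeights(lambda_cls=0.0)
        assert L.composite_supervised(1.0, 2.0, w0) == pytest.approx(1.0)

    def test_perfect_class_prediction(self):
        assert L.cls_loss(np.array([0.0, 1.0]), 1) <= 1e-6

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            L.LossWeights(lambda_da=-1.0)
        with pytest.raises(ValidationError):
            L.LossWeights(tau=0.0)


class TestDomainAlignment:
    def test_identical_singletons(self):
        b = L.DomainBatch(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]))
        assert L.domain_alignment_loss(b) == pytest.approx(0.0)

    def test_three_four_five(self):
        b = L.DomainBatch(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
        assert L.domain_alignment_loss(b) == pytest.approx(25.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            fs = rng.normal(size=(rng.integers(1, 6), 4))
            ft = rng.normal(size=(rng.integers(1, 6), 4))
            expect = np.mean(
                [np.sum((a - b) ** 2) for a in fs for b in ft]
            )
            got = L.domain_alignment_loss(L.DomainBatch(fs, ft))
            assert got == pytest.approx(expect, abs=1e-6)

    def test_dimension_mismatch(self):
        with pytest.raises(Exception):
            L.DomainBatch(np.zeros((2, 3)), np.zeros((2, 4)))


class TestDiscriminator:
    def test_chance_level_value(self):
        d = np.full(8, 0.5)
        assert L.discriminator_loss(d, d) == pytest.approx(2 * np.log(0.5))

    def test_perfect_discrimination_approaches_zero(self):
        before = L.CLAMP_COUNTER["count"]
        with pytest.warns(UserWarning):
            v = L.discriminator_loss(np.ones(4), np.zeros(4))
        assert -1e-6 <= v <= 0.0
        assert L.CLAMP_COUNTER["count"] > before

    def test_always_nonpositive(self, rng):
        for _ in range(20):
            v = L.discriminator_loss(rng.uniform(0.01, 0.99, 5),
                                     rng.uniform(0.01, 0.99, 5))
            assert v <= 0.0

    def test_label_swap_maximized_at_half(self):
        vals = {p: np.log(p) + np.log(1 - p) for p in np.arange(0.1, 0.95, 0.1)}
        assert max(vals, key=vals.get) == pytest.approx(0.5)

    def test_adversarial_objective_arithmetic(self):
        w1 = L.LossWeights(lambda_adv=1.0)
        assert L.adversarial_objective(25.0, -1.3863, w1) == pytest.approx(23.6137)
        w0 = L.LossWeights(lambda_adv=0.0)
        assert L.adversarial_objective(25.0, -1.3863, w0) == pytest.approx(25.0)

    def test_alternating_updates_reduce_encoder_objective(self):
        """A linear encoder on 2-D shifted toy domains learns to align."""
        rng = np.random.default_rng(0)
        xs = rng.normal(size=(16, 2))
        xt = rng.normal(size=(16, 2)) + np.array([3.0, -2.0])
        enc = {"w": ad.Tensor(np.eye(2), requires_grad=True),
               "b": ad.Tensor(np.zeros(2), requires_grad=True)}
        opt = ad.Adam(enc, lr=0.05)
        w = L.LossWeights()

        def encode(x):
            return ad.Tensor(x) @ enc["w"] + enc["b"]

        def objective():
            return L.domain_alignment_loss(
                L.DomainBatch(encode(xs), encode(xt))
            )

        start = float(objective().data)
        for _ in range(50):
            obj = objective()
            opt.zero_grad()
            obj.backward()
            opt.step()
        assert float(objective().data) < start


class TestContrastive:
    def test_cosine_cases(self):
        assert L.cosine_sim([1.0, 0.0], [1.0, 0.0]) == pytest.approx(1.0)
        assert L.cosine_sim([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)
        assert L.cosine_sim([1.0, 2.0], [-1.0, -2.0]) == pytest.approx(-1.0)
        with pytest.raises(DomainError):
            L.cosine_sim([0.0, 0.0], [1.0, 0.0])

    def test_identical_embeddings_give_b_ln_b(self):
        e = np.array([[1.0, 1.0], [1.0, 1.0]])
        v = L.contrastive_loss(L.EmbeddingBatch(e, e), tau=0.07)
        assert v == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_orthogonal_pair_closed_form(self):
        v1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        v = L.contrastive_loss(L.EmbeddingBatch(v1, v1.copy()), tau=1.0)
        assert v == pytest.approx(2 * (np.log(np.e + 1) - 1), abs=1e-6)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            b = rng.integers(2, 7)
            v1 = rng.normal(size=(b, 5))
            v2 = rng.normal(size=(b, 5))

            def cos(u, w):
                return u @ w / (np.linalg.norm(u) * np.linalg.norm(w))

            tau = 0.07
            expect = 0.0
            for i in range(b):
                num = np.exp(cos(v1[i], v2[i]) / tau)
                den = sum(np.exp(cos(v1[i], v2[j]) / tau) for j in range(b))
                expect -= np.log(num / den)
            got = L.contrastive_loss(L.EmbeddingBatch(v1, v2), tau)
            assert got == pytest.approx(expect, abs=1e-6)

    def test_decreases_when_positive_similarity_rises(self):
        """Rotate v2_0 toward v1_0 in a plane orthogonal to every other
        embedding, so only the one positive similarity changes."""
        e1, e2, e3 = np.eye(3)
        v1 = np.stack([e1, e2])
        losses = []
        for theta in (1.2, 0.8, 0.4, 0.0):
            v2 = np.stack([np.cos(theta) * e1 + np.sin(theta) * e3, e2])
            losses.append(L.contrastive_loss(L.EmbeddingBatch(v1, v2), 0.5))
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_nonnegative(self, rng):
        for _ in range(10):
            v = L.contrastive_loss(
                L.EmbeddingBatch(rng.normal(size=(4, 3)), rng.normal(size=(4, 3))),
                0.07,
            )
            assert v >= 0


class TestKnowledgeRegularization:
    def test_matching_distances_give_zero(self):
        prior = AnatomicalPriorSet(pairs=((0, 1, 5.0),))
        cents = {0: (0.0, 0.0), 1: (3.0, 4.0)}
        assert L.knowledge_reg_loss(cents, prior) == pytest.approx(0.0, abs=1e-9)

    def test_single_pair_gap(self):
        prior = AnatomicalPriorSet(pairs=((0, 1, 5.0),))
        cents = {0: (0.0, 0.0), 1: (0.0, 3.0)}
        assert L.knowledge_reg_loss(cents, prior) == pytest.approx(4.0, abs=1e-9)

    def test_translation_invariance(self, rng):
        prior = AnatomicalPriorSet(pairs=((0, 1, 2.0), (1, 2, 4.0), (0, 2, 3.0)))
        cents = {i: tuple(rng.normal(size=2)) for i in range(3)}
        shifted = {i: (r + 10.0, c - 7.0) for i, (r, c) in cents.items()}
        assert L.knowledge_reg_loss(cents, prior) == pytest.approx(
            L.knowledge_reg_loss(shifted, prior), rel=1e-9
        )

    def test_missing_structure_named(self):
        prior = AnatomicalPriorSet(pairs=((0, 3, 5.0),))
        with pytest.raises(DataError, match="3"):
            L.knowledge_reg_loss({0: (0.0, 0.0)}, prior)

    def test_soft_centroid_point_mass_and_split_mass(self):
        m = np.zeros((5, 5))
        m[2, 3] = 1.0
        assert L.soft_centroid(m) == pytest.approx((2.0, 3.0))
        m2 = np.zeros((3, 3))
        m2[0, 0] = m2[0, 2] = 0.5
        assert L.soft_centroid(m2) == pytest.approx((0.0, 1.0))


class TestUncertainty:
    def test_confident_and_correct(self):
        probs = np.zeros((3, 3, 2))
        probs[..., 1] = 1.0
        assert L.uncertainty_loss(probs, np.ones((3, 3), int)) == pytest.approx(0.0)

    def test_confident_and_wrong(self):
        probs = np.zeros((3, 3, 2))
        probs[..., 1] = 1.0
        assert L.uncertainty_loss(probs, np.zeros((3, 3), int)) == pytest.approx(1.0)

    def test_half_confident_half_correct(self):
        probs = np.full((2, 2, 2), 0.5)
        mask = np.array([[0, 0], [1, 1]])  # argmax ties to 0: half correct
        assert L.uncertainty_loss(probs, mask) == pytest.approx(0.25)

    def test_bounded(self, rng):
        probs = rng.dirichlet(np.ones(3), size=(4, 4))
        mask = rng.integers(0, 3, size=(4, 4))
        assert 0.0 <= L.uncertainty_loss(probs, mask) <= 1.0


class TestTotalLoss:
    def test_published_weights_arithmetic(self):
        w = L.LossWeights()  # lambda_cls=1, da=1, cl=0.5, kr=1, uc=0.2
        rep = L.total_loss(1, 1, 1, 1, 1, 1, 1, w)
        assert rep.total == pytest.approx(4.7)

    def test_zero_weights_leave_seg(self):
        w = L.LossWeights(lambda_cls=0, lambda_da=0, lambda_cl=0, lambda_kr=0,
                          lambda_uc=0)
        assert L.total_loss(3.0, 9, 9, 9, 9, 9, 9, w).total == pytest.approx(3.0)

    def test_linear_in_each_part(self):
        w = L.LossWeights()
        base = L.total_loss(1, 1, 1, 1, 1, 1.0, 1, w).total
        doubled = L.total_loss(1, 1, 1, 1, 1, 2.0, 1, w).total
        assert doubled - base == pytest.approx(w.lambda_kr * 1.0)

    def test_nonfinite_part_named(self):
        with pytest.raises(NumericError, match="kr"):
            L.total_loss(1, 1, 1, 1, 1, np.nan, 1, L.LossWeights())


class TestGradients:
    """The Tensor path of each loss agrees with central differences."""

    def test_contrastive_gradient(self, rng):
        v1 = rng.normal(size=(3, 4))
        v2 = rng.normal(size=(3, 4))
        t1 = ad.Tensor(v1, requires_grad=True)
        loss = L.contrastive_loss(L.EmbeddingBatch(t1, ad.Tensor(v2)), 0.5)
        loss.backward()
        eps = 1e-6
        for i in [(0, 0), (2, 3)]:
            v1[i] += eps
            up = L.contrastive_loss(L.EmbeddingBatch(v1, v2), 0.5)
            v1[i] -= 2 * eps
            dn = L.contrastive_loss(L.EmbeddingBatch(v1, v2), 0.5)
            v1[i] += eps
            assert t1.grad[i] == pytest.approx((up - dn) / (2 * eps), abs=1e-4)

    def test_domain_alignment_gradient(self, rng):
        fs = rng.normal(size=(3, 4))
        ft = rng.normal(size=(2, 4))
        t = ad.Tensor(fs, requires_grad=True)
        L.domain_alignment_loss(L.DomainBatch(t, ad.Tensor(ft))).backward()
        eps = 1e-6
        fs[0, 0] += eps
        up = L.domain_alignment_loss(L.DomainBatch(fs, ft))
        fs[0, 0] -= 2 * eps
        dn = L.domain_alignment_loss(L.DomainBatch(fs, ft))
        fs[0, 0] += eps
        assert t.grad[0, 0] == pytest.approx((up - dn) / (2 * eps), abs=1e-5)
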