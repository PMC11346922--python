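"""Pair sampling law, batch structure and the NT-Xent objective."""

import numpy as np
import pytest
from scipy import stats

from rascl import nn
from rascl.augmentation import AugmentationConfig
from rascl.contrastive import (
    ContrastiveConfig,
    build_pair_batch,
    neighbor_support,
    nt_xent_loss,
    nt_xent_loss_and_grad,
    sample_positive_pair,
)
from rascl.exceptions import BatchError, DomainError, SamplingError


def nt_xent_oracle(projections, tau):
    """Independent double-loop NT-Xent: explicit softmax denominator sums."""
    z = np.asarray(projections, dtype=float)
    m = len(z)
    zh = z / np.linalg.norm(z, axis=1, keepdims=True)
    total = 0.0
    for k in range(m // 2):
        for i, j in ((2 * k, 2 * k + 1), (2 * k + 1, 2 * k)):
            num = np.exp(zh[i] @ zh[j] / tau)
            den = 0.0
            for other in range(m):
                if other != i:
                    den += np.exp(zh[i] @ zh[other] / tau)
            total += -np.log(num / den)
    return total / m


_AUG32 = AugmentationConfig(output_size=(32, 32))


class TestSamplePositivePair:
    def test_interior_anchor_neighbors_uniform(self):
        """5-slice volume, anchor 2, D=2: neighbors {0,1,3,4} equally likely
        (chi-squared over 10^4 draws, alpha 0.01)."""
        g = np.random.default_rng(0)
        draws = [sample_positive_pair(5, 2, g, anchor=2)[1] for _ in range(10_000)]
        values, counts = np.unique(draws, return_counts=True)
        assert list(values) == [0, 1, 3, 4]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_edge_anchor_support_clipped(self):
        g = np.random.default_rng(1)
        draws = {sample_positive_pair(5, 2, g, anchor=0)[1] for _ in range(200)}
        assert draws == {1, 2}

    def test_neighbor_never_equals_anchor(self):
        g = np.random.default_rng(2)
        for _ in range(500):
            a, b = sample_positive_pair(7, 2, g)
            assert a != b and 1 <= abs(a - b) <= 2

    def test_single_slice_rejected(self, rng):
        with pytest.raises(SamplingError):
            sample_positive_pair(1, 2, rng)

    @pytest.mark.parametrize("n", range(2, 10))
    @pytest.mark.parametrize("d_max", [1, 2, 3])
    def test_joint_law_matches_renormalized_uniform(self, n, d_max):
        """For every volume size 2-9 and D in {1,2,3}: the (anchor, neighbor)
        frequencies over 10^4 draws match (1/n) * uniform-over-clipped-support
        by chi-squared at alpha 0.01, and offset 0 never occurs."""
        g = np.random.default_rng(n * 100 + d_max)
        counts = np.zeros((n, n))
        for _ in range(10_000):
            a, b = sample_positive_pair(n, d_max, g)
            counts[a, b] += 1
        assert np.trace(counts) == 0  # offset 0 never observed
        expected = np.zeros((n, n))
        for a in range(n):
            support = neighbor_support(a, n, d_max)
            for b in support:
                expected[a, b] = 1.0 / (n * len(support))
        mask = expected > 0
        assert np.all(counts[~mask] == 0)
        res = stats.chisquare(counts[mask], 10_000 * expected[mask])
        assert res.pvalue > 0.01

    def test_resample_mode_interior_unchanged(self):
        g = np.random.default_rng(3)
        for _ in range(300):
            a, b = sample_positive_pair(7, 2, g, boundary_mode="resample")
            assert 0 <= b < 7 and 1 <= abs(a - b) <= 2


class TestBuildPairBatch:
    def _cfg(self, n_pairs):
        return ContrastiveConfig(batch_pairs=n_pairs)

    def test_batch_structure(self, small_cohort, rng):
        batch = build_pair_batch(
            small_cohort.manifest, small_cohort.volumes, self._cfg(4), _AUG32, rng
        )
        assert batch.views.shape == (8, 32, 32)
        assert len(set(batch.eye_ids)) == 4
        for k in range(4):
            assert batch.eye_ids[2 * k] == batch.eye_ids[2 * k + 1]
        assert all(1 <= abs(d) <= 2 for d in batch.offsets)

    def test_patient_disjoint_within_batch(self, small_cohort, rng):
        batch = build_pair_batch(
            small_cohort.manifest, small_cohort.volumes, self._cfg(8), _AUG32, rng
        )
        patients = dict(
            zip(small_cohort.manifest["eye_id"], small_cohort.manifest["patient_id"])
        )
        batch_patients = [patients[e] for e in batch.eye_ids[::2]]
        assert len(set(batch_patients)) == 8

    def test_insufficient_eyes_rejected(self, small_cohort, rng):
        with pytest.raises(BatchError):
            build_pair_batch(
                small_cohort.manifest, small_cohort.volumes, self._cfg(1000), _AUG32, rng
            )

    def test_fixed_seed_reproducible(self, small_cohort):
        batches = [
            build_pair_batch(
                small_cohort.manifest,
                small_cohort.volumes,
                self._cfg(4),
                _AUG32,
                np.random.default_rng(5),
            )
            for _ in range(2)
        ]
        assert batches[0].eye_ids == batches[1].eye_ids
        assert np.array_equal(batches[0].views, batches[1].views)


class TestNTXent:
    def test_orthogonal_pairs_closed_form(self):
        """Two orthogonal unit pairs at tau=1: loss = log(1 + 2/e)."""
        e1, e2 = np.eye(2)
        z = np.array([e1, e1, e2, e2])
        assert nt_xent_loss(z, 1.0) == pytest.approx(np.log(1 + 2 / np.e), abs=1e-12)

    def test_collapsed_projections_closed_form(self):
        """All four projections identical: every similarity equal, loss = log 3."""
        z = np.tile([1.0, 0.0], (4, 1))
        assert nt_xent_loss(z, 1.0) == pytest.approx(np.log(3), abs=1e-12)

    @pytest.mark.parametrize("tau", [0.1, 0.5, 1.0])
    def test_matches_double_loop_oracle(self, tau):
        g = np.random.default_rng(int(tau * 10))
        for _ in range(30):
            n = int(g.integers(2, 5))
            z = g.normal(size=(2 * n, 8))
            assert nt_xent_loss(z, tau) == pytest.approx(
                nt_xent_oracle(z, tau), abs=1e-6
            )

    def test_invariances(self, rng):
        """Permuting pairs, swapping views within a pair, and rescaling a
        single projection all leave the loss unchanged."""
        z = rng.normal(size=(8, 5))
        base = nt_xent_loss(z, 0.5)
        perm = np.concatenate([z[4:6], z[0:2], z[6:8], z[2:4]])
        assert nt_xent_loss(perm, 0.5) == pytest.approx(base, abs=1e-12)
        swapped = z.copy()
        swapped[[2, 3]] = swapped[[3, 2]]
        assert nt_xent_loss(swapped, 0.5) == pytest.approx(base, abs=1e-12)
        scaled = z.copy()
        scaled[5] *= 42.0
        assert nt_xent_loss(scaled, 0.5) == pytest.approx(base, abs=1e-12)

    def test_tightening_a_positive_pair_lowers_loss(self, rng):
        """With negatives fixed, raising a positive pair's cosine similarity
        never increases the loss."""
        z = rng.normal(size=(8, 4))
        target = z[0] / np.linalg.norm(z[0])
        losses = []
        for alpha in np.linspace(0.0, 0.95, 8):
            zz = z.copy()
            zz[1] = (1 - alpha) * z[1] / np.linalg.norm(z[1]) + alpha * target
            losses.append(nt_xent_loss(zz, 0.5))
        assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_gradient_descent_decreases_loss(self, rng):
        """100 steps of a linear projection model on a fixed batch strictly
        decrease the contrastive loss."""
        x = rng.normal(size=(8, 10))
        w = nn.Parameter(rng.normal(size=(10, 6)) * 0.3)
        losses = []
        for _ in range(100):
            z = x @ w.data
            loss, dz = nt_xent_loss_and_grad(z, 0.5)
            losses.append(loss)
            w.data -= 0.1 * (x.T @ dz)
        assert losses[-1] < losses[0]
        assert losses[-1] < 0.9 * losses[0]

    def test_zero_projection_rejected(self):
        z = np.array([[1.0, 0], [0, 0], [1, 1], [1, -1]])
        with pytest.raises(DomainError):
            nt_xent_loss(z, 1.0)
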