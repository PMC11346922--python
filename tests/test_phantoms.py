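"""Phantom generator: lesion rendering, demographics, coherence, determinism."""

import numpy as np
import pytest
from scipy import stats

from rascl.exceptions import ConfigurationError
from rascl.phantoms import (
    CohortConfig,
    RetinaPhantomParams,
    detect_full_thickness_defect,
    generate_challenge_set,
    generate_cohort,
    generate_eye,
)


def _noiseless_params(**kw):
    defaults = dict(image_height=64, image_width=64, speckle_sigma=0.0)
    defaults.update(kw)
    return RetinaPhantomParams(**defaults)


class TestGenerateEye:
    def test_ftmh_removes_inner_signal_in_foveal_band(self):
        """A hole column has near-zero signal between surface and RPE while
        flanking columns keep bright inner retina."""
        params = _noiseless_params(lesion_class="ftmh", lesion_width=12)
        vol, _ = generate_eye(params, rng=np.random.default_rng(3))
        img = vol.slices[vol.central_slice_index]
        h, w = img.shape
        # locate the hole: columns whose first supra-0.2 pixel is deepest
        deep = img > 0.2
        first = np.where(deep.any(axis=0), deep.argmax(axis=0), h - 1)
        hole_cols = np.flatnonzero(first > np.median(first) + 0.08 * h)
        assert len(hole_cols) >= 8
        surface = int(np.median(first))
        for c in hole_cols[2:-2]:
            inner = img[surface + 2 : first[c] - 2, c]
            assert inner.mean() < 0.05
        flank = np.concatenate([img[surface + 1 : surface + 5, hole_cols[0] - 6],
                                img[surface + 1 : surface + 5, hole_cols[-1] + 6]])
        assert flank.mean() > 0.3

    def test_lamellar_keeps_rpe_bright_under_defect(self):
        params = _noiseless_params(lesion_class="lamellar", lesion_width=10)
        vol, _ = generate_eye(params, rng=np.random.default_rng(5))
        img = vol.slices[vol.central_slice_index]
        # across every column (defect included) the column max is RPE-bright
        assert np.all(img.max(axis=0) > 0.3)
        assert not detect_full_thickness_defect(img)

    def test_control_erm_has_unbroken_layers(self):
        params = _noiseless_params(lesion_class="control_erm")
        vol, _ = generate_eye(params, rng=np.random.default_rng(1))
        img = vol.slices[vol.central_slice_index]
        # no column has a full-depth gap: every column retains tissue > 0.25
        assert np.all(img.max(axis=0) > 0.25)
        assert not detect_full_thickness_defect(img)

    def test_intensities_within_unit_interval(self):
        params = RetinaPhantomParams(
            image_height=48, image_width=48, speckle_sigma=0.8, lesion_class="ftmh"
        )
        vol, _ = generate_eye(params, rng=np.random.default_rng(0))
        assert vol.slices.min() >= 0.0 and vol.slices.max() <= 1.0

    def test_same_seed_gives_bit_identical_stacks(self):
        params = _noiseless_params(lesion_class="ftmh", speckle_sigma=0.3)
        v1, _ = generate_eye(params, rng=np.random.default_rng(11))
        v2, _ = generate_eye(params, rng=np.random.default_rng(11))
        assert np.array_equal(v1.slices, v2.slices)

    @pytest.mark.parametrize(
        "kw",
        [
            {"lesion_class": "nonsense"},
            {"image_height": 16},
            {"n_slices": 2},
            {"speckle_sigma": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            generate_eye(_noiseless_params(**kw), rng=np.random.default_rng(0))


class TestCohorts:
    def test_default_study_counts(self):
        """Default configuration reproduces the 334-eye cohort composition."""
        cfg = CohortConfig(image_height=32, image_width=32, n_slices=3)
        _, manifest = generate_cohort(cfg, np.random.default_rng(0))
        counts = manifest["diagnosis"].value_counts().to_dict()
        assert len(manifest) == 334
        assert counts == {"ERM": 273, "FTMH": 61}

    def test_small_request_and_zero_class(self):
        cfg = CohortConfig(n_ftmh=2, n_erm=0, image_height=32, image_width=32, n_slices=3)
        vols, manifest = generate_cohort(cfg, np.random.default_rng(0))
        assert len(manifest) == 2 and set(manifest["diagnosis"]) == {"FTMH"}
        assert len(vols) == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(
                CohortConfig(n_ftmh=0, n_erm=0), np.random.default_rng(0)
            )

    def test_age_distribution_matches_configuration(self):
        """FTMH ages ~ N(69.6, 6.4): a 1000-eye sample mean lands within the
        3-sigma CLT band around 69.6."""
        cfg = CohortConfig(
            n_ftmh=1000, n_erm=0, image_height=32, image_width=32, n_slices=3
        )
        _, manifest = generate_cohort(cfg, np.random.default_rng(123))
        assert abs(manifest["age"].mean() - 69.6) < 3 * 6.4 / np.sqrt(1000)

    def test_patients_have_at_most_two_eyes(self):
        cfg = CohortConfig(
            n_ftmh=30, n_erm=30, two_eye_prob=0.5,
            image_height=32, image_width=32, n_slices=3,
        )
        _, manifest = generate_cohort(cfg, np.random.default_rng(2))
        per_patient = manifest.groupby("patient_id")["eye_id"].nunique()
        assert per_patient.max() <= 2 and (per_patient == 2).any()
        # both eyes of a patient share the diagnosis
        for _, sub in manifest.groupby("patient_id"):
            assert sub["diagnosis"].nunique() == 1

    def test_reproducible_from_seed(self):
        cfg = CohortConfig(n_ftmh=3, n_erm=3, image_height=32, image_width=32, n_slices=3)
        v1, m1 = generate_cohort(cfg, np.random.default_rng(9))
        v2, m2 = generate_cohort(cfg, np.random.default_rng(9))
        assert m1.equals(m2)
        assert all(np.array_equal(a.slices, b.slices) for a, b in zip(v1, v2))


class TestChallengeSet:
    def test_default_count_is_34_lamellar_eyes(self):
        cfg = CohortConfig(image_height=32, image_width=32, n_slices=3)
        vols, manifest = generate_challenge_set(cfg, np.random.default_rng(0))
        assert len(manifest) == 34
        assert set(manifest["diagnosis"]) == {"LAMELLAR"}

    def test_single_eye_challenge(self):
        cfg = CohortConfig(image_height=32, image_width=32, n_slices=3)
        _, manifest = generate_challenge_set(cfg, np.random.default_rng(0), count=1)
        assert len(manifest) == 1

    def test_zero_count_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_challenge_set(count=0)


class TestCohortProperties:
    def test_within_eye_coherence_exceeds_between_eye(self):
        """Adjacent slices of one eye correlate more strongly than central
        slices of distinct eyes — the signal slice-offset positive pairs
        rely on (one-sided Mann-Whitney, p < 0.01, 50 noiseless eyes)."""
        cfg = CohortConfig(
            n_ftmh=25, n_erm=25, image_height=64, image_width=64, speckle_sigma=0.0
        )
        vols, _ = generate_cohort(cfg, np.random.default_rng(21))
        within = [
            np.corrcoef(v.slices[i].ravel(), v.slices[i + 1].ravel())[0, 1]
            for v in vols
            for i in range(v.n_slices - 1)
        ]
        centrals = [v.slices[v.central_slice_index].ravel() for v in vols]
        idx = np.random.default_rng(0).choice(len(centrals), size=(300, 2))
        across = [
            np.corrcoef(centrals[i], centrals[j])[0, 1] for i, j in idx if i != j
        ]
        res = stats.mannwhitneyu(within, across, alternative="greater")
        assert np.mean(within) > np.mean(across)
        assert res.pvalue < 0.01

    def test_pixel_oracle_separates_classes_perfectly(self):
        """On noiseless phantoms the full-depth-defect oracle classifies FTMH
        vs control/lamellar with 100% accuracy, so the downstream task is
        learnable by construction."""
        cfg = CohortConfig(
            n_ftmh=15, n_erm=15, n_lamellar=15,
            image_height=64, image_width=64, speckle_sigma=0.0,
        )
        vols, manifest = generate_cohort(cfg, np.random.default_rng(33))
        for vol, diagnosis in zip(vols, manifest["diagnosis"]):
            img = vol.slices[vol.central_slice_index]
            assert detect_full_thickness_defect(img) == (diagnosis == "FTMH")
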