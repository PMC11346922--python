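"""Random Slice Contrastive Learning: pair sampling and the NT-Xent objective.

Positive pairs are two B-scans of the *same* eye at a slice offset of at most
``max_offset`` (default 2) on either side, drawn uniformly over the in-bounds
nonzero offsets; every other view in the batch comes from an unrelated eye
and acts as a negative.  Near volume edges the offset support is clipped to
in-bounds indices and the uniform law renormalised over what remains (a
rejection-and-resample alternative is available as a config switch).

The objective is the SimCLR normalised-temperature cross-entropy (NT-Xent)
over cosine similarities of L2-normalised projections:

    l(i, j) = -log [ exp(sim(z_i, z_j)/tau) / sum_{k != i} exp(sim(z_i, z_k)/tau) ]

averaged over both directions of every pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augmentation import AugmentationConfig, augment_view
from .data_io import BScanVolume
from .exceptions import BatchError, ConfigurationError, DomainError, SamplingError

__all__ = [
    "ContrastiveConfig",
    "SlicePairBatch",
    "neighbor_support",
    "sample_positive_pair",
    "build_pair_batch",
    "nt_xent_loss",
    "nt_xent_loss_and_grad",
]


@dataclass
class ContrastiveConfig:
    max_offset: int = 2  # D: slices on either side eligible as positives
    temperature: float = 0.5  # tau; SimCLR-recommended region
    batch_pairs: int = 16  # N positive pairs (2N views) per batch
    embedding_dim: int = 512
    boundary_mode: str = "clip"  # clip | resample

    def validate(self) -> None:
        if self.max_offset < 1:
            raise ConfigurationError("max_offset must be >= 1")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        if self.batch_pairs < 2:
            raise ConfigurationError("batch_pairs must be >= 2")
        if self.boundary_mode not in ("clip", "resample"):
            raise ConfigurationError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass
class SlicePairBatch:
    """2N augmented views with pair bookkeeping.

    Views at indices (2k, 2k+1) form positive pair k and share an eye;
    all other cross-pair view combinations are from distinct eyes.
    """

    views: np.ndarray  # (2N, H, W)
    eye_ids: list[str]
    anchor_indices: list[int]
    offsets: list[int]

    @property
    def n_pairs(self) -> int:
        return self.views.shape[0] // 2


def neighbor_support(anchor: int, n_slices: int, max_offset: int) -> list[int]:
    """In-bounds neighbor indices {anchor+d : 1 <= |d| <= D}, excluding the anchor."""
    return [
        anchor + d
        for d in range(-max_offset, max_offset + 1)
        if d != 0 and 0 <= anchor + d < n_slices
    ]


def sample_positive_pair(
    volume: BScanVolume | int,
    max_offset: int,
    rng: np.random.Generator,
    anchor: int | None = None,
    boundary_mode: str = "clip",
) -> tuple[int, int]:
    """Draw (anchor_index, neighbor_index) for one positive pair.

    The anchor is uniform over the eligible slices and the neighbor uniform
    over the anchor's in-bounds nonzero offsets; a neighbor never equals its
    anchor.  ``volume`` may be a :class:`BScanVolume` or a plain slice count.
    In ``resample`` boundary mode, anchor/offset draws whose offset falls out
    of bounds are rejected and the anchor redrawn, rather than renormalising
    the clipped support.
    """
    n = volume.n_slices if isinstance(volume, BScanVolume) else int(volume)
    if n < 2:
        raise SamplingError(f"cannot sample a positive pair from {n} slice(s)")
    if max_offset < 1:
        raise DomainError("max_offset must be >= 1")
    if anchor is not None:
        support = neighbor_support(anchor, n, max_offset)
        if not support:
            raise SamplingError(f"anchor {anchor} has no in-bounds neighbors")
        return anchor, int(rng.choice(support))
    if boundary_mode == "resample":
        while True:
            a = int(rng.integers(0, n))
            d = int(rng.choice([d for d in range(-max_offset, max_offset + 1) if d != 0]))
            if 0 <= a + d < n:
                return a, a + d
    a = int(rng.integers(0, n))
    return a, int(rng.choice(neighbor_support(a, n, max_offset)))


def build_pair_batch(
    manifest: pd.DataFrame,
    volumes: dict[str, BScanVolume],
    config: ContrastiveConfig,
    augmentation_config: AugmentationConfig,
    rng: np.random.Generator,
    slice_windows: dict[str, list[int]] | None = None,
) -> SlicePairBatch:
    """Assemble one contrastive batch of N positive pairs.

    N eyes are drawn without replacement, at most one eye per patient, so
    every cross-pair view is from an unrelated eye.  Both views of a pair are
    augmented independently.  ``slice_windows`` optionally restricts sampling
    to a contiguous run of each eye's slices (e.g. the three scans centred on
    the fovea used during training); offsets are then clipped to the window.
    """
    config.validate()
    n_pairs = config.batch_pairs

    eligible: list[tuple[str, str]] = []  # (patient_id, eye_id)
    for row in manifest.itertuples():
        eye = str(row.eye_id)
        if eye not in volumes:
            continue
        window = slice_windows.get(eye) if slice_windows else None
        n_avail = len(window) if window is not None else volumes[eye].n_slices
        if n_avail >= 2:
            eligible.append((str(row.patient_id), eye))

    by_patient: dict[str, list[str]] = {}
    for pid, eye in eligible:
        by_patient.setdefault(pid, []).append(eye)
    patients = sorted(by_patient)
    if len(patients) < n_pairs:
        raise BatchError(
            f"need {n_pairs} eligible eyes from distinct patients, have {len(patients)}"
        )
    chosen_patients = rng.choice(np.asarray(patients, dtype=object), size=n_pairs, replace=False)

    views, eye_ids, anchors, offsets = [], [], [], []
    for pid in chosen_patients:
        eyes = by_patient[str(pid)]
        eye = str(eyes[int(rng.integers(0, len(eyes)))])
        vol = volumes[eye]
        window = slice_windows.get(eye) if slice_windows else None
        if window is not None:
            a_local, nb_local = sample_positive_pair(
                len(window), config.max_offset, rng, boundary_mode=config.boundary_mode
            )
            a, nb = window[a_local], window[nb_local]
        else:
            a, nb = sample_positive_pair(
                vol, config.max_offset, rng, boundary_mode=config.boundary_mode
            )
        for idx in (a, nb):
            views.append(augment_view(vol.slices[idx], augmentation_config, rng))
            eye_ids.append(eye)
        anchors.append(a)
        offsets.append(nb - a)
    return SlicePairBatch(
        views=np.stack(views), eye_ids=eye_ids, anchor_indices=anchors, offsets=offsets
    )


# ---------------------------------------------------------------------------
# NT-Xent


def _normalized(projections: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(projections, dtype=np.float64)
    if z.ndim != 2 or z.shape[0] < 4 or z.shape[0] % 2:
        raise DomainError(f"projections must be (2N, d) with N >= 2, got {z.shape}")
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0):
        raise DomainError("zero-norm projection")
    return z / norms[:, None], norms


def nt_xent_loss(projections: np.ndarray, temperature: float) -> float:
    """NT-Xent loss over views ordered so (2k, 2k+1) are positive pairs."""
    loss, _ = nt_xent_loss_and_grad(projections, temperature)
    return loss


def nt_xent_loss_and_grad(projections: np.ndarray, temperature: float):
    """Loss plus its gradient with respect to the raw (unnormalised) projections."""
    if temperature <= 0:
        raise DomainError("temperature must be > 0")
    zhat, norms = _normalized(projections)
    m = zhat.shape[0]
    partner = np.arange(m) ^ 1  # 0<->1, 2<->3, ...

    sim = zhat @ zhat.T / temperature
    np.fill_diagonal(sim, -np.inf)
    smax = sim.max(axis=1, keepdims=True)
    p = np.exp(sim - smax)
    p /= p.sum(axis=1, keepdims=True)
    loss = float(-np.mean(np.log(p[np.arange(m), partner] + 1e-300)))

    # d loss / d sim rows, then back through cosine normalisation
    dsim = p.copy()
    dsim[np.arange(m), partner] -= 1.0
    dsim /= m * temperature
    dsim = dsim + dsim.T  # each sim(i,k) appears in rows i and k
    np.fill_diagonal(dsim, 0.0)
    dzhat = dsim @ zhat
    # project out the radial component: d(z/|z|) Jacobian
    radial = np.sum(dzhat * zhat, axis=1, keepdims=True)
    dz = (dzhat - radial * zhat) / norms[:, None]
    return loss, dz
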