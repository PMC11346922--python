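"""Synthetic retinal B-scan phantoms with within-eye slice coherence.

The generator emulates what slice-offset contrastive pre-training needs from
clinical macular OCT: a layered retina (vitreous / inner retina / outer
nuclear layer / RPE band / choroid) drawn as smooth per-eye boundary curves,
a foveal pit, small smooth geometry drift from slice to slice so neighboring
B-scans of one eye are highly correlated, and three lesion classes:

* ``ftmh`` — full-thickness macular hole: a contiguous column band at the
  fovea where all signal between the ILM and the RPE is removed (the RPE band
  itself stays intact, as in a Gass stage 3/4 hole);
* ``control_erm`` — epiretinal membrane: a thin hyperreflective membrane on
  the retinal surface with a shallow, partially effaced pit;
* ``lamellar`` — partial-thickness defect: the inner retina is excavated at
  the fovea but the outer layers and RPE remain, the challenge-set mimic.

Speckle is multiplicative log-normal (OCT speckle is multiplicative), applied
before the final clip to [0, 1].  Per-eye reflectivity and geometry jitter
make global image statistics overlap across classes so that class membership
is carried by foveal structure rather than by image brightness.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .data_io import MANIFEST_COLUMNS, BScanVolume, Cohort
from .exceptions import ConfigurationError

LESION_CLASSES = ("control_erm", "ftmh", "lamellar")

_LESION_TO_DIAGNOSIS = {"control_erm": "ERM", "ftmh": "FTMH", "lamellar": "LAMELLAR"}
_DIAGNOSIS_TO_LESION = {v: k for k, v in _LESION_TO_DIAGNOSIS.items()}


@dataclass
class RetinaPhantomParams:
    """Rendering controls for one synthetic eye.

    ``layer_boundaries`` may pin the four boundary curves (ILM, inner/outer
    interface, RPE top, RPE bottom; one row index per column, strictly
    ordered top to bottom); when ``None`` they are sampled per eye.
    """

    image_height: int = 496
    image_width: int = 512
    layer_boundaries: list[np.ndarray] | None = None
    pit_depth: float = 0.10  # fraction of image height
    pit_width: float = 0.22  # fraction of image width (FWHM of the pit)
    lesion_class: str = "control_erm"
    lesion_width: int = 0  # columns; 0 -> class-typical default
    membrane_brightness: float = 0.95
    slice_drift: float = 1.5  # px per slice-step geometry random walk
    speckle_sigma: float = 0.30
    n_slices: int = 7
    slice_spacing_um: float = 243.0

    def validate(self) -> None:
        if self.lesion_class not in LESION_CLASSES:
            raise ConfigurationError(f"unknown lesion_class {self.lesion_class!r}")
        if self.image_height < 32 or self.image_width < 32:
            raise ConfigurationError("image dimensions must be at least 32x32")
        if self.n_slices < 3:
            raise ConfigurationError("n_slices must be >= 3")
        if not (0.0 <= self.membrane_brightness <= 1.0):
            raise ConfigurationError("membrane_brightness must lie in [0,1]")
        if self.speckle_sigma < 0 or self.slice_drift < 0:
            raise ConfigurationError("noise/drift scales must be non-negative")


@dataclass
class EyeMetadata:
    eye_id: str
    patient_id: str
    laterality: str  # OD | OS
    diagnosis: str  # FTMH | ERM | LAMELLAR
    age: float
    sex: int  # ordinal: 0 = male, 1 = female
    preop_vision: float
    central_slice_index: int


# ---------------------------------------------------------------------------
# Geometry and rendering


def _smooth_curve(width: int, base_row: float, rng: np.random.Generator,
                  amp: float) -> np.ndarray:
    """Low-order smooth curve: tilt plus two long-wavelength cosines."""
    x = np.linspace(0.0, 1.0, width)
    tilt = rng.uniform(-amp, amp)
    c = base_row + tilt * (x - 0.5)
    for k in (1, 2):
        c += rng.uniform(-amp, amp) / k * np.cos(np.pi * k * x + rng.uniform(0, 2 * np.pi))
    return c


def _sample_geometry(params: RetinaPhantomParams, rng: np.random.Generator) -> dict:
    """Per-eye anatomy: boundary curves, fovea position, reflectivities."""
    h, w = params.image_height, params.image_width
    amp = 0.03 * h
    base = rng.uniform(-0.08, 0.08)  # whole-retina vertical offset (fraction)
    if params.layer_boundaries is not None:
        ilm, iface, rpe_top, rpe_bot = [np.asarray(b, dtype=float) for b in params.layer_boundaries]
    else:
        ilm = _smooth_curve(w, (0.30 + base) * h, rng, amp)
        iface = _smooth_curve(w, (0.46 + base) * h, rng, amp * 0.7)
        rpe_top = _smooth_curve(w, (0.62 + base) * h, rng, amp * 0.5)
        # RPE band must stay resolvable at desk-scale resolutions
        rpe_bot = rpe_top + max(rng.uniform(0.035, 0.055) * h, 3.5)
    fovea_col = int(round(w * rng.uniform(0.42, 0.58)))
    # wide per-eye reflectivity jitter: clinical scans vary strongly in
    # brightness, so class membership must not be readable from global
    # intensity statistics (the RPE stays the brightest band throughout)
    refl = {
        "vitreous": 0.03,
        "inner": 0.55 * rng.uniform(0.75, 1.15),
        "outer": 0.30 * rng.uniform(0.70, 1.30),
        "rpe": 0.88 * rng.uniform(0.92, 1.05),
        "choroid": 0.16 * rng.uniform(0.60, 1.40),
    }
    lesion_width = params.lesion_width
    if lesion_width <= 0:
        lesion_width = max(6, int(round(0.09 * w * rng.uniform(0.7, 1.3))))
    # epiretinal membranes vary in brightness and lateral extent, and a faint
    # membrane co-occurs with many full-thickness holes
    mem_gain = rng.uniform(0.55, 1.0)
    if params.lesion_class == "ftmh":
        mem_gain = rng.uniform(0.25, 0.55) if rng.random() < 0.4 else 0.0
    elif params.lesion_class == "lamellar":
        # pseudoholes are membrane-defined and most lamellar holes carry
        # epiretinal proliferation: membranes like the ERM class
        mem_gain = rng.uniform(0.45, 0.95)
    mem_span = rng.uniform(0.45, 1.0)  # fraction of width covered
    mem_center = rng.uniform(0.35, 0.65)
    return {
        "boundaries": [ilm, iface, rpe_top, rpe_bot],
        "fovea_col": fovea_col,
        "refl": refl,
        "lesion_width": lesion_width,
        "pit_depth_px": params.pit_depth * h * rng.uniform(0.6, 1.4),
        "pit_width_px": max(4.0, params.pit_width * w * rng.uniform(0.8, 1.2)),
        "membrane_wrinkle": rng.uniform(0.0, 1.5),
        "erm_pit_factor": rng.uniform(0.35, 1.3),
        "lamellar_reach": rng.uniform(0.0, 0.15),  # fraction of outer zone lost
        "membrane_gain": mem_gain,
        "membrane_span": (mem_center - mem_span / 2, mem_center + mem_span / 2),
    }


def _order_boundaries(bounds: list[np.ndarray], h: int) -> list[np.ndarray]:
    """Enforce strict top-to-bottom ordering with >= 2 px separation."""
    out = [np.clip(bounds[0], 2, h - 10)]
    for b in bounds[1:]:
        out.append(np.clip(np.maximum(b, out[-1] + 2.0), 2, h - 4))
    return out


def _render_slice(
    params: RetinaPhantomParams,
    geom: dict,
    slice_offset: int,
    drift: np.ndarray,
    fovea_shift: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one B-scan of the eye at a signed offset from the central slice.

    ``drift`` is the per-column vertical displacement of the whole retina for
    this slice; ``fovea_shift`` displaces the foveal center laterally.
    """
    h, w = params.image_height, params.image_width
    rows = np.arange(h, dtype=float)[:, None]
    bounds = [b + drift for b in geom["boundaries"]]

    fovea = geom["fovea_col"] + fovea_shift
    cols = np.arange(w, dtype=float)
    pit_sigma = geom["pit_width_px"] / 2.355  # FWHM -> sigma
    pit = np.exp(-0.5 * ((cols - fovea) / pit_sigma) ** 2)

    lesion = params.lesion_class
    pit_depth = geom["pit_depth_px"]
    if lesion == "control_erm":
        # ERM pits range from traction-flattened to steep pseudoholes —
        # deep surface depressions with fully intact retina, the classic
        # FTMH mimic; the classifier must not equate depth with a hole
        pit_depth *= geom["erm_pit_factor"]
    ilm = bounds[0] + pit_depth * pit
    # the pit thins the inner retina: pull the interface down less than the ILM
    iface = np.maximum(bounds[1] + 0.35 * pit_depth * pit, ilm + 1.5)
    rpe_top, rpe_bot = bounds[2], bounds[3]
    ilm, iface, rpe_top, rpe_bot = _order_boundaries([ilm, iface, rpe_top, rpe_bot], h)

    refl = geom["refl"]

    # soft 1-px band edges via clipped signed distances
    def band(top, bot):
        return np.clip(rows - top, 0.0, 1.0) * np.clip(bot - rows, 0.0, 1.0)

    base = np.full((h, w), refl["vitreous"])
    base += (refl["rpe"] - refl["vitreous"]) * band(rpe_top, rpe_bot)
    choroid = (refl["choroid"] - refl["vitreous"]) * band(rpe_bot, np.full(w, float(h)))
    depth_fade = np.clip(1.0 - (rows - rpe_bot) / (0.25 * h), 0.2, 1.0)
    base += choroid * depth_fade  # deep layers present in every class

    inner = (refl["inner"] - refl["vitreous"]) * band(ilm, iface)
    outer = (refl["outer"] - refl["vitreous"]) * band(iface, rpe_top)
    img = base + inner + outer

    # --- lesions, centred on the foveal column, shrinking away from centre --
    extent = 1.0 - abs(slice_offset) / 3.0  # hole visible on central +/- 2 slices
    half = 0.5 * geom["lesion_width"] * extent
    in_band = np.abs(cols - fovea) <= half if extent > 0 else np.zeros(len(cols), dtype=bool)
    if lesion == "ftmh" and in_band.any():
        # full-thickness: hole columns carry only the RPE band and choroid —
        # no neurosensory signal survives between surface and RPE
        img[:, in_band] = base[:, in_band]
    elif lesion == "lamellar" and in_band.any():
        # partial thickness: the *inner* retina is excavated down to the
        # inner/outer interface; the outer neuronal layers and the RPE stay
        # intact, so the defect floor is tissue rather than exposed RPE
        floor = iface + geom["lamellar_reach"] * (rpe_top - iface)
        remnant = (refl["outer"] - refl["vitreous"]) * band(floor, rpe_top)
        img[:, in_band] = base[:, in_band] + remnant[:, in_band]

    if geom["membrane_gain"] > 0:
        # taut hyperreflective membrane bridging the (shallow) pit; lateral
        # extent and brightness vary per eye, and faint membranes co-occur
        # with holes — membrane presence alone does not identify the class
        base_surface = bounds[0]  # membrane does not follow the pit
        wr = geom["membrane_wrinkle"] * np.sin(2 * np.pi * cols / max(w / 6.0, 1.0))
        mem_top = base_surface - 2.0 + wr
        mem = band(mem_top, mem_top + 2.0)
        lo, hi = geom["membrane_span"]
        lateral = (cols >= lo * w) & (cols <= hi * w)
        lateral &= ~in_band  # the defect is open: no membrane bridges it
        mem = mem * lateral.astype(float)[None, :]
        bright = params.membrane_brightness * geom["membrane_gain"]
        img = img * (1 - mem) + bright * mem

    if params.speckle_sigma > 0:
        s = params.speckle_sigma
        img = img * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_eye(
    params: RetinaPhantomParams,
    demographics: EyeMetadata | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BScanVolume, EyeMetadata]:
    """Generate one eye's B-scan stack plus metadata.

    Slices share the eye's sampled geometry; from slice to slice the retina
    drifts by a smooth random walk of scale ``params.slice_drift`` pixels and
    the fovea shifts laterally by up to ~1 px per step, so adjacent slices
    are strongly correlated.  The lesion is centred on the foveal column of
    the central slice and shrinks on more peripheral slices.
    """
    params.validate()
    rng = np.random.default_rng(0) if rng is None else rng
    geom = _sample_geometry(params, rng)
    n = params.n_slices
    central = n // 2
    h, w = params.image_height, params.image_width

    # smooth per-slice displacement: random walk outward from the centre
    offsets = np.arange(n) - central
    vshift = np.zeros(n)
    fshift = np.zeros(n)
    tilt = np.zeros(n)
    for i in range(central + 1, n):
        vshift[i] = vshift[i - 1] + rng.normal(0, params.slice_drift)
        fshift[i] = fshift[i - 1] + rng.normal(0, 0.6)
        tilt[i] = tilt[i - 1] + rng.normal(0, params.slice_drift * 0.3)
    for i in range(central - 1, -1, -1):
        vshift[i] = vshift[i + 1] + rng.normal(0, params.slice_drift)
        fshift[i] = fshift[i + 1] + rng.normal(0, 0.6)
        tilt[i] = tilt[i + 1] + rng.normal(0, params.slice_drift * 0.3)

    x = np.linspace(-0.5, 0.5, w)
    stack = np.empty((n, h, w))
    for i in range(n):
        drift = vshift[i] + tilt[i] * x
        stack[i] = _render_slice(params, geom, int(offsets[i]), drift, fshift[i], rng)

    if demographics is None:
        demographics = EyeMetadata(
            eye_id="eye-0",
            patient_id="pat-0",
            laterality="OD" if rng.random() < 0.5 else "OS",
            diagnosis=_LESION_TO_DIAGNOSIS[params.lesion_class],
            age=float(rng.normal(70.0, 8.0)),
            sex=int(rng.random() < 0.5),
            preop_vision=float(rng.normal(0.6, 0.25)),
            central_slice_index=central,
        )
    else:
        demographics = replace(demographics, central_slice_index=central)
    volume = BScanVolume(
        eye_id=demographics.eye_id,
        slices=stack,
        central_slice_index=central,
        slice_spacing_um=params.slice_spacing_um,
    )
    return volume, demographics


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortConfig:
    """Synthetic study population.

    Defaults mirror the clinical cohort the pipeline emulates: 61 FTMH and
    273 ERM eyes; ages normal with class-conditional moments (FTMH 69.6/6.4,
    ERM 70.5/8.6 years), a female-skewed FTMH group (46 F / 15 M) and a
    near-balanced ERM group; occasionally both eyes of one patient enrolled.
    Pre-operative vision is a generic continuous acuity score (logMAR-like,
    higher = worse) with FTMH eyes worse on average.
    """

    n_ftmh: int = 61
    n_erm: int = 273
    n_lamellar: int = 0
    image_height: int = 496
    image_width: int = 512
    n_slices: int = 7
    slice_spacing_um: tuple[float, ...] = (243.0, 121.0)
    speckle_sigma: float = 0.30
    slice_drift: float = 1.5
    two_eye_prob: float = 0.02
    age_params: dict = field(
        default_factory=lambda: {
            "FTMH": (69.6, 6.4),
            "ERM": (70.5, 8.6),
            "LAMELLAR": (70.0, 8.0),
        }
    )
    female_prob: dict = field(
        default_factory=lambda: {"FTMH": 46 / 61, "ERM": 140 / 273, "LAMELLAR": 0.5}
    )
    vision_params: dict = field(
        default_factory=lambda: {
            "FTMH": (0.90, 0.25),
            "ERM": (0.45, 0.20),
            "LAMELLAR": (0.50, 0.20),
        }
    )

    def validate(self) -> None:
        if min(self.n_ftmh, self.n_erm, self.n_lamellar) < 0:
            raise ConfigurationError("class counts must be >= 0")
        if self.n_ftmh + self.n_erm + self.n_lamellar == 0:
            raise ConfigurationError("cohort must contain at least one eye")
        if self.n_slices < 3:
            raise ConfigurationError("n_slices must be >= 3")
        if not (0.0 <= self.two_eye_prob <= 1.0):
            raise ConfigurationError("two_eye_prob must be a probability")


def _eye_params(config: CohortConfig, lesion: str, rng: np.random.Generator) -> RetinaPhantomParams:
    return RetinaPhantomParams(
        image_height=config.image_height,
        image_width=config.image_width,
        lesion_class=lesion,
        slice_drift=config.slice_drift,
        speckle_sigma=config.speckle_sigma,
        n_slices=config.n_slices,
        slice_spacing_um=float(rng.choice(np.asarray(config.slice_spacing_um))),
    )


def generate_cohort(
    config: CohortConfig,
    rng: np.random.Generator,
    id_prefix: str = "",
) -> tuple[list[BScanVolume], pd.DataFrame]:
    """Generate a full cohort; returns volumes and a manifest DataFrame.

    The manifest ``path`` column is empty until the cohort is written to disk
    (see :func:`write_cohort`).
    """
    config.validate()
    volumes: list[BScanVolume] = []
    rows: list[dict] = []
    eye_counter = itertools.count(1)
    patient_counter = itertools.count(1)

    schedule: list[str] = (
        ["FTMH"] * config.n_ftmh + ["ERM"] * config.n_erm + ["LAMELLAR"] * config.n_lamellar
    )
    i = 0
    while i < len(schedule):
        diagnosis = schedule[i]
        pid = f"{id_prefix}P{next(patient_counter):04d}"
        # a patient occasionally contributes both eyes (same diagnosis)
        n_eyes = 2 if (rng.random() < config.two_eye_prob and schedule[i : i + 2].count(diagnosis) == 2) else 1
        age = float(rng.normal(*config.age_params[diagnosis]))
        sex = int(rng.random() < config.female_prob[diagnosis])
        first_side = "OD" if rng.random() < 0.5 else "OS"
        for j in range(n_eyes):
            eid = f"{id_prefix}E{next(eye_counter):04d}"
            meta = EyeMetadata(
                eye_id=eid,
                patient_id=pid,
                laterality=first_side if j == 0 else ("OS" if first_side == "OD" else "OD"),
                diagnosis=diagnosis,
                age=age,
                sex=sex,
                preop_vision=float(rng.normal(*config.vision_params[diagnosis])),
                central_slice_index=config.n_slices // 2,
            )
            params = _eye_params(config, _DIAGNOSIS_TO_LESION[diagnosis], rng)
            volume, meta = generate_eye(params, meta, rng)
            volumes.append(volume)
            rows.append(
                {
                    "eye_id": meta.eye_id,
                    "patient_id": meta.patient_id,
                    "laterality": meta.laterality,
                    "diagnosis": meta.diagnosis,
                    "age": round(meta.age, 2),
                    "sex": meta.sex,
                    "preop_vision": round(meta.preop_vision, 3),
                    "n_slices": volume.n_slices,
                    "central_slice_index": volume.central_slice_index,
                    "slice_spacing_um": volume.slice_spacing_um,
                    "path": "",
                }
            )
            i += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return volumes, manifest


def generate_challenge_set(
    config: CohortConfig | None = None,
    rng: np.random.Generator | None = None,
    count: int = 34,
) -> tuple[list[BScanVolume], pd.DataFrame]:
    """Generate the lamellar/pseudohole challenge set.

    Every eye has ``lesion_class='lamellar'``; the ground-truth binary label
    for challenge evaluation is FTMH-negative.
    """
    if count < 1:
        raise ConfigurationError("challenge set needs count >= 1")
    base = config if config is not None else CohortConfig()
    cfg = replace(base, n_ftmh=0, n_erm=0, n_lamellar=count)
    rng = np.random.default_rng(0) if rng is None else rng
    return generate_cohort(cfg, rng, id_prefix="C")


def as_cohort(volumes: Iterable[BScanVolume], manifest: pd.DataFrame) -> Cohort:
    return Cohort(manifest, {v.eye_id: v for v in volumes})


# ---------------------------------------------------------------------------
# The pixel-threshold class oracle

def detect_full_thickness_defect(image: np.ndarray, columns: slice | None = None) -> bool:
    """Pixel-threshold oracle: does a full-depth low-intensity foveal column exist?

    Scans each column for the first row with intensity above 0.2 (the tissue
    surface).  A column counts as a full-thickness defect when that first
    supra-threshold pixel is already bright RPE-like tissue (> 0.7) *and*
    lies well below the surrounding surface — i.e. all inner retinal signal
    above the RPE is gone.  On noiseless phantoms this separates FTMH from
    ERM/lamellar eyes exactly; it is the guarantee that the downstream
    classification task is learnable.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    deep = img > 0.2
    first = np.where(deep.any(axis=0), deep.argmax(axis=0), h - 1)
    surface = float(np.median(first))
    # peak intensity just below the first crossing (band edges are soft)
    look = max(3, int(0.03 * h))
    hit = np.array([img[first[c] : first[c] + look, c].max(initial=0.0) for c in range(w)])
    # RPE reflectivity is always > 0.7 on phantoms; inner retina never is
    candidates = (hit > 0.7) & (first > surface + 0.08 * h)
    if columns is not None:
        mask = np.zeros(w, dtype=bool)
        mask[columns] = True
        candidates &= mask
    # require a run of at least 3 consecutive defect columns
    run = 0
    for c in candidates:
        run = run + 1 if c else 0
        if run >= 3:
            return True
    return False
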