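"""Synthetic pelvic phantom and per-session image sequences.

Anatomy is ellipsoid-based — prostate with an embedded GTV, an
anterior-superior bladder and a posterior rectum — with smoothed organ
boundaries, a smooth random intra-pelvic texture and voxel noise.  Realism
is bounded by what contrast-pattern-matching registration needs (distinct,
consistent contrast patterns), not by MR physics.

Each fraction session consists of four scans: MR1 (daily planning image),
MR2 (during plan adaptation), MR3 and MR4 (during the first and second
subfraction delivery).  MR2-MR4 are generated from MR1 by applying the
sampled rigid prostate/CTV translations, feathered smoothly to zero away
from the target so the ground-truth CTV displacement equals the sampled
translation exactly.  Interfraction change combines a prostate position
offset with a bladder-filling expansion modeled as a radial displacement
bump centred in the bladder.

All ground truth (translations, deformed label maps) is retained so every
downstream estimate has an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .grid import LabelMap, ScalarImage, VoxelGrid
from .motion import (
    INTERFRACTION,
    INTERVALS,
    CohortConfig,
    MotionSample,
    sample_motion,
)
from .planning import ctv_from_gtv
from .protocol import ShiftRecord
from .seeding import substream

SCAN_NAMES = ("MR1", "MR2", "MR3", "MR4")


@dataclass(frozen=True)
class AnatomyParams:
    """Ellipsoid anatomy description (all lengths in mm).

    Offsets are relative to the prostate centre, which sits at the grid
    centre; axes are (LR, AP, SI) with posterior and superior positive.
    """

    prostate_semiaxes: Tuple[float, float, float] = (20.0, 18.0, 22.0)
    gtv_semiaxes: Tuple[float, float, float] = (6.0, 5.0, 6.0)
    gtv_offset: Tuple[float, float, float] = (5.0, -4.0, 3.0)
    bladder_semiaxes: Tuple[float, float, float] = (22.0, 20.0, 18.0)
    bladder_offset: Tuple[float, float, float] = (0.0, -26.0, 32.0)
    rectum_semiaxes: Tuple[float, float, float] = (11.0, 11.0, 38.0)
    rectum_offset: Tuple[float, float, float] = (0.0, 32.0, 0.0)
    intensities: Dict[str, float] = field(
        default_factory=lambda: {
            "background": 120.0,
            "prostate": 180.0,
            "gtv": 205.0,
            "bladder": 235.0,
            "rectum": 60.0,
        }
    )
    noise_sd: float = 3.0
    texture_sd: float = 16.0
    texture_scale_mm: float = 5.0
    boundary_smooth_mm: float = 1.5
    border_mm: float = 5.0
    overlap_tolerance: float = 0.05

    def scaled(self, factor: float) -> "AnatomyParams":
        """Geometrically scaled copy (for small smoke-test grids)."""
        def s(v):
            return tuple(factor * x for x in v)

        return replace(
            self,
            prostate_semiaxes=s(self.prostate_semiaxes),
            gtv_semiaxes=s(self.gtv_semiaxes),
            gtv_offset=s(self.gtv_offset),
            bladder_semiaxes=s(self.bladder_semiaxes),
            bladder_offset=s(self.bladder_offset),
            rectum_semiaxes=s(self.rectum_semiaxes),
            rectum_offset=s(self.rectum_offset),
        )


DEFAULT_GRID = VoxelGrid((48, 48, 48), (2.5, 2.5, 2.5))
SMOKE_GRID = VoxelGrid((32, 32, 32), (3.0, 3.0, 3.0))
DEFAULT_ANATOMY = AnatomyParams()
SMOKE_ANATOMY = AnatomyParams().scaled(0.6)


def _ellipsoid_mask(grid: VoxelGrid, center_mm, semiaxes_mm) -> np.ndarray:
    semi = np.asarray(semiaxes_mm, dtype=float)
    if np.any(semi <= 0):
        return np.zeros(grid.shape, dtype=bool)
    X, Y, Z = grid.world_coordinates()
    c = np.asarray(center_mm, dtype=float)
    q = (
        ((X - c[0]) / semi[0]) ** 2
        + ((Y - c[1]) / semi[1]) ** 2
        + ((Z - c[2]) / semi[2]) ** 2
    )
    return q <= 1.0


def build_phantom(
    anatomy: AnatomyParams = DEFAULT_ANATOMY,
    grid: VoxelGrid = DEFAULT_GRID,
    seed: int = 0,
) -> Tuple[ScalarImage, LabelMap]:
    """Construct the base pelvic image and organ label map.

    Raises ``ValueError`` if an organ does not fit inside the grid with the
    configured border, or if organs overlap beyond the tolerance.
    """
    center = np.asarray(grid.origin) + (np.asarray(grid.shape) - 1) * grid.spacing_arr / 2
    centers = {
        "prostate": center,
        "gtv": center + np.asarray(anatomy.gtv_offset),
        "bladder": center + np.asarray(anatomy.bladder_offset),
        "rectum": center + np.asarray(anatomy.rectum_offset),
    }
    semis = {
        "prostate": anatomy.prostate_semiaxes,
        "gtv": anatomy.gtv_semiaxes,
        "bladder": anatomy.bladder_semiaxes,
        "rectum": anatomy.rectum_semiaxes,
    }
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * grid.spacing_arr
    for name, c in centers.items():
        semi = np.asarray(semis[name])
        if np.all(semi <= 0):
            continue
        if np.any(c - semi < lo + anatomy.border_mm) or np.any(
            c + semi > hi - anatomy.border_mm
        ):
            raise ValueError(
                f"invalid anatomy: {name} does not fit the grid with a "
                f"{anatomy.border_mm} mm border"
            )

    masks = {name: _ellipsoid_mask(grid, centers[name], semis[name]) for name in centers}
    for a, b in (("prostate", "bladder"), ("prostate", "rectum"), ("bladder", "rectum")):
        inter = np.count_nonzero(masks[a] & masks[b])
        ref = max(1, min(np.count_nonzero(masks[a]), np.count_nonzero(masks[b])))
        if masks[a].any() and masks[b].any() and inter / ref > anatomy.overlap_tolerance:
            raise ValueError(f"invalid anatomy: {a} and {b} overlap beyond tolerance")

    if masks["prostate"].any():
        ctv = ctv_from_gtv(
            masks["gtv"], masks["prostate"], masks["bladder"], masks["rectum"], grid
        )
    else:
        ctv = np.zeros(grid.shape, dtype=bool)
    labels = LabelMap(grid, {**masks, "ctv": ctv})

    inten = anatomy.intensities
    ideal = np.full(grid.shape, inten["background"], dtype=float)
    for name in ("rectum", "bladder", "prostate", "gtv"):  # later wins
        ideal[masks[name]] = inten[name]
    sigma_vox = anatomy.boundary_smooth_mm / grid.spacing_arr
    img = ndimage.gaussian_filter(ideal, sigma_vox)

    rng = substream(seed, "phantom-texture")
    if anatomy.texture_sd > 0:
        tex = ndimage.gaussian_filter(
            rng.standard_normal(grid.shape), anatomy.texture_scale_mm / grid.spacing_arr
        )
        std = tex.std()
        if std > 0:
            img += anatomy.texture_sd * tex / std
    if anatomy.noise_sd > 0:
        img += anatomy.noise_sd * rng.standard_normal(grid.shape)
    return ScalarImage(grid, img), labels


def _target_weight(labels: LabelMap, pad_mm: float, feather_mm: float = 12.0) -> np.ndarray:
    """Feathered weight: 1 on the CTV region (plus pad), ramping to 0."""
    grid = labels.grid
    core = labels["ctv"] if "ctv" in labels and labels["ctv"].any() else None
    if core is None:
        core = labels["prostate"] if "prostate" in labels else None
    if core is None or not core.any():
        return np.zeros(grid.shape)
    dist = ndimage.distance_transform_edt(~core, sampling=grid.spacing_arr)
    return np.clip(1.0 - (dist - pad_mm) / feather_mm, 0.0, 1.0)


def _bladder_bump(labels: LabelMap, amplitude_mm: float) -> np.ndarray:
    """Radial bladder-expansion displacement (mm), zero at the centre."""
    grid = labels.grid
    if amplitude_mm == 0 or "bladder" not in labels or not labels["bladder"].any():
        return np.zeros(tuple(grid.shape) + (3,))
    c = labels.centroid_mm("bladder")
    s = (3.0 * labels.volume_cm3("bladder") * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    X, Y, Z = grid.world_coordinates()
    r = np.stack([X - c[0], Y - c[1], Z - c[2]], axis=-1)
    rho = np.linalg.norm(r, axis=-1)
    profile = amplitude_mm * (rho / s) * np.exp(0.5 * (1.0 - (rho / s) ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(rho[..., None] > 0, r / np.maximum(rho, 1e-12)[..., None], 0.0)
    return profile[..., None] * unit


def deform_anatomy(
    image: ScalarImage,
    labels: LabelMap,
    motion: MotionSample,
    feather_mm: float = 12.0,
) -> Tuple[ScalarImage, LabelMap]:
    """Apply a sampled motion to an image and its labels.

    The rigid translation acts on the whole CTV region (weight 1 within the
    CTV plus a pad of the shift magnitude, feathered to zero over
    ``feather_mm``); the bladder-filling bump acts complementarily so the
    CTV stays rigid.  Images are resampled linearly, labels with
    nearest-neighbour.
    """
    grid = image.grid
    t = motion.translation
    amp = motion.bladder_amplitude_mm
    if np.allclose(t, 0.0) and amp == 0.0:
        return image.copy(), labels.copy()

    if "ctv" in labels and labels["ctv"].any():
        idx = np.argwhere(labels["ctv"])
        lo = idx.min(axis=0) + np.minimum(t, 0) / grid.spacing_arr
        hi = idx.max(axis=0) + np.maximum(t, 0) / grid.spacing_arr
        if np.any(lo < 0) or np.any(hi > np.asarray(grid.shape) - 1):
            raise ValueError(f"translation {t} moves the CTV outside the grid")

    w = _target_weight(labels, pad_mm=float(np.linalg.norm(t)) + 2.0, feather_mm=feather_mm)
    disp = w[..., None] * t
    if amp != 0.0:
        disp = disp + (1.0 - w)[..., None] * _bladder_bump(labels, amp)

    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
    sample = [coords[i] - disp[..., i] / grid.spacing[i] for i in range(3)]
    new_img = ndimage.map_coordinates(image.data, sample, order=1, mode="nearest")
    new_masks = {
        name: ndimage.map_coordinates(
            labels[name].astype(np.uint8), sample, order=0, mode="nearest"
        ).astype(bool)
        for name in labels
    }
    return ScalarImage(grid, new_img), LabelMap(grid, new_masks)


@dataclass
class FractionSession:
    """One treatment session: MR1-MR4 with ground truth."""

    fraction: int
    images: Dict[str, ScalarImage]
    labels: Dict[str, LabelMap]
    motions: Dict[str, MotionSample]
    cumulative: Dict[str, np.ndarray]  # translation MR1 -> MRk (mm)

    @property
    def grid(self) -> VoxelGrid:
        return self.images["MR1"].grid

    @property
    def shift1(self) -> np.ndarray:
        """Ground-truth residual shift during the first delivery (MR2->MR3)."""
        return self.motions["MR2_MR3"].translation

    @property
    def shift2(self) -> np.ndarray:
        """Ground-truth residual shift during the second delivery (MR3->MR4)."""
        return self.motions["MR3_MR4"].translation


@dataclass
class Patient:
    """Simulated patient: five sessions plus interfraction ground truth."""

    patient_id: int
    subgroup: str
    systematic_shift: np.ndarray
    sessions: List[FractionSession]
    interfraction: Dict[int, MotionSample]

    @property
    def grid(self) -> VoxelGrid:
        return self.sessions[0].grid


def simulate_session(
    base_image: ScalarImage,
    base_labels: LabelMap,
    config: CohortConfig,
    patient_id: int,
    fraction: int,
    seed: Optional[int] = None,
) -> FractionSession:
    """Generate MR1-MR4 of one fraction from its daily (MR1) anatomy."""
    motions = {
        tag: sample_motion(config, patient_id, fraction, tag, seed) for tag in INTERVALS
    }
    t2 = motions["MR1_MR2"].translation
    t3 = t2 + motions["MR2_MR3"].translation
    t4 = t3 + motions["MR3_MR4"].translation
    cumulative = {"MR2": t2, "MR3": t3, "MR4": t4}
    images = {"MR1": base_image}
    labels = {"MR1": base_labels}
    for scan in ("MR2", "MR3", "MR4"):
        img, lab = deform_anatomy(
            base_image, base_labels, MotionSample(cumulative[scan], "MR1_MR2")
        )
        images[scan] = img
        labels[scan] = lab
    return FractionSession(fraction, images, labels, motions, cumulative)


def simulate_cohort(
    config: CohortConfig,
    anatomy: AnatomyParams = DEFAULT_ANATOMY,
    grid: VoxelGrid = DEFAULT_GRID,
) -> List[Patient]:
    """Simulate the full cohort with complete ground truth."""
    patients = []
    for pid in range(config.n_patients):
        base_img, base_lab = build_phantom(anatomy, grid, seed_for_patient(config.seed, pid))
        subgroup = config.subgroup_of(pid)
        sessions = []
        interfraction: Dict[int, MotionSample] = {}
        for fraction in range(1, config.n_fractions + 1):
            if fraction == 1:
                img_f, lab_f = base_img, base_lab
            else:
                m_if = sample_motion(config, pid, fraction, INTERFRACTION)
                interfraction[fraction] = m_if
                img_f, lab_f = deform_anatomy(base_img, base_lab, m_if)
            sessions.append(
                simulate_session(img_f, lab_f, config, pid, fraction)
            )
        patients.append(
            Patient(
                patient_id=pid,
                subgroup=subgroup,
                systematic_shift=config.systematic_shift_of(pid),
                sessions=sessions,
                interfraction=interfraction,
            )
        )
    return patients


def seed_for_patient(master_seed: int, patient_id: int) -> int:
    return int(substream(master_seed, "phantom", patient_id).integers(0, 2**31 - 1))


def ground_truth_records(patient: Patient) -> List[ShiftRecord]:
    """Shift records straight from the generating translations."""
    records = []
    for session in patient.sessions:
        records.append(
            ShiftRecord(patient.patient_id, session.fraction, "shift1", session.shift1)
        )
        records.append(
            ShiftRecord(patient.patient_id, session.fraction, "shift2", session.shift2)
        )
    return records
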