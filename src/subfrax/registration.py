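"""Variational deformable image registration and its robustness wrappers.

The registration matches contrast patterns between two images of one
session by minimizing an intensity-difference data term with diffusion-type
regularization, solved coarse-to-fine on a multiresolution pyramid with
demons-style normalized gradient-descent updates: at each iteration the
update at a voxel is

    du = -(M(x + u) - F(x)) * grad F(x) / (|grad F|^2 + diff^2 / step^2)

followed by Gaussian smoothing of the field (the diffusion regularizer).
Images are band-pass filtered first so the data term responds to local
contrast patterns rather than absolute intensity.

Fields use the pull-back convention: ``u`` maps fixed-image coordinates to
moving-image coordinates, so for a structure translated by ``t`` from fixed
to moving the field over that structure equals ``t``.

Because the solver can settle in slightly different local optima, a
median-of-repeats wrapper re-runs it (default 30 times) from randomly
jittered initial fields and takes the per-voxel, per-component median.

The contour-guided variant adds a term penalizing misalignment of signed
distance maps of the bladder, prostate and rectum contours, applied only
inside a ring around the PTV — used for interfraction registration where
day-to-day bladder/rectum volume changes defeat intensity matching alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import DisplacementField, ScalarImage, VoxelGrid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegistrationSettings:
    """Solver parameters.

    ``regularization_mm`` is the Gaussian width of the diffusion smoothing
    applied to the field each iteration; ``step_mm`` bounds the per-iteration
    voxel update; ``tolerance_mm`` stops a level once the 99th percentile of
    the update magnitude falls below it (a volume mean would be diluted by
    the motion-free background).  ``n_repeats`` and ``jitter_sd_mm`` control the
    median-of-repeats wrapper.
    """

    regularization_mm: float = 1.5
    pyramid_levels: int = 3
    max_iterations: int = 100
    tolerance_mm: float = 0.05
    step_mm: float = 2.0
    bandpass_mm: Tuple[float, float] = (1.0, 12.0)
    n_repeats: int = 30
    jitter_sd_mm: float = 0.2
    jitter_smooth_mm: float = 4.0
    guidance_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regularization_mm < 0 or self.guidance_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.pyramid_levels < 1 or self.n_repeats < 1:
            raise ValueError("pyramid levels and repeat count must be >= 1")


@dataclass
class GuidanceContours:
    """Contour guidance input: per-structure masks on both images + ring."""

    fixed_masks: Dict[str, np.ndarray]
    moving_masks: Dict[str, np.ndarray]
    ring: np.ndarray

    def structures(self) -> List[str]:
        return [s for s in self.fixed_masks if s in self.moving_masks]


def _bandpass(data: np.ndarray, spacing: np.ndarray, lo_mm: float, hi_mm: float) -> np.ndarray:
    out = ndimage.gaussian_filter(data, lo_mm / spacing) if lo_mm > 0 else data
    if hi_mm > 0:
        out = out - ndimage.gaussian_filter(data, hi_mm / spacing)
    return out


def _downsample(data: np.ndarray, smooth_vox: float = 1.0) -> np.ndarray:
    return ndimage.gaussian_filter(data, smooth_vox)[::2, ::2, ::2]


def _resize_to(vol: np.ndarray, new_shape: Tuple[int, ...], scale: float) -> np.ndarray:
    """Sample ``vol`` at ``new_index * scale`` (linear, edge-clamped)."""
    coords = np.meshgrid(
        *[np.arange(n, dtype=float) * scale for n in new_shape], indexing="ij"
    )
    return ndimage.map_coordinates(vol, coords, order=1, mode="nearest")


def _sample(vol: np.ndarray, u_mm: np.ndarray, spacing: np.ndarray, base) -> np.ndarray:
    """Evaluate ``vol`` at index + u/spacing (pull-back sampling)."""
    sample = [base[i] + u_mm[..., i] / spacing[i] for i in range(3)]
    return ndimage.map_coordinates(vol, sample, order=1, mode="nearest")


def _demons_force(
    diff: np.ndarray, grads: Sequence[np.ndarray], step_mm: float
) -> np.ndarray:
    gsq = sum(g * g for g in grads)
    denom = gsq + (diff / step_mm) ** 2 + 1e-12
    return np.stack([-(diff * g) / denom for g in grads], axis=-1)


def register(
    fixed: ScalarImage,
    moving: ScalarImage,
    settings: RegistrationSettings = RegistrationSettings(),
    initial_field: Optional[DisplacementField] = None,
    guidance: Optional[GuidanceContours] = None,
) -> DisplacementField:
    """Deformable registration of ``moving`` onto ``fixed``.

    Returns the displacement field at full resolution.  Non-convergence
    within the iteration budget sets ``converged=False`` on the result (a
    warning, not an error).  The iteration log is attached as ``field.log``.
    """
    grid = fixed.grid
    if not grid.same_geometry(moving.grid):
        raise ValueError("fixed and moving images must share one grid")

    spacing0 = grid.spacing_arr
    lo, hi = settings.bandpass_mm
    fdat = _bandpass(fixed.data, spacing0, lo, hi)
    mdat = _bandpass(moving.data, spacing0, lo, hi)

    # pyramid, coarsest last; never below 8 voxels per axis
    pyr: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = [(fdat, mdat, spacing0)]
    for _ in range(settings.pyramid_levels - 1):
        f_prev, m_prev, sp = pyr[-1]
        if min(f_prev.shape) < 16:
            break
        pyr.append((_downsample(f_prev), _downsample(m_prev), sp * 2.0))

    use_guidance = guidance is not None and guidance.ring.any()
    if guidance is not None and not use_guidance:
        logger.warning("empty guidance ring: falling back to unguided registration")
    sdm_pyr: List[dict] = []
    if use_guidance:
        sdms = {
            "__ring__": guidance.ring.astype(float),
        }
        for s in guidance.structures():
            sdms[f"f_{s}"] = _signed_distance(guidance.fixed_masks[s], spacing0)
            sdms[f"m_{s}"] = _signed_distance(guidance.moving_masks[s], spacing0)
        sdm_pyr = [sdms]
        for _ in range(len(pyr) - 1):
            prev = sdm_pyr[-1]
            sdm_pyr.append({k: _downsample(v) for k, v in prev.items()})

    # initial field at coarsest level
    coarse_shape = pyr[-1][0].shape
    if initial_field is not None:
        scale = pyr[-1][2][0] / spacing0[0]
        u = np.stack(
            [_resize_to(initial_field.vectors[..., i], coarse_shape, scale) for i in range(3)],
            axis=-1,
        )
    else:
        u = np.zeros(tuple(coarse_shape) + (3,))

    log: List[dict] = []
    converged_all = True
    for level in range(len(pyr) - 1, -1, -1):
        fL, mL, sp = pyr[level]
        base = np.meshgrid(*[np.arange(n, dtype=float) for n in fL.shape], indexing="ij")
        gF = np.gradient(fL, *sp)
        if use_guidance:
            s_level = sdm_pyr[level]
            ringL = s_level["__ring__"] > 0.5
            g_sdm = {
                s: np.gradient(s_level[f"f_{s}"], *sp)
                for s in (guidance.structures() if guidance else [])
            }
        sigma_vox = settings.regularization_mm / sp
        converged = False
        n_iter = 0
        for n_iter in range(1, settings.max_iterations + 1):
            warped = _sample(mL, u, sp, base)
            diff = warped - fL
            du = _demons_force(diff, gF, settings.step_mm)
            if use_guidance:
                du_g = np.zeros_like(du)
                for s in guidance.structures():
                    wsdm = _sample(s_level[f"m_{s}"], u, sp, base)
                    dsd = (wsdm - s_level[f"f_{s}"]) * ringL
                    du_g += _demons_force(dsd, g_sdm[s], settings.step_mm)
                du = du + settings.guidance_weight * du_g
            u += du
            for c in range(3):
                u[..., c] = ndimage.gaussian_filter(u[..., c], sigma_vox)
            update = float(np.percentile(np.linalg.norm(du, axis=-1), 99))
            if update < settings.tolerance_mm:
                converged = True
                break
        log.append(
            {
                "level": level,
                "shape": list(fL.shape),
                "iterations": n_iter,
                "p99_update_mm": update,
                "converged": converged,
            }
        )
        converged_all &= converged
        if level > 0:
            finer_shape = pyr[level - 1][0].shape
            u = np.stack(
                [_resize_to(u[..., i], finer_shape, 0.5) for i in range(3)], axis=-1
            )
    if not converged_all:
        logger.debug("registration did not fully converge: %s", log)
    out = DisplacementField(grid, u, converged=converged_all)
    out.log = log  # type: ignore[attr-defined]
    return out


def _signed_distance(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    if not mask.any():
        return np.full(mask.shape, 0.0)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside


def register_contour_guided(
    fixed: ScalarImage,
    moving: ScalarImage,
    guidance: GuidanceContours,
    settings: RegistrationSettings = RegistrationSettings(),
    initial_field: Optional[DisplacementField] = None,
) -> DisplacementField:
    """Registration with contour guidance inside the ring structure."""
    return register(fixed, moving, settings, initial_field, guidance=guidance)


def _jitter_field(
    grid: VoxelGrid, settings: RegistrationSettings, rng: np.random.Generator
) -> DisplacementField:
    """Smooth zero-mean random initial field for repeat perturbation."""
    vec = rng.standard_normal(tuple(grid.shape) + (3,))
    for c in range(3):
        vec[..., c] = ndimage.gaussian_filter(
            vec[..., c], settings.jitter_smooth_mm / grid.spacing_arr
        )
    std = vec.std()
    if std > 0:
        vec *= settings.jitter_sd_mm / std
    return DisplacementField(grid, vec)


def median_field(fields: Sequence[DisplacementField]) -> DisplacementField:
    """Per-voxel, per-component median of a set of fields."""
    if not fields:
        raise ValueError("no fields")
    stack = np.stack([f.vectors for f in fields], axis=0)
    med = np.median(stack, axis=0)
    return DisplacementField(
        fields[0].grid, med, converged=all(f.converged for f in fields)
    )


def median_of_repeats(
    registration_call: Callable[[Optional[DisplacementField]], DisplacementField],
    grid: VoxelGrid,
    settings: RegistrationSettings = RegistrationSettings(),
    n_repeats: Optional[int] = None,
    seed: Optional[int] = None,
) -> DisplacementField:
    """Run a registration repeatedly with jittered starts; median the fields.

    ``registration_call`` maps an initial field (or None) to a
    :class:`DisplacementField`.  Every repeat starts from an independent
    jittered initial field (unless ``jitter_sd_mm`` is zero), emulating the
    run-to-run variation of a solver settling in nearby local optima.
    """
    n = settings.n_repeats if n_repeats is None else int(n_repeats)
    if n < 1:
        raise ValueError("repeat count must be >= 1")
    rng = np.random.default_rng(settings.seed if seed is None else seed)
    fields = []
    for _ in range(n):
        init = _jitter_field(grid, settings, rng) if settings.jitter_sd_mm > 0 else None
        fields.append(registration_call(init))
    return median_field(fields)


def estimate_ctv_shift(field: DisplacementField, ctv_mask: np.ndarray) -> np.ndarray:
    """Mean displacement vector (mm) over the CTV voxels."""
    if not np.any(ctv_mask):
        raise ValueError("CTV mask is empty")
    return field.vectors[ctv_mask].mean(axis=0)


def warp_image(moving: ScalarImage, field: DisplacementField) -> ScalarImage:
    """Pull-back resampling: ``out(x) = moving(x + u(x))``."""
    grid = moving.grid
    if not grid.same_geometry(field.grid):
        raise ValueError("image and field must share one grid")
    base = np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
    data = _sample(moving.data, field.vectors, grid.spacing_arr, base)
    return ScalarImage(grid, data)
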