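"""Target volumes and idealized sub-fraction dose plans.

Target construction follows the clinical definitions: the CTV is the
prostate plus a 4 mm isotropic expansion of the GTV, excluding bladder and
rectum voxels; the PTV expands the CTV anisotropically (tight preset:
2 mm LR/SI, 3 mm AP; fallback: 5 mm isotropic); a registration-guidance
ring extends (20, 20, 10) mm (LR, AP, SI) beyond the PTV.

The dose model is geometric rather than fluence-based: each 3.625 Gy
subfraction plan delivers the prescription uniformly inside the PTV with a
Gaussian penumbra of the Euclidean distance outside it.  Adapt-to-Position
is a rigid translation of the planned dose.  This gives the dose gradients
the accumulation analysis needs without modeling treatment-machine
specifics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grid import DoseGrid, VoxelGrid
from .protocol import MarginSpec, TIGHT_MARGINS, TrafficLightState

#: ring extension beyond the PTV in mm (LR, AP, SI)
RING_EXTENT_MM = (20.0, 20.0, 10.0)


@dataclass(frozen=True)
class PlanSpec:
    """Fractionation scheme and dose-model parameters.

    Defaults follow the sub-fractionation scheme: 5 fractions x 2
    subfractions of 3.625 Gy (36.25 Gy total), i.e. 7.25 Gy per fraction.
    """

    subfraction_dose_gy: float = 3.625
    n_fractions: int = 5
    n_subfractions: int = 2
    margins: MarginSpec = TIGHT_MARGINS
    penumbra_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.subfraction_dose_gy <= 0:
            raise ValueError("prescription must be positive")
        if self.penumbra_mm <= 0:
            raise ValueError("penumbra scale must be positive")

    @property
    def fraction_dose_gy(self) -> float:
        return self.subfraction_dose_gy * self.n_subfractions

    @property
    def total_dose_gy(self) -> float:
        return self.fraction_dose_gy * self.n_fractions


def _scaled_distance(mask: np.ndarray, grid: VoxelGrid, scales_mm) -> np.ndarray:
    """Axis-scaled Euclidean distance (in units of ``scales_mm``) to a mask."""
    scales = np.maximum(np.asarray(scales_mm, dtype=float), 1e-9)
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(
        ~mask, sampling=grid.spacing_arr / scales
    )


def ctv_from_gtv(
    gtv: np.ndarray,
    prostate: np.ndarray,
    bladder: np.ndarray,
    rectum: np.ndarray,
    grid: VoxelGrid,
    gtv_expansion_mm: float = 4.0,
) -> np.ndarray:
    """CTV = prostate ∪ (GTV + 4 mm isotropic), excluding bladder and rectum."""
    if not prostate.any():
        raise ValueError("prostate mask is empty")
    if gtv.any():
        expanded = _scaled_distance(gtv, grid, (1.0, 1.0, 1.0)) <= gtv_expansion_mm
    else:
        expanded = np.zeros_like(gtv, dtype=bool)
    ctv = (prostate | expanded) & ~bladder & ~rectum
    return ctv


def expand_margin(ctv: np.ndarray, grid: VoxelGrid, margins: MarginSpec) -> np.ndarray:
    """Anisotropic (ellipsoidal-metric) dilation of the CTV into a PTV.

    A voxel belongs to the PTV iff its axis-scaled distance to the CTV is
    <= 1, with the margin vector as the scaling semi-axes.
    """
    m = margins.as_array()
    if not ctv.any():
        raise ValueError("CTV mask is empty")
    if np.all(m == 0):
        return ctv.copy()
    ptv = _scaled_distance(ctv, grid, m) <= 1.0
    # PTV must not touch the grid boundary (dose support would be clipped)
    edge = np.zeros_like(ptv)
    edge[0, :, :] = edge[-1, :, :] = True
    edge[:, 0, :] = edge[:, -1, :] = True
    edge[:, :, 0] = edge[:, :, -1] = True
    if np.any(ptv & edge):
        raise ValueError("PTV exceeds the grid")
    return ptv


def make_ring(ptv: np.ndarray, grid: VoxelGrid, extent_mm=RING_EXTENT_MM) -> np.ndarray:
    """Guidance ring: anisotropic expansion of the PTV minus the PTV itself."""
    if not ptv.any():
        raise ValueError("PTV mask is empty")
    outer = _scaled_distance(ptv, grid, extent_mm) <= 1.0
    return outer & ~ptv


def make_plan(ptv: np.ndarray, grid: VoxelGrid, spec: PlanSpec) -> DoseGrid:
    """Idealized subfraction plan: prescription in the PTV, Gaussian falloff.

    Outside the PTV the dose is ``Rx * exp(-d^2 / (2 p^2))`` with ``d`` the
    Euclidean distance (mm) to the PTV surface and ``p`` the penumbra scale.
    """
    if not ptv.any():
        raise ValueError("PTV mask is empty")
    d = ndimage.distance_transform_edt(~ptv, sampling=grid.spacing_arr)
    dose = spec.subfraction_dose_gy * np.exp(-0.5 * (d / spec.penumbra_mm) ** 2)
    dose[ptv] = spec.subfraction_dose_gy
    return DoseGrid(grid, dose)


def adapt_to_position(plan: DoseGrid, shift) -> DoseGrid:
    """Rigid translation of a planned dose distribution by ``shift`` (mm).

    Mirrors the Adapt-to-Position step: the dose cloud follows the target.
    Raises if the high-dose region would leave the grid.
    """
    t = np.asarray(shift, dtype=float).reshape(3)
    grid = plan.grid
    if np.allclose(t, 0.0):
        return plan.copy()
    hot = plan.dose >= 0.5 * plan.dose.max()
    idx = np.argwhere(hot)
    shifted_lo = idx.min(axis=0) + t / grid.spacing_arr
    shifted_hi = idx.max(axis=0) + t / grid.spacing_arr
    if np.any(shifted_lo < 0) or np.any(shifted_hi > np.asarray(grid.shape) - 1):
        raise ValueError(f"shift {t} moves the dose support off the grid")
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
    sample = [coords[i] - t[i] / grid.spacing[i] for i in range(3)]
    dose = ndimage.map_coordinates(plan.dose, sample, order=1, mode="nearest")
    return DoseGrid(grid, dose)


def fraction_subplans(
    ctv: np.ndarray,
    grid: VoxelGrid,
    spec: PlanSpec,
    margins: MarginSpec,
    atp_shifts: Sequence[np.ndarray],
) -> Tuple[DoseGrid, DoseGrid]:
    """The two delivered subfraction doses of one fraction.

    The base plan is built on the fraction's own (daily, Adapt-to-Shape)
    CTV; ATP1 translates it to the target position seen on MR2, ATP2 to the
    position seen on MR3.  ``atp_shifts`` are the cumulative target
    translations (mm) relative to MR1 at those two time points.
    """
    ptv = expand_margin(ctv, grid, margins)
    base = make_plan(ptv, grid, spec)
    atp1 = adapt_to_position(base, atp_shifts[0])
    atp2 = adapt_to_position(base, atp_shifts[1])
    return atp1, atp2


def replan_counterfactual(
    fraction_ctvs: Dict[int, np.ndarray],
    grid: VoxelGrid,
    spec: PlanSpec,
    protocol_state: TrafficLightState,
    atp_shifts: Dict[int, Sequence[np.ndarray]],
    tight_margins: Optional[MarginSpec] = None,
) -> Dict[int, Tuple[DoseGrid, DoseGrid]]:
    """Re-plan every fraction with the original tight margins.

    For fractions actually delivered with large margins (post-switch) this
    substitutes tight-margin plans on the same anatomy with the same ATP
    shifts, so accumulation can be repeated under the counterfactual
    scenario.  Fractions delivered with tight margins are unchanged.
    """
    tight = tight_margins or protocol_state.config.tight_margins
    out: Dict[int, Tuple[DoseGrid, DoseGrid]] = {}
    for fraction, ctv in fraction_ctvs.items():
        out[fraction] = fraction_subplans(
            ctv, grid, spec, tight, atp_shifts[fraction]
        )
    return out
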