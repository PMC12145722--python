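"""Shift bookkeeping, cohort error statistics and the traffic-light protocol.

During each fraction two residual intrafraction shifts are measured from the
CTV displacement: *shift 1* (between MR2 and MR3, i.e. during the first
subfraction delivery) and *shift 2* (between MR3 and MR4).  Fractions 1-3
are monitored against green/orange/red thresholds on the per-subfraction 3D
shift magnitude; an orange light in fraction 3 extends monitoring to
fraction 4, and a red light in any monitored fraction triggers a permanent
switch to large (5 mm isotropic) PTV margins for all subsequent fractions.

The actual clinical thresholds are an institutional protocol detail; the
defaults here (green < 3 mm, orange 3-5 mm, red >= 5 mm) are configurable
and deliberately looser than the 2-3 mm planning margins, since a whole
treatment averages over ten subfractions while a single subfraction shift
does not.

Cohort-level errors follow the standard decomposition: the systematic error
``Sigma`` per axis is the SD over patients of the per-patient mean shift,
the random error ``sigma`` is the RMS over patients of the within-patient
SD.  The CTV-to-PTV margin recipe is the van Herk population formula
``2.5 Sigma + 0.7 sigma`` (coefficients configurable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COLORS = ("green", "orange", "red")


@dataclass(frozen=True)
class MarginSpec:
    """CTV-to-PTV margin per axis, in mm (LR, AP, SI)."""

    lr: float
    ap: float
    si: float

    def __post_init__(self) -> None:
        if min(self.lr, self.ap, self.si) < 0:
            raise ValueError("margins must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.lr, self.ap, self.si], dtype=float)

    def __str__(self) -> str:
        return f"({self.lr:g}, {self.ap:g}, {self.si:g}) mm"


#: clinical tight margins: 2 mm LR/SI, 3 mm AP
TIGHT_MARGINS = MarginSpec(2.0, 3.0, 2.0)
#: fallback margins adopted after a red traffic light: 5 mm isotropic
LARGE_MARGINS = MarginSpec(5.0, 5.0, 5.0)


@dataclass(frozen=True)
class ShiftRecord:
    """One residual intrafraction CTV shift of one subfraction interval."""

    patient_id: int
    fraction: int
    interval: str  # "shift1" (MR2->MR3) or "shift2" (MR3->MR4)
    translation: np.ndarray  # mm, (LR, AP, SI)
    source: str = "ground_truth"  # or "estimated"

    def __post_init__(self) -> None:
        if self.interval not in ("shift1", "shift2"):
            raise ValueError(f"interval must be 'shift1' or 'shift2', got {self.interval!r}")
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.translation))


@dataclass(frozen=True)
class ErrorStats:
    """Cohort systematic/random error decomposition (mm, per axis LR/AP/SI)."""

    systematic: np.ndarray  # Sigma
    random: np.ndarray  # sigma
    mean_3d: float
    sd_3d: float
    n_patients: int

    def report(self) -> str:
        """Render per-axis errors in LR, SI, AP order as 'Sigma ± sigma mm'."""
        order = [("LR", 0), ("SI", 2), ("AP", 1)]
        parts = [
            f"{ax}: {self.systematic[i]:.1f} ± {self.random[i]:.1f} mm"
            for ax, i in order
        ]
        return ", ".join(parts)


def cohort_error_stats(records: Iterable[ShiftRecord]) -> ErrorStats:
    """Systematic (Sigma) and random (sigma) errors from pooled shift records.

    Sigma per axis = SD over patients of the per-patient mean translation;
    sigma per axis = RMS over patients of the within-patient SD.  Patients
    with a single record contribute to Sigma but are excluded from sigma
    (with a warning).
    """
    by_patient: Dict[int, List[np.ndarray]] = {}
    for rec in records:
        by_patient.setdefault(rec.patient_id, []).append(rec.translation)
    if not by_patient:
        raise ValueError("no shift records")
    means, variances, mags = [], [], []
    excluded = []
    for pid, shifts in by_patient.items():
        arr = np.asarray(shifts)
        means.append(arr.mean(axis=0))
        mags.append(np.linalg.norm(arr, axis=1))
        if arr.shape[0] >= 2:
            variances.append(arr.var(axis=0, ddof=1))
        else:
            excluded.append(pid)
    if excluded:
        warnings.warn(
            f"{len(excluded)} patient(s) with a single shift record excluded "
            f"from the random-error estimate: {excluded}",
            stacklevel=2,
        )
    if not variances:
        raise ValueError("need at least one patient with >= 2 shift records")
    means_arr = np.asarray(means)
    systematic = (
        means_arr.std(axis=0, ddof=1) if len(means) > 1 else np.zeros(3)
    )
    random = np.sqrt(np.asarray(variances).mean(axis=0))
    all_mags = np.concatenate(mags)
    return ErrorStats(
        systematic=systematic,
        random=random,
        mean_3d=float(all_mags.mean()),
        sd_3d=float(all_mags.std()),
        n_patients=len(by_patient),
    )


def van_herk_margin(
    stats: ErrorStats, alpha: float = 2.5, beta: float = 0.7
) -> MarginSpec:
    """Population margin recipe ``alpha * Sigma + beta * sigma`` per axis."""
    if alpha < 0 or beta < 0:
        raise ValueError("margin coefficients must be >= 0")
    m = alpha * np.asarray(stats.systematic) + beta * np.asarray(stats.random)
    return MarginSpec(float(m[0]), float(m[1]), float(m[2]))


@dataclass(frozen=True)
class TrafficLightConfig:
    """Thresholds and rules of the traffic-light protocol.

    Colours are assigned from the worst per-subfraction 3D shift magnitude
    of a fraction; an optional per-axis red threshold may trigger red as
    well.  ``monitored_fractions`` are always evaluated; an orange in the
    last monitored fraction extends monitoring by one fraction.
    """

    green_max_mm: float = 3.0
    red_min_mm: float = 5.0
    axis_red_mm: Optional[Tuple[float, float, float]] = None
    monitored_fractions: Tuple[int, ...] = (1, 2, 3)
    tight_margins: MarginSpec = TIGHT_MARGINS
    large_margins: MarginSpec = LARGE_MARGINS

    def __post_init__(self) -> None:
        if not 0 <= self.green_max_mm <= self.red_min_mm:
            raise ValueError("need 0 <= green threshold <= red threshold")

    def classify(self, records: Sequence[ShiftRecord]) -> str:
        """Colour of a fraction from its subfraction shift records."""
        worst = "green"
        for rec in records:
            mag = rec.magnitude
            if mag >= self.red_min_mm:
                return "red"
            if self.axis_red_mm is not None and np.any(
                np.abs(rec.translation) >= np.asarray(self.axis_red_mm)
            ):
                return "red"
            if mag >= self.green_max_mm:
                worst = "orange"
        return worst


@dataclass
class TrafficLightState:
    """Per-patient protocol trace.

    Once ``switched`` is set the state is absorbing: every subsequent
    fraction is delivered with the large margins.
    """

    config: TrafficLightConfig
    colors: Dict[int, str] = field(default_factory=dict)
    monitored: List[int] = field(default_factory=list)
    unevaluable: List[int] = field(default_factory=list)
    switched: bool = False
    switch_fraction: Optional[int] = None
    margins_by_fraction: Dict[int, MarginSpec] = field(default_factory=dict)
    extra_monitored: List[int] = field(default_factory=list)
    log: List[str] = field(default_factory=list)

    def active_margins(self, fraction: int) -> MarginSpec:
        """Margins in effect for a fraction, given decisions made before it."""
        if self.switched and self.switch_fraction is not None and fraction >= self.switch_fraction:
            return self.config.large_margins
        return self.config.tight_margins

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in sorted(self.colors):
            rows.append(
                {
                    "fraction": f,
                    "color": self.colors[f],
                    "monitored": f in self.monitored,
                    "evaluable": f not in self.unevaluable,
                    "margin_lr": self.margins_by_fraction[f].lr,
                    "margin_ap": self.margins_by_fraction[f].ap,
                    "margin_si": self.margins_by_fraction[f].si,
                }
            )
        return pd.DataFrame(rows)


def traffic_light_step(
    state: TrafficLightState,
    fraction: int,
    shift_records: Sequence[ShiftRecord],
    config: Optional[TrafficLightConfig] = None,
) -> TrafficLightState:
    """Evaluate one delivered fraction and update the protocol state.

    The margins recorded for ``fraction`` are those already in force when it
    was delivered (decisions are prospective); its shifts then update the
    state for subsequent fractions.
    """
    config = config or state.config
    state.margins_by_fraction[fraction] = state.active_margins(fraction)

    records = [r for r in shift_records if r.fraction == fraction]
    if len(records) < 2:
        # missing subfraction measurement: conservative handling
        color = config.classify(records) if records else "orange"
        if color == "green":
            color = "orange"
        state.unevaluable.append(fraction)
        state.log.append(
            f"fraction {fraction}: incomplete shift records "
            f"({len(records)}/2), treated as {color}"
        )
    else:
        color = config.classify(records)
    state.colors[fraction] = color

    monitored = fraction in config.monitored_fractions or fraction in state.extra_monitored
    if monitored:
        state.monitored.append(fraction)
        last_monitored = max(config.monitored_fractions)
        if color == "orange" and fraction == last_monitored and not state.switched:
            state.extra_monitored.append(fraction + 1)
            state.log.append(
                f"fraction {fraction}: orange in the last monitored fraction, "
                f"extending monitoring to fraction {fraction + 1}"
            )
        if color == "red" and not state.switched:
            state.switched = True
            state.switch_fraction = fraction + 1
            state.log.append(
                f"fraction {fraction}: red traffic light, switching to larger "
                f"margins {config.large_margins} for subsequent fractions"
            )
    return state


def apply_protocol(
    shift_records: Sequence[ShiftRecord],
    config: Optional[TrafficLightConfig] = None,
    n_fractions: int = 5,
) -> TrafficLightState:
    """Run the full protocol over one patient's shift records.

    Returns the complete trace including the per-fraction active margins
    that the planning and accumulation stages consume.
    """
    config = config or TrafficLightConfig()
    state = TrafficLightState(config=config)
    for fraction in range(1, n_fractions + 1):
        traffic_light_step(state, fraction, shift_records, config)
    return state


def records_to_frame(records: Iterable[ShiftRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient": r.patient_id,
            "fraction": r.fraction,
            "interval": r.interval,
            "dx_LR": r.translation[0],
            "dy_AP": r.translation[1],
            "dz_SI": r.translation[2],
            "magnitude_3d": r.magnitude,
            "source": r.source,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> List[ShiftRecord]:
    return [
        ShiftRecord(
            patient_id=int(row.patient),
            fraction=int(row.fraction),
            interval=str(row.interval),
            translation=np.array([row.dx_LR, row.dy_AP, row.dz_SI]),
            source=str(getattr(row, "source", "ground_truth")),
        )
        for row in df.itertuples()
    ]
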