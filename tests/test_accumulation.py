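"""DVH engine against sort-based oracles; warp-and-sum accumulation
properties (conservation, linearity, degradation direction)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from subfrax.grid import DisplacementField, DoseGrid, VoxelGrid
from subfrax.motion import CohortConfig, MotionSample
from subfrax.phantom import FractionSession, simulate_cohort, SMOKE_ANATOMY, SMOKE_GRID, deform_anatomy
from subfrax.planning import PlanSpec, fraction_subplans
from subfrax.protocol import TIGHT_MARGINS
from subfrax.registration import RegistrationSettings
from subfrax.accumulation import (
    ConstraintSet,
    accumulate_interfraction,
    accumulate_intrafraction,
    cumulative_shift_table,
    dvh_query,
    summarize_cohort,
    warp_dose,
)


def _random_dose(rng, shape=(10, 10, 10), spacing=(1, 1, 1)):
    grid = VoxelGrid(shape, spacing)
    return DoseGrid(grid, rng.random(shape) * 40)


# ---------------------------------------------------------------------------
# DVH engine

def _oracle_dp(doses, p):
    """Sort-based brute force: interpolated dose exceeded by p% of volume."""
    srt = np.sort(doses)
    pos = (100.0 - p) / 100.0 * (len(srt) - 1)
    lo, w = int(np.floor(pos)), pos - int(np.floor(pos))
    return srt[lo] * (1 - w) + srt[min(lo + 1, len(srt) - 1)] * w


def test_dvh_queries_match_sort_oracle_exactly(rng):
    dose = _random_dose(rng)
    mask = rng.random(dose.grid.shape) < 0.7
    vals = dose.dose[mask]
    for p in (99, 95, 90, 50, 2):
        assert dvh_query(dose, mask, f"D{p}%") == pytest.approx(
            _oracle_dp(vals, p), abs=1e-12
        )
    # Dv cm3: minimum dose of the hottest v cm3 (voxel volume 0.001 cm3)
    total = vals.size * dose.grid.voxel_volume_cm3
    for v in (0.01, 0.1, 0.3):
        frac = (total - v) / total
        assert dvh_query(dose, mask, f"D{v}cc") == pytest.approx(
            _oracle_dp(vals, 100 * (1 - frac)), abs=1e-9
        )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_dvh_ordering_invariants(seed):
    rng = np.random.default_rng(seed)
    dose = _random_dose(rng)
    mask = np.ones(dose.grid.shape, bool)
    d99 = dvh_query(dose, mask, "D99%")
    d95 = dvh_query(dose, mask, "D95%")
    assert d99 <= d95 <= dose.dose.max() + 1e-12
    vols = [0.05, 0.2, 0.5]
    dv = [dvh_query(dose, mask, f"D{v}cc") for v in vols]
    assert dv[0] >= dv[1] >= dv[2]


def test_dvh_uniform_dose_and_constraints():
    grid = VoxelGrid((10, 10, 10), (2, 2, 2))
    dose = DoseGrid(grid, np.full(grid.shape, 36.25))
    mask = np.ones(grid.shape, bool)
    assert dvh_query(dose, mask, "D99%") == pytest.approx(36.25)
    assert dvh_query(dose, mask, "D95%") == pytest.approx(36.25)
    flags = ConstraintSet().evaluate(
        {"ctv_d99": 36.25, "rectum_d1cc": 30.0, "bladder_d5cc": 30.0}
    )
    assert all(flags.values())


def test_dvh_errors():
    grid = VoxelGrid((8, 8, 8), (1, 1, 1))
    dose = DoseGrid(grid, np.ones(grid.shape))
    with pytest.raises(ValueError, match="empty"):
        dvh_query(dose, np.zeros(grid.shape, bool), "D99%")
    small = np.zeros(grid.shape, bool)
    small[0, 0, :2] = True  # 0.002 cm3
    with pytest.raises(ValueError, match="smaller"):
        dvh_query(dose, small, "D1cc")
    with pytest.raises(ValueError, match="unrecognized"):
        dvh_query(dose, small, "V50Gy")


# ---------------------------------------------------------------------------
# dose warping

def test_warp_dose_zero_field_and_constant(rng):
    dose = _random_dose(rng)
    assert np.array_equal(
        warp_dose(dose, DisplacementField.zero(dose.grid)).dose, dose.dose
    )
    const = DoseGrid(dose.grid, np.full(dose.grid.shape, 5.0))
    field = DisplacementField(
        dose.grid, rng.standard_normal(tuple(dose.grid.shape) + (3,))
    )
    assert np.allclose(warp_dose(const, field).dose, 5.0)


def test_warp_dose_gaussian_against_closed_form():
    grid = VoxelGrid((32, 32, 32), (2, 2, 2))
    X, Y, Z = grid.world_coordinates()
    c = 31.0

    def gauss(x, y, z):
        return 10 * np.exp(-((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) / (2 * 8**2))

    dose = DoseGrid(grid, gauss(X, Y, Z))
    shift = np.array([2.0, 0, 0])
    warped = warp_dose(dose, DisplacementField.uniform(grid, shift))
    expected = gauss(X + 2.0, Y, Z)
    interior = (slice(2, -2),) * 3
    assert np.allclose(warped.dose[interior], expected[interior], rtol=0.01, atol=0.01)


# ---------------------------------------------------------------------------
# intrafraction accumulation

def _still_session(img, lab):
    zero = np.zeros(3)
    return FractionSession(
        1,
        {s: img for s in ("MR1", "MR2", "MR3", "MR4")},
        {s: lab for s in ("MR1", "MR2", "MR3", "MR4")},
        {
            "MR1_MR2": MotionSample(zero, "MR1_MR2"),
            "MR2_MR3": MotionSample(zero, "MR2_MR3"),
            "MR3_MR4": MotionSample(zero, "MR3_MR4"),
        },
        {"MR2": zero, "MR3": zero, "MR4": zero},
    )


def test_zero_motion_fraction_conserves_prescription(default_phantom):
    """Zero motion, ideal plans: intrafraction CTV D99% = 7.25 Gy within 1%."""
    img, lab = default_phantom
    session = _still_session(img, lab)
    spec = PlanSpec()
    atp1, atp2 = fraction_subplans(
        lab["ctv"], img.grid, spec, TIGHT_MARGINS, (np.zeros(3), np.zeros(3))
    )
    s = RegistrationSettings(n_repeats=1, seed=0)
    dose = accumulate_intrafraction(session, atp1, atp2, s)
    d99 = dvh_query(dose, lab["ctv"], "D99%")
    assert d99 == pytest.approx(spec.fraction_dose_gy, rel=0.01)


def test_large_second_delivery_shift_underdoses_toward_bladder(default_phantom):
    """An inferior 12 mm shift during the second delivery drops the fraction
    CTV D99% and dumps the surplus toward the bladder (superior), mirroring
    a urinary-urgency event."""
    img, lab = default_phantom
    grid = img.grid
    spec = PlanSpec()
    t = np.array([0.0, 0.0, -12.0])  # prostate drops inferior
    img4, lab4 = deform_anatomy(img, lab, MotionSample(t, "MR1_MR2"))
    session = FractionSession(
        1,
        {"MR1": img, "MR2": img, "MR3": img, "MR4": img4},
        {"MR1": lab, "MR2": lab, "MR3": lab, "MR4": lab4},
        {
            "MR1_MR2": MotionSample(np.zeros(3), "MR1_MR2"),
            "MR2_MR3": MotionSample(np.zeros(3), "MR2_MR3"),
            "MR3_MR4": MotionSample(t, "MR3_MR4"),
        },
        {"MR2": np.zeros(3), "MR3": np.zeros(3), "MR4": t},
    )
    atp1, atp2 = fraction_subplans(
        lab["ctv"], grid, spec, TIGHT_MARGINS, (np.zeros(3), np.zeros(3))
    )
    s = RegistrationSettings(n_repeats=1, seed=0)
    moved = accumulate_intrafraction(session, atp1, atp2, s)
    still = accumulate_intrafraction(
        _still_session(img, lab), atp1, atp2, s
    )
    d99_moved = dvh_query(moved, lab["ctv"], "D99%")
    d99_still = dvh_query(still, lab["ctv"], "D99%")
    assert d99_moved < d99_still
    # oracle: delivered dose evaluated directly in the ground-truth frame
    truth = accumulate_intrafraction(session, atp1, atp2, s, use_ground_truth_motion=True)
    assert dvh_query(truth, lab["ctv"], "D99%") < d99_still
    # surplus dose lands superior of the dropped target: bladder dose rises
    bladder_moved = moved.dose[lab["bladder"]].mean()
    bladder_still = still.dose[lab["bladder"]].mean()
    assert bladder_moved > bladder_still


def test_accumulation_linear_in_dose(default_phantom):
    img, lab = default_phantom
    session = _still_session(img, lab)
    spec = PlanSpec()
    atp1, atp2 = fraction_subplans(
        lab["ctv"], img.grid, spec, TIGHT_MARGINS, (np.zeros(3), np.zeros(3))
    )
    s = RegistrationSettings(n_repeats=1, seed=0)
    base = accumulate_intrafraction(session, atp1, atp2, s, use_ground_truth_motion=True)
    scaled = accumulate_intrafraction(
        session, 0.5 * atp1, 0.5 * atp2, s, use_ground_truth_motion=True
    )
    assert np.allclose(scaled.dose, 0.5 * base.dose, atol=1e-9)


def test_degradation_monotone_in_shift(default_phantom):
    """Fraction CTV D99% never increases over a 0-10 mm MR3->MR4 sweep."""
    img, lab = default_phantom
    grid = img.grid
    spec = PlanSpec()
    atp1, atp2 = fraction_subplans(
        lab["ctv"], grid, spec, TIGHT_MARGINS, (np.zeros(3), np.zeros(3))
    )
    s = RegistrationSettings(n_repeats=1, seed=0)
    d99s = []
    for si in (0.0, 2.5, 5.0, 7.5, 10.0):
        t = np.array([0.0, 0.0, si])
        img4, lab4 = deform_anatomy(img, lab, MotionSample(t, "MR1_MR2"))
        session = FractionSession(
            1,
            {"MR1": img, "MR2": img, "MR3": img, "MR4": img4},
            {"MR1": lab, "MR2": lab, "MR3": lab, "MR4": lab4},
            {
                "MR1_MR2": MotionSample(np.zeros(3), "MR1_MR2"),
                "MR2_MR3": MotionSample(np.zeros(3), "MR2_MR3"),
                "MR3_MR4": MotionSample(t, "MR3_MR4"),
            },
            {"MR2": np.zeros(3), "MR3": np.zeros(3), "MR4": t},
        )
        dose = accumulate_intrafraction(session, atp1, atp2, s, use_ground_truth_motion=True)
        d99s.append(dvh_query(dose, lab["ctv"], "D99%"))
    assert all(a >= b - 1e-9 for a, b in zip(d99s, d99s[1:]))


# ---------------------------------------------------------------------------
# interfraction accumulation

def _cohort_patient(seed=3, zero=False, n_fractions=5):
    cfg = (
        CohortConfig.zero_motion(n_patients=1, n_fractions=n_fractions, seed=seed)
        if zero
        else CohortConfig(n_patients=1, n_fractions=n_fractions, seed=seed)
    )
    (patient,) = simulate_cohort(cfg, SMOKE_ANATOMY, SMOKE_GRID)
    return patient


def _truth_fraction_doses(patient, margins=TIGHT_MARGINS):
    spec = PlanSpec()
    s = RegistrationSettings(n_repeats=1, seed=0)
    doses = {}
    for session in patient.sessions:
        atp1, atp2 = fraction_subplans(
            session.labels["MR1"]["ctv"], session.grid, spec, margins,
            (session.cumulative["MR2"], session.cumulative["MR3"]),
        )
        doses[session.fraction] = accumulate_intrafraction(
            session, atp1, atp2, s, use_ground_truth_motion=True
        )
    return doses


def test_single_fraction_total_equals_fraction_dose():
    patient = _cohort_patient(zero=False, n_fractions=1)
    doses = _truth_fraction_doses(patient)
    res = accumulate_interfraction(
        patient, doses, RegistrationSettings(n_repeats=1, seed=0),
        use_ground_truth_motion=True,
    )
    assert np.array_equal(res.total.dose, doses[1].dose)


def test_total_equals_brute_force_sum_of_warped_fractions():
    patient = _cohort_patient(seed=9)
    doses = _truth_fraction_doses(patient)
    res = accumulate_interfraction(
        patient, doses, RegistrationSettings(n_repeats=1, seed=0),
        use_ground_truth_motion=True,
    )
    # brute force: warp each fraction dose by its ground-truth field and add
    expected = doses[1].dose.copy()
    for session in patient.sessions[1:]:
        k = session.fraction
        t = patient.interfraction[k].translation
        warped = warp_dose(doses[k], DisplacementField.uniform(patient.grid, t))
        expected = expected + warped.dose
    assert np.allclose(res.total.dose, expected, atol=1e-12)


def test_zero_motion_treatment_total_on_smoke_grid():
    """Identical anatomy, zero motion: total CTV D99% = 36.25 Gy within 1%
    (ground-truth motion path; the DIR path is covered in acceptance)."""
    patient = _cohort_patient(zero=True)
    doses = _truth_fraction_doses(patient)
    res = accumulate_interfraction(
        patient, doses, RegistrationSettings(n_repeats=1, seed=0),
        use_ground_truth_motion=True,
    )
    assert res.metrics["ctv_d99"] == pytest.approx(36.25, rel=0.01)
    assert res.constraints["ctv_d99"]


# ---------------------------------------------------------------------------
# cohort summaries

def test_summarize_single_patient_iqr_zero():
    rows = [
        {
            "patient": 0,
            "subgroup": "tight",
            "scenario": "actual",
            "ctv_d99": 35.0,
            "ctv_d95": 35.5,
            "rectum_d1cc": 30.0,
            "bladder_d5cc": 25.0,
        }
    ]
    df = summarize_cohort(rows)
    row = df.iloc[0]
    assert row.ctv_d99_median == 35.0
    assert row.ctv_d99_iqr_lo == row.ctv_d99_iqr_hi == 35.0
    assert row.d99_pass_fraction == 1.0


def test_summarize_median_iqr_against_sorted_oracle(rng):
    vals = rng.random(14) * 10 + 30
    rows = [
        {
            "patient": i,
            "subgroup": "switched",
            "scenario": "actual",
            "ctv_d99": float(v),
            "ctv_d95": float(v),
            "rectum_d1cc": 0.0,
            "bladder_d5cc": 0.0,
        }
        for i, v in enumerate(vals)
    ]
    df = summarize_cohort(rows)
    row = df.iloc[0]
    assert row.ctv_d99_median == pytest.approx(np.median(vals))
    assert row.ctv_d99_iqr_lo == pytest.approx(np.percentile(vals, 25))
    assert row.ctv_d99_iqr_hi == pytest.approx(np.percentile(vals, 75))
    assert row.d99_pass_fraction == pytest.approx(np.mean(vals >= 34.4))
    assert row.n_patients == 14


def test_cumulative_shift_table_is_cdf():
    import pandas as pd

    df = pd.DataFrame(
        {
            "fraction": [1, 1, 1, 2, 2],
            "magnitude_3d": [2.0, 1.0, 3.0, 0.5, 1.5],
        }
    )
    out = cumulative_shift_table(df)
    f1 = out[out.fraction == 1]
    assert list(f1.magnitude_3d) == [1.0, 2.0, 3.0]
    assert list(f1.cumulative_probability) == pytest.approx([1 / 3, 2 / 3, 1.0])
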