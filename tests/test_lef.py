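"""Coulomb field core: oracle values, superposition, equivariance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cagefield import (
    COULOMB_K,
    ChargedFrame,
    build_axis_frame,
    field_at_point,
    field_on_axis,
    field_series,
)
from cagefield.errors import SingularityError
from cagefield.lef import records_to_frame

from conftest import random_rotation


def _frame(positions, charges, groups=None, names=None):
    n = len(charges)
    return ChargedFrame(
        np.asarray(positions, float), np.asarray(charges, float),
        names or [f"A{i}" for i in range(n)],
        groups or ["SRC"] * n)


def test_single_charge_inverse_square_value():
    frame = _frame([[0, 0, -10.0]], [1.0])
    f = field_at_point(frame, "all", [0, 0, 0])
    np.testing.assert_allclose(f, [0, 0, COULOMB_K / 100], atol=1e-12)


def test_mirror_symmetric_charges_cancel_transverse():
    frame = _frame([[5.0, 0, 3], [-5.0, 0, 3]], [0.7, 0.7])
    f = field_at_point(frame, "all", [0, 0, 0])
    assert abs(f[0]) < 1e-12 and abs(f[1]) < 1e-12


def test_superposition_on_random_frames(rng):
    n = 60
    pos = rng.uniform(-8, 8, (n, 3))
    pos[np.linalg.norm(pos, axis=1) < 1.0] += 3.0  # keep away from the probe
    q = rng.uniform(-1, 1, n)
    groups = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    frame = _frame(pos, q, groups=groups)
    fa = field_at_point(frame, "group A", [0, 0, 0])
    fb = field_at_point(frame, "group B", [0, 0, 0])
    ftot = field_at_point(frame, "all", [0, 0, 0])
    np.testing.assert_allclose(fa + fb, ftot, atol=1e-10)
    # and against the per-atom brute-force sum
    brute = sum(COULOMB_K * qi * (-ri) / np.linalg.norm(ri) ** 3
                for ri, qi in zip(pos, q))
    np.testing.assert_allclose(ftot, brute, atol=1e-9)


def test_inverse_square_scaling_of_distances(rng):
    pos = rng.uniform(2, 6, (10, 3))
    q = rng.uniform(-1, 1, 10)
    f1 = field_at_point(_frame(pos, q), "all", [0, 0, 0])
    f2 = field_at_point(_frame(2 * pos, q), "all", [0, 0, 0])
    np.testing.assert_allclose(np.linalg.norm(f2), np.linalg.norm(f1) / 4,
                               rtol=1e-12)


def test_probe_on_source_atom_raises_naming_atom():
    frame = _frame([[0, 0, 0]], [1.0], names=["QQ"])
    with pytest.raises(SingularityError, match="QQ"):
        field_at_point(frame, "all", [0, 0, 0])


def test_excluded_atoms_contribute_nothing():
    frame = _frame([[0, 0, -5], [0, 0, 5]], [1.0, 1.0], groups=["IN", "OUT"])
    f = field_at_point(frame, "group IN", [0, 0, 0])
    np.testing.assert_allclose(f, [0, 0, COULOMB_K / 25], atol=1e-12)


# ------------------------------------------------------------- axis projections

def _axis_system():
    pos = np.array([[0.0, 0, -1], [0, 0, 1], [0, 4, 0], [0, 0, 6], [3, 2, -4]])
    q = np.array([0.0, 0.0, 0.0, -1.0, 0.6])
    names = ["FE", "O1", "LR", "S1", "S2"]
    groups = ["FE", "O", "TLN", "SRC", "SRC"]
    return ChargedFrame(pos, q, names, groups)


def test_negative_charge_beyond_o_pulls_field_positive_z():
    """Coulomb sign convention: field at the probe points toward a −q source."""
    frame = _axis_system()
    axis = build_axis_frame(frame, "name FE", "name O1", "group TLN")
    rec = field_on_axis(frame, axis, "name S1", probe="midpoint")
    assert rec.F_z > 0


def test_projection_equivariance_under_rigid_motion(rng):
    frame = _axis_system()
    axis = build_axis_frame(frame, "name FE", "name O1", "group TLN")
    rec = field_on_axis(frame, axis, "group SRC", probe="midpoint")
    for _ in range(5):
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        moved = ChargedFrame(frame.positions @ R.T + t, frame.charges,
                             frame.names, frame.groups)
        maxis = build_axis_frame(moved, "name FE", "name O1", "group TLN")
        mrec = field_on_axis(moved, maxis, "group SRC", probe="midpoint")
        assert mrec.F_y == pytest.approx(rec.F_y, abs=1e-10)
        assert mrec.F_z == pytest.approx(rec.F_z, abs=1e-10)


def test_symmetric_periphery_gives_zero_lateral_field(small_cage):
    _, _, traj, _ = small_cage
    frame = traj[0]
    axis = build_axis_frame(frame, "name FE", "name O1", "group TLN")
    rec = field_on_axis(frame, axis, "group HM1 or group CION", probe="midpoint")
    # periphery and counter-ions are symmetric rings in the z = 0 plane and
    # the probe (Fe-O midpoint) sits at their common center, so both the
    # lateral and the axial components cancel exactly on frame 0
    assert abs(rec.F_y) < 1e-10
    assert abs(rec.F_z) < 1e-10


def test_probe_variants_average3():
    frame = _axis_system()
    axis = build_axis_frame(frame, "name FE", "name O1", "group TLN")
    recs = {p: field_on_axis(frame, axis, "group SRC", probe=p,
                             fe="name FE", o="name O1")
            for p in ("fe", "midpoint", "o", "average3")}
    avg = (recs["fe"].F + recs["midpoint"].F + recs["o"].F) / 3
    np.testing.assert_allclose(recs["average3"].F, avg, atol=1e-12)


# ---------------------------------------------------------------- time series

def test_series_constant_on_jitter_free_trajectory(small_cage):
    spec, _, _, truth = small_cage
    from cagefield import CageSpec, gen_cage_system
    frozen = CageSpec(**{**spec.__dict__, "positional_sigma": 0.0, "n_frames": 3})
    _, traj, truth0 = gen_cage_system(frozen)
    builder = lambda fr: build_axis_frame(fr, "name FE", "name O1", "group TLN")
    recs = field_series(traj, builder, "not (group FE or group O)")
    assert len(recs) == 3
    for rec in recs:
        np.testing.assert_allclose(rec.F, truth0.expected_field_at_origin,
                                   atol=1e-10)


def test_series_stride_subsamples_every_other_frame(small_cage):
    _, _, traj, _ = small_cage
    builder = lambda fr: build_axis_frame(fr, "name FE", "name O1", "group TLN")
    recs = field_series(traj, builder, "group HM1",
                        stride=2 * traj.stride)
    assert [r.time for r in recs] == list(traj.times[::2])


def test_group_decomposition_sums_to_total(small_cage):
    _, _, traj, _ = small_cage
    builder = lambda fr: build_axis_frame(fr, "name FE", "name O1", "group TLN")
    recs = field_series(traj, builder, "not (group FE or group O)",
                        decompose=["HM1", "CAGE", "SOLV", "TLN", "CION"])
    for rec in recs:
        total = np.sum(list(rec.contributions.values()), axis=0)
        np.testing.assert_allclose(total, rec.F, atol=1e-10)
    df = records_to_frame(recs)
    # linearity holds for the projected means as well
    assert df["F_z"].mean() == pytest.approx(
        sum(df[f"{g}_F_z"].mean() for g in ("HM1", "CAGE", "SOLV", "TLN", "CION")),
        abs=1e-10)


def test_empty_trajectory_yields_empty_series():
    from cagefield import Trajectory
    builder = lambda fr: None
    assert field_series(Trajectory([]), builder, "all") == []


@given(st.floats(1.5, 20), st.floats(-2, 2))
def test_field_magnitude_closed_form(r, q):
    """|F| of one charge at distance r is k|q|/r² (hypothesis sweep)."""
    frame = _frame([[0, 0, -r]], [q])
    f = field_at_point(frame, "all", [0, 0, 0])
    assert np.linalg.norm(f) == pytest.approx(COULOMB_K * abs(q) / r**2,
                                              rel=1e-12)
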