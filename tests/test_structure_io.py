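"""File dialects, selections and reaction-axis frame construction."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from cagefield import (
    Atom,
    ChargedFrame,
    Trajectory,
    build_axis_frame,
    read_pqr,
    read_xyz_trajectory,
    resolve_selection,
    write_pqr,
    write_xyz_trajectory,
)
from cagefield.errors import (
    FormatError,
    GeometryError,
    SelectionError,
    StructureError,
)

from conftest import random_rotation


# ---------------------------------------------------------------------- PQR

def test_pqr_single_record_echoes_charge(tmp_path):
    p = tmp_path / "one.pqr"
    p.write_text("ATOM 1 OW SOLV 1 1.000 2.000 3.000 -0.8340 1.400\n")
    atoms = read_pqr(p)
    assert len(atoms) == 1
    assert atoms[0].charge == pytest.approx(-0.834)
    assert atoms[0].group == "SOLV"
    np.testing.assert_allclose(atoms[0].position, [1.0, 2.0, 3.0])


def test_pqr_empty_file_gives_empty_list(tmp_path):
    p = tmp_path / "empty.pqr"
    p.write_text("REMARK nothing here\n")
    assert read_pqr(p) == []


def test_pqr_round_trip_preserves_fields(tmp_path, small_cage):
    _, atoms, _, _ = small_cage
    p = tmp_path / "rt.pqr"
    write_pqr(atoms, p)
    back = read_pqr(p)
    assert len(back) == len(atoms)
    for a, b in zip(atoms, back):
        assert a.name == b.name and a.group == b.group
        np.testing.assert_allclose(a.position, b.position, atol=1e-3)
        assert abs(a.charge - b.charge) <= 1e-4


@pytest.mark.parametrize("bad", [
    "ATOM 1 OW SOLV 1 1.0 2.0 3.0\n",              # missing charge+radius
    "ATOM 1 OW SOLV 1 1.0 2.0 xx -0.8 1.4\n",      # non-numeric coordinate
])
def test_pqr_malformed_record_names_line(tmp_path, bad):
    p = tmp_path / "bad.pqr"
    p.write_text("ATOM 1 OW SOLV 1 0 0 0 0.1 1.0\n" + bad)
    with pytest.raises(FormatError, match=":2"):
        read_pqr(p)


def test_pqr_read_matches_mdanalysis(tmp_path, small_cage):
    """A standard reader sees the same positions and charges we wrote."""
    mda = pytest.importorskip("MDAnalysis")
    _, atoms, _, _ = small_cage
    p = tmp_path / "x.pqr"
    write_pqr(atoms, p)
    u = mda.Universe(str(p))
    np.testing.assert_allclose(
        u.atoms.positions, np.array([a.position for a in atoms]), atol=1e-3)
    np.testing.assert_allclose(
        u.atoms.charges, np.array([a.charge for a in atoms]), atol=1e-4)


# ---------------------------------------------------------------------- XYZ

def _tiny_atoms(n):
    return [Atom(i, f"A{i}", "G", np.array([float(i), 0, 0]), 0.1 * i)
            for i in range(n)]


def test_xyz_two_frames_three_atoms(tmp_path):
    p = tmp_path / "t.xyz"
    p.write_text(
        "3\ntime=0.0\nA 0 0 0\nB 1 0 0\nC 2 0 0\n"
        "3\ntime=10.0\nA 0 0 1\nB 1 0 1\nC 2 0 1\n")
    traj = read_xyz_trajectory(p, _tiny_atoms(3))
    assert len(traj) == 2 and len(traj[0]) == 3
    assert traj.times.tolist() == [0.0, 10.0]
    # positional join: charges come from the charge map
    np.testing.assert_allclose(traj[1].charges, [0.0, 0.1, 0.2])


def test_xyz_atom_count_mismatch_between_frames(tmp_path):
    p = tmp_path / "t.xyz"
    p.write_text("3\n\nA 0 0 0\nB 1 0 0\nC 2 0 0\n"
                 "4\n\nA 0 0 0\nB 1 0 0\nC 2 0 0\nD 3 0 0\n")
    with pytest.raises(StructureError):
        read_xyz_trajectory(p, _tiny_atoms(3))


def test_xyz_times_default_to_stride_multiples(tmp_path):
    p = tmp_path / "t.xyz"
    p.write_text("1\nframe a\nA 0 0 0\n1\nframe b\nA 0 0 1\n")
    traj = read_xyz_trajectory(p, _tiny_atoms(1), stride=2.5)
    assert traj.times.tolist() == [0.0, 2.5]


def test_xyz_round_trip_of_generated_trajectory(tmp_path, small_cage):
    _, atoms, traj, _ = small_cage
    p = tmp_path / "rt.xyz"
    write_xyz_trajectory(traj, p)
    back = read_xyz_trajectory(p, atoms)
    assert len(back) == len(traj)
    for fa, fb in zip(traj, back):
        np.testing.assert_allclose(fa.positions, fb.positions, atol=1e-3)
        assert fa.time == pytest.approx(fb.time, abs=1e-4)


def test_xyz_read_matches_mdanalysis(tmp_path, small_cage):
    mda = pytest.importorskip("MDAnalysis")
    _, atoms, traj, _ = small_cage
    p = tmp_path / "x.xyz"
    write_xyz_trajectory(traj, p)
    u = mda.Universe(str(p))
    assert len(u.trajectory) == len(traj)
    for ts, frame in zip(u.trajectory, traj):
        np.testing.assert_allclose(ts.positions, frame.positions, atol=1e-3)


# ----------------------------------------------------------------- selections

def _shell_frame(solv_dist):
    """One HM1 atom at the origin, one SOLV atom at a given distance."""
    return ChargedFrame(
        np.array([[0.0, 0, 0], [solv_dist, 0, 0]]),
        np.zeros(2), ["P1", "OW"], ["HM1", "SOLV"])


@pytest.mark.parametrize("dist,included", [(2.9, True), (3.0, True), (3.1, False)])
def test_distance_shell_boundary_is_closed(dist, included):
    idx = resolve_selection(_shell_frame(dist),
                            "group SOLV within 3.0 of group HM1")
    assert (1 in idx) == included


def test_shell_matches_brute_force_on_synthetic_frame(rng):
    n = 200
    pos = rng.uniform(-10, 10, (n, 3))
    groups = ["HM1" if i < 20 else "SOLV" for i in range(n)]
    frame = ChargedFrame(pos, np.zeros(n), [f"A{i}" for i in range(n)], groups)
    got = resolve_selection(frame, "group SOLV within 3.0 of group HM1")
    # independent double loop
    expected = []
    for i in range(20, n):
        if min(np.linalg.norm(pos[i] - pos[j]) for j in range(20)) <= 3.0:
            expected.append(i)
    assert got.tolist() == expected


def test_selection_idempotent_and_composable(small_cage):
    _, _, traj, _ = small_cage
    frame = traj[0]
    a = resolve_selection(frame, "group CAGE or group SOLV")
    b = resolve_selection(frame, "group SOLV or group CAGE")
    assert a.tolist() == b.tolist()
    assert resolve_selection(frame, "group CAGE and group CAGE").tolist() == \
        resolve_selection(frame, "group CAGE").tolist()
    inv = resolve_selection(frame, "not (group CAGE or group SOLV)")
    assert sorted(a.tolist() + inv.tolist()) == list(range(len(frame)))


def test_unknown_label_lists_valid_groups(small_cage):
    _, _, traj, _ = small_cage
    with pytest.raises(SelectionError, match="HM1"):
        resolve_selection(traj[0], "group NOPE")


def test_name_and_index_primaries(small_cage):
    _, _, traj, _ = small_cage
    frame = traj[0]
    fe = resolve_selection(frame, "name FE")
    assert len(fe) == 1 and frame.names[fe[0]] == "FE"
    assert resolve_selection(frame, "index 0-2").tolist() == [0, 1, 2]


# ------------------------------------------------------------------ axis frame

def test_axis_frame_axis_aligned_construction():
    frame = ChargedFrame(
        np.array([[0.0, 0, 0], [0, 0, 2], [0, 3, 1]]),
        np.zeros(3), ["FE", "O1", "C1"], ["FE", "O", "TLN"])
    ax = build_axis_frame(frame, "name FE", "name O1", "group TLN")
    np.testing.assert_allclose(ax.z_hat, [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(ax.y_hat, [0, 1, 0], atol=1e-12)
    np.testing.assert_allclose(ax.origin, [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(ax.x_hat, np.cross(ax.y_hat, ax.z_hat), atol=1e-12)


def test_axis_frame_rotation_equivariance(rng):
    pos = np.array([[0.0, 0, 0], [0, 0, 2], [0, 3, 1], [1.0, -2.0, 0.5]])
    frame = ChargedFrame(pos, np.zeros(4), ["FE", "O1", "C1", "C2"],
                         ["FE", "O", "TLN", "TLN"])
    ax = build_axis_frame(frame, "name FE", "name O1", "group TLN")
    covector = rng.standard_normal(3)
    for _ in range(5):
        R = random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        rframe = ChargedFrame(pos @ R.T + t, np.zeros(4), frame.names, frame.groups)
        rax = build_axis_frame(rframe, "name FE", "name O1", "group TLN")
        # projections of a co-rotated vector are invariant
        _, y0, z0 = ax.project(covector)
        _, y1, z1 = rax.project(R @ covector)
        assert y1 == pytest.approx(y0, abs=1e-10)
        assert z1 == pytest.approx(z0, abs=1e-10)


def test_axis_frame_degenerate_geometries():
    coincident = ChargedFrame(
        np.array([[0.0, 0, 0], [0, 0, 0.1], [0, 3, 0]]),
        np.zeros(3), ["FE", "O1", "C1"], ["FE", "O", "TLN"])
    with pytest.raises(GeometryError):
        build_axis_frame(coincident, "name FE", "name O1", "group TLN")
    collinear = ChargedFrame(
        np.array([[0.0, 0, 0], [0, 0, 2], [0, 0, 5]]),
        np.zeros(3), ["FE", "O1", "C1"], ["FE", "O", "TLN"])
    with pytest.raises(GeometryError):
        build_axis_frame(collinear, "name FE", "name O1", "group TLN")


def test_trajectory_rejects_nonincreasing_times():
    f = ChargedFrame(np.zeros((1, 3)), np.zeros(1), ["A"], ["G"], time=1.0)
    g = ChargedFrame(np.zeros((1, 3)), np.zeros(1), ["A"], ["G"], time=1.0)
    with pytest.raises(StructureError):
        Trajectory([f, g])
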