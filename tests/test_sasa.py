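"""Shrake–Rupley SASA: closed forms, reference oracle, window profiles."""

import numpy as np
import pytest

from cgagg.core import AnalysisWindow, Topology, Trajectory, TrajectoryFrame
from cgagg.sasa import (
    bead_sasa,
    buried_residues,
    delta_sasa,
    residue_sasa_window,
    sphere_points,
)
from cgagg.synth import make_sasa_fixture, protein_blob_offsets
from conftest import make_frame, make_protein_topology

PROBE = 0.56
R = 0.26


def two_sphere_analytic(r1, r2, probe, d):
    """Closed-form accessible areas of two mutually occluding spheres."""
    R1, R2 = r1 + probe, r2 + probe
    full1, full2 = 4 * np.pi * R1**2, 4 * np.pi * R2**2
    if d >= R1 + R2:
        return full1, full2
    def cap(Ra, Rb):
        x = (d * d + Ra * Ra - Rb * Rb) / (2 * d)
        return 2 * np.pi * Ra * (Ra - x)
    return full1 - cap(R1, R2), full2 - cap(R2, R1)


def test_sphere_points_are_unit_and_balanced():
    pts = sphere_points(960)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
    assert np.allclose(pts.mean(axis=0), 0.0, atol=0.01)


def test_isolated_bead_matches_closed_form():
    fr, topo = make_sasa_fixture("single_sphere", radius=R)
    a = bead_sasa(fr, topo, probe=PROBE, n_points=960)
    assert a[0] == pytest.approx(4 * np.pi * (R + PROBE)**2, rel=0.005)


def test_fully_buried_core_is_zero():
    fr, topo = make_sasa_fixture("buried_core", n_shell=60)
    a = bead_sasa(fr, topo, probe=PROBE, n_points=960)
    assert a[0] == 0.0


def test_distant_spheres_equal_isolated_value():
    sep = 2 * (R + PROBE) + 0.01
    fr, topo = make_sasa_fixture("two_spheres", separation=sep)
    a = bead_sasa(fr, topo, probe=PROBE, n_points=960)
    iso = 4 * np.pi * (R + PROBE)**2
    assert np.allclose(a, iso, rtol=1e-12)


@pytest.mark.parametrize("sep", [0.2, 0.5, 0.9, 1.3, 1.6])
def test_two_sphere_sweep_matches_analytic(sep):
    fr, topo = make_sasa_fixture("two_spheres", separation=sep)
    a = bead_sasa(fr, topo, probe=PROBE, n_points=960)
    ref = two_sphere_analytic(R, R, PROBE, sep)
    assert a.sum() == pytest.approx(sum(ref), rel=0.02)


def test_point_count_convergence_is_monotone(rng):
    pos = rng.uniform(14, 16, size=(12, 3))
    topo = make_protein_topology(1, 12)
    fr = make_frame(pos, box=(30., 30., 30.))
    totals = [bead_sasa(fr, topo, probe=PROBE, n_points=n).sum()
              for n in (240, 960, 3840)]
    d1 = abs(totals[1] - totals[0])
    d2 = abs(totals[2] - totals[1])
    assert d2 < d1


def test_periodic_images_occlude():
    # a bead near the box face is shadowed by its own periodic neighbor
    topo = make_protein_topology(2, 1)
    box = (5.0, 20.0, 20.0)
    fr = make_frame([[0.1, 10., 10.], [4.9, 10., 10.]], box=box)
    a = bead_sasa(fr, topo, probe=PROBE, n_points=960)
    ref = two_sphere_analytic(R, R, PROBE, 0.2)   # wrapped distance 0.2 nm
    assert a[0] == pytest.approx(ref[0], rel=0.02)


def test_translation_invariance_with_wrap(rng):
    pos = rng.uniform(14, 17, size=(10, 3))
    topo = make_protein_topology(1, 10)
    box = (30., 30., 30.)
    a0 = bead_sasa(make_frame(pos, box=box), topo, probe=PROBE, n_points=240)
    a1 = bead_sasa(make_frame(pos + np.array([14.0, -5.0, 28.0]), box=box),
                   topo, probe=PROBE, n_points=240)
    assert np.allclose(a0, a1, atol=1e-9)


def test_rotation_invariance_within_discretization(rng):
    pos = rng.uniform(14, 17, size=(15, 3))
    topo = make_protein_topology(1, 15)
    box = (40., 40., 40.)
    th = 1.1
    Rz = np.array([[np.cos(th), -np.sin(th), 0],
                   [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    center = pos.mean(axis=0)
    rot = (pos - center) @ Rz.T + center
    a0 = bead_sasa(make_frame(pos, box=box), topo, probe=PROBE, n_points=960)
    a1 = bead_sasa(make_frame(rot, box=box), topo, probe=PROBE, n_points=960)
    assert a1.sum() == pytest.approx(a0.sum(), rel=0.005)


def test_reference_implementation_agreement(rng):
    struc = pytest.importorskip("biotite.structure")
    n = 40
    pos = rng.uniform(12, 18, size=(n, 3))
    radii = rng.uniform(0.2, 0.35, n)
    topo = make_protein_topology(1, n)
    topo.bead_radius[:] = radii
    fr = make_frame(pos, box=(40., 40., 40.))
    mine = bead_sasa(fr, topo, probe=PROBE, n_points=3840, periodic=False)

    arr = struc.AtomArray(n)
    arr.coord = (pos * 10).astype(np.float32)       # nm -> Angstrom
    arr.element = np.full(n, "C")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, "UNK")
    arr.atom_name = np.full(n, "C")
    ref = struc.sasa(arr, probe_radius=PROBE * 10, vdw_radii=radii * 10,
                     point_number=3840) / 100.0     # A^2 -> nm^2
    sel = ref > 0.1
    assert np.all(np.abs(mine[sel] - ref[sel]) / ref[sel] < 0.01)


# ---------------------------------------------------------------------------
# window profiles / delta
# ---------------------------------------------------------------------------

def blob_trajectory(centers_per_frame, n_res=8, dt=4.0):
    topo = make_protein_topology(len(centers_per_frame[0]), n_res)
    offs = protein_blob_offsets(n_res, 1.0)
    frames = []
    for k, centers in enumerate(centers_per_frame):
        pos = (np.asarray(centers)[:, None, :] + offs).reshape(-1, 3)
        frames.append(make_frame(pos, box=(40., 40., 40.), time=k * dt))
    return Trajectory(frames, topo), topo


def test_single_frame_profile_equals_per_frame_sums():
    traj, topo = blob_trajectory([[[20., 20., 20.]]])
    prof = residue_sasa_window(traj, topo, AnalysisWindow(-1.0, 1.0),
                               n_points=240)
    areas = bead_sasa(traj[0], topo, probe=PROBE, n_points=240)
    ref = np.array([areas[topo.residue_index == r].sum()
                    for r in prof.residues])
    assert np.allclose(prof.values, ref)
    # partition conservation: residue sums equal bead total
    assert prof.values.sum() == pytest.approx(np.nansum(areas), rel=1e-9)


def test_constant_geometry_window_average_equals_single_frame():
    traj, topo = blob_trajectory([[[20., 20., 20.]]] * 4)
    win_all = residue_sasa_window(traj, topo, AnalysisWindow(0., 12.),
                                  n_points=240)
    win_one = residue_sasa_window(traj, topo, AnalysisWindow(0., 1.),
                                  n_points=240)
    assert np.allclose(win_all.values, win_one.values)


def test_two_frame_average_is_arithmetic_mean():
    traj, topo = blob_trajectory([
        [[20., 20., 20.], [30., 20., 20.]],      # separated
        [[20., 20., 20.], [21.2, 20., 20.]]])    # touching
    a = residue_sasa_window(traj, topo, AnalysisWindow(0., 1.), n_points=240)
    b = residue_sasa_window(traj, topo, AnalysisWindow(3., 5.), n_points=240)
    both = residue_sasa_window(traj, topo, AnalysisWindow(0., 5.),
                               n_points=240)
    assert np.allclose(both.values, (a.values + b.values) / 2, atol=1e-12)


def test_spacing_must_be_multiple_of_frame_interval():
    traj, topo = blob_trajectory([[[20., 20., 20.]]] * 4)
    with pytest.raises(ValueError, match="multiple"):
        residue_sasa_window(traj, topo, AnalysisWindow(0., 12.), spacing=6.0)


def test_delta_sasa_monomer_to_dimer_interface():
    # early: two separated blobs; late: touching -> interface residues lose
    # area; magnitudes must match the direct two-configuration difference
    traj, topo = blob_trajectory([
        [[15., 20., 20.], [30., 20., 20.]],
        [[19.4, 20., 20.], [21.0, 20., 20.]]])
    early = residue_sasa_window(traj, topo, AnalysisWindow(0., 1.),
                                n_points=240)
    late = residue_sasa_window(traj, topo, AnalysisWindow(3., 5.),
                               n_points=240)
    d = delta_sasa(early, late)
    assert np.allclose(d.delta, late.values - early.values)
    assert d.delta.min() < 0           # something buried
    buried = buried_residues(d, threshold=0.1)
    assert buried, "interface residues expected above threshold"
    # sorted by burial magnitude descending
    mags = [m for _, m in buried]
    assert mags == sorted(mags, reverse=True)


def test_identical_profiles_give_zero_delta_and_probe_mismatch_raises():
    traj, topo = blob_trajectory([[[20., 20., 20.]]] * 2)
    a = residue_sasa_window(traj, topo, AnalysisWindow(0., 1.), n_points=240)
    b = residue_sasa_window(traj, topo, AnalysisWindow(3., 5.), n_points=240)
    assert np.allclose(delta_sasa(a, b).delta, 0.0)
    c = residue_sasa_window(traj, topo, AnalysisWindow(3., 5.), probe=0.14,
                            n_points=240)
    with pytest.raises(ValueError, match="probe mismatch"):
        delta_sasa(a, c)


def test_buried_filter_matches_exhaustive_scan(rng):
    from cgagg.sasa import DeltaSasa
    delta = rng.normal(0, 1.0, 50)
    d = DeltaSasa(residues=np.arange(1, 51), delta=delta)
    got = buried_residues(d, threshold=0.75)
    ref = [(int(r), float(-v)) for r, v in zip(d.residues, delta)
           if -v > 0.75]
    ref.sort(key=lambda t: -t[1])
    assert [r for r, _ in got] == [r for r, _ in ref]
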