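"""Tests for superposition, iterative averaging, RMSF and loop reports."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cryoevb.errors import DegenerateGeometryError
from cryoevb.flexibility import (
    LoopRegion,
    Structure,
    Trajectory,
    apply_transform,
    iterative_average,
    kabsch_superpose,
    loop_report,
    make_bead_atoms,
    rmsf,
)
from cryoevb.surrogate import generate_backbone_ensemble, make_flex_profile


def _quaternion_fit(mobile, reference):
    """Independent oracle: optimal rotation via the quaternion method."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    vals, vecs = np.linalg.eigh(k)
    q = vecs[:, np.argmax(vals)]  # w, x, y, z
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


@pytest.fixture()
def cloud():
    rng = np.random.default_rng(8)
    return rng.normal(scale=4.0, size=(50, 3))


def test_superpose_identity(cloud):
    rot, trans, rmsd = kabsch_superpose(cloud, cloud)
    assert np.allclose(rot, np.eye(3), atol=1e-10)
    assert rmsd == pytest.approx(0.0, abs=1e-10)


def test_superpose_inverts_known_transform(cloud):
    rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = cloud @ rot90.T + np.array([3.0, -2.0, 7.0])
    rot, trans, rmsd = kabsch_superpose(moved, cloud)
    assert rmsd < 1e-9
    assert np.allclose(apply_transform(moved, rot, trans), cloud, atol=1e-9)
    assert np.linalg.det(rot) == pytest.approx(1.0)


def test_superpose_agrees_with_quaternion_oracle(cloud):
    rng = np.random.default_rng(9)
    moved = (
        cloud @ Rotation.random(rng=rng).as_matrix().T
        + rng.normal(scale=0.1, size=cloud.shape)
        + np.array([1.0, 2.0, 3.0])
    )
    rot, _, rmsd = kabsch_superpose(moved, cloud)
    oracle = _quaternion_fit(moved, cloud)
    assert np.allclose(rot, oracle, atol=1e-8)
    # sigma=0.1 per-coordinate noise: post-fit rmsd near sigma*sqrt(3),
    # slightly deflated by the 6 fitted rigid degrees of freedom
    assert rmsd == pytest.approx(0.1 * np.sqrt(3.0), rel=0.06)


def test_superpose_rejects_degenerate_selections():
    line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(line, line)
    tiny = np.eye(3)[:2]
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(tiny, tiny)


def _static_traj(n_frames=4, n_residues=6):
    atoms = make_bead_atoms(n_residues)
    profile = make_flex_profile(n_residues=n_residues, loop_regions=())
    coords = np.repeat(profile.reference_coords[None], n_frames, axis=0)
    return Trajectory(atoms=atoms, coords=coords)


def test_iterative_average_of_identical_frames_converges_immediately():
    traj = _static_traj()
    avg, n_iter = iterative_average(traj)
    assert n_iter == 1
    assert np.allclose(avg.coords, traj.coords[0], atol=1e-12)


def test_iterative_average_recovers_reference_under_noise():
    profile = make_flex_profile(n_residues=12, base_amplitude=0.3, loop_regions=())
    traj = generate_backbone_ensemble(profile, 800, seed=12)
    avg, _ = iterative_average(traj)
    rms = np.sqrt(((avg.coords - profile.reference_coords) ** 2).mean())
    assert rms < 2 * 0.3 / np.sqrt(800) * 3


def test_iterative_average_is_rigid_body_invariant():
    """Random per-frame rotations/translations leave the average unchanged."""
    profile = make_flex_profile(n_residues=12, base_amplitude=0.3, loop_regions=())
    plain = generate_backbone_ensemble(profile, 1000, seed=21, rigid_body=False)
    moved = generate_backbone_ensemble(profile, 1000, seed=21, rigid_body=True)
    avg_plain, _ = iterative_average(plain)
    avg_moved, _ = iterative_average(moved)
    rot, trans, rmsd = kabsch_superpose(avg_moved.coords, avg_plain.coords)
    assert rmsd < 0.02


def test_rmsf_static_trajectory_is_zero():
    traj = _static_traj()
    avg, _ = iterative_average(traj)
    assert np.allclose(rmsf(traj, avg), 0.0, atol=1e-12)


def test_rmsf_matches_brute_force_two_pass():
    profile = make_flex_profile(n_residues=8, base_amplitude=0.4, loop_regions=())
    traj = generate_backbone_ensemble(profile, 10, seed=33)
    avg, _ = iterative_average(traj)
    got = rmsf(traj, avg)
    acc = np.zeros(len(traj.atoms))
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.coords[f], avg.coords)
        acc += ((apply_transform(traj.coords[f], rot, trans) - avg.coords) ** 2).sum(axis=1)
    oracle = np.sqrt(acc / traj.n_frames)
    assert np.allclose(got, oracle, atol=1e-12)


def test_rmsf_invariant_under_global_rigid_transform():
    profile = make_flex_profile(n_residues=10, base_amplitude=0.5, loop_regions=())
    traj = generate_backbone_ensemble(profile, 200, seed=44)
    avg, _ = iterative_average(traj)
    base = rmsf(traj, avg)
    rot = Rotation.from_euler("xyz", [10, 250, 33], degrees=True).as_matrix()
    moved = Trajectory(
        atoms=traj.atoms, coords=traj.coords @ rot.T + np.array([5.0, -8.0, 2.0])
    )
    assert np.allclose(rmsf(moved, avg), base, atol=1e-9)


def test_rmsf_of_concatenated_copies_is_unchanged():
    profile = make_flex_profile(n_residues=6, base_amplitude=0.3, loop_regions=())
    traj = generate_backbone_ensemble(profile, 100, seed=5)
    avg, _ = iterative_average(traj)
    doubled = Trajectory(
        atoms=traj.atoms, coords=np.concatenate([traj.coords, traj.coords])
    )
    assert np.allclose(rmsf(doubled, avg), rmsf(traj, avg), atol=1e-12)


def test_rmsf_equilibration_discard_drops_leading_sixth():
    """First sixth of frames (the 2 ns equilibration analog) is excluded."""
    profile = make_flex_profile(n_residues=6, base_amplitude=0.1, loop_regions=())
    traj = generate_backbone_ensemble(profile, 600, seed=6)
    coords = traj.coords.copy()
    coords[:100] += 50.0  # corrupt exactly the discarded sixth uniformly
    corrupted = Trajectory(atoms=traj.atoms, coords=coords)
    avg, _ = iterative_average(
        Trajectory(atoms=traj.atoms, coords=coords[100:])
    )
    with_discard = rmsf(corrupted, avg, discard_fraction=1.0 / 6.0)
    clean = rmsf(Trajectory(atoms=traj.atoms, coords=coords[100:]), avg)
    assert np.allclose(with_discard, clean, atol=1e-12)


def test_rmsf_rejects_empty_mask():
    traj = _static_traj()
    avg, _ = iterative_average(traj)
    with pytest.raises(ValueError):
        rmsf(traj, avg, mask=np.zeros(len(traj.atoms), dtype=bool))


# --- loop reports ---


def test_loop_report_percent_change_arithmetic():
    atoms = make_bead_atoms(10)
    region = LoopRegion("loop", "A", 3, 5)
    wt = np.full(len(atoms), 1.0)
    mut = np.full(len(atoms), 1.0)
    mut[atoms["resid"].isin([3, 4, 5])] = 0.83
    report = loop_report({"wt": wt, "mut": mut}, atoms, [region], "wt")
    assert report.percent_change("mut") == pytest.approx(-17.0)
    assert report.percent_change("wt") == pytest.approx(0.0)


def test_loop_report_averages_replicates_before_ratio():
    atoms = make_bead_atoms(6)
    region = LoopRegion("loop", "A", 1, 6)
    wt = [np.full(len(atoms), 1.0), np.full(len(atoms), 1.0)]
    mut = [np.full(len(atoms), 1.2), np.full(len(atoms), 1.5)]
    report = loop_report({"wt": wt, "mut": mut}, atoms, [region], "wt")
    assert report.percent_change("mut") == pytest.approx(35.0)
    assert report.n_replicates["mut"] == 2


def test_loop_report_rejects_out_of_range_region():
    atoms = make_bead_atoms(5)
    with pytest.raises(ValueError):
        loop_report(
            {"wt": np.ones(len(atoms))},
            atoms,
            [LoopRegion("far", "A", 40, 45)],
            "wt",
        )
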