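"""Superposition, RMSF, normalization, selections and proximity."""

import numpy as np
import pytest

from flavotune.flexibility import (
    RMSFProfile,
    normalize,
    residues_within,
    rmsf,
    select_above_average,
    superpose_to_mean,
    write_bfactor_pdb,
)
from flavotune.structures_io import Trajectory, read_pdb, write_pdb
from flavotune.synthetic import (
    GeneratorConfig,
    make_mini_protein,
    make_residue_shell,
    make_toy_flavin,
    make_trajectory,
)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def test_pure_rigid_motion_gives_zero_rmsf(rng):
    topo = make_mini_protein(8)
    base = topo.positions
    frames = [base @ _random_rotation(rng).T + rng.uniform(-3, 3, 3) for _ in range(20)]
    traj = Trajectory(topology=topo, frames=frames, times=list(range(1, 21)))
    profile = rmsf(superpose_to_mean(traj))
    assert max(profile.values.values()) < 1e-6


def test_identical_frames_unchanged_by_superposition():
    topo = make_mini_protein(5)
    frames = [topo.positions.copy() for _ in range(3)]
    traj = Trajectory(topology=topo, frames=frames, times=[1.0, 2.0, 3.0])
    aligned = superpose_to_mean(traj)
    for f in aligned.frames:
        np.testing.assert_allclose(f, topo.positions, atol=1e-9)


def test_rigid_jitter_does_not_change_rmsf(rng):
    """RMSF after removing random rigid motion matches the noise-only RMSF."""
    noise_only = make_trajectory(
        GeneratorConfig(seed=11, n_residues=12, frame_count=1500, per_residue_sigma=0.3)
    )
    frames = [
        f @ _random_rotation(rng).T + rng.uniform(-2, 2, 3) for f in noise_only.frames
    ]
    with_rigid = Trajectory(
        topology=noise_only.topology, frames=frames, times=list(noise_only.times)
    )
    ref = rmsf(superpose_to_mean(noise_only))
    got = rmsf(superpose_to_mean(with_rigid))
    for res in ref.values:
        assert got.values[res] == pytest.approx(ref.values[res], rel=0.02)


def test_static_trajectory_gives_zero_rmsf():
    traj = make_trajectory(GeneratorConfig(seed=0, n_residues=4, frame_count=10,
                                           per_residue_sigma=1e-12))
    profile = rmsf(traj)
    assert max(profile.values.values()) < 1e-9


def test_sigma_recovery_at_500_frames():
    """Per-axis σ = 0.3 Å appears as RMSF ≈ σ√3 within 15% at 500 frames."""
    traj = make_trajectory(
        GeneratorConfig(seed=2, n_residues=50, frame_count=500, per_residue_sigma=0.3)
    )
    profile = rmsf(superpose_to_mean(traj))
    expected = 0.3 * np.sqrt(3)
    vals = np.array(list(profile.values.values()))
    assert np.abs(vals / expected - 1).max() < 0.15


def test_rmsf_ratio_recovers_sigma_ratio_prealigned():
    """σ = 0.2 vs 0.6 Å gives an RMSF ratio of 3 (pre-aligned frames)."""
    sig = {1: 0.2, 2: 0.6}
    traj = make_trajectory(
        GeneratorConfig(seed=4, n_residues=2, frame_count=12000, per_residue_sigma=sig)
    )
    profile = rmsf(traj)  # generator frames share one frame already
    ratio = profile.values[2] / profile.values[1]
    assert ratio == pytest.approx(3.0, rel=0.05)


def test_degenerate_collinear_selection_errors():
    topo = make_mini_protein(4)
    line = np.zeros((topo.n_atoms, 3))
    line[:, 0] = np.arange(topo.n_atoms)
    traj = Trajectory(topology=topo, frames=[line, line + 0.1], times=[1.0, 2.0])
    with pytest.raises(ValueError, match="degenerate"):
        superpose_to_mean(traj, selection=np.arange(topo.n_atoms))


def test_normalize_affine_map():
    prof = RMSFProfile(values={1: 0.32, 2: 0.82, 3: 1.32})
    norm = normalize(prof)
    assert norm.normalized == pytest.approx({1: 0.0, 2: 0.5, 3: 1.0})
    assert not norm.degenerate


def test_normalize_constant_profile_flagged():
    norm = normalize(RMSFProfile(values={1: 0.5, 2: 0.5}))
    assert norm.normalized == {1: 0.0, 2: 0.0}
    assert norm.degenerate


def test_normalize_already_unit_range_unchanged():
    prof = RMSFProfile(values={1: 0.0, 2: 0.25, 3: 1.0})
    norm = normalize(prof)
    assert norm.normalized == pytest.approx(prof.values)


def test_select_above_average_strict():
    prof = normalize(RMSFProfile(values={1: 0.0, 2: 0.5, 3: 1.0}))
    assert select_above_average(prof) == [3]  # mean 0.5, strict inequality


def test_select_above_average_constant_empty():
    prof = normalize(RMSFProfile(values={1: 0.4, 2: 0.4}))
    assert select_above_average(prof) == []


def test_select_above_average_single_outlier():
    prof = normalize(RMSFProfile(values={1: 0.2, 2: 0.2, 3: 0.2, 4: 0.9}))
    assert select_above_average(prof) == [4]


def test_residue_far_away_excluded_and_boundary_included():
    chrom = make_toy_flavin()
    far = make_residue_shell([10.0], chrom)
    assert residues_within(far, chrom, cutoff=4.0) == ([], 0)
    near = make_residue_shell([3.9], chrom)
    ids, count = residues_within(near, chrom, cutoff=4.0)
    assert ids == [1] and count == 1


def test_residue_shell_matches_brute_force(rng):
    chrom = make_toy_flavin()
    distances = list(np.linspace(2.0, 8.0, 20))
    shell = make_residue_shell(distances, chrom, seed=5)
    ids, count = residues_within(shell, chrom, cutoff=4.0)
    chrom_heavy = chrom.positions[chrom.heavy_indices()]
    expected = set()
    for a in shell.atoms:  # exhaustive all-pairs distance check
        if not a.is_heavy:
            continue
        if min(np.linalg.norm(chrom_heavy - a.position, axis=1)) <= 4.0:
            expected.add(a.residue_id)
    assert set(ids) == expected
    assert count == len(expected)


def test_proximity_monotone_in_cutoff():
    chrom = make_toy_flavin()
    shell = make_residue_shell(list(np.linspace(2.0, 8.0, 20)), chrom, seed=6)
    prev: set[int] = set()
    for cutoff in (2.0, 3.0, 4.0, 6.0, 9.0):
        ids, _ = residues_within(shell, chrom, cutoff=cutoff)
        assert prev <= set(ids)
        prev = set(ids)


def test_bfactor_pdb_round_trip(tmp_path):
    topo = make_mini_protein(3)
    prof = normalize(RMSFProfile(values={1: 0.1, 2: 0.6, 3: 1.1}))
    p = tmp_path / "b.pdb"
    write_bfactor_pdb(topo, prof, p)
    # every atom of a residue carries the residue's value at 2 decimals
    for line in p.read_text().splitlines():
        if line.startswith("ATOM"):
            res = int(line[22:26])
            b = float(line[60:66])
            assert b == pytest.approx(prof.normalized[res], abs=0.01)


def test_bfactor_pdb_missing_residue_warns(tmp_path):
    topo = make_mini_protein(2)
    prof = RMSFProfile(values={1: 0.5}, normalized={1: 1.0})
    with pytest.warns(UserWarning, match="B=0.00"):
        write_bfactor_pdb(topo, prof, tmp_path / "m.pdb")


def test_rmsf_against_mdanalysis_oracle(tmp_path):
    """Cross-check per-residue Cα RMSF against MDAnalysis on the same frames."""
    MDAnalysis = pytest.importorskip("MDAnalysis")
    from MDAnalysis.analysis.rms import RMSF as MDARMSF

    traj = make_trajectory(
        GeneratorConfig(seed=9, n_residues=8, frame_count=400, per_residue_sigma=0.25)
    )
    p = tmp_path / "traj.pdb"
    write_pdb(traj.topology, p, frames=traj.frames)
    ours = rmsf(traj)  # frames already share one frame; no superposition
    u = MDAnalysis.Universe(str(p))
    ca = u.select_atoms("name CA")
    theirs = MDARMSF(ca).run().results.rmsf
    for (res, val), ref in zip(sorted(ours.values.items()), theirs):
        assert val == pytest.approx(ref, rel=0.01, abs=2e-3)
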