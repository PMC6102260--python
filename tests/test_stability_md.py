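"""Melt-curve Tm extraction and trajectory flexibility metrics."""

import numpy as np
import pytest

from conftest import random_rotation
from ublsurf import synth
from ublsurf.stability_md import (
    MeltCurve,
    frames_from_structure,
    group_distance,
    melt_tm,
    read_melt_csv,
    read_xyz_table,
    rmsd_cluster,
    rmsf,
    rmsf_profile,
)


class TestMeltTm:
    def test_noiseless_midpoint_within_one_grid_step(self):
        curve, truth = synth.make_melt(50.0, steepness=1.0, noise_sd=0.0, seed=0)
        result = melt_tm(curve)
        assert not result.boundary_flag
        assert abs(result.tm - truth["tm"]) <= curve.step

    def test_flat_signal_flagged_unreliable(self):
        t = np.arange(20, 95, 0.036)
        result = melt_tm(MeltCurve(t, np.ones_like(t)))
        assert result.boundary_flag
        assert result.tm is None

    def test_affine_signal_rescaling_leaves_tm_unchanged(self):
        curve, _ = synth.make_melt(61.0, steepness=1.5, noise_sd=0.005, seed=4)
        base = melt_tm(curve).tm
        scaled = MeltCurve(curve.temperature, 7.5 * curve.signal + 42.0)
        assert melt_tm(scaled).tm == pytest.approx(base, abs=1e-9)

    def test_replicates_mean_and_sd(self):
        curves = [synth.make_melt(55.0, 1.0, 0.01, seed=s)[0] for s in range(3)]
        result = melt_tm(curves)
        assert len(result.replicates) == 3
        assert result.mean == pytest.approx(55.0, abs=0.2)
        assert result.sd is not None and result.sd >= 0.0

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            MeltCurve(np.array([20.0, 21.0, 20.5]), np.zeros(3))

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            melt_tm(MeltCurve(np.arange(20, 21, 0.036),
                              np.zeros(len(np.arange(20, 21, 0.036)))),
                    smooth_window=25)

    def test_melt_csv_round_trip(self, tmp_path):
        curve, _ = synth.make_melt(48.0, seed=1)
        import pandas as pd

        pd.DataFrame({"temperature": curve.temperature, "signal": curve.signal}
                     ).to_csv(tmp_path / "m.csv", index=False)
        curves = read_melt_csv(tmp_path / "m.csv")
        assert len(curves) == 1
        assert melt_tm(curves[0]).tm == pytest.approx(48.0, abs=0.05)


class TestRmsf:
    def test_identical_frames_zero(self, rng):
        f0 = rng.normal(size=(9, 3))
        assert rmsf(np.repeat(f0[None], 5, axis=0)).max() == pytest.approx(0.0)

    def test_rigid_motion_only_gives_zero(self, rng):
        f0 = rng.normal(size=(9, 3)) * 3
        frames = np.array([
            f0 @ random_rotation(rng).T + rng.normal(size=3) * 8 for _ in range(15)
        ])
        assert rmsf(frames).max() < 1e-9

    def test_jittered_residue_recovers_sigma_sqrt3(self, helix10):
        structure, _ = helix10
        sigma = {i: 0.0 for i in range(1, 11)}
        sigma[6] = 0.4
        ens, _ = synth.make_ensemble(structure, sigma, 1000, seed=13)
        frames, labels = frames_from_structure(ens)
        fit = np.array([i for i, n in enumerate(labels) if n != 6])
        values = rmsf(frames, fit)
        expect = 0.4 * np.sqrt(3)
        assert values[labels.index(6)] == pytest.approx(expect, rel=0.05)

    def test_common_rigid_transform_invariance(self, rng):
        frames = rng.normal(size=(8, 6, 3))
        base = rmsf(frames)
        rot = random_rotation(rng)
        moved = frames @ rot.T + np.array([1.0, 2.0, 3.0])
        assert np.allclose(rmsf(moved), base, atol=1e-9)

    def test_profile_step_shape(self, helix10):
        """Core/tail sigma step (0.1 vs 1.0 A) shows up as a step in RMSF."""
        structure, _ = helix10
        ens, _ = synth.make_ensemble(structure, 0.1, 200,
                                     disordered_tail=(8, 10), tail_sigma=1.0,
                                     seed=14)
        profile = rmsf_profile(structure=ens, fit_range=(1, 7))
        core = np.mean([profile.per_residue[i] for i in range(2, 7)])
        tail = np.mean([profile.per_residue[i] for i in range(8, 11)])
        assert tail > 3 * core


class TestRmsdCluster:
    def test_all_identical_one_cluster(self, rng):
        f0 = rng.normal(size=(7, 3))
        result = rmsd_cluster(np.repeat(f0[None], 6, axis=0), cutoff=1.0)
        assert len(result.clusters) == 1
        assert result.clusters[0][1] == list(range(6))

    def test_two_separated_groups(self, helix10, strand20):
        helix, _ = helix10
        ha, _ = synth.make_ensemble(helix, 0.05, 4, seed=1)
        frames_a, _ = frames_from_structure(ha, atom_set=("N", "CA", "C"))
        strand, _ = synth.make_structure(10, "strand", seed=2)
        sa, _ = synth.make_ensemble(strand, 0.05, 3, seed=2)
        frames_b, _ = frames_from_structure(sa, atom_set=("N", "CA", "C"))
        frames = np.concatenate([frames_a, frames_b])
        result = rmsd_cluster(frames, cutoff=1.0)
        assert len(result.clusters) == 2
        assert result.clusters[0][1] == [0, 1, 2, 3]
        assert result.clusters[1][1] == [4, 5, 6]

    def test_every_member_within_cutoff_and_sizes_sorted(self, rng):
        frames = rng.normal(size=(25, 6, 3)) * 1.5
        cutoff = 2.0
        result = rmsd_cluster(frames, cutoff)
        from ublsurf.superpose import kabsch

        sizes = [len(m) for _, m in result.clusters]
        assert sizes == sorted(sizes, reverse=True)
        assigned = sorted(j for _, m in result.clusters for j in m)
        assert assigned == list(range(25))
        for center, members in result.clusters:
            for j in members:
                assert kabsch(frames[j], frames[center]).rmsd <= cutoff + 1e-9


class TestGroupDistance:
    def test_coincident_groups_zero(self, rng):
        frames = rng.normal(size=(4, 6, 3))
        series = group_distance(frames, [0, 1, 2], [0, 1, 2])
        assert np.allclose(series, 0.0)

    def test_three_four_five(self):
        frames = np.zeros((2, 2, 3))
        frames[:, 1] = [3.0, 4.0, 0.0]
        assert np.allclose(group_distance(frames, [1], [0]), 5.0)

    def test_rigid_transform_invariance(self, rng):
        frames = rng.normal(size=(5, 8, 3))
        base = group_distance(frames, [0, 1], [5, 6, 7])
        moved = np.array([
            f @ random_rotation(rng).T + rng.normal(size=3) for f in frames
        ])
        assert np.allclose(group_distance(moved, [0, 1], [5, 6, 7]), base,
                           atol=1e-9)

    def test_planted_tether_release_series(self, helix10):
        """A trajectory with scripted approach/release of a terminal group
        reproduces the planted distance series to numerical precision."""
        structure, _ = helix10
        frames, labels = frames_from_structure(
            synth.make_ensemble(structure, 0.0, 2, seed=1)[0])
        f0 = frames[0]
        idx_a = [i for i, n in enumerate(labels) if n <= 2]
        idx_b = [i for i, n in enumerate(labels) if n >= 5]
        base_a = f0[idx_a].mean(axis=0)
        base_b = f0[idx_b].mean(axis=0)
        direction = base_a - base_b
        direction /= np.linalg.norm(direction)
        planted = [0.0, 2.5, 5.0, 2.5, 0.0, 7.5]
        traj = []
        d0 = np.linalg.norm(base_a - base_b)
        for extra in planted:
            frame = f0.copy()
            frame[idx_a] += direction * extra
            traj.append(frame)
        series = group_distance(np.array(traj), idx_a, idx_b)
        assert np.allclose(series, np.array(planted) + d0, atol=1e-9)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_distance(rng.normal(size=(3, 4, 3)), [], [0])


def test_xyz_table_reader(tmp_path):
    path = tmp_path / "frames.csv"
    path.write_text("frame,x,y,z\n0,0,0,0\n0,1,0,0\n1,0,0,1\n1,1,0,1\n")
    frames = read_xyz_table(path)
    assert frames.shape == (2, 2, 3)
    assert frames[1, 0, 2] == 1.0
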