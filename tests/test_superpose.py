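"""Superposition: Kabsch optimality, pairwise/ensemble r.m.s.d., alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_rotation
from ublsurf import synth
from ublsurf.structio import Atom, Residue, Structure
from ublsurf.superpose import (
    ResidueCorrespondence,
    _monotone_match,
    apply_transform,
    ensemble_rmsd,
    kabsch,
    pairwise_rmsd,
    structure_align,
)


def identity_correspondence(n, start=1):
    return ResidueCorrespondence(pairs=[(i, i) for i in range(start, start + n)])


class TestKabsch:
    def test_identical_sets(self, rng):
        x = rng.normal(size=(8, 3))
        res = kabsch(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_translation_invariance(self, rng):
        x = rng.normal(size=(8, 3))
        res = kabsch(x, x + np.array([5.0, 0.0, 0.0]))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_input_validation(self, rng):
        x = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            kabsch(x, rng.normal(size=(6, 3)))
        with pytest.raises(ValueError):
            kabsch(x[:2], x[:2])

    def test_no_reflection(self, rng):
        x = rng.normal(size=(10, 3))
        y = x.copy()
        y[:, 0] *= -1  # mirrored cloud
        res = kabsch(x, y)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)
        assert res.rmsd > 0.0  # cannot be matched without a reflection

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_transform_invariance(self, seed):
        """kabsch rmsd is unchanged when either input is rigidly moved."""
        g = np.random.default_rng(seed)
        x = g.normal(size=(7, 3))
        y = g.normal(size=(7, 3))
        base = kabsch(x, y).rmsd
        rot = random_rotation(g)
        shift = g.normal(size=3) * 10
        assert kabsch(x @ rot.T + shift, y).rmsd == pytest.approx(base, abs=1e-9)
        assert kabsch(x, y @ rot.T + shift).rmsd == pytest.approx(base, abs=1e-9)


class TestPairwiseRmsd:
    def test_self_is_zero(self, helix10):
        structure, _ = helix10
        res = pairwise_rmsd(structure, structure, identity_correspondence(10))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_atoms == 40

    def test_symmetry(self, helix10, rng):
        structure, _ = helix10
        other, _ = synth.make_ensemble(structure, 0.5, 2, seed=3)
        single = Structure(id="j", models=[other.models[0]])
        ab = pairwise_rmsd(structure, single, identity_correspondence(10)).rmsd
        ba = pairwise_rmsd(single, structure, identity_correspondence(10)).rmsd
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_displaced_residue_matches_direct_formula(self, helix10):
        """One residue moved 1 A along x: rmsd equals sqrt(sum d^2 / N) after
        an independent brute-force superposition (scipy rotation fit)."""
        from scipy.spatial.transform import Rotation

        structure, _ = helix10
        moved = synth._copy_model(structure.models[0])
        for atom in moved["A"][4].atoms:
            atom.coords = atom.coords + np.array([1.0, 0.0, 0.0])
        other = Structure(id="moved", models=[moved])
        res = pairwise_rmsd(structure, other, identity_correspondence(10))

        xa = np.array([a.coords for r in structure.models[0]["A"] for a in r.atoms])
        xb = np.array([a.coords for r in moved["A"] for a in r.atoms])
        ac, bc = xa - xa.mean(0), xb - xb.mean(0)
        _, rssd = Rotation.align_vectors(ac, bc)
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(xa)), abs=1e-6)

    def test_too_few_pairs(self, helix10):
        structure, _ = helix10
        corr = ResidueCorrespondence(pairs=[(1, 1), (2, 2)])
        with pytest.raises(ValueError):
            pairwise_rmsd(structure, structure, corr)


class TestEnsembleRmsd:
    def test_identical_models_zero(self, helix10):
        structure, _ = helix10
        ens, _ = synth.make_ensemble(structure, 0.0, 5, seed=1)
        res = ensemble_rmsd(ens, (1, 10))
        assert res.mean == pytest.approx(0.0, abs=1e-9)
        assert res.sd == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_jitter_matches_simulation_oracle(self, helix10):
        """Isotropic jitter sigma=0.2 A/coordinate, 10 models: the ensemble
        mean r.m.s.d. must agree within 10% with a direct Monte-Carlo oracle
        built from raw displaced point clouds (no superposition machinery)."""
        structure, _ = helix10
        sigma, n_models = 0.2, 10
        ens, _ = synth.make_ensemble(structure, sigma, n_models, seed=7)
        res = ensemble_rmsd(ens, (1, 10))

        g = np.random.default_rng(99)
        base = np.array(
            [a.coords for r in structure.models[0]["A"] for a in r.atoms]
        )
        sims = []
        for _ in range(300):
            clouds = base + g.normal(scale=sigma, size=(n_models,) + base.shape)
            mean = clouds.mean(axis=0)
            sims.append(np.mean(np.sqrt(np.mean(
                np.sum((clouds - mean) ** 2, axis=2), axis=1))))
        oracle = float(np.mean(sims))
        assert res.mean == pytest.approx(oracle, rel=0.10)

    def test_single_model_rejected(self, helix10):
        structure, _ = helix10
        with pytest.raises(ValueError):
            ensemble_rmsd(structure, (1, 10))


class TestStructureAlign:
    def test_self_alignment_is_identity(self, helix10):
        structure, _ = helix10
        corr = structure_align(structure, structure)
        assert corr.matched() == [(i, i) for i in range(1, 11)]

    def test_insertion_left_unpaired(self):
        base, _ = synth.make_structure(15, "strand", seed=4)
        residues = []
        num = 0
        for i, r in enumerate(base.chain("A")):
            num += 1
            residues.append(Residue("A", num, r.res_name, [
                Atom(a.name, a.element, a.coords.copy()) for a in r.atoms]))
            if i == 6:  # 2-residue loop bump after residue 7
                for k in range(2):
                    num += 1
                    residues.append(Residue("A", num, "GLY", [
                        Atom(a.name, a.element, a.coords + [0, 6 + 2 * k, 3])
                        for a in r.atoms]))
        other = Structure(id="ins", models=[{"A": residues}])
        corr = structure_align(base, other)
        mapping = corr.mapping()
        assert mapping[7] == 7
        assert mapping[8] == 10  # numbering shifts past the insertion
        unpaired_b = {b for a, b in corr.pairs if a is None}
        assert unpaired_b == {8, 9}

    def test_idempotent(self, strand20):
        structure, _ = strand20
        jit, _ = synth.make_ensemble(structure, 0.3, 2, seed=8)
        other = Structure(id="j", models=[jit.models[0]])
        corr = structure_align(structure, other)
        again = structure_align(structure, other, seed_alignment=corr)
        assert again.pairs == corr.pairs

    def test_monotone_match_equals_exhaustive_oracle(self):
        """DP pairing == exhaustive order-preserving minimum-distance search."""

        def exhaustive(ca_a, ca_b, cutoff):
            best = (-1, 0.0, [])

            def rec(i, j, pairs, total):
                nonlocal best
                key = (len(pairs), -total)
                if key > (best[0], best[1]):
                    best = (len(pairs), -total, pairs[:])
                if i >= len(ca_a) or j >= len(ca_b):
                    return
                d = np.linalg.norm(ca_a[i] - ca_b[j])
                if d <= cutoff:
                    rec(i + 1, j + 1, pairs + [(i, j)], total + d)
                rec(i + 1, j, pairs, total)
                rec(i, j + 1, pairs, total)

            rec(0, 0, [], 0.0)
            return best[2]

        for seed in range(5):
            g = np.random.default_rng(seed)
            ca_a = g.normal(size=(8, 3)) * 3
            ca_b = ca_a[: 7] + g.normal(size=(7, 3)) * 0.8
            assert _monotone_match(ca_a, ca_b, 2.5) == exhaustive(ca_a, ca_b, 2.5)


def test_correspondence_tsv_round_trip(tmp_path):
    corr = ResidueCorrespondence(pairs=[(1, 4), (2, None), (None, 5), (3, 6)],
                                 method="structure")
    path = tmp_path / "corr.tsv"
    corr.write_tsv(path)
    back = ResidueCorrespondence.read_tsv(path)
    assert back.pairs == corr.pairs
    assert back.method == "structure"
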