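"""Model validity rules, real-space scaling and canonical forms."""

import numpy as np
import pytest

import latticefit as lf


def brute_force_valid(m):
    """Independent validity check: direct pairwise/pointwise constraint test."""
    N = {tuple(v) for v in m.lattice.neighbors}
    bb = m.backbone.tolist()
    for a, b in zip(bb, bb[1:]):
        if tuple(np.subtract(b, a)) not in N:
            return False
    nodes = [tuple(p) for p in bb]
    if m.side_chains is not None:
        sc = m.side_chains.tolist()
        for a, s in zip(bb, sc):
            if tuple(np.subtract(a, s)) not in N:
                return False
        nodes += [tuple(p) for p in sc]
    return len(set(nodes)) == len(nodes)


class TestValidate:
    def test_collision_reported_with_indices(self):
        lat = lf.make_lattice("CUB")
        m = lf.LatticeModel(np.array([[0, 0, 0], [1, 0, 0], [0, 0, 0]]), None, lat)
        rep = m.validate()
        assert not rep.ok and rep.kind == "collision" and rep.indices == (1, 3)

    def test_backbone_break_reported(self):
        lat = lf.make_lattice("CUB")
        rep = lf.LatticeModel(np.array([[0, 0, 0], [2, 0, 0]]), None, lat).validate()
        assert not rep.ok and rep.kind == "backbone-break" and rep.indices == (1,)

    def test_side_chain_break_reported(self):
        lat = lf.make_lattice("CUB")
        rep = lf.LatticeModel(np.array([[0, 0, 0]]), np.array([[0, 2, 0]]), lat).validate()
        assert not rep.ok and rep.kind == "side-chain-break"

    def test_single_residue_with_adjacent_side_chain_valid(self):
        lat = lf.make_lattice("FCC")
        m = lf.LatticeModel(np.array([[0, 0, 0]]), np.array([[1, 1, 0]]), lat)
        assert m.validate().ok

    @pytest.mark.parametrize("mode", [lf.BACKBONE, lf.SIDE_CHAIN])
    def test_agrees_with_brute_force_on_random_instances(self, lattice, mode):
        rng = np.random.default_rng(42)
        for seed in range(8):
            m = lf.random_structure(lf.FixtureSpec(lattice.name, 10, mode, seed=seed), lattice)
            assert m.validate().ok and brute_force_valid(m)
            # corrupt one node and re-compare verdicts
            bb = m.backbone.copy()
            bb[rng.integers(len(bb))] += rng.integers(-2, 3, 3)
            corrupted = lf.LatticeModel(bb, m.side_chains, lattice)
            assert corrupted.validate().ok == brute_force_valid(corrupted)


class TestToReal:
    def test_cub_two_mer_spacing(self):
        lat = lf.make_lattice("CUB")
        real = lf.LatticeModel(np.array([[0, 0, 0], [1, 0, 0]]), None, lat).to_real(3.8)
        assert np.linalg.norm(real.backbone[1] - real.backbone[0]) == pytest.approx(3.8)

    def test_fcc_diagonal_normalised(self):
        lat = lf.make_lattice("FCC")
        real = lf.LatticeModel(np.array([[0, 0, 0], [1, 1, 0]]), None, lat).to_real(3.8)
        assert np.linalg.norm(real.backbone[1] - real.backbone[0]) == pytest.approx(3.8)

    def test_identity_at_native_step_length(self):
        lat = lf.make_lattice("CUB")
        m = lf.LatticeModel(np.array([[1, 2, 3], [1, 2, 4]]), None, lat)
        real = m.to_real(lat.step_length)
        assert np.array_equal(real.backbone, m.backbone.astype(float))

    @pytest.mark.parametrize("mode", [lf.BACKBONE, lf.SIDE_CHAIN])
    def test_all_bonds_have_bond_length(self, lattice, mode):
        m = lf.random_structure(lf.FixtureSpec(lattice.name, 12, mode, seed=3), lattice)
        real = m.to_real(3.8)
        d = np.linalg.norm(np.diff(real.backbone, axis=0), axis=1)
        assert np.allclose(d, 3.8, atol=1e-6)
        if mode == lf.SIDE_CHAIN:
            ds = np.linalg.norm(real.side_chains - real.backbone, axis=1)
            assert np.allclose(ds, 3.8, atol=1e-6)

    def test_invalid_model_rejected(self):
        lat = lf.make_lattice("CUB")
        with pytest.raises(lf.InvalidStructureError):
            lf.LatticeModel(np.array([[0, 0, 0], [3, 0, 0]]), None, lat).to_real()


class TestCanonicalForm:
    def test_mirror_image_same_form(self):
        lat = lf.make_lattice("FCC")
        m = lf.random_structure(lf.FixtureSpec("FCC", 7, lf.BACKBONE, seed=5), lat)
        mirror = lf.LatticeModel(m.backbone * np.array([-1, 1, 1]), None, lat)
        assert lf.canonical_form(m) == lf.canonical_form(mirror)

    def test_translation_invariant(self, lattice):
        m = lf.random_structure(lf.FixtureSpec(lattice.name, 6, lf.BACKBONE, seed=2), lattice)
        assert lf.canonical_form(m) == lf.canonical_form(m.translated((5, 5, 5)))

    def test_idempotent_and_constant_on_orbit(self, lattice):
        group = lf.point_group(lattice)
        m = lf.random_structure(lf.FixtureSpec(lattice.name, 6, lf.SIDE_CHAIN, seed=4), lattice)
        can = lf.canonical_form(m, group)
        assert lf.canonical_form(can, group) == can
        for g in group.as_array():
            assert lf.canonical_form(m.transformed(g), group) == can

    def test_sqr_length4_orbits_match_independent_grouping(self):
        """Orbit count of 3-step square-lattice walks vs pairwise congruence."""
        lat = lf.make_lattice("SQR")
        group = lf.point_group(lat).as_array()

        # brute force: enumerate all walks, group by explicit congruence test
        def walks(n):
            N = [tuple(v) for v in lat.neighbors]
            out = []

            def grow(path):
                if len(path) == n:
                    out.append(tuple(path))
                    return
                for v in N:
                    nxt = tuple(np.add(path[-1], v))
                    if nxt not in path:
                        grow(path + [nxt])

            grow([(0, 0, 0)])
            return out

        all_walks = walks(4)

        def congruent(a, b):
            a = np.array(a) - a[0]
            for g in group:
                img = np.array(b) @ g.T
                img = img - img[0]
                if np.array_equal(a, img):
                    return True
            return False

        classes = []
        for w in all_walks:
            if not any(congruent(w, rep) for rep in classes):
                classes.append(w)

        canon = {
            lf.canonical_form(
                lf.LatticeModel(np.array(w), None, lat)
            ).node_key()
            for w in all_walks
        }
        assert len(canon) == len(classes)
        # two genuinely different folds map to different forms
        straight = lf.LatticeModel(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]), None, lat)
        hook = lf.LatticeModel(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]), None, lat)
        assert lf.canonical_form(straight) != lf.canonical_form(hook)
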