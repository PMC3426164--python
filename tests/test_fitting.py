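"""Chain-growth fitting strategies: recovery, oracle agreement, determinism."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import latticefit as lf


def grid_rotations(r, span=np.pi / 2):
    angles = np.arange(r) * (span / r)
    return [
        Rotation.from_euler("xyz", (ax, ay, az)).as_matrix()
        for ax in angles for ay in angles for az in angles
    ]


class TestSelfFit:
    @pytest.mark.parametrize("mode", [lf.BACKBONE, lf.SIDE_CHAIN])
    def test_drmsd_recovers_on_lattice_target(self, lattice, mode):
        for seed in range(3):
            m = lf.random_structure(lf.FixtureSpec(lattice.name, 10, mode, seed=seed), lattice)
            target = lf.perturb(m, 0.0, seed=seed, rigid_motion=True)
            res = lf.fit_drmsd(target.fragments[0], lattice, n_keep=20, mode=mode)
            assert res.drmsd == pytest.approx(0.0, abs=1e-9)
            assert res.crmsd < 1e-6
            assert res.model.validate().ok

    @pytest.mark.parametrize("mode", [lf.BACKBONE, lf.SIDE_CHAIN])
    def test_crmsd_recovers_identity_orientation(self, lattice, mode):
        for seed in range(3):
            m = lf.random_structure(lf.FixtureSpec(lattice.name, 10, mode, seed=seed), lattice)
            target = lf.perturb(m, 0.0, seed=seed, rigid_motion=False)
            res = lf.fit_crmsd(target.fragments[0], lattice, n_keep=5, r=2, r_ref=0, mode=mode)
            assert res.crmsd < 1e-6
            assert res.model.validate().ok

    def test_greedy_beam_suffices_for_self_fit(self):
        lat = lf.make_lattice("FCC")
        m = lf.random_structure(lf.FixtureSpec("FCC", 15, lf.BACKBONE, seed=9), lat)
        target = lf.perturb(m, 0.0, seed=9, rigid_motion=True)
        res = lf.fit_drmsd(target.fragments[0], lat, n_keep=1)
        assert res.drmsd == pytest.approx(0.0, abs=1e-9)

    def test_mirror_image_target_same_drmsd(self):
        lat = lf.make_lattice("FCC")
        m = lf.random_structure(lf.FixtureSpec("FCC", 9, lf.BACKBONE, seed=1), lat)
        t = lf.perturb(m, 0.2, seed=2, rigid_motion=False)
        frag = t.fragments[0]
        mirrored = lf.Fragment(
            [lf.Residue(r.name, r.number, r.icode, -r.ca, None) for r in frag.residues],
            frag.chain_id,
        )
        a = lf.fit_drmsd(frag, lat, n_keep=50)
        b = lf.fit_drmsd(mirrored, lat, n_keep=50)
        assert a.drmsd == pytest.approx(b.drmsd, abs=1e-9)
        assert a.crmsd == pytest.approx(b.crmsd, abs=1e-6)


class TestOracleAgreement:
    @pytest.mark.parametrize("name,l", [("SQR", 4), ("CUB", 3), ("CUB", 4)])
    def test_drmsd_beam_reaches_global_optimum(self, name, l):
        lat = lf.make_lattice(name)
        for seed, base in enumerate(lf.enumerate_structures(lat, l)):
            target = lf.perturb(base, 0.5, seed=seed)
            frag = target.fragments[0]
            _, opt = lf.exhaustive_oracle(frag, lat, objective="drmsd")
            res = lf.fit_drmsd(frag, lat, n_keep=100_000)
            assert res.drmsd == pytest.approx(opt, abs=1e-9)

    def test_crmsd_screen_matches_enumeration(self):
        """2-residue backbone: beam of width 1 must find the grid optimum."""
        lat = lf.make_lattice("CUB")
        rng = np.random.default_rng(3)
        pts = np.array([[0.0, 0.0, 0.0], rng.normal(0, 3, 3)])
        frag = lf.Fragment([lf.Residue("ALA", i + 1, "", p, None) for i, p in enumerate(pts)])
        rots = grid_rotations(3)
        _, opt = lf.exhaustive_oracle(frag, lat, objective="crmsd", rotations=rots)
        res = lf.fit_crmsd(frag, lat, n_keep=1, r=3, r_ref=0)
        assert res.params["screen_crmsd"] == pytest.approx(opt, abs=1e-9)

    def test_crmsd_oracle_is_lower_bound_for_screen(self):
        lat = lf.make_lattice("CUB")
        m = lf.random_structure(lf.FixtureSpec("CUB", 4, lf.BACKBONE, seed=4), lat)
        frag = lf.perturb(m, 0.4, seed=5, rigid_motion=False).fragments[0]
        rots = grid_rotations(2)
        _, opt = lf.exhaustive_oracle(frag, lat, objective="crmsd", rotations=rots)
        res = lf.fit_crmsd(frag, lat, n_keep=10_000, r=2, r_ref=0)
        assert res.params["screen_crmsd"] == pytest.approx(opt, abs=1e-9)


class TestBeamBehaviour:
    def test_final_drmsd_monotone_in_beam_width(self):
        for seed in range(5):
            m, target = lf.make_target(lf.FixtureSpec("CUB", 10, lf.BACKBONE, seed=seed, sigma=0.4))
            frag = target.fragments[0]
            scores = [lf.fit_drmsd(frag, m.lattice, n_keep=k).drmsd for k in (1, 10, 100)]
            assert all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_deterministic_result(self):
        m, target = lf.make_target(lf.FixtureSpec("FCC", 10, lf.SIDE_CHAIN, seed=6, sigma=0.5))
        frag = target.fragments[0]
        a = lf.fit_drmsd(frag, m.lattice, n_keep=30, mode=lf.SIDE_CHAIN)
        b = lf.fit_drmsd(frag, m.lattice, n_keep=30, mode=lf.SIDE_CHAIN)
        assert a.model == b.model and a.drmsd == b.drmsd and a.crmsd == b.crmsd

    def test_reported_scores_match_metric_recomputation(self):
        """The additive accumulator must equal a from-scratch evaluation."""
        m, target = lf.make_target(lf.FixtureSpec("FCC", 12, lf.SIDE_CHAIN, seed=7, sigma=0.6))
        frag = target.fragments[0]
        res = lf.fit_drmsd(frag, m.lattice, n_keep=40, mode=lf.SIDE_CHAIN)
        pts = frag.points(lf.SIDE_CHAIN)
        assert res.drmsd == pytest.approx(
            lf.drmsd(pts, res.model.to_real().interleaved()), abs=1e-9
        )
        assert res.crmsd == pytest.approx(
            lf.crmsd(pts, res.superposed.interleaved()), abs=1e-9
        )

    def test_drmsd_invariant_to_target_pose(self):
        lat = lf.make_lattice("CUB")
        m = lf.random_structure(lf.FixtureSpec("CUB", 8, lf.BACKBONE, seed=8), lat)
        base = lf.perturb(m, 0.3, seed=1, rigid_motion=False)
        ref = lf.fit_drmsd(base.fragments[0], lat, n_keep=30).drmsd
        pts = base.fragments[0].points(lf.BACKBONE)
        rng = np.random.default_rng(10)
        for _ in range(10):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(0, 8, 3)
            moved = pts @ R.T + t
            frag = lf.Fragment([lf.Residue("ALA", i + 1, "", p, None)
                                for i, p in enumerate(moved)])
            assert lf.fit_drmsd(frag, lat, n_keep=30).drmsd == pytest.approx(ref, abs=1e-9)

    def test_crmsd_refinement_never_hurts(self):
        m, target = lf.make_target(lf.FixtureSpec("CUB", 6, lf.BACKBONE, seed=11, sigma=0.5))
        frag = target.fragments[0]
        coarse = lf.fit_crmsd(frag, m.lattice, n_keep=20, r=2, r_ref=0)
        refined = lf.fit_crmsd(frag, m.lattice, n_keep=20, r=2, r_ref=3)
        assert refined.params["screen_crmsd"] <= coarse.params["screen_crmsd"] + 1e-12

    def test_parameter_domain_errors(self):
        lat = lf.make_lattice("CUB")
        frag = lf.Fragment([lf.Residue("ALA", 1, "", np.zeros(3), None)])
        with pytest.raises(ValueError):
            lf.fit_drmsd(frag, lat, n_keep=0)
        with pytest.raises(ValueError):
            lf.fit_crmsd(frag, lat, r=0)


class TestWholeTarget:
    def test_two_fragments_fit_independently(self):
        m, target = lf.make_target(
            lf.FixtureSpec("FCC", 12, lf.BACKBONE, seed=12, sigma=0.3,
                           fragment_lengths=(7, 5))
        )
        report = lf.fit(target, "drmsd", lat=m.lattice, n_keep=20)
        assert len(report.results) == 2 and not report.failures
        # length-weighted overall cRMSD
        tot_n = sum(len(r.fragment) for r in report.results)
        expect = np.sqrt(sum(len(r.fragment) * r.crmsd**2 for r in report.results) / tot_n)
        assert report.overall_crmsd == pytest.approx(expect)

    def test_single_fragment_equals_direct_call(self):
        m, target = lf.make_target(lf.FixtureSpec("CUB", 8, lf.BACKBONE, seed=13, sigma=0.2))
        report = lf.fit(target, "drmsd", lat=m.lattice, n_keep=15)
        direct = lf.fit_drmsd(target.fragments[0], m.lattice, n_keep=15)
        assert report.results[0].model == direct.model
        assert report.overall_drmsd == pytest.approx(direct.drmsd)

    def test_failures_recorded_without_aborting(self):
        m, target = lf.make_target(
            lf.FixtureSpec("CUB", 8, lf.BACKBONE, seed=14, fragment_lengths=(4, 4))
        )
        # strip centroids from fragment 0 only, then request side-chain mode
        good = target.fragments[1]
        for r in good.residues:
            object.__setattr__(r, "centroid", r.ca.copy())
        report = lf.fit(target, "drmsd", lat=m.lattice, n_keep=10, mode=lf.SIDE_CHAIN)
        assert len(report.results) == 1 and len(report.failures) == 1

    def test_unknown_strategy(self):
        m, target = lf.make_target(lf.FixtureSpec("CUB", 5, lf.BACKBONE, seed=15))
        with pytest.raises(ValueError):
            lf.fit(target, "anneal", lat=m.lattice)
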