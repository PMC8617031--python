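"""Clash detection, catalytic distances, chemical/SASA screens, and
band-region classification."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bandscan import (AtomSet, ConformerEnsemble, ContactCriteria, LysineSite,
                      catalytic_distance, chemical_screen, classify_band,
                      detect_clash, sample_hinge, select, surface_exposure)
from bandscan.enm import FrameInfo
from bandscan.structure import Structure
from bandscan.synthetic import (HingeComplexSpec, _concat, make_hinge_complex,
                                make_ideal_chain)


def _cloud(coords, chain="A"):
    n = len(coords)
    return Structure(serial=np.arange(n), name=["C"] * n, element=["C"] * n,
                     chain_id=[chain] * n, res_name=["UNK"] * n,
                     res_seq=np.arange(1, n + 1), icode=[""] * n, coord=coords)


def _hinge_ensemble(s, loop, n_draws=150, seed=7, include_parent=True):
    ens = ConformerEnsemble(parent=s)
    if include_parent:
        ens.append(s.coord.copy(), FrameInfo(stage="parent"))
    for conf, prov in sample_hinge(s, loop, n_draws=n_draws, seed=seed):
        ens.append(conf.coord, FrameInfo(stage="loop",
                                         draw_index=prov["draw_index"]))
    return ens


class TestDetectClash:
    def test_far_apart_counts_zero(self):
        s = _cloud(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        assert detect_clash(s, AtomSet(s, [0]), AtomSet(s, [1]), 2.5) == 0

    def test_coincident_copy_counts_every_atom(self):
        pts = np.random.default_rng(0).normal(size=(20, 3)) * 10
        s = _cloud(np.vstack([pts, pts]))
        a = AtomSet(s, np.arange(20))
        b = AtomSet(s, np.arange(20, 40))
        assert detect_clash(s, a, b, 2.5) >= 20  # each atom at least its copy

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(4)
        for trial in range(3):
            pa = rng.uniform(0, 20, size=(200, 3))
            pb = rng.uniform(0, 20, size=(200, 3))
            s = _cloud(np.vstack([pa, pb]))
            a = AtomSet(s, np.arange(200))
            b = AtomSet(s, np.arange(200, 400))
            cutoff = 2.5
            brute = int(np.sum(np.linalg.norm(
                pa[:, None] - pb[None], axis=-1) < cutoff))
            assert detect_clash(s, a, b, cutoff) == brute

    def test_overlapping_sets_rejected(self):
        s = _cloud(np.zeros((3, 3)) + np.arange(3)[:, None])
        with pytest.raises(ValueError, match="disjoint"):
            detect_clash(s, AtomSet(s, [0, 1]), AtomSet(s, [1, 2]), 2.5)

    def test_excluded_seam_pairs_not_counted(self):
        s = _cloud(np.array([[0.0, 0, 0], [1.0, 0, 0], [9.0, 0, 0]]))
        a = AtomSet(s, [0])
        b = AtomSet(s, [1, 2])
        assert detect_clash(s, a, b, 2.5) == 1
        assert detect_clash(s, a, b, 2.5, exclude_pairs={(0, 1)}) == 0


class TestCatalyticDistance:
    def test_three_four_five(self):
        coord = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert catalytic_distance(coord, 0, 1) == pytest.approx(5.0)

    def test_coincident_atoms(self):
        coord = np.zeros((2, 3))
        assert catalytic_distance(coord, 0, 1) == 0.0

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(1)
        coord = rng.normal(size=(5, 3)) * 8
        d0 = catalytic_distance(coord, 0, 4)
        R = Rotation.random(random_state=3).as_matrix()
        assert catalytic_distance(coord @ R.T + 100.0, 0, 4) \
            == pytest.approx(d0, abs=1e-9)

    def test_missing_atom_rejected(self):
        with pytest.raises(KeyError):
            catalytic_distance(np.zeros((2, 3)), 0, 5)


class TestChemicalScreen:
    def test_isolated_lysine_has_no_partners(self):
        s = make_ideal_chain("AAKAA", "extended")
        site = LysineSite.from_structure(s, "A", 3)
        partners, excluded = chemical_screen(s, site)
        salt = [p for p in partners if p["kind"] == "salt_bridge"]
        assert not salt and not excluded

    def test_planted_carboxylate_excludes(self, hinge):
        s, truth = hinge
        site_info = next(x for x in truth["sites"] if x["intended"] == "excluded")
        site = LysineSite.from_structure(s, site_info["chain_id"],
                                         site_info["res_seq"])
        partners, excluded = chemical_screen(s, site)
        assert excluded
        bridge = [p for p in partners if p["kind"] == "salt_bridge"]
        assert bridge and bridge[0]["res_name"] == "GLU"
        assert bridge[0]["distance"] == pytest.approx(3.0, abs=0.05)

    def test_hbond_only_partner_does_not_exclude(self):
        lys = make_ideal_chain("K", "extended", chain_id="A")
        nz = lys.coord[lys.find_atom("A", 1, "NZ")]
        # a backbone-like oxygen acceptor 3.2 A away: H-bond range, not a
        # carboxylate salt bridge
        o = Structure(serial=[1], name=["O"], element=["O"], chain_id=["B"],
                      res_name=["ALA"], res_seq=[1], icode=[""],
                      coord=(nz + [0, 0, 3.2])[None])
        s = _concat(lys, o)
        site = LysineSite.from_structure(s, "A", 1)
        partners, excluded = chemical_screen(s, site)
        assert not excluded
        assert any(p["kind"] == "hbond" for p in partners)


class TestSurfaceExposure:
    def test_isolated_tripeptide_near_unity(self):
        s = make_ideal_chain("GKG", "extended")
        assert surface_exposure(s, "A", 2) == pytest.approx(1.0, abs=0.1)

    def test_buried_in_shell_is_low(self):
        s = make_ideal_chain("GKG", "extended")
        res_coords = s.coord[s.residue_indices("A", 2)]
        rng = np.random.default_rng(0)
        shell_pts = []
        for atom in res_coords:  # a tight cage 4 A off every residue atom
            u = rng.normal(size=(200, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            shell_pts.append(atom + 4.0 * u)
        shell = _cloud(np.vstack(shell_pts), chain="S")
        buried = _concat(s, shell)
        assert surface_exposure(buried, "A", 2) < 0.05

    def test_quadrature_converged(self):
        s = make_ideal_chain("GKG", "extended")
        a = surface_exposure(s, "A", 2, point_number=960)
        b = surface_exposure(s, "A", 2, point_number=1920)
        assert abs(a - b) / a < 0.02


class TestClassifyBand:
    def test_recovers_planted_labels(self, hinge, hinge_loop, hinge_parts):
        s, truth = hinge
        ens = _hinge_ensemble(s, hinge_loop)
        sites = [LysineSite.from_structure(s, x["chain_id"], x["res_seq"],
                                           x["label"]) for x in truth["sites"]]
        report = classify_band(ens, sites, hinge_parts["sg"],
                               moving=AtomSet(s, hinge_parts["moving"]),
                               poi=hinge_parts["poi"])
        verdicts = {r.site.label: r.verdict for r in report.results}
        assert verdicts == {x["label"]: x["intended"] for x in truth["sites"]}
        in_band = next(r for r in report.results if r.verdict == "in_band")
        assert in_band.min_distance <= 6.0
        assert in_band.n_contact_frames >= 1
        out = next(r for r in report.results if r.verdict == "out_of_band")
        assert out.min_distance > 10.0

    def test_threshold_boundary_is_inclusive(self):
        probe = _cloud(np.array([[0.0, 0, 0]]), chain="E")
        lys = make_ideal_chain("K", "extended", chain_id="P")
        nz_idx_local = lys.find_atom("P", 1, "NZ")
        shift = np.array([8.0, 0, 0]) - lys.coord[nz_idx_local]
        lys = lys.with_coord(lys.coord + shift)  # NZ exactly 8.0 from probe
        s = _concat(probe, lys)
        ens = ConformerEnsemble(parent=s, frames=[s.coord.copy()],
                                provenance=[FrameInfo(stage="static")])
        site = LysineSite.from_structure(s, "P", 1)
        report = classify_band(ens, [site], cys_sg=0)
        assert report.results[0].min_distance == pytest.approx(8.0, abs=1e-12)
        assert report.results[0].verdict == "in_band"

    def test_monotone_in_contact_threshold(self, hinge, hinge_loop, hinge_parts):
        s, truth = hinge
        ens = _hinge_ensemble(s, hinge_loop, n_draws=60)
        sites = [LysineSite.from_structure(s, x["chain_id"], x["res_seq"])
                 for x in truth["sites"]]
        previous_in_band: set[str] = set()
        for threshold in (4.0, 8.0, 16.0, 40.0):
            report = classify_band(
                ens, sites, hinge_parts["sg"],
                ContactCriteria(contact_threshold=threshold),
                moving=AtomSet(s, hinge_parts["moving"]), poi=hinge_parts["poi"])
            now = {r.site.label for r in report.results if r.verdict == "in_band"}
            assert previous_in_band <= now
            previous_in_band = now

    def test_verdicts_invariant_under_rigid_motion(self, hinge, hinge_loop,
                                                   hinge_parts):
        s, truth = hinge
        ens = _hinge_ensemble(s, hinge_loop, n_draws=40)
        sites = [LysineSite.from_structure(s, x["chain_id"], x["res_seq"])
                 for x in truth["sites"]]
        base = classify_band(ens, sites, hinge_parts["sg"],
                             moving=AtomSet(s, hinge_parts["moving"]),
                             poi=hinge_parts["poi"])
        R = Rotation.random(random_state=9).as_matrix()
        t = np.array([50.0, -20.0, 5.0])
        s2 = s.with_coord(s.coord @ R.T + t)
        ens2 = ConformerEnsemble(
            parent=s2, frames=[f @ R.T + t for f in ens.frames],
            provenance=ens.provenance)
        moved = classify_band(ens2, sites, hinge_parts["sg"],
                              moving=AtomSet(s2, hinge_parts["moving"]),
                              poi=select(s2, "chain P"))
        for r0, r1 in zip(base.results, moved.results):
            assert r0.verdict == r1.verdict
            assert r0.min_distance == pytest.approx(r1.min_distance, abs=1e-9)

    def test_all_frames_clashing_reports_no_survivors(self, hinge, hinge_parts):
        s, truth = hinge
        # drive the whole moving group into the target chain: every frame clashes
        target_atom = s.coord[hinge_parts["poi"].indices[0]]
        coord = s.coord.copy()
        coord[hinge_parts["moving"]] = target_atom + 0.1 * (
            coord[hinge_parts["moving"]] - coord[hinge_parts["moving"]].mean(axis=0))
        crashed = s.with_coord(coord)
        ens = ConformerEnsemble(parent=crashed, frames=[coord.copy()],
                                provenance=[FrameInfo(stage="crashed")])
        sites = [LysineSite.from_structure(s, x["chain_id"], x["res_seq"])
                 for x in truth["sites"] if x["intended"] != "excluded"]
        report = classify_band(ens, sites, hinge_parts["sg"],
                               moving=AtomSet(crashed, hinge_parts["moving"]),
                               poi=select(crashed, "chain P"))
        assert report.metadata["n_surviving"] == 0
        assert all(r.verdict == "out_of_band" for r in report.results)

    def test_empty_ensemble_rejected(self, hinge):
        s, _ = hinge
        with pytest.raises(ValueError, match="empty"):
            classify_band(ConformerEnsemble(parent=s), [], 0)
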