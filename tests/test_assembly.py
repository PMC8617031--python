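"""Rigid superposition, grafting, and homolog RMSD."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bandscan import (AtomSet, RigidTransform, graft_subunit, homolog_rmsd,
                      kabsch_fit, select)
from bandscan.assembly import AtomPairing, _kabsch
from bandscan.synthetic import make_ideal_chain

rng = np.random.default_rng(42)


def _atomset(coords):
    """Wrap bare coordinates in a minimal Structure for fitting."""
    from bandscan.structure import Structure
    n = len(coords)
    s = Structure(serial=np.arange(n), name=["CA"] * n, element=["C"] * n,
                  chain_id=["A"] * n, res_name=["ALA"] * n,
                  res_seq=np.arange(1, n + 1), icode=[""] * n, coord=coords)
    return AtomSet(s, np.arange(n))


class TestKabsch:
    def test_identity_fit(self):
        pts = rng.normal(size=(10, 3))
        transform, rmsd = kabsch_fit(_atomset(pts), _atomset(pts.copy()))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rotation_translation(self):
        pts = rng.normal(size=(12, 3)) * 5
        R = Rotation.from_rotvec(np.radians(30) * np.array([0, 0, 1])).as_matrix()
        moved = pts @ R.T + np.array([10.0, 0.0, 0.0])
        transform, rmsd = kabsch_fit(_atomset(moved), _atomset(pts))
        assert rmsd < 1e-6
        assert np.allclose(transform.rotation, R.T, atol=1e-8)
        # applying the fit inverts the original motion
        assert np.allclose(transform.apply(moved), pts, atol=1e-8)

    def test_rmsd_invariant_under_rigid_pretransform(self):
        a = rng.normal(size=(8, 3)) * 4
        b = a + rng.normal(size=(8, 3)) * 0.5
        _, rmsd0 = kabsch_fit(_atomset(a), _atomset(b))
        for _ in range(5):
            R = Rotation.random(random_state=7).as_matrix()
            a2 = a @ R.T + rng.normal(size=3) * 20
            _, rmsd1 = kabsch_fit(_atomset(a2), _atomset(b))
            assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_four_point_fit_matches_rotation_search_oracle(self):
        """Brute-force search over rotations (coarse quaternion sampling with
        local refinement) agrees with the analytic fit on a perturbed
        4-point set."""
        x = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [0, 0, 5]])
        y = x.copy()
        y[2] += np.array([1.0, 0, 0])  # 1 A perturbation
        _, rmsd = kabsch_fit(_atomset(x), _atomset(y))

        def search_rmsd(x, y):
            xc, yc = x - x.mean(0), y - y.mean(0)
            search = Rotation.random(20000, random_state=0)
            best, best_q = np.inf, None
            for stage, spread in [(search, None), *[(None, s) for s in
                                                    (0.3, 0.1, 0.03, 0.01, 0.003)]]:
                if stage is None:
                    qs = Rotation.from_quat(
                        best_q.as_quat() + np.random.default_rng(1).normal(
                            scale=spread, size=(4000, 4)))
                else:
                    qs = stage
                vals = np.sqrt(np.mean(np.sum(
                    (np.einsum("rij,nj->rni", qs.as_matrix(), xc) - yc) ** 2,
                    axis=-1), axis=-1))
                k = int(np.argmin(vals))
                if vals[k] < best:
                    best, best_q = vals[k], qs[k]
            return best

        assert rmsd == pytest.approx(search_rmsd(x, y), abs=1e-3)
        # independent library cross-check
        r, rssd = Rotation.align_vectors(y - y.mean(0), x - x.mean(0))
        assert rmsd == pytest.approx(rssd / np.sqrt(len(x)), abs=1e-9)

    def test_collinear_pairing_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_fit(_atomset(line), _atomset(line + 1.0))

    def test_rigid_transform_validates_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestGraft:
    def _two_body(self):
        helix = make_ideal_chain("A" * 8, "helix", chain_id="S")
        cargo = make_ideal_chain("A" * 5, "helix", chain_id="C")
        cargo = cargo.with_coord(cargo.coord + np.array([15.0, 0, 0]))
        from bandscan.synthetic import _concat
        return _concat(helix, cargo)

    def test_self_graft_is_identity_on_cargo(self):
        donor = self._two_body()
        out = graft_subunit(donor, select(donor, "chain S and name CA"),
                            donor, select(donor, "chain S and name CA"),
                            select(donor, "chain C"))
        grafted = out.coord[out.chain_id == "Z"]  # fresh ID after collision
        original = donor.coord[donor.chain_id == "C"]
        assert np.abs(grafted - original).max() < 1e-9

    def test_cargo_follows_known_rotation_and_stays_rigid(self):
        donor = self._two_body()
        R = Rotation.from_rotvec([0, 0, np.pi / 2]).as_matrix()
        acceptor = donor.subset(np.flatnonzero(donor.chain_id == "S"))
        acceptor = acceptor.with_coord(acceptor.coord @ R.T)
        cargo_sel = select(donor, "chain C")
        out = graft_subunit(donor, select(donor, "chain S and name CA"),
                            acceptor, select(acceptor, "name CA"), cargo_sel)
        landed = out.coord[out.chain_id == "C"]
        assert np.abs(landed - cargo_sel.coord @ R.T).max() < 1e-8
        d0 = np.linalg.norm(cargo_sel.coord[:, None] - cargo_sel.coord[None], axis=-1)
        d1 = np.linalg.norm(landed[:, None] - landed[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-6

    def test_acceptor_atoms_never_move(self):
        donor = self._two_body()
        acceptor = donor.subset(np.flatnonzero(donor.chain_id == "S"))
        before = acceptor.coord.copy()
        out = graft_subunit(donor, select(donor, "chain S and name CA"),
                            acceptor, select(acceptor, "name CA"),
                            select(donor, "chain C"))
        assert np.array_equal(out.coord[:len(before)], before)

    def test_chain_collision_warns_and_renames(self):
        donor = self._two_body()
        with pytest.warns(UserWarning, match="collide"):
            out = graft_subunit(donor, select(donor, "chain S and name CA"),
                                donor, select(donor, "chain S and name CA"),
                                select(donor, "chain C"))
        assert "C" in donor.chains and set(out.chains) == {"S", "C", "Z"}


class TestHomologRmsd:
    def test_identical_chains_give_zero(self):
        a = make_ideal_chain("A" * 25, "helix")
        assert homolog_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_planted_segment_displacement(self):
        """A copy with one 5-residue segment moved 4 A: the duplicate-aligned
        RMSD must match an independent optimal-rotation oracle."""
        a = make_ideal_chain("A" * 30, "helix")
        ca_mask = a.name == "CA"
        coord = a.coord.copy()
        seg = ca_mask & (a.res_seq >= 10) & (a.res_seq <= 14)
        coord[(a.res_seq >= 10) & (a.res_seq <= 14)] += np.array([0, 0, 4.0])
        b = a.with_coord(coord)
        value = homolog_rmsd(a, b)
        x = a.coord[ca_mask]
        y = b.coord[ca_mask]
        _, rssd = Rotation.align_vectors(y - y.mean(0), x - x.mean(0))
        assert value == pytest.approx(rssd / np.sqrt(ca_mask.sum()), abs=1e-6)
        # never exceeds the no-refit closed form sqrt(sum d^2 / n)
        assert value <= np.sqrt(5 * 16.0 / ca_mask.sum()) + 1e-9

    def test_symmetry(self):
        a = make_ideal_chain("A" * 30, "helix")
        coord = a.coord.copy()
        coord[(a.res_seq >= 5) & (a.res_seq <= 9)] += np.array([2.0, 1.0, 0])
        b = a.with_coord(coord)
        assert abs(homolog_rmsd(a, b) - homolog_rmsd(b, a)) < 0.1

    def test_too_few_matches_rejected(self):
        a = make_ideal_chain("A" * 5, "helix")
        with pytest.raises(ValueError, match="matched"):
            homolog_rmsd(a, a)


class TestAtomPairing:
    def test_by_name_pairs_on_residue_and_atom(self):
        a = make_ideal_chain("AKD", "extended", chain_id="A")
        b = make_ideal_chain("AKD", "helix", chain_id="B")
        pairing = AtomPairing.by_name(AtomSet(a, np.arange(len(a))),
                                      AtomSet(b, np.arange(len(b))))
        assert len(pairing.pairs) == len(a)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValueError):
            AtomPairing([(0, 0), (1, 1)])
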