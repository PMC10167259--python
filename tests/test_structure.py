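"""Structural correlation functions: RDF/CN, ADF, CDFs and SDF."""

import numpy as np
import pytest
from scipy import stats

from destraj import structure, synth
from destraj.structure import (RDFResult, adf, cdf_dist_angle, cdf_dist_dist,
                               first_minimum, rdf, sdf)
from destraj.trajio import Frame, SimulationBox, Trajectory, ValidationError

from conftest import make_point_topology, make_topology, single_frame_traj


class TestRDF:
    def test_ideal_gas_is_uncorrelated(self):
        """g(r) of a Poisson gas is 1 within 3σ per bin (binomial error
        bars from the expected bin counts)."""
        box = SimulationBox([20.0] * 3)
        traj = synth.gen_ideal_gas(500, box, 30, seed=14)
        idx = np.arange(500)
        res = rdf(traj, idx, idx, dr=0.5, r_max=8.0)
        sel = (res.r > 2.0) & (res.r < 8.0)
        shell = 4 * np.pi / 3 * (res.r_edges[1:] ** 3 - res.r_edges[:-1] ** 3)
        expected = res.rho * shell * 500 * 30
        # same-group counting sees each unordered pair twice -> factor 2
        sigma_g = np.sqrt(2.0 / expected)
        assert np.all(np.abs(res.g[sel] - 1.0) < 3 * sigma_g[sel])

    def test_fixed_pair_single_bin_and_cn(self, box20):
        top = make_point_topology(2)
        pos = np.array([[5.0, 5.0, 5.0], [8.0, 5.0, 5.0]])
        traj = single_frame_traj(pos, top, box20)
        res = rdf(traj, [0], [1], dr=0.1, r_max=6.0)
        nz = np.nonzero(res.g)[0]
        assert len(nz) == 1
        assert res.r_edges[nz[0]] <= 3.0 < res.r_edges[nz[0] + 1]
        assert res.cn_at(4.0) == pytest.approx(1.0, abs=1e-12)

    def test_cn_equals_brute_force_counting(self):
        """CN at randomly chosen bin edges ≡ direct neighbour counting to
        1e-9 over random configurations."""
        box = SimulationBox([12.0] * 3)
        traj = synth.gen_ideal_gas(30, box, 50, seed=15)
        idx_a = np.arange(10)
        idx_b = np.arange(10, 30)
        res = rdf(traj, idx_a, idx_b, dr=0.05, r_max=5.0)
        rng = np.random.default_rng(0)
        edges = rng.choice(res.r_edges[1:], size=20, replace=False)
        from destraj.trajio import distance_matrix
        for r in edges:
            count = 0.0
            for fr in traj.frames:
                d = distance_matrix(fr, idx_a, idx_b)
                count += np.sum(d < r)
            brute = count / (len(traj.frames) * len(idx_a))
            i = np.searchsorted(res.r_edges, r) - 1
            assert res.cn[i] == pytest.approx(brute, abs=1e-9)
            assert res.cn_at(r) == pytest.approx(brute, abs=1e-9)

    def test_cn_is_nondecreasing_and_g_nonnegative(self, toy_mixture):
        top = toy_mixture.topology
        res = rdf(toy_mixture, top.select(site_label="HA",
                                          molecule_type="CAP"),
                  top.select(site_label="CL"), dr=0.05, r_max=10.0)
        assert np.all(res.g >= 0)
        assert np.all(np.diff(res.cn) >= -1e-15)

    def test_r_max_beyond_half_box_rejected(self, box20):
        traj = synth.gen_ideal_gas(10, box20, 1, 0)
        with pytest.raises(ValidationError):
            rdf(traj, np.arange(5), np.arange(5, 10), r_max=11.0)

    def test_empty_group_rejected(self, box20):
        traj = synth.gen_ideal_gas(10, box20, 1, 0)
        with pytest.raises(ValidationError):
            rdf(traj, [], np.arange(10))

    def test_intramolecular_exclusion(self, box20):
        top = make_topology(["A", "B"], [0, 0])
        traj = single_frame_traj(np.array([[5.0, 5, 5], [7.0, 5, 5]]),
                                 top, box20)
        res = rdf(traj, [0], [1], dr=0.1, r_max=6.0)
        assert np.all(res.g == 0)
        res2 = rdf(traj, [0], [1], dr=0.1, r_max=6.0,
                   exclude_intramolecular=False)
        assert res2.g.max() > 0


class TestFirstMinimum:
    def test_analytic_double_gaussian(self):
        """g(r) = 1 + e^{−(r−2)²/0.02} − 0.5·e^{−(r−3)²/0.02} has its
        first post-peak minimum at r = 3."""
        dr = 0.05
        edges = np.arange(0.0, 5.0 + dr / 2, dr)
        r = 0.5 * (edges[1:] + edges[:-1])
        g = (1.0 + np.exp(-((r - 2.0) ** 2) / 0.02)
             - 0.5 * np.exp(-((r - 3.0) ** 2) / 0.02))
        res = RDFResult(r, g, np.zeros_like(r), edges, rho=0.1)
        rmin = first_minimum(res)
        assert rmin == pytest.approx(3.0, abs=dr)

    def test_ideal_gas_has_no_shell(self):
        box = SimulationBox([20.0] * 3)
        traj = synth.gen_ideal_gas(400, box, 20, seed=16)
        idx = np.arange(400)
        res = rdf(traj, idx, idx, dr=0.1, r_max=8.0)
        assert first_minimum(res) is None
        assert res.cn_at_first_min is None

    def test_planted_shell_in_toy_mixture(self, toy_mixture):
        """Planted 2 Å HA···Cl⁻ contacts with a clearance gap give a first
        minimum between the shell and the random background."""
        top = toy_mixture.topology
        res = rdf(toy_mixture, top.select(site_label="HA",
                                          molecule_type="CAP"),
                  top.select(site_label="CL"), dr=0.05, r_max=10.0)
        rmin = first_minimum(res)
        assert rmin is not None
        assert 2.0 < rmin < 4.0
        assert res.cn_at_first_min == pytest.approx(
            toy_mixture.meta["n_planted"] / 60, abs=1e-9)


class TestADF:
    def _triple_traj(self, angle_deg, box):
        top = make_point_topology(3)
        theta = np.radians(angle_deg)
        pos = np.array([
            [10.0 + 2.0, 10.0, 10.0],
            [10.0, 10.0, 10.0],
            [10.0 + 2.0 * np.cos(theta), 10.0 + 2.0 * np.sin(theta), 10.0],
        ])
        return single_frame_traj(pos, top, box)

    @pytest.mark.parametrize("angle", [90.0, 179.999])
    def test_fixed_angle_lands_in_its_bin(self, angle, box20):
        traj = self._triple_traj(angle, box20)
        res = adf(traj, [0], [1], [2], cutoff_ab=5.0, cutoff_bc=5.0)
        occupied = np.nonzero(res.counts)[0]
        assert len(occupied) == 1
        lo, hi = res.edges[occupied[0]], res.edges[occupied[0] + 1]
        assert lo <= angle < hi or angle == pytest.approx(hi, abs=1e-3)

    def test_normalized_to_unit_integral(self, toy_mixture):
        top = toy_mixture.topology
        res = adf(toy_mixture, top.select(site_label="OA"),
                  top.select(site_label="HA", molecule_type="CAP"),
                  top.select(site_label="CL"),
                  cutoff_ab=1.5, cutoff_bc=2.5)
        assert np.trapezoid(res.density, res.alpha) == pytest.approx(
            1.0, abs=1e-6)

    def test_isotropic_triples_flat_after_sin_correction(self):
        """c uniform on a sphere around the vertex: raw angle counts follow
        sin α, so the 1/sin-corrected density is flat (χ² p > 0.01)."""
        rng = np.random.default_rng(21)
        n = 100_000
        box = SimulationBox([40.0] * 3)
        c = rng.normal(size=(n, 3))
        c = 20.0 + 3.0 * c / np.linalg.norm(c, axis=1, keepdims=True)
        pos = np.vstack([[[25.0, 20.0, 20.0]], [[20.0, 20.0, 20.0]], c])
        top = make_point_topology(n + 2)
        traj = single_frame_traj(pos, top, box)
        res = adf(traj, [0], [1], np.arange(2, n + 2),
                  cutoff_ab=6.0, cutoff_bc=4.0, bin_width=10.0)
        expected = n * np.diff(-np.cos(np.radians(res.edges))) / 2.0
        chi2 = np.sum((res.counts - expected) ** 2 / expected)
        p = stats.chi2.sf(chi2, df=len(expected) - 1)
        assert p > 0.01

    def test_rotation_translation_invariance(self):
        """ADF of a compact (non-boundary-spanning) configuration is
        unchanged by a rigid rotation + translation of the frame."""
        from scipy.spatial.transform import Rotation
        box = SimulationBox([40.0] * 3)
        traj = _two_triples_frame(box)
        top = traj.topology
        args = (top.select(site_label="OA"),
                top.select(site_label="HA"),
                top.select(site_label="CL"))
        res1 = adf(traj, *args, cutoff_ab=1.5, cutoff_bc=4.0)
        R = Rotation.from_euler("xyz", [20, 35, -10], degrees=True)
        centre = box.lengths / 2
        pos = traj.frames[0].positions
        rot = (pos - centre) @ R.as_matrix().T + centre + [1.0, 0.5, -0.7]
        traj2 = Trajectory([Frame(0.0, box.wrap(rot), box)], top)
        res2 = adf(traj2, *args, cutoff_ab=1.5, cutoff_bc=4.0)
        np.testing.assert_allclose(res2.density, res1.density, atol=1e-9)


def _two_triples_frame(box):
    """Two D–H···A triples: (2.1 Å, 112°) and (3.1 Å, 161°), both off
    histogram bin edges."""
    def triple(origin, d, ang):
        theta = np.radians(ang)
        h = np.asarray(origin, float)
        a = h + [d, 0.0, 0.0]
        dd = h + [np.cos(theta), np.sin(theta), 0.0]
        return dd, h, a
    d1, h1, a1 = triple([10.0, 10.0, 10.0], 2.1, 112.0)
    d2, h2, a2 = triple([25.0, 25.0, 25.0], 3.1, 161.0)
    top = make_topology(["OA", "HA", "CL", "OA", "HA", "CL"],
                        [0, 0, 1, 2, 2, 3],
                        ["CAP", "CAP", "CL", "CAP", "CAP", "CL"])
    pos = np.array([d1, h1, a1, d2, h2, a2])
    return single_frame_traj(pos, top, box)


class TestCDFDistAngle:
    def test_two_planted_populations_two_cells(self):
        box = SimulationBox([40.0] * 3)
        traj = _two_triples_frame(box)
        top = traj.topology
        res = cdf_dist_angle(traj, "CAP", top.select(site_label="CL"),
                             dist_site="HA",
                             angle_sites=("OA", "HA", "partner"),
                             d_edges=np.arange(0.0, 6.05, 0.25),
                             a_edges=np.arange(0.0, 181.0, 10.0))
        occ = np.argwhere(res.counts > 0)
        # the far cross-pairs fall outside the distance range, so exactly
        # the two planted cells at (2.1 Å, 112°) and (3.1 Å, 161°) remain
        assert len(occ) == 2
        hits = 0
        for i, j in occ:
            for d, a in [(2.1, 112.0), (3.1, 161.0)]:
                if res.edges1[i] <= d < res.edges1[i + 1] and \
                   res.edges2[j] <= a < res.edges2[j + 1]:
                    hits += 1
        assert hits == 2
        assert res.values.max() == 1.0

    def test_marginal_over_angle_matches_distance_histogram(self,
                                                            toy_mixture):
        top = toy_mixture.topology
        d_edges = np.arange(0.0, 8.05, 0.2)
        a_edges = np.arange(0.0, 181.0, 5.0)
        res = cdf_dist_angle(toy_mixture, "CAP", top.select(site_label="CL"),
                             dist_site="HA",
                             angle_sites=("OA", "HA", "partner"),
                             d_edges=d_edges, a_edges=a_edges)
        # brute-force instance distances
        from destraj.trajio import minimum_image
        fr = toy_mixture.frames[0]
        ha = top.select(site_label="HA", molecule_type="CAP")
        cl = top.select(site_label="CL")
        d = np.linalg.norm(minimum_image(
            fr.positions[cl][None] - fr.positions[ha][:, None], fr.box),
            axis=-1)
        hist, _ = np.histogram(d.ravel(), bins=d_edges)
        np.testing.assert_allclose(res.counts.sum(axis=1), hist, atol=1e-9)


class TestCDFDistDist:
    def test_planted_two_distances_single_cell(self):
        box = SimulationBox([40.0] * 3)
        top = make_topology(["HA", "OA", "O", "C1"], [0, 0, 1, 1],
                            ["CAP", "CAP", "CH", "CH"])
        pos = np.array([[10.0, 10, 10], [11.0, 10, 10],
                        [12.0, 10, 10], [14.5, 10, 10]])
        traj = single_frame_traj(pos, top, box)
        res = cdf_dist_dist(traj, "CAP", "CH", ("HA", "O"), ("OA", "C1"),
                            np.arange(0.0, 8.1, 0.5), np.arange(0.0, 8.1, 0.5))
        occ = np.argwhere(res.counts > 0)
        assert len(occ) == 1
        i, j = occ[0]
        assert res.edges1[i] <= 2.0 < res.edges1[i + 1]
        assert res.edges2[j] <= 3.5 < res.edges2[j + 1]

    def test_swapping_specs_transposes(self, toy_mixture):
        edges = np.arange(0.0, 10.1, 0.5)
        res1 = cdf_dist_dist(toy_mixture, "CAP", "CH", ("HA", "O"),
                             ("OA", "C1"), edges, edges)
        res2 = cdf_dist_dist(toy_mixture, "CAP", "CH", ("OA", "C1"),
                             ("HA", "O"), edges, edges)
        np.testing.assert_array_equal(res2.counts, res1.counts.T)

    def test_independent_distances_factorize(self):
        """Distances drawn independently produce a product-form joint
        histogram (G-test p > 0.01)."""
        rng = np.random.default_rng(31)
        n = 500
        box = SimulationBox([200.0] * 3)
        frames = []
        top = make_topology(["HA", "OA", "O", "C1"], [0, 0, 1, 1],
                            ["CAP", "CAP", "CH", "CH"])
        for k in range(n):
            da, db = rng.uniform(1.0, 5.0, 2)
            ua, ub = rng.normal(size=(2, 3))
            ua /= np.linalg.norm(ua)
            ub /= np.linalg.norm(ub)
            ha = np.array([50.0, 50.0, 50.0])
            oa = np.array([150.0, 150.0, 150.0])
            pos = np.array([ha, oa, ha + da * ua, oa + db * ub])
            frames.append(Frame(float(k), pos, box))
        traj = Trajectory(frames, top)
        edges = np.array([0.0, 2.4, 3.7, 5.1])
        res = cdf_dist_dist(traj, "CAP", "CH", ("HA", "O"), ("OA", "C1"),
                            edges, edges)
        obs = res.counts
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        mask = obs > 0
        g_stat = 2.0 * np.sum(obs[mask] * np.log(obs[mask] / expected[mask]))
        dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
        assert stats.chi2.sf(g_stat, dof) > 0.01


class TestSDF:
    def _reference_frame(self, rng, n_refs, targets_local, box):
        """References at random poses with targets planted at fixed local
        coordinates; returns (traj, target indices)."""
        from scipy.spatial.transform import Rotation
        labels, mids, types, coords = [], [], [], []
        mol = 0
        anchors_local = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 0, 1.0]])
        for k in range(n_refs):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(10.0, box.lengths - 10.0)
            pts = anchors_local @ R.T + t
            coords.extend(pts)
            labels.extend(["C1", "O1", "O2"])
            mids.extend([mol] * 3)
            types.extend(["CAP"] * 3)
            mol += 1
            for loc in targets_local:
                coords.append(np.asarray(loc) @ R.T + t)
                labels.append("CL")
                mids.append(mol)
                types.append("CL")
                mol += 1
        top = make_topology(labels, mids, types)
        traj = single_frame_traj(np.array(coords), top, box)
        return traj, top.select(site_label="CL")

    def test_planted_local_position_concentrates(self):
        rng = np.random.default_rng(41)
        box = SimulationBox([60.0] * 3)
        traj, targets = self._reference_frame(rng, 40, [(2.3, 0.1, 0.2)], box)
        grid = sdf(traj, "CAP", ("C1", "O1", "O2"), targets,
                   voxel=0.5, extent=4.0)
        peak = np.unravel_index(np.argmax(grid.counts), grid.counts.shape)
        centres = grid.grid_centres
        assert centres[peak[0]] == pytest.approx(2.25, abs=1e-9)
        assert centres[peak[1]] == pytest.approx(0.25, abs=1e-9)
        assert centres[peak[2]] == pytest.approx(0.25, abs=1e-9)
        # every reference contributes its own planted target to the peak
        assert grid.counts[peak] >= 40

    def test_isotropic_shell_is_uniform(self):
        """Targets isotropic in a thick shell: voxels well inside the shell
        have comparable density (max/min < 2)."""
        rng = np.random.default_rng(43)
        n = 300_000
        box = SimulationBox([60.0] * 3)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = rng.uniform(2.5, 3.5, n)
        centre = box.lengths / 2
        coords = [centre, centre + [1.0, 0, 0], centre + [0, 0, 1.0]]
        labels = ["C1", "O1", "O2"]
        mids = [0, 0, 0]
        types = ["CAP", "CAP", "CAP"]
        coords.extend(centre + radii[:, None] * u)
        labels.extend(["CL"] * n)
        mids.extend(range(1, n + 1))
        types.extend(["CL"] * n)
        top = make_topology(labels, mids, types)
        traj = single_frame_traj(np.array(coords), top, box)
        grid = sdf(traj, "CAP", ("C1", "O1", "O2"),
                   top.select(site_label="CL"), voxel=0.5, extent=5.0)
        centres = grid.grid_centres
        xx, yy, zz = np.meshgrid(centres, centres, centres, indexing="ij")
        rr = np.sqrt(xx ** 2 + yy ** 2 + zz ** 2)
        shell = (rr > 2.9) & (rr < 3.1)
        vals = grid.density[shell]
        assert vals.min() > 0
        assert vals.max() / vals.min() < 2.0

    def test_rigid_motion_invariance(self):
        """Rotating + translating the whole frame leaves the SDF grid
        unchanged to 1e-9."""
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(44)
        box = SimulationBox([60.0] * 3)
        traj, targets = self._reference_frame(
            rng, 10, [(2.3, 0.1, 0.2), (-1.1, 1.6, 0.6)], box)
        grid1 = sdf(traj, "CAP", ("C1", "O1", "O2"), targets,
                    voxel=0.5, extent=4.0)
        R = Rotation.from_euler("zyx", [25, -40, 60], degrees=True)
        centre = box.lengths / 2
        pos = traj.frames[0].positions
        moved = (pos - centre) @ R.as_matrix().T + centre + [1.0, -2.0, 0.5]
        traj2 = Trajectory([Frame(0.0, box.wrap(moved), box)], traj.topology)
        grid2 = sdf(traj2, "CAP", ("C1", "O1", "O2"), targets,
                    voxel=0.5, extent=4.0)
        np.testing.assert_allclose(grid2.density, grid1.density, atol=1e-9)

    def test_collinear_anchors_skipped(self, box20):
        top = make_topology(["C1", "O1", "O2", "CL"], [0, 0, 0, 1],
                            ["CAP", "CAP", "CAP", "CL"])
        pos = np.array([[5.0, 5, 5], [6.0, 5, 5], [7.0, 5, 5],
                        [5.0, 7, 5]])
        traj = single_frame_traj(pos, top, box20)
        grid = sdf(traj, "CAP", ("C1", "O1", "O2"),
                   top.select(site_label="CL"), voxel=0.5, extent=4.0)
        assert grid.n_skipped == 1
        assert grid.n_instances == 0
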