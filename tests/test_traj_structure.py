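"""Structural metrics: glucose proximity, dihedrals, H-bonds, RDF, profiles."""

import numpy as np
import pytest

import memglass as mg
from memglass._pbc import minimum_image, pair_distances
from conftest import make_tail_only_system


def point_system(lipid_pos, glucose_pos, box):
    """One single-bead 'lipid' and one glucose bead at fixed positions."""
    coords = np.array([[lipid_pos, glucose_pos]], dtype=float)
    traj = mg.Trajectory(times=np.array([0.0]), boxes=np.array([box], dtype=float),
                         coords=coords)
    roles = mg.TopologyRoles(
        molecule_id=np.array([0, 1]),
        molecule_type=np.array(["lipid", "glucose"], dtype=object),
        role=np.array(["phosphate", "glucose-atom"], dtype=object),
        electron_weight=np.array([47.0, 96.0]),
    )
    return traj, roles


def hbond_system(da_dist, hda_angle_deg):
    """Water donor at a planted distance/angle from a lipid acceptor oxygen."""
    acc = np.zeros(3)
    e = np.array([0.0, 0.0, 1.0])
    o_pos = acc + da_dist * e
    axis = np.array([1.0, 0.0, 0.0])
    a = np.radians(hda_angle_deg)
    h_dir = -e * np.cos(a) + np.cross(axis, -e) * np.sin(a)
    h1 = o_pos + h_dir
    h2 = o_pos + np.array([0.0, 1.0, 0.3]) / np.linalg.norm([0.0, 1.0, 0.3])
    coords = np.array([[acc, o_pos, h1, h2]])
    traj = mg.Trajectory(times=np.array([0.0]), boxes=np.array([[50.0, 50.0, 50.0]]),
                         coords=coords)
    roles = mg.TopologyRoles(
        molecule_id=np.array([0, 1, 1, 1]),
        molecule_type=np.array(["lipid", "water", "water", "water"], dtype=object),
        role=np.array(["acceptor-oxygen", "water-oxygen", "water-hydrogen",
                       "water-hydrogen"], dtype=object),
        electron_weight=np.array([8.0, 8.0, 1.0, 1.0]),
    )
    return traj, roles


class TestLipidsNearGlucose:
    def test_inside_radius_included(self):
        traj, roles = point_system([4.0, 0, 0], [0, 0, 0], [40.0, 40, 40])
        assert mg.lipids_near_glucose(traj, roles, radius=5.0) == {0}

    def test_outside_radius_excluded(self):
        traj, roles = point_system([4.0, 0, 0], [0, 0, 0], [40.0, 40, 40])
        assert mg.lipids_near_glucose(traj, roles, radius=3.0) == set()

    def test_wrapped_neighbour_included(self):
        # lipid across the periodic boundary: |18 − (−18)| wraps to 4 Å
        traj, roles = point_system([18.0, 0, 0], [-18.0, 0, 0], [40.0, 40, 40])
        d_brute = min(abs(18.0 - (-18.0)), 40.0 - abs(18.0 - (-18.0)))
        assert d_brute == 4.0
        assert mg.lipids_near_glucose(traj, roles, radius=5.0) == {0}

    def test_no_glucose_returns_empty(self, dyn_traj):
        _, traj, roles = dyn_traj
        assert mg.lipids_near_glucose(traj, roles, radius=5.0) == set()

    def test_nonpositive_radius_rejected(self):
        traj, roles = point_system([1, 0, 0], [0, 0, 0], [40.0, 40, 40])
        with pytest.raises(ValueError):
            mg.lipids_near_glucose(traj, roles, radius=0.0)


class TestGaucheFraction:
    def test_planted_trajectory_recovers_target(self, small_traj):
        spec, traj, roles = small_traj
        pt = mg.gauche_fraction(traj, roles, frame_stride=10)
        assert pt.value == pytest.approx(spec.gauche_target, abs=0.005)

    def test_uniform_dihedrals_give_two_thirds(self):
        # 360 chains, one dihedral value each, evenly covering (−180°, 180°]:
        # the |φ| < 120° gauche window covers exactly 240/360 of angle space
        values = -179.5 + np.arange(360)
        traj, roles = make_tail_only_system(values)
        pt = mg.gauche_fraction(traj, roles, chain="SN1", frame_stride=1)
        assert pt.value == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_measured_dihedrals_match_planted(self):
        planted = np.array([180.0, 65.0, -65.0, 120.5, 119.5])
        traj, roles = make_tail_only_system(planted)
        expected = np.mean(np.abs(planted) < 120.0)
        pt = mg.gauche_fraction(traj, roles, chain="SN1", frame_stride=1)
        assert pt.value == pytest.approx(expected, abs=1e-9)

    def test_rigid_translation_invariance(self, small_traj):
        _, traj, roles = small_traj
        a = mg.gauche_fraction(traj, roles, frame_stride=25)
        shifted = mg.Trajectory(
            times=traj.times, boxes=traj.boxes,
            coords=minimum_image(traj.coords + np.array([13.0, -7.0, 3.0]),
                                 traj.boxes[:, None, :]))
        b = mg.gauche_fraction(shifted, roles, frame_stride=25)
        assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_empty_selection_flagged_undefined(self, dyn_traj):
        _, traj, roles = dyn_traj  # no glucose present
        pt = mg.gauche_fraction(traj, roles, radius=5.0, frame_stride=500)
        assert not pt.defined


class TestCountHbonds:
    @pytest.mark.parametrize("dist,angle,expected", [
        (3.2, 10.0, 1.0),   # inside both cutoffs
        (3.6, 10.0, 0.0),   # distance cutoff violated
        (3.2, 35.0, 0.0),   # angle cutoff violated
        (3.5, 30.0, 1.0),   # exactly at the cutoffs still counts
    ])
    def test_geometric_truth_table(self, dist, angle, expected):
        traj, roles = hbond_system(dist, angle)
        pt = mg.count_hbonds(traj, roles, frame_stride=1)
        assert pt.value == expected

    def test_planted_bonds_counted_per_lipid(self, small_traj):
        spec, traj, roles = small_traj
        pt = mg.count_hbonds(traj, roles, frame_stride=10)
        assert pt.value == pytest.approx(spec.hbond_pairs_per_lipid, abs=1e-9)


class TestComputeRdf:
    def test_bruteforce_oracle_equivalence(self):
        rng = np.random.default_rng(3)
        n = 60
        box = np.array([20.0, 20.0, 20.0])
        coords = rng.uniform(-10, 10, (1, n, 3))
        traj = mg.Trajectory(times=np.array([0.0]), boxes=box[None], coords=coords)
        roles = mg.TopologyRoles(
            molecule_id=np.arange(n),
            molecule_type=np.array(["water"] * n, dtype=object),
            role=np.array(["water-oxygen"] * n, dtype=object),
            electron_weight=np.full(n, 8.0))
        sel = np.arange(n)
        rdf = mg.compute_rdf(traj, roles, sel, sel, bin_width=0.25)
        # independent brute force: explicit double loop over ordered pairs
        edges = np.arange(0.0, 10.0 + 0.25, 0.25)
        hist = np.zeros(edges.size - 1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = coords[0, i] - coords[0, j]
                d -= box * np.round(d / box)
                r = np.linalg.norm(d)
                if r < edges[-1]:
                    hist[int(r // 0.25)] += 1
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        g_brute = hist / (n * (n - 1) / np.prod(box) * shell)
        assert np.allclose(rdf.g, g_brute, atol=1e-10)

    def test_two_fixed_particles_single_bin(self):
        coords = np.array([[[0.0, 0, 0], [5.0, 0, 0]]])
        traj = mg.Trajectory(times=np.array([0.0]), boxes=np.array([[30.0, 30, 30]]),
                             coords=coords)
        roles = mg.TopologyRoles(
            molecule_id=np.array([0, 1]),
            molecule_type=np.array(["water", "water"], dtype=object),
            role=np.array(["water-oxygen", "water-oxygen"], dtype=object),
            electron_weight=np.array([8.0, 8.0]))
        rdf = mg.compute_rdf(traj, roles, np.array([0]), np.array([1]), bin_width=0.02)
        nz = np.flatnonzero(rdf.g)
        assert nz.size == 1
        assert rdf.r[nz[0]] == pytest.approx(5.0, abs=0.02)

    def test_ideal_gas_tends_to_one(self):
        rng = np.random.default_rng(7)
        n = 400
        box = np.array([25.0, 25.0, 25.0])
        coords = rng.uniform(-12.5, 12.5, (4, n, 3))
        traj = mg.Trajectory(times=np.arange(4.0), boxes=np.tile(box, (4, 1)),
                             coords=coords)
        roles = mg.TopologyRoles(
            molecule_id=np.arange(n),
            molecule_type=np.array(["water"] * n, dtype=object),
            role=np.array(["water-oxygen"] * n, dtype=object),
            electron_weight=np.full(n, 8.0))
        rdf = mg.compute_rdf(traj, roles, np.arange(n), np.arange(n), bin_width=0.5)
        far = rdf.r > 2.0
        assert np.abs(rdf.g[far].mean() - 1.0) < 0.02
        assert np.abs(rdf.g[far] - 1.0).max() < 0.25

    def test_simple_cubic_first_peak_at_lattice_spacing(self):
        a = 4.0
        grid = np.arange(5) * a - 8.0
        pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        n = pts.shape[0]
        traj = mg.Trajectory(times=np.array([0.0]), boxes=np.array([[20.0, 20, 20]]),
                             coords=pts[None])
        roles = mg.TopologyRoles(
            molecule_id=np.arange(n),
            molecule_type=np.array(["water"] * n, dtype=object),
            role=np.array(["water-oxygen"] * n, dtype=object),
            electron_weight=np.full(n, 8.0))
        rdf = mg.compute_rdf(traj, roles, np.arange(n), np.arange(n), bin_width=0.1)
        first = np.flatnonzero(rdf.g > 0)[0]
        assert rdf.r[first] == pytest.approx(a, abs=0.1)


class TestRdfHydrationScore:
    def make_rdf(self, fn):
        r = np.arange(1, 400) * 0.02  # hits 4.50 and 5.50 exactly
        return mg.RdfCurve(r=r, g=np.clip(fn(r), 0, None), bin_width=0.02)

    def test_direct_difference(self):
        rdf = self.make_rdf(lambda r: 1.0 + 0.5 * np.exp(-(r - 5.5) ** 2 / 0.02))
        score, err = mg.rdf_hydration_score(rdf)
        assert score == pytest.approx(rdf.g[np.argmin(np.abs(rdf.r - 5.5))]
                                      - rdf.g[np.argmin(np.abs(rdf.r - 4.5))])
        assert score > 0.4

    def test_symmetric_curve_scores_zero(self):
        rdf = self.make_rdf(lambda r: 1.0 + np.exp(-(r - 5.0) ** 2 / 0.5))
        score, _ = mg.rdf_hydration_score(rdf)
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_range_rejected(self):
        r = np.arange(0.01, 3.0, 0.02)
        rdf = mg.RdfCurve(r=r, g=np.ones_like(r), bin_width=0.02)
        with pytest.raises(ValueError):
            mg.rdf_hydration_score(rdf)


class TestDensityProfile:
    def test_united_atom_weights_land_in_central_bin(self):
        # one methylene at z = 0 → weight 8; terminal methyl → weight 9
        for role, weight in (("SN1-carbon-3", 8.0), ("terminal-methyl", 9.0)):
            coords = np.zeros((1, 1, 3))
            traj = mg.Trajectory(times=np.array([0.0]),
                                 boxes=np.array([[10.0, 10.0, 20.0]]), coords=coords)
            roles = mg.TopologyRoles(
                molecule_id=np.array([0]),
                molecule_type=np.array(["lipid"], dtype=object),
                role=np.array([role], dtype=object),
                electron_weight=np.array([weight]))
            comp = "core" if role == "terminal-methyl" else "tail"
            prof = mg.density_profile(traj, roles, component=comp, bin_width=1.0)
            area = 100.0
            assert prof.rho.sum() * 1.0 * area == pytest.approx(weight)
            assert prof.rho[np.argmin(np.abs(prof.z))] == pytest.approx(weight / area)

    def test_total_electron_weight_conserved(self, small_traj):
        _, traj, roles = small_traj
        prof = mg.density_profile(traj, roles, component="whole-membrane",
                                  bin_width=0.5, frame_stride=10)
        area = float(traj.boxes[0, 0] * traj.boxes[0, 1])
        total = prof.rho.sum() * prof.grid_step * area
        assert total == pytest.approx(roles.electron_weight.sum(), rel=1e-9)

    def test_unknown_component_rejected(self, small_traj):
        _, traj, roles = small_traj
        with pytest.raises(ValueError):
            mg.density_profile(traj, roles, component="cholesterol")


class TestInterdigitation:
    def test_separated_leaflets_score_zero(self):
        z = np.linspace(-20, 20, 81)
        rho = np.exp(-(np.abs(z) - 10) ** 2)  # mass away from the midplane
        rho[np.abs(z) < 2.5] = 0.0
        prof = mg.ElectronDensityProfile(z=z, rho=rho, component_label="core")
        assert mg.interdigitation_score(prof) == 0.0

    def test_planted_central_overlap(self):
        # k methyls in the central bin of a one-frame system
        k = 5
        coords = np.zeros((1, k, 3))
        traj = mg.Trajectory(times=np.array([0.0]), boxes=np.array([[10.0, 10.0, 20.0]]),
                             coords=coords)
        roles = mg.TopologyRoles(
            molecule_id=np.arange(k),
            molecule_type=np.array(["lipid"] * k, dtype=object),
            role=np.array(["terminal-methyl"] * k, dtype=object),
            electron_weight=np.full(k, 9.0))
        prof = mg.density_profile(traj, roles, component="core", bin_width=1.0)
        assert mg.interdigitation_score(prof) == pytest.approx(k * 9.0 / 100.0)

    def test_symmetrization_invariance(self):
        z = np.linspace(-20, 20, 81)
        rng = np.random.default_rng(5)
        rho = np.abs(rng.normal(1, 0.2, z.size))
        a = mg.interdigitation_score(
            mg.ElectronDensityProfile(z=z, rho=rho, component_label="core"))
        b = mg.interdigitation_score(
            mg.ElectronDensityProfile(z=z, rho=rho[::-1], component_label="core"))
        assert a == pytest.approx(b)

    def test_wrong_component_rejected(self):
        z = np.linspace(-5, 5, 11)
        prof = mg.ElectronDensityProfile(z=z, rho=np.ones(11), component_label="head")
        with pytest.raises(ValueError):
            mg.interdigitation_score(prof)


class TestDistanceFluctuation:
    def make_lipid(self, distances):
        f = len(distances)
        coords = np.zeros((f, 2, 3))
        coords[:, 1, 0] = distances
        traj = mg.Trajectory(times=np.arange(float(f)),
                             boxes=np.tile([100.0, 100, 100], (f, 1)), coords=coords)
        roles = mg.TopologyRoles(
            molecule_id=np.array([0, 0]),
            molecule_type=np.array(["lipid", "lipid"], dtype=object),
            role=np.array(["phosphate", "terminal-methyl"], dtype=object),
            electron_weight=np.array([47.0, 9.0]))
        return traj, roles

    def test_rigid_molecule_zero(self):
        traj, roles = self.make_lipid(np.full(10, 12.0))
        res = mg.distance_fluctuation(traj, roles, "terminal-methyl")
        assert res.normalized == 0.0 and res.raw == 0.0

    def test_translation_leaves_zero(self):
        traj, roles = self.make_lipid(np.full(10, 12.0))
        moved = mg.Trajectory(times=traj.times, boxes=traj.boxes,
                              coords=traj.coords + np.linspace(0, 9, 10)[:, None, None])
        res = mg.distance_fluctuation(moved, roles, "terminal-methyl")
        assert res.raw == pytest.approx(0.0, abs=1e-12)

    def test_planted_jitter_recovered(self):
        rng = np.random.default_rng(8)
        sigma, mean = 0.5, 12.0
        traj, roles = self.make_lipid(mean + rng.normal(0, sigma, 10000))
        res = mg.distance_fluctuation(traj, roles, "terminal-methyl")
        assert res.normalized == pytest.approx(sigma / mean, rel=0.05)

    def test_missing_target_rejected(self):
        traj, roles = self.make_lipid(np.full(5, 12.0))
        with pytest.raises(ValueError):
            mg.distance_fluctuation(traj, roles, "SN2-carbon-9")


class TestBlockStandardError:
    def test_constant_series_zero(self):
        assert mg.block_standard_error(np.full(25, 3.3)) == 0.0

    def test_hand_computed_example(self):
        # blocks of [1,1,1,1,1,3,3,3,3,3] → means [1,1,2,3,3]
        series = [1, 1, 1, 1, 1, 3, 3, 3, 3, 3]
        expected = np.std([1, 1, 2, 3, 3]) / np.sqrt(5)
        assert mg.block_standard_error(series) == pytest.approx(expected)

    def test_permutation_within_blocks_invariant(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        orig = mg.block_standard_error(x, n_blocks=5)
        perm = x.copy()
        for b in range(5):
            seg = perm[4 * b:4 * b + 4]
            rng.shuffle(seg)
        assert mg.block_standard_error(perm, n_blocks=5) == pytest.approx(orig)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            mg.block_standard_error([1.0, 2.0], n_blocks=5)


class TestDistanceResolvedSeries:
    def test_contributions_grow_and_converge_to_whole_membrane(self, small_traj):
        _, traj, roles = small_traj
        series = mg.distance_resolved_series(traj, roles, [5.0, 15.0, 500.0],
                                             metric="gauche", frame_stride=25)
        assert np.all(np.diff(series.n_contributing) >= 0)
        whole = mg.gauche_fraction(traj, roles, radius=None, frame_stride=25)
        assert series.value[-1] == pytest.approx(whole.value, abs=1e-12)
        assert series.n_contributing[-1] == roles.lipid_ids.size
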