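"""Hydration-site clustering, energetics, entropies and network comparison."""

import numpy as np
import pytest

import thermoprof as tp
from thermoprof.constants import K_B
from thermoprof.hydration import (
    Frame,
    HydrationSite,
    Trajectory,
    cluster_sites,
    compare_networks,
    site_energies,
    site_entropy,
)

from conftest import gaussian_trans_entropy_oracle, vmf_orient_entropy_oracle


def _single_site_traj(n_frames=300, center=(0.0, 0.0, 0.0), temperature=300.0):
    frames = [
        Frame(
            water_ids=np.array([0]),
            positions=np.array([center]),
            orientations=np.array([[0.0, 0.0, 1.0]]),
        )
        for _ in range(n_frames)
    ]
    return Trajectory(frames, np.zeros(3), 5.0, temperature)


class TestTrajectoryValidation:
    def test_nonunit_orientations_rejected(self):
        with pytest.raises(ValueError, match="unit norm"):
            Frame(np.array([0]), np.zeros((1, 3)), np.array([[0.0, 0.0, 2.0]]))

    def test_near_unit_orientations_renormalized(self):
        f = Frame(np.array([0]), np.zeros((1, 3)), np.array([[0.0, 0.0, 1.0005]]))
        assert np.linalg.norm(f.orientations[0]) == pytest.approx(1.0, abs=1e-12)

    def test_waters_outside_region_rejected(self):
        f = Frame(np.array([0]), np.array([[10.0, 0.0, 0.0]]),
                  np.array([[0.0, 0.0, 1.0]]))
        with pytest.raises(ValueError, match="outside the region"):
            Trajectory([f], np.zeros(3), 5.0, 300.0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_sites(Trajectory([], np.zeros(3), 5.0, 300.0))


class TestClustering:
    def test_always_occupied_site_has_unit_occupancy(self):
        with pytest.warns(UserWarning, match="frames"):
            sites = cluster_sites(_single_site_traj(50))
        assert len(sites) == 1
        assert sites[0].occupancy == 1.0

    def test_planted_sites_recovered(self, small_planted_network):
        spec, traj = small_planted_network
        sites = cluster_sites(traj, site_radius=1.0, min_occupancy=0.5)
        assert len(sites) == len(spec.sites)
        planted = np.array([s.center for s in spec.sites])
        occs = {}
        for s in sites:
            d = np.linalg.norm(planted - s.center, axis=1)
            k = int(np.argmin(d))
            assert d[k] < 0.5
            occs[k] = s.occupancy
        for k, site_spec in enumerate(spec.sites):
            p = site_spec.occupancy_prob
            tol = 3 * np.sqrt(max(p * (1 - p), 1e-4) / spec.n_frames) + 0.01
            assert occs[k] == pytest.approx(p, abs=tol)

    def test_frame_permutation_stability(self, small_planted_network):
        _, traj = small_planted_network
        rng = np.random.default_rng(0)
        shuffled = Trajectory(
            [traj.frames[i] for i in rng.permutation(traj.n_frames)],
            traj.region_center, traj.region_radius, traj.temperature,
        )
        a = cluster_sites(traj)
        b = cluster_sites(shuffled)
        assert len(a) == len(b)
        ca = sorted(map(tuple, (s.center for s in a)))
        cb = sorted(map(tuple, (s.center for s in b)))
        assert np.allclose(ca, cb, atol=1e-6)


class TestSiteEnergies:
    def test_two_fixed_waters_give_pair_energy_at_separation(self):
        pot = tp.pseudo_water_potential(epsilon=0.2, sigma=2.8, mu=1.0)
        r = 3.2
        u = np.array([0.0, 0.0, 1.0])
        frames = [
            Frame(
                water_ids=np.array([0, 1]),
                positions=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
                orientations=np.array([u, u]),
            )
            for _ in range(120)
        ]
        traj = Trajectory(frames, np.zeros(3), 6.0, 300.0)
        sites = cluster_sites(traj)
        expected = float(pot(np.zeros(3), u, np.array([[r, 0.0, 0.0]]), u[None])[0])
        for s in sites:
            s = site_energies(s, traj, pot)
            assert s.e_ww == pytest.approx(expected, abs=1e-9)
            assert s.e_sw == 0.0  # no solute present

    def test_isolated_site_has_zero_energies(self):
        traj = _single_site_traj(150)
        site = cluster_sites(traj)[0]
        site = site_energies(site, traj, tp.pseudo_water_potential())
        assert site.e_ww == 0.0 and site.e_sw == 0.0

    def test_never_occupied_site_rejected(self):
        traj = _single_site_traj(150)
        ghost = HydrationSite(9, np.array([3.0, 3.0, 0.0]), 0.0, 0)
        with pytest.raises(ValueError, match="never occupied"):
            site_energies(ghost, traj, tp.pseudo_water_potential())

    def test_solute_water_energy_uses_solute_positions(self):
        pot = tp.pseudo_water_potential(epsilon=0.2, sigma=2.8, mu=0.0)
        solute = np.array([[2.5, 0.0, 0.0]])
        frames = [
            Frame(np.array([0]), np.zeros((1, 3)),
                  np.array([[0.0, 0.0, 1.0]]), solute_positions=solute)
            for _ in range(120)
        ]
        traj = Trajectory(frames, np.zeros(3), 5.0, 300.0)
        site = site_energies(cluster_sites(traj)[0], traj, pot)
        expected = float(pot(np.zeros(3), np.array([0, 0, 1.0]), solute, None)[0])
        assert site.e_sw == pytest.approx(expected, abs=1e-9)


class TestSiteEntropy:
    def test_bulk_like_site_has_near_zero_entropies(self):
        # uniform positions in a 1.5 A ball at matching occupancy/density
        rng = np.random.default_rng(8)
        rho = 0.0334
        rv = 1.5
        occ = rho * 4.0 / 3.0 * np.pi * rv**3  # ~0.47
        n = 6000
        frames = []
        for i in range(n):
            if rng.random() < occ:
                v = rng.normal(size=3)
                v *= rv * rng.random() ** (1 / 3) / np.linalg.norm(v)
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                frames.append(Frame(np.array([0]), v[None], u[None]))
            else:
                frames.append(Frame(np.array([], dtype=int),
                                    np.zeros((0, 3)), np.zeros((0, 3))))
        traj = Trajectory(frames, np.zeros(3), 5.0, 300.0)
        site = HydrationSite(0, np.zeros(3), occ, int(occ * n))
        site = site_entropy(site, traj, bulk_density=rho, site_radius=rv)
        assert abs(site.s_trans) < 0.25 * K_B
        assert abs(site.s_orient) < 0.1 * K_B

    def test_translational_entropy_tracks_gaussian_oracle(self):
        for sd, tol in ((0.2, 0.3), (0.4, 0.3)):
            spec = tp.PlantedNetworkSpec(
                sites=(tp.SiteSpec((0, 0, 0), sd, 0.0, 1.0),),
                bulk_density=0.0, region_radius=5.0, n_frames=3000, seed=5,
            )
            traj = tp.generate_water_network(spec)
            site = HydrationSite(0, np.zeros(3), 1.0, 3000)
            site = site_entropy(site, traj, bulk_density=0.0334, site_radius=2.0)
            oracle = gaussian_trans_entropy_oracle(sd, 1.0, 0.0334)
            assert site.s_trans < 0
            assert site.s_trans == pytest.approx(oracle, abs=tol * K_B)

    def test_narrower_sites_pay_more_translational_entropy(self):
        vals = []
        for sd in (0.15, 0.3, 0.6):
            spec = tp.PlantedNetworkSpec(
                sites=(tp.SiteSpec((0, 0, 0), sd, 0.0, 1.0),),
                bulk_density=0.0, region_radius=5.0, n_frames=2000, seed=6,
            )
            traj = tp.generate_water_network(spec)
            site = site_entropy(
                HydrationSite(0, np.zeros(3), 1.0, 2000), traj,
                bulk_density=0.0334, site_radius=2.5,
            )
            vals.append(site.s_trans)
        assert vals[0] < vals[1] < vals[2]

    def test_orientational_entropy_tracks_vmf_oracle(self):
        vals = {}
        for kappa in (0.0, 2.0, 8.0):
            spec = tp.PlantedNetworkSpec(
                sites=(tp.SiteSpec((0, 0, 0), 0.2, kappa, 1.0),),
                bulk_density=0.0, region_radius=5.0, n_frames=3000, seed=7,
            )
            traj = tp.generate_water_network(spec)
            site = site_entropy(
                HydrationSite(0, np.zeros(3), 1.0, 3000), traj,
                bulk_density=0.0334,
            )
            vals[kappa] = site.s_orient
            assert site.s_orient == pytest.approx(
                vmf_orient_entropy_oracle(kappa), abs=0.15 * K_B
            )
        assert vals[8.0] < vals[2.0] < vals[0.0] + 0.05 * K_B

    def test_insufficient_occupancy_rejected(self):
        traj = _single_site_traj(30)
        ghost = HydrationSite(9, np.array([3.0, 3.0, 0.0]), 0.0, 0)
        with pytest.raises(ValueError, match="insufficient"):
            site_entropy(ghost, traj, bulk_density=0.03)


class TestNetworkComparison:
    def _sites(self, energies, offset=0.0):
        out = []
        for i, (ww, sw, ts) in enumerate(energies):
            out.append(
                HydrationSite(
                    i, np.array([3.0 * i + offset, 0.0, 0.0]), 0.9, 900,
                    e_ww=ww, e_sw=sw, minus_t_ds=ts,
                )
            )
        return out

    def test_identical_networks_difference_to_zero(self):
        a = self._sites([(-5.0, -1.0, 1.2), (-4.0, -0.5, 0.8)])
        cmp = compare_networks(a, self._sites([(-5.0, -1.0, 1.2), (-4.0, -0.5, 0.8)]))
        assert not cmp.displaced_site_ids
        assert cmp.d_e_total == 0.0
        assert all(m.d_e_ww == 0.0 for m in cmp.matches)

    def test_missing_site_flagged_displaced(self, small_planted_network):
        spec, traj_a = small_planted_network
        spec_b = tp.PlantedNetworkSpec(
            sites=spec.sites[:-1], bulk_density=spec.bulk_density,
            region_radius=spec.region_radius, n_frames=spec.n_frames, seed=spec.seed,
        )
        traj_b = tp.generate_water_network(spec_b)
        sites_a = cluster_sites(traj_a)
        sites_b = cluster_sites(traj_b)
        cmp = compare_networks(sites_a, sites_b, match_radius=1.5)
        assert len(cmp.displaced_site_ids) == 1
        lost = next(s for s in sites_a if s.site_id == cmp.displaced_site_ids[0])
        assert np.linalg.norm(lost.center - np.array(spec.sites[-1].center)) < 0.5

    def test_totals_are_sums_of_per_site_terms(self):
        a = self._sites([(-5.0, -1.0, 0.1), (-4.0, -0.5, 0.2), (-6.0, 1.0, 0.3)])
        b = self._sites([(-6.0, -0.8, 0.4), (-3.0, -0.9, 0.1)])
        cmp = compare_networks(a, b)
        ww = sum(m.d_e_ww for m in cmp.matches) - (-6.0)
        pw = sum(m.d_e_pw for m in cmp.matches) - 1.0
        assert cmp.d_e_ww_total == pytest.approx(ww, abs=1e-12)
        assert cmp.d_e_pw_total == pytest.approx(pw, abs=1e-12)
        assert cmp.d_e_total == pytest.approx(
            cmp.d_e_ww_total + cmp.d_e_pw_total, abs=1e-12
        )

    def test_empty_comparison_allowed(self):
        cmp = compare_networks([], [])
        assert cmp.d_e_total == 0.0 and not cmp.matches
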