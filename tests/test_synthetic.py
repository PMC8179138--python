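"""Generators: Metropolis samplers, dG(T) tables, planted water networks."""

import numpy as np
import pytest

import thermoprof as tp
from thermoprof._stats import block_sem
from thermoprof.constants import K_B
from thermoprof.fep import LambdaLadder


class TestHarmonicSampler:
    def test_identical_end_states_give_identically_zero_differences(self):
        spec = tp.HarmonicSpec(1.5, 1.5, temperature=300.0)
        run = tp.sample_alchemical_path(
            spec, LambdaLadder.evenly_spaced(11), n_steps=2000, seed=0,
            store_frames=False,
        )
        for s in run.series:
            assert np.all(s.delta_u == 0.0)

    def test_seed_determinism_is_bitwise(self, harmonic_spec):
        kw = dict(ladder=LambdaLadder.evenly_spaced(5), n_steps=2000, seed=9)
        a = tp.sample_alchemical_path(harmonic_spec, **kw)
        b = tp.sample_alchemical_path(harmonic_spec, **kw)
        for sa, sb in zip(a.series, b.series):
            assert np.array_equal(sa.delta_u, sb.delta_u)
        c = tp.sample_alchemical_path(
            harmonic_spec, LambdaLadder.evenly_spaced(5), n_steps=2000, seed=10
        )
        assert not np.array_equal(a.series[0].delta_u, c.series[0].delta_u)

    def test_equipartition(self, harmonic_spec):
        x = tp.sample_harmonic_positions(harmonic_spec, 0.0, 60000, seed=3)
        x2 = x[:, 0] ** 2
        sem = block_sem(x2, 20)
        assert x2.mean() == pytest.approx(K_B * 300.0 / 1.0, abs=3 * sem)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            tp.HarmonicSpec(-1.0, 2.0)
        with pytest.raises(ValueError):
            tp.HarmonicSpec(1.0, 2.0, dimensionality=2)
        with pytest.raises(ValueError, match="temperature"):
            tp.HarmonicSpec(1.0, 2.0, temperature=-10.0)
        with pytest.raises(ValueError, match="n_steps"):
            tp.sample_alchemical_path(tp.HarmonicSpec(1.0, 2.0), n_steps=0)


class TestVantHoffTable:
    def test_noiseless_table_sits_exactly_on_the_line(self):
        spec = tp.SyntheticVantHoffSpec(
            -11.6, -0.016, (280.0, 300.0, 315.0), 0.0, 2, 0
        )
        table = tp.generate_vanthoff_table(spec)
        expected = -11.6 - table["temperature"] * (-0.016)
        assert np.allclose(table["ddg"], expected, atol=1e-12)

    def test_seed_reproducibility(self):
        spec = tp.SyntheticVantHoffSpec(
            -11.6, -0.016, (280.0, 300.0, 315.0), 0.3, 3, 42
        )
        assert tp.generate_vanthoff_table(spec).equals(
            tp.generate_vanthoff_table(spec)
        )

    def test_single_temperature_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            tp.SyntheticVantHoffSpec(-11.6, -0.016, (300.0,), 0.0, 3, 0)


class TestWaterNetwork:
    def test_rigid_always_occupied_site_sits_at_center(self):
        spec = tp.PlantedNetworkSpec(
            sites=(tp.SiteSpec((1.0, 0.0, 0.0), 0.0, 0.0, 1.0),),
            bulk_density=0.0, region_radius=4.0, n_frames=50, seed=0,
        )
        traj = tp.generate_water_network(spec)
        for f in traj.frames:
            assert len(f.positions) == 1
            assert np.allclose(f.positions[0], [1.0, 0.0, 0.0])

    def test_occupancy_is_binomial(self):
        p = 0.78
        spec = tp.PlantedNetworkSpec(
            sites=(tp.SiteSpec((0, 0, 0), 0.2, 0.0, p),),
            bulk_density=0.0, region_radius=4.0, n_frames=5000, seed=17,
        )
        traj = tp.generate_water_network(spec)
        occ = np.mean([len(f.positions) > 0 for f in traj.frames])
        assert occ == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 5000))

    def test_site_outside_region_rejected(self):
        with pytest.raises(ValueError, match="outside the region"):
            tp.PlantedNetworkSpec(
                sites=(tp.SiteSpec((9.0, 0, 0), 0.2, 0.0, 1.0),),
                bulk_density=0.0, region_radius=4.0, n_frames=10, seed=0,
            )

    def test_overlapping_sites_rejected(self):
        with pytest.raises(ValueError, match="closer"):
            tp.PlantedNetworkSpec(
                sites=(
                    tp.SiteSpec((0, 0, 0), 0.2, 0.0, 1.0),
                    tp.SiteSpec((1.0, 0, 0), 0.2, 0.0, 1.0),
                ),
                bulk_density=0.0, region_radius=4.0, n_frames=10, seed=0,
            )

    def test_all_waters_stay_inside_region(self):
        spec = tp.PlantedNetworkSpec(
            sites=(tp.SiteSpec((3.4, 0, 0), 0.4, 0.0, 1.0),),
            bulk_density=0.005, region_radius=4.0, n_frames=300, seed=3,
        )
        traj = tp.generate_water_network(spec)  # validates internally
        assert traj.n_frames == 300


class TestHostGuestSampler:
    def test_recorded_energies_match_bruteforce_pair_sum(self):
        spec = tp.hostguest_benchmark(bound=True)
        run = tp.sample_alchemical_path(
            spec, LambdaLadder((0.0, 1.0)), n_steps=300, seed=4, sample_interval=60
        )
        bond = spec.guest_bond
        nh, ng = len(spec.host_particles), len(spec.guest_particles)

        def brute_total(pos, ori, state):
            eps = [p.epsilon for p in spec.host_particles]
            sig = [p.sigma for p in spec.host_particles]
            mu = [p.mu for p in spec.host_particles]
            for g in spec.guest_particles:
                eps.append(g.epsilon_b if state else g.epsilon_a)
                sig.append(g.sigma_b if state else g.sigma_a)
                mu.append(g.mu_b if state else g.mu_a)
            for _ in range(spec.n_solvent):
                eps.append(spec.solvent_epsilon)
                sig.append(spec.solvent_sigma)
                mu.append(spec.solvent_mu)
            n = len(eps)
            e = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    d = pos[j] - pos[i]
                    r = max(np.linalg.norm(d), 0.5)
                    eij = np.sqrt(eps[i] * eps[j])
                    sij = 0.5 * (sig[i] + sig[j])
                    if eij > 0:
                        sr6 = (sij / r) ** 6
                        e += 4 * eij * (sr6**2 - sr6)
                    i_or, j_or = i >= nh + ng, j >= nh + ng
                    if i_or and j_or:
                        g_ = ori[i - nh - ng] @ ori[j - nh - ng]
                    elif i_or:
                        g_ = (ori[i - nh - ng] @ d) / r
                    elif j_or:
                        g_ = -(ori[j - nh - ng] @ d) / r
                    else:
                        g_ = 1.0
                    e += -mu[i] * mu[j] * g_ / r**3
            k, r0 = (bond[2], bond[3]) if state else (bond[0], bond[1])
            rb = np.linalg.norm(pos[nh + 1] - pos[nh])
            e += 0.5 * k * (rb - r0) ** 2
            anchors = np.array([g.position for g in spec.guest_particles])
            e += 0.5 * spec.restraint_constant * np.sum(
                (pos[nh : nh + ng] - anchors) ** 2
            )
            return e

        for which, state in (("A", 0), ("B", 1)):
            positions, orientations = run.endstate_frames[which]
            table = run.endstate_tables[which]
            for k in range(len(positions)):
                ref = brute_total(positions[k], orientations[k], state)
                assert table["total"].iloc[k] == pytest.approx(ref, abs=1e-8)

    def test_all_particles_stay_inside_sphere(self):
        spec = tp.hostguest_benchmark(bound=False)
        run = tp.sample_alchemical_path(
            spec, LambdaLadder((0.0, 1.0)), n_steps=400, seed=5, sample_interval=40
        )
        for which in ("A", "B"):
            pos, _ = run.endstate_frames[which]
            assert np.linalg.norm(pos, axis=-1).max() <= spec.sphere_radius + 1e-9

    def test_overlapping_initialization_rejected_with_diagnostic(self):
        with pytest.raises(ValueError, match="overlap"):
            spec = tp.HostGuestSpec(
                host_particles=(tp.Particle((0, 0, 0), 0.3, 3.0),),
                guest_particles=(
                    tp.GuestParticle((0.1, 0, 0), 0.2, 0.2, 3.0, 3.0),
                ),
                n_solvent=0, sphere_radius=5.0,
            )
            tp.sample_alchemical_path(spec, LambdaLadder((0.0, 1.0)),
                                      n_steps=10, seed=0)

    def test_scan_matches_single_runs_statistically(self):
        spec = tp.hostguest_benchmark(bound=False)
        ladder = LambdaLadder.evenly_spaced(4)
        runs = tp.sample_alchemical_scan(
            spec, ladder, [300.0], n_replicates=2, n_steps=1200, seed=8,
            sample_interval=4,
        )
        legs = [tp.estimate_leg(runs[(300.0, r)].series, "u", ladder) for r in (0, 1)]
        assert abs(legs[0].leg_dg - legs[1].leg_dg) < 4 * np.hypot(
            legs[0].leg_sem, legs[1].leg_sem
        ) + 0.05
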