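"""Synthetic benchmark systems with known thermodynamics.

Three generators provide every input the pipeline consumes:

* Boltzmann samples along an alchemical lambda ladder, from Metropolis
  Monte Carlo on toy Hamiltonians — a (1D or 3D) harmonic oscillator whose
  free energy is known in closed form, and a host-guest model of
  Lennard-Jones particles plus orientable single-site pseudo-waters in a
  reflecting sphere;
* dG(T) tables on an exact enthalpy/entropy line with Gaussian noise, for
  exercising the van't Hoff stage;
* water-network trajectories with planted hydration sites of prescribed
  center, positional spread, orientational concentration and occupancy
  over a uniform bulk background.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _hostguest_kernel as _kernel
from .constants import K_B
from .fep import LambdaLadder, PerturbationSeries
from .hydration import Frame, Trajectory

#: Pair distances are clamped below this (A) to keep toy potentials finite.
_R_MIN = 0.5
#: Metropolis translational step (A) and orientational step for pseudo-waters.
_TRANS_STEP = 0.35
_ROT_STEP = 0.5

_TAG_KEYS = ("receptor_ligand", "ligand_internal", "ligand_water", "surroundings")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicSpec:
    """Alchemical mutation between two harmonic wells.

    U_lambda(x) = (1-lambda) * kA/2 |x-cA|^2 + lambda * kB/2 |x-cB|^2.
    The exact transformation free energy is d * (kT/2) ln(kB/kA) per the
    Gaussian partition functions (centers do not contribute).
    """

    force_constant_a: float
    force_constant_b: float
    center_a: float = 0.0
    center_b: float = 0.0
    dimensionality: int = 1
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.force_constant_a <= 0 or self.force_constant_b <= 0:
            raise ValueError("force constants must be strictly positive")
        if self.dimensionality not in (1, 3):
            raise ValueError("dimensionality must be 1 or 3")
        if self.temperature <= 0:
            raise ValueError("non-positive temperature")

    def exact_delta_f(self, temperature: float | None = None) -> float:
        """Closed-form dF(A->B) = d*(kT/2) ln(kB/kA), kcal/mol."""
        t = self.temperature if temperature is None else temperature
        return float(
            self.dimensionality
            * 0.5
            * K_B
            * t
            * np.log(self.force_constant_b / self.force_constant_a)
        )


@dataclass(frozen=True)
class Particle:
    """A fixed-parameter Lennard-Jones particle with a scalar dipole moment."""

    position: tuple[float, float, float]
    epsilon: float
    sigma: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.sigma < 0 or self.mu < 0:
            raise ValueError("epsilon, sigma and mu must be non-negative")


@dataclass(frozen=True)
class GuestParticle:
    """A mobile particle whose parameters differ between end states A and B."""

    position: tuple[float, float, float]
    epsilon_a: float
    epsilon_b: float
    sigma_a: float
    sigma_b: float
    mu_a: float = 0.0
    mu_b: float = 0.0

    def __post_init__(self) -> None:
        for v in (
            self.epsilon_a,
            self.epsilon_b,
            self.sigma_a,
            self.sigma_b,
            self.mu_a,
            self.mu_b,
        ):
            if v < 0:
                raise ValueError("epsilon, sigma and mu must be non-negative")


@dataclass(frozen=True)
class HostGuestSpec:
    """Toy host-guest system in a reflecting sphere.

    The guest particles are alchemically transformed (A -> B parameters);
    the host is fixed in space; ``n_solvent`` orientable single-site
    pseudo-waters fill the sphere.  Pseudo-water pairs interact through LJ
    plus a dipolar term -mu_i mu_j (u_i . u_j) / r^3; a pseudo-water and an
    orientation-less particle couple through -mu_i mu_j (u_i . r_hat) / r^3.
    ``restraint_constant`` harmonically tethers the guest to its initial
    position (0 = unrestrained).  An optional harmonic guest-guest bond
    (k, r0 per end state) provides an internal "strain" energy.
    """

    host_particles: tuple[Particle, ...]
    guest_particles: tuple[GuestParticle, ...]
    n_solvent: int
    sphere_radius: float
    restraint_constant: float = 0.0
    temperature: float = 300.0
    solvent_epsilon: float = 0.15
    solvent_sigma: float = 2.8
    solvent_mu: float = 1.0
    guest_bond: tuple[float, float, float, float] | None = None  # kA, r0A, kB, r0B

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("non-positive temperature")
        if self.sphere_radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.n_solvent < 0:
            raise ValueError("negative solvent count")
        if self.restraint_constant < 0:
            raise ValueError("negative restraint constant")
        if self.guest_bond is not None and len(self.guest_particles) < 2:
            raise ValueError("guest bond needs at least two guest particles")
        for p in list(self.host_particles) + list(self.guest_particles):
            if np.linalg.norm(p.position) > self.sphere_radius:
                raise ValueError("particle initialised outside the sphere")


@dataclass(frozen=True)
class SiteSpec:
    """One planted hydration site."""

    center: tuple[float, float, float]
    positional_sd: float
    orientational_concentration: float
    occupancy_prob: float
    mean_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.positional_sd < 0:
            raise ValueError("positional sd must be non-negative")
        if self.orientational_concentration < 0:
            raise ValueError("orientational concentration must be non-negative")
        if not 0.0 <= self.occupancy_prob <= 1.0:
            raise ValueError("occupancy probability must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """A water network with known ground truth, over a uniform bulk."""

    sites: tuple[SiteSpec, ...]
    bulk_density: float
    region_radius: float
    n_frames: int
    seed: int
    region_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    temperature: float = 300.0
    #: planted centers must be separated by more than twice the clustering
    #: radius used downstream (default 1 A) so sites stay resolvable
    min_site_separation: float = 2.0

    def __post_init__(self) -> None:
        if self.bulk_density < 0:
            raise ValueError("bulk density must be non-negative")
        if self.n_frames <= 0:
            raise ValueError("need at least one frame")
        center = np.asarray(self.region_center)
        for s in self.sites:
            if np.linalg.norm(np.asarray(s.center) - center) > self.region_radius:
                raise ValueError(f"site at {s.center} lies outside the region")
        for i, a in enumerate(self.sites):
            for b in self.sites[i + 1 :]:
                d = np.linalg.norm(np.asarray(a.center) - np.asarray(b.center))
                if d <= self.min_site_separation:
                    raise ValueError(
                        f"planted sites closer than {self.min_site_separation} A"
                    )


@dataclass(frozen=True)
class SyntheticVantHoffSpec:
    """Exact dG(T) line dH - T*dS with i.i.d. Gaussian noise."""

    delta_h: float
    delta_s: float
    temperatures: tuple[float, ...]
    noise_sd: float
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.temperatures)) < 3:
            raise ValueError("need at least 3 distinct temperatures")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


#: Eight temperatures in 5 K steps bracketing 300 K — the default
#: temperature set for computational van't Hoff scans.
DEFAULT_TEMPERATURES: tuple[float, ...] = tuple(np.arange(280.0, 316.0, 5.0))


# ---------------------------------------------------------------------------
# dG(T) tables
# ---------------------------------------------------------------------------


def generate_vanthoff_table(spec: SyntheticVantHoffSpec) -> pd.DataFrame:
    """Replicated dG(T) = dH - T*dS + Normal(0, noise_sd^2) table."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for t in spec.temperatures:
        base = spec.delta_h - t * spec.delta_s
        for r in range(spec.n_replicates):
            rows.append(
                {
                    "temperature": float(t),
                    "replicate": r,
                    "ddg": base + rng.normal(0.0, spec.noise_sd)
                    if spec.noise_sd > 0
                    else base,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# water networks
# ---------------------------------------------------------------------------


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform unit vectors."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _vmf_sample(
    rng: np.random.Generator, mean: np.ndarray, kappa: float, n: int
) -> np.ndarray:
    if kappa == 0.0:
        return _uniform_sphere(rng, n)
    from scipy.stats import vonmises_fisher

    return vonmises_fisher(mu=mean, kappa=kappa).rvs(size=n, random_state=rng)


def generate_water_network(spec: PlantedNetworkSpec) -> Trajectory:
    """Trajectory with planted hydration sites over a uniform bulk.

    Per frame each site is occupied with its stated probability by a water
    at center + Normal(0, sd^2 I) (resampled until inside the region) with a
    von Mises-Fisher orientation; bulk waters are Poisson in number, uniform
    in the sphere, and uniformly oriented.  Site waters carry the site index
    as a persistent water id; bulk ids start at 1000 within each frame.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(spec.region_center, dtype=float)
    n = spec.n_frames

    site_occ, site_pos, site_ori = [], [], []
    for s in spec.sites:
        occ = rng.random(n) < s.occupancy_prob
        c = np.asarray(s.center, dtype=float)
        if s.positional_sd > 0:
            pos = c + rng.normal(0.0, s.positional_sd, size=(n, 3))
            # resample stragglers so the region invariant holds
            for _ in range(100):
                out = np.linalg.norm(pos - center, axis=1) > spec.region_radius
                if not out.any():
                    break
                pos[out] = c + rng.normal(0.0, s.positional_sd, size=(out.sum(), 3))
        else:
            pos = np.tile(c, (n, 1))
        mean = np.asarray(s.mean_orientation, dtype=float)
        mean = mean / np.linalg.norm(mean)
        ori = _vmf_sample(rng, mean, s.orientational_concentration, n)
        site_occ.append(occ)
        site_pos.append(pos)
        site_ori.append(ori)

    volume = 4.0 / 3.0 * np.pi * spec.region_radius**3
    n_bulk = rng.poisson(spec.bulk_density * volume, size=n)

    frames = []
    for i in range(n):
        ids, pos, ori = [], [], []
        for k in range(len(spec.sites)):
            if site_occ[k][i]:
                ids.append(k)
                pos.append(site_pos[k][i])
                ori.append(site_ori[k][i])
        nb = int(n_bulk[i])
        if nb:
            r = spec.region_radius * rng.random(nb) ** (1.0 / 3.0)
            bulk_xyz = center + r[:, None] * _uniform_sphere(rng, nb)
            bulk_ori = _uniform_sphere(rng, nb)
            ids.extend(range(1000, 1000 + nb))
            pos.extend(bulk_xyz)
            ori.extend(bulk_ori)
        frames.append(
            Frame(
                water_ids=np.array(ids, dtype=int),
                positions=np.array(pos, dtype=float).reshape(-1, 3),
                orientations=np.array(ori, dtype=float).reshape(-1, 3),
            )
        )
    return Trajectory(
        frames=frames,
        region_center=center,
        region_radius=spec.region_radius,
        temperature=spec.temperature,
    )


def pseudo_water_potential(epsilon: float = 0.15, sigma: float = 2.8, mu: float = 1.0):
    """Pair potential of the single-site pseudo-water, as a callable.

    Returns ``pair(pos_i, ori_i, pos_j, ori_j)`` evaluating, vectorised over
    j, LJ plus the dipolar term; pass ``ori_j=None`` for orientation-less
    solute particles (dipole-charge form -mu^2 (u_i . r_hat)/r^3).
    """

    def pair(pos_i, ori_i, pos_j, ori_j=None):
        pos_j = np.atleast_2d(np.asarray(pos_j, dtype=float))
        vec = pos_j - np.asarray(pos_i, dtype=float)
        r = np.maximum(np.linalg.norm(vec, axis=1), _R_MIN)
        sr6 = (sigma / r) ** 6
        e = 4.0 * epsilon * (sr6 * sr6 - sr6)
        if mu > 0:
            if ori_j is not None:
                ori_j = np.atleast_2d(np.asarray(ori_j, dtype=float))
                g = ori_j @ np.asarray(ori_i, dtype=float)
            else:
                g = (vec / r[:, None]) @ np.asarray(ori_i, dtype=float)
            e = e - mu * mu * g / r**3
        return e

    return pair


# ---------------------------------------------------------------------------
# Metropolis engines
# ---------------------------------------------------------------------------


@dataclass
class AlchemicalRun:
    """Output of one alchemical sampling run at a single temperature."""

    ladder: LambdaLadder
    temperature: float
    series: list[PerturbationSeries]
    acceptance_rate: float
    #: per-frame tagged end-state energies; keys 'A' (lambda=0 frames,
    #: A parameters) and 'B' (lambda=1 frames, B parameters)
    endstate_tables: dict[str, pd.DataFrame]
    #: retained configurations of the end-state chains, when stored:
    #: {'A': (positions, orientations or None), 'B': ...}
    endstate_frames: dict[str, tuple[np.ndarray, np.ndarray | None]] = field(
        default_factory=dict
    )

    def mean_endstate_energy(self, which: str) -> tuple[float, float]:
        """Mean total energy of an end-state ensemble with its block SEM."""
        from ._stats import block_sem

        tot = self.endstate_tables[which]["total"].to_numpy()
        return float(tot.mean()), block_sem(tot)


class _HarmonicSystem:
    def __init__(self, spec: HarmonicSpec):
        self.spec = spec
        self.d = spec.dimensionality
        self.ka, self.kb = spec.force_constant_a, spec.force_constant_b
        self.ca = np.full(self.d, float(spec.center_a))
        self.cb = np.full(self.d, float(spec.center_b))

    def initial_positions(self, lam: np.ndarray) -> np.ndarray:
        x = (1 - lam)[:, None] * self.ca + lam[:, None] * self.cb
        return x.copy()

    def u_a(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.ka * np.sum((x - self.ca) ** 2, axis=-1)

    def u_b(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.kb * np.sum((x - self.cb) ** 2, axis=-1)

    def u_lam(self, x: np.ndarray, lam: np.ndarray) -> np.ndarray:
        return (1 - lam) * self.u_a(x) + lam * self.u_b(x)


def _run_harmonic(
    spec: HarmonicSpec,
    lam: np.ndarray,
    beta: np.ndarray,
    n_steps: int,
    equil_fraction: float,
    sample_interval: int,
    rng: np.random.Generator,
    store_frames: Sequence[int] = (),
):
    sys_ = _HarmonicSystem(spec)
    nb = len(lam)
    x = sys_.initial_positions(lam)
    kbar = (1 - lam) * sys_.ka + lam * sys_.kb
    step = 2.0 * np.sqrt(1.0 / (beta * kbar))
    n_equil = int(equil_fraction * n_steps)
    du_rec, frame_rec = [], {i: [] for i in store_frames}
    n_acc = 0
    for t in range(n_steps):
        prop = x + rng.normal(size=(nb, sys_.d)) * step[:, None]
        du = sys_.u_lam(prop, lam) - sys_.u_lam(x, lam)
        acc = rng.random(nb) < np.exp(np.minimum(0.0, -beta * du))
        x[acc] = prop[acc]
        n_acc += int(acc.sum())
        if t >= n_equil and (t - n_equil) % sample_interval == 0:
            du_rec.append(sys_.u_b(x) - sys_.u_a(x))
            for i in store_frames:
                frame_rec[i].append(x[i].copy())
    records = {
        "du_ab": np.asarray(du_rec),
        "acceptance": n_acc / (n_steps * nb),
        "frames": {i: np.asarray(v) for i, v in frame_rec.items()},
        "system": sys_,
    }
    return records


class _HostGuestSystem:
    def __init__(self, spec: HostGuestSpec, rng: np.random.Generator):
        self.spec = spec
        nh, ng, ns = len(spec.host_particles), len(spec.guest_particles), spec.n_solvent
        self.nh, self.ng, self.ns = nh, ng, ns
        self.n = nh + ng + ns
        eps = np.zeros((2, self.n))
        sig = np.zeros((2, self.n))
        mu = np.zeros((2, self.n))
        pos0 = np.zeros((self.n, 3))
        for i, p in enumerate(spec.host_particles):
            pos0[i] = p.position
            eps[:, i], sig[:, i], mu[:, i] = p.epsilon, p.sigma, p.mu
        for k, g in enumerate(spec.guest_particles):
            i = nh + k
            pos0[i] = g.position
            eps[0, i], eps[1, i] = g.epsilon_a, g.epsilon_b
            sig[0, i], sig[1, i] = g.sigma_a, g.sigma_b
            mu[0, i], mu[1, i] = g.mu_a, g.mu_b
        # solvent placement: uniform with a short-range overlap rejection
        placed = 0
        attempts = 0
        min_sep = 0.85 * spec.solvent_sigma
        while placed < ns:
            attempts += 1
            if attempts > 20000:
                raise ValueError(
                    "could not place solvent without overlaps; "
                    "reduce n_solvent or density"
                )
            r = spec.sphere_radius * rng.random() ** (1.0 / 3.0)
            cand = r * _uniform_sphere(rng, 1)[0]
            prev = pos0[: nh + ng + placed]
            if len(prev) and np.min(np.linalg.norm(prev - cand, axis=1)) < min_sep:
                continue
            i = nh + ng + placed
            pos0[i] = cand
            eps[:, i], sig[:, i], mu[:, i] = (
                spec.solvent_epsilon,
                spec.solvent_sigma,
                spec.solvent_mu,
            )
            placed += 1
        # reject overlapping user-specified particles with a diagnostic
        fixed = pos0[: nh + ng]
        for i in range(nh + ng):
            for j in range(i + 1, nh + ng):
                sij = 0.5 * (sig[0, i] + sig[0, j])
                d = np.linalg.norm(fixed[i] - fixed[j])
                if sij > 0 and d < 0.5 * sij:
                    raise ValueError(
                        f"particles {i} and {j} overlap at initialization "
                        f"(separation {d:.2f} A < 0.5*sigma_ij {0.5 * sij:.2f} A)"
                    )
        self.pos0 = pos0
        self.anchors = pos0[nh : nh + ng].copy()
        # pairwise parameter matrices per state (Lorentz-Berthelot)
        self.EPS = np.sqrt(eps[:, :, None] * eps[:, None, :])
        self.SIG = 0.5 * (sig[:, :, None] + sig[:, None, :])
        self.MUMU = mu[:, :, None] * mu[:, None, :]
        self.oriented = np.zeros(self.n, dtype=bool)
        self.oriented[nh + ng :] = True
        self.is_guest = np.zeros(self.n, dtype=bool)
        self.is_guest[nh : nh + ng] = True
        self.is_host = np.zeros(self.n, dtype=bool)
        self.is_host[:nh] = True
        self.mobile = np.arange(nh, self.n)
        self.ip, self.jp = np.triu_indices(self.n, 1)
        gi = self.is_guest[self.ip]
        gj = self.is_guest[self.jp]
        hi = self.is_host[self.ip]
        hj = self.is_host[self.jp]
        si = self.oriented[self.ip]
        sj = self.oriented[self.jp]
        self.tag_masks = {
            "receptor_ligand": (gi & hj) | (gj & hi),
            "ligand_internal": gi & gj,
            "ligand_water": (gi & sj) | (gj & si),
            "surroundings": ~(gi | gj),
        }
        self.pair_both = si & sj
        self.pair_one_i = si & ~sj
        self.pair_one_j = sj & ~si
        self.ori_index = np.where(self.oriented, np.arange(self.n) - (nh + ng), -1)
        self._others = [
            np.concatenate([np.arange(j), np.arange(j + 1, self.n)])
            for j in range(self.n)
        ]

    # -- full-configuration energies -------------------------------------

    def pair_energies(self, pos, ori, state: int):
        """(B, n_pairs) pair energies under one end state's parameters."""
        vec = pos[:, self.jp] - pos[:, self.ip]
        r = np.maximum(np.linalg.norm(vec, axis=-1), _R_MIN)
        eps = self.EPS[state][self.ip, self.jp]
        sig = self.SIG[state][self.ip, self.jp]
        mumu = self.MUMU[state][self.ip, self.jp]
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
        e = 4.0 * eps * (sr6 * sr6 - sr6)
        g = np.ones_like(r)
        m = self.pair_both
        if m.any():
            ui = ori[:, self.ori_index[self.ip[m]]]
            uj = ori[:, self.ori_index[self.jp[m]]]
            g[:, m] = np.sum(ui * uj, axis=-1)
        m = self.pair_one_i
        if m.any():
            ui = ori[:, self.ori_index[self.ip[m]]]
            g[:, m] = np.sum(ui * vec[:, m], axis=-1) / r[:, m]
        m = self.pair_one_j
        if m.any():
            uj = ori[:, self.ori_index[self.jp[m]]]
            g[:, m] = -np.sum(uj * vec[:, m], axis=-1) / r[:, m]
        return e - mumu * g / r**3

    def bond_energy(self, pos, state: int):
        if self.spec.guest_bond is None:
            return np.zeros(pos.shape[0])
        ka, r0a, kb, r0b = self.spec.guest_bond
        k, r0 = (ka, r0a) if state == 0 else (kb, r0b)
        rb = np.linalg.norm(pos[:, self.nh + 1] - pos[:, self.nh], axis=-1)
        return 0.5 * k * (rb - r0) ** 2

    def restraint_energy(self, pos):
        if self.spec.restraint_constant == 0.0 or self.ng == 0:
            return np.zeros(pos.shape[0])
        d2 = np.sum(
            (pos[:, self.nh : self.nh + self.ng] - self.anchors) ** 2, axis=(-2, -1)
        )
        return 0.5 * self.spec.restraint_constant * d2

    def tagged_energies(self, pos, ori, state: int) -> dict[str, np.ndarray]:
        e = self.pair_energies(pos, ori, state)
        out = {k: e[:, m].sum(axis=1) for k, m in self.tag_masks.items()}
        out["ligand_internal"] = out["ligand_internal"] + self.bond_energy(pos, state)
        out["restraint"] = self.restraint_energy(pos)
        out["total"] = sum(out[k] for k in _TAG_KEYS) + out["restraint"]
        return out

    # -- single-particle energy for MC moves ------------------------------

    def one_particle_energy_blend(self, pos, ori, j: int, xj, uj, lam):
        """lambda-blended energy of particle j with everything else, (B,).

        A- and B-state terms share the pair geometry; the blend
        (1-lam) e_A + lam e_B follows the linear coupling.
        """
        others = self._others[j]
        vec = pos[:, others] - xj[:, None, :]
        r = np.maximum(np.linalg.norm(vec, axis=-1), _R_MIN)
        inv_r3 = 1.0 / r**3
        g = np.ones_like(r)
        j_or = self.oriented[j]
        o_or = self.oriented[others]
        if j_or:
            m = o_or
            if m.any():
                uo = ori[:, self.ori_index[others[m]]]
                g[:, m] = np.sum(uo * uj[:, None, :], axis=-1)
            m = ~o_or
            if m.any():
                g[:, m] = np.sum(uj[:, None, :] * vec[:, m], axis=-1) / r[:, m]
        else:
            m = o_or
            if m.any():
                uo = ori[:, self.ori_index[others[m]]]
                g[:, m] = -np.sum(uo * vec[:, m], axis=-1) / r[:, m]
        e_states = []
        for state in (0, 1):
            eps = self.EPS[state][j, others]
            sig = self.SIG[state][j, others]
            mumu = self.MUMU[state][j, others]
            sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
            e = np.sum(4.0 * eps * (sr6 * sr6 - sr6) - mumu * g * inv_r3, axis=-1)
            if self.is_guest[j]:
                gk = j - self.nh
                if self.spec.guest_bond is not None and gk in (0, 1):
                    ka, r0a, kb, r0b = self.spec.guest_bond
                    k, r0 = (ka, r0a) if state == 0 else (kb, r0b)
                    partner = self.nh + (1 - gk)
                    rb = np.linalg.norm(pos[:, partner] - xj, axis=-1)
                    e = e + 0.5 * k * (rb - r0) ** 2
            e_states.append(e)
        e = (1.0 - lam) * e_states[0] + lam * e_states[1]
        if self.is_guest[j] and self.spec.restraint_constant:
            gk = j - self.nh
            e = e + 0.5 * self.spec.restraint_constant * np.sum(
                (xj - self.anchors[gk]) ** 2, axis=-1
            )
        return e

    def reflect(self, x):
        """Radial reflection at the spherical wall."""
        r = np.linalg.norm(x, axis=-1)
        out = r > self.spec.sphere_radius
        if out.any():
            scale = (2.0 * self.spec.sphere_radius - r[out]) / r[out]
            scale = np.maximum(scale, 0.0)
            x = x.copy()
            x[out] = x[out] * scale[:, None]
        return x


def _run_hostguest(
    spec: HostGuestSpec,
    lam: np.ndarray,
    beta: np.ndarray,
    n_steps: int,
    equil_fraction: float,
    sample_interval: int,
    rng: np.random.Generator,
    store_frames: Sequence[int] = (),
):
    sys_ = _HostGuestSystem(spec, rng)
    nb = len(lam)
    pos = np.tile(sys_.pos0, (nb, 1, 1))
    ori = _uniform_sphere(rng, nb * sys_.ns).reshape(nb, sys_.ns, 3)
    n_equil = int(equil_fraction * n_steps)
    rec = {
        k: []
        for k in (
            "du_ab",
            *(f"{t}_A" for t in _TAG_KEYS),
            *(f"{t}_B" for t in _TAG_KEYS),
            "restraint",
            "total_A",
            "total_B",
        )
    }
    frame_rec = {i: ([], []) for i in store_frames}
    n_acc = 0
    n_try = 0
    n_mob = len(sys_.mobile)
    use_kernel = _kernel.HAVE_NUMBA
    mobile = np.asarray(sys_.mobile, dtype=np.int64)
    ori_index = sys_.ori_index.astype(np.int64)
    bond = sys_.spec.guest_bond or (0.0, 0.0, 0.0, 0.0)
    for t in range(n_steps):
        trans_disp = rng.normal(size=(n_mob, nb, 3)) * _TRANS_STEP
        trans_u = rng.random((n_mob, nb))
        rot_disp = rng.normal(size=(sys_.ns, nb, 3)) * _ROT_STEP
        rot_u = rng.random((sys_.ns, nb))
        if use_kernel:
            n_acc += _kernel.sweep(
                pos, ori, lam, beta,
                sys_.EPS[0], sys_.EPS[1], sys_.SIG[0], sys_.SIG[1],
                sys_.MUMU[0], sys_.MUMU[1],
                sys_.oriented, ori_index, sys_.is_guest, sys_.anchors,
                sys_.nh, sys_.ng, float(spec.restraint_constant),
                spec.guest_bond is not None, *map(float, bond),
                float(spec.sphere_radius), mobile,
                trans_disp, trans_u, rot_disp, rot_u,
            )
        else:
            for m, j in enumerate(sys_.mobile):
                xj = pos[:, j]
                uj = ori[:, sys_.ori_index[j]] if sys_.oriented[j] else None
                prop = sys_.reflect(xj + trans_disp[m])
                e0 = sys_.one_particle_energy_blend(pos, ori, j, xj, uj, lam)
                e1 = sys_.one_particle_energy_blend(pos, ori, j, prop, uj, lam)
                du = e1 - e0
                acc = (du <= 0.0) | (trans_u[m] < np.exp(np.minimum(0.0, -beta * du)))
                pos[acc, j] = prop[acc]
                n_acc += int(acc.sum())
            for oj in range(sys_.ns):
                j = sys_.nh + sys_.ng + oj
                xj = pos[:, j]
                uj = ori[:, oj]
                uprop = uj + rot_disp[oj]
                uprop = uprop / np.linalg.norm(uprop, axis=-1, keepdims=True)
                e0 = sys_.one_particle_energy_blend(pos, ori, j, xj, uj, lam)
                e1 = sys_.one_particle_energy_blend(pos, ori, j, xj, uprop, lam)
                du = e1 - e0
                acc = (du <= 0.0) | (rot_u[oj] < np.exp(np.minimum(0.0, -beta * du)))
                ori[acc, oj] = uprop[acc]
                n_acc += int(acc.sum())
        n_try += nb * (n_mob + sys_.ns)
        if t >= n_equil and (t - n_equil) % sample_interval == 0:
            ta = sys_.tagged_energies(pos, ori, 0)
            tb = sys_.tagged_energies(pos, ori, 1)
            rec["du_ab"].append(tb["total"] - ta["total"])
            for k in _TAG_KEYS:
                rec[f"{k}_A"].append(ta[k])
                rec[f"{k}_B"].append(tb[k])
            rec["restraint"].append(ta["restraint"])
            rec["total_A"].append(ta["total"])
            rec["total_B"].append(tb["total"])
            for i in store_frames:
                frame_rec[i][0].append(pos[i].copy())
                frame_rec[i][1].append(ori[i].copy())
    records = {k: np.asarray(v) for k, v in rec.items()}
    records["acceptance"] = n_acc / max(n_try, 1)
    records["frames"] = {
        i: (np.asarray(p), np.asarray(o)) for i, (p, o) in frame_rec.items()
    }
    records["system"] = sys_
    return records


# ---------------------------------------------------------------------------
# public sampling API
# ---------------------------------------------------------------------------


def _harmonic_endstate_table(sys_: _HarmonicSystem, frames: np.ndarray, which: str):
    u = sys_.u_a(frames) if which == "A" else sys_.u_b(frames)
    n = len(frames)
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "receptor_ligand": np.zeros(n),
            "ligand_internal": u,
            "ligand_water": np.zeros(n),
            "surroundings": np.zeros(n),
            "total": u,
        }
    )


def _series_from_du(
    du_ab: np.ndarray, ladder: LambdaLadder, temperature: float
) -> list[PerturbationSeries]:
    lams = np.asarray(ladder.lambdas)
    out = []
    for i in range(ladder.n_windows):
        width = lams[i + 1] - lams[i]
        out.append(
            PerturbationSeries(
                window_index=i,
                lam=float(lams[i]),
                delta_u=width * du_ab[:, i],
                temperature=temperature,
            )
        )
    return out


def sample_alchemical_path(
    spec: HarmonicSpec | HostGuestSpec,
    ladder: LambdaLadder | None = None,
    n_steps: int = 20000,
    equil_fraction: float = 0.1,
    seed: int = 0,
    sample_interval: int = 1,
    store_frames: bool = True,
) -> AlchemicalRun:
    """Sample every lambda state and emit per-window perturbation series.

    Every state in the ladder runs as an independent Metropolis chain (all
    chains are propagated in one vectorised batch); window ``i`` collects
    dU = U_{lambda_{i+1}} - U_{lambda_i} on the frames of chain ``i`` after
    the equilibration fraction is discarded.  With the linear coupling
    U_lambda = (1-lambda) U_A + lambda U_B this is (dlambda_i)(U_B - U_A).
    Identical seeds give bit-identical output.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if not 0.0 <= equil_fraction < 1.0:
        raise ValueError("equil_fraction must lie in [0, 1)")
    if ladder is None:
        ladder = LambdaLadder.evenly_spaced()
    rng = np.random.default_rng(seed)
    lam = np.asarray(ladder.lambdas)
    beta = np.full(len(lam), 1.0 / (K_B * spec.temperature))
    endpoints = (0, len(lam) - 1) if store_frames else ()
    if isinstance(spec, HarmonicSpec):
        recs = _run_harmonic(
            spec, lam, beta, n_steps, equil_fraction, sample_interval, rng, endpoints
        )
        sys_ = recs["system"]
        tables = {}
        frames = {}
        if store_frames:
            fa, fb = recs["frames"][0], recs["frames"][len(lam) - 1]
            tables["A"] = _harmonic_endstate_table(sys_, fa, "A")
            tables["B"] = _harmonic_endstate_table(sys_, fb, "B")
            frames = {"A": (fa, None), "B": (fb, None)}
    else:
        recs = _run_hostguest(
            spec, lam, beta, n_steps, equil_fraction, sample_interval, rng, endpoints
        )
        tables = {}
        frames = {}
        if store_frames:
            tables["A"] = _hostguest_endstate_table(recs, 0, "A")
            tables["B"] = _hostguest_endstate_table(recs, len(lam) - 1, "B")
            fa = recs["frames"][0]
            fb = recs["frames"][len(lam) - 1]
            frames = {"A": fa, "B": fb}
    series = _series_from_du(recs["du_ab"], ladder, spec.temperature)
    return AlchemicalRun(
        ladder=ladder,
        temperature=spec.temperature,
        series=series,
        acceptance_rate=float(recs["acceptance"]),
        endstate_tables=tables,
        endstate_frames=frames,
    )


def _hostguest_endstate_table(recs, chain: int, which: str) -> pd.DataFrame:
    s = which
    n = recs["du_ab"].shape[0]
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "receptor_ligand": recs[f"receptor_ligand_{s}"][:, chain],
            "ligand_internal": recs[f"ligand_internal_{s}"][:, chain],
            "ligand_water": recs[f"ligand_water_{s}"][:, chain],
            "surroundings": recs[f"surroundings_{s}"][:, chain],
            "restraint": recs["restraint"][:, chain],
            "total": recs[f"total_{s}"][:, chain],
        }
    )


def sample_alchemical_scan(
    spec: HostGuestSpec | HarmonicSpec,
    ladder: LambdaLadder,
    temperatures: Sequence[float],
    n_replicates: int = 3,
    n_steps: int = 20000,
    equil_fraction: float = 0.1,
    seed: int = 0,
    sample_interval: int = 1,
) -> dict[tuple[float, int], AlchemicalRun]:
    """Alchemical runs at several temperatures and replicate seeds.

    All (temperature, replicate, lambda) chains propagate in one vectorised
    batch, which keeps multi-temperature van't Hoff scans affordable; the
    result maps (temperature, replicate) to an :class:`AlchemicalRun`
    (end-state configurations are not stored in scans).
    """
    rng = np.random.default_rng(seed)
    lams = np.asarray(ladder.lambdas)
    nl = len(lams)
    combos = [(float(t), r) for t in temperatures for r in range(n_replicates)]
    lam = np.concatenate([lams for _ in combos])
    beta = np.concatenate(
        [np.full(nl, 1.0 / (K_B * t)) for (t, _) in combos]
    )
    if isinstance(spec, HarmonicSpec):
        recs = _run_harmonic(
            spec, lam, beta, n_steps, equil_fraction, sample_interval, rng
        )
    else:
        recs = _run_hostguest(
            spec, lam, beta, n_steps, equil_fraction, sample_interval, rng
        )
    out = {}
    for c, (t, r) in enumerate(combos):
        sl = slice(c * nl, (c + 1) * nl)
        du = recs["du_ab"][:, sl]
        tables = {}
        if not isinstance(spec, HarmonicSpec):
            sub = {
                k: v[:, sl]
                for k, v in recs.items()
                if isinstance(v, np.ndarray) and v.ndim == 2
            }
            sub["du_ab"] = du
            tables = {
                "A": _hostguest_endstate_table(sub, 0, "A"),
                "B": _hostguest_endstate_table(sub, nl - 1, "B"),
            }
        lams_t = np.asarray(ladder.lambdas)
        series = []
        for i in range(ladder.n_windows):
            series.append(
                PerturbationSeries(
                    window_index=i,
                    lam=float(lams_t[i]),
                    delta_u=(lams_t[i + 1] - lams_t[i]) * du[:, i],
                    temperature=t,
                )
            )
        out[(t, r)] = AlchemicalRun(
            ladder=ladder,
            temperature=t,
            series=series,
            acceptance_rate=float(recs["acceptance"]),
            endstate_tables=tables,
            endstate_frames={},
        )
    return out


def hostguest_benchmark(bound: bool = True, temperature: float = 300.0) -> HostGuestSpec:
    """The standard toy host-guest benchmark pair.

    The bound leg holds two guest particles near a fixed two-particle host
    inside a 6.5 A solvent sphere, tethered by a weak positional restraint;
    the unbound leg is the same guest in solvent alone.  The alchemical
    transformation deepens the guest's dispersion well and strengthens its
    dipolar coupling and internal bond — a caricature of growing a polar
    substituent — giving a relative free energy with non-trivial enthalpy
    in both legs.
    """
    guests = (
        GuestParticle((0.0, 2.6, 0.0), 0.2, 0.4, 3.0, 3.0, 0.4, 1.0),
        GuestParticle((1.2, 3.2, 1.0), 0.2, 0.3, 2.9, 2.9, 0.2, 0.6),
    )
    host = (
        (
            Particle((0.0, 0.0, 0.0), 0.3, 3.0, 3.0),
            Particle((2.8, 0.0, 0.0), 0.3, 3.0, 3.0),
        )
        if bound
        else ()
    )
    return HostGuestSpec(
        host_particles=host,
        guest_particles=guests,
        n_solvent=18,
        sphere_radius=6.5,
        restraint_constant=2.0,
        temperature=temperature,
        guest_bond=(10.0, 1.6, 15.0, 1.5),
    )


def sample_harmonic_positions(
    spec: HarmonicSpec,
    lam: float = 0.0,
    n_steps: int = 20000,
    equil_fraction: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Retained positions of a single harmonic chain (for diagnostics)."""
    rng = np.random.default_rng(seed)
    recs = _run_harmonic(
        spec,
        np.array([lam]),
        np.array([1.0 / (K_B * spec.temperature)]),
        n_steps,
        equil_fraction,
        1,
        rng,
        store_frames=(0,),
    )
    return recs["frames"][0].reshape(-1, spec.dimensionality)
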