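"""Hydration-site structure and thermodynamics.

Water positions accumulated over trajectory frames are clustered into
discrete hydration sites; each site is then characterised by its occupancy,
its mean interaction energy with other waters (E_ww) and with the solute
(E_sw), and translational/orientational entropies relative to bulk water
estimated with nearest-neighbour estimators in the spirit of inhomogeneous
solvation theory.  Site networks from two complexes can be matched and
differenced to locate where binding-induced reorganisation of the water
structure pays or costs energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .constants import K_B
from ._stats import kl_entropy, sphere_nn_entropy

_UNIT_TOL = 1e-6


@dataclass
class Frame:
    """One trajectory snapshot: rigid solute plus pseudo-waters.

    Each water carries a persistent integer id, a position (A) and a unit
    orientation vector.
    """

    water_ids: np.ndarray
    positions: np.ndarray
    orientations: np.ndarray
    solute_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.water_ids = np.asarray(self.water_ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        if not (
            len(self.water_ids) == len(self.positions) == len(self.orientations)
        ):
            raise ValueError("water ids, positions and orientations disagree in length")
        if len(self.orientations):
            norms = np.linalg.norm(self.orientations, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-3):
                raise ValueError("orientation vectors must be unit norm")
            if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
                self.orientations = self.orientations / norms[:, None]
        if self.solute_positions is not None:
            self.solute_positions = np.asarray(
                self.solute_positions, dtype=float
            ).reshape(-1, 3)


@dataclass
class Trajectory:
    """A sequence of frames over a fixed spherical analysis region."""

    frames: list[Frame]
    region_center: np.ndarray
    region_radius: float
    temperature: float

    def __post_init__(self) -> None:
        self.region_center = np.asarray(self.region_center, dtype=float).reshape(3)
        if self.region_radius <= 0:
            raise ValueError("region radius must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for i, f in enumerate(self.frames):
            if len(f.positions):
                r = np.linalg.norm(f.positions - self.region_center, axis=1)
                if np.any(r > self.region_radius + 1e-6):
                    raise ValueError(f"frame {i} has waters outside the region")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class HydrationSite:
    """A localized high-occupancy water position.

    Energies are kcal/mol, entropies kcal/(mol K) relative to bulk;
    they are ``None`` until filled in by :func:`site_energies` /
    :func:`site_entropy` (see :func:`analyze_sites`).
    """

    site_id: int
    center: np.ndarray
    occupancy: float
    n_frames_occupied: int
    e_ww: float | None = None
    e_sw: float | None = None
    s_trans: float | None = None
    s_orient: float | None = None
    minus_t_ds: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


def _pooled_observations(traj: Trajectory):
    pos, frame_idx, wid = [], [], []
    for i, f in enumerate(traj.frames):
        if len(f.positions):
            pos.append(f.positions)
            frame_idx.append(np.full(len(f.positions), i))
            wid.append(f.water_ids)
    if not pos:
        raise ValueError("trajectory contains no waters")
    return np.vstack(pos), np.concatenate(frame_idx), np.concatenate(wid)


def cluster_sites(
    traj: Trajectory,
    site_radius: float = 1.0,
    min_occupancy: float = 0.5,
) -> list[HydrationSite]:
    """Greedy density clustering of pooled water observations.

    The observation with the largest number of water observations within
    ``site_radius`` (over all frames) becomes a site center; its claimed
    observations are removed and the search repeats until the best remaining
    candidate's occupancy falls below ``min_occupancy``.  Ties are broken by
    the lowest (frame, water_id) pair, making the procedure deterministic.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if traj.n_frames < 100:
        warnings.warn(
            f"only {traj.n_frames} frames; occupancies will be noisy", stacklevel=2
        )
    pos, frame_idx, wid = _pooled_observations(traj)
    n_frames = traj.n_frames
    alive = np.ones(len(pos), dtype=bool)
    sites: list[HydrationSite] = []
    while alive.any():
        p = pos[alive]
        tree = cKDTree(p)
        counts = tree.query_ball_point(p, r=site_radius, return_length=True)
        best = counts.max()
        # distinct-frame occupancy of the best candidate(s)
        cand = np.flatnonzero(counts == best)
        f_alive = frame_idx[alive]
        w_alive = wid[alive]
        order = np.lexsort((w_alive[cand], f_alive[cand]))
        pick = cand[order[0]]
        members = tree.query_ball_point(p[pick], r=site_radius)
        occ_frames = np.unique(f_alive[members])
        occupancy = len(occ_frames) / n_frames
        if occupancy < min_occupancy:
            break
        sites.append(
            HydrationSite(
                site_id=len(sites),
                center=p[pick].copy(),
                occupancy=occupancy,
                n_frames_occupied=len(occ_frames),
            )
        )
        alive_idx = np.flatnonzero(alive)
        alive[alive_idx[members]] = False
    return sites


def _site_water_in_frame(frame: Frame, center: np.ndarray, site_radius: float):
    """Index of the frame's water occupying the site, or None."""
    if not len(frame.positions):
        return None
    d = np.linalg.norm(frame.positions - center, axis=1)
    inside = np.flatnonzero(d <= site_radius)
    if not len(inside):
        return None
    # nearest wins; tie-break on lowest water id
    order = np.lexsort((frame.water_ids[inside], d[inside]))
    return inside[order[0]]


def site_energies(
    site: HydrationSite,
    traj: Trajectory,
    pair_potential,
    site_radius: float = 1.0,
) -> HydrationSite:
    """Mean interaction energies of the site water over occupied frames.

    ``pair_potential(pos_i, ori_i, pos_j, ori_j)`` must return per-pair
    energies for one water against arrays of positions (``ori_j=None`` for
    orientation-less solute particles).  The full pair energy is assigned to
    the site water (no 1/2 factor).  Frames where the site is unoccupied do
    not contribute.
    """
    e_ww_frames, e_sw_frames = [], []
    for frame in traj.frames:
        idx = _site_water_in_frame(frame, site.center, site_radius)
        if idx is None:
            continue
        others = np.arange(len(frame.positions)) != idx
        if others.any():
            e_ww_frames.append(
                float(
                    np.sum(
                        pair_potential(
                            frame.positions[idx],
                            frame.orientations[idx],
                            frame.positions[others],
                            frame.orientations[others],
                        )
                    )
                )
            )
        else:
            e_ww_frames.append(0.0)
        solute = frame.solute_positions
        if solute is not None and len(solute):
            e_sw_frames.append(
                float(
                    np.sum(
                        pair_potential(
                            frame.positions[idx],
                            frame.orientations[idx],
                            solute,
                            None,
                        )
                    )
                )
            )
        else:
            e_sw_frames.append(0.0)
    if not e_ww_frames:
        raise ValueError(f"site {site.site_id} is never occupied")
    return replace(
        site,
        e_ww=float(np.mean(e_ww_frames)),
        e_sw=float(np.mean(e_sw_frames)),
    )


def site_entropy(
    site: HydrationSite,
    traj: Trajectory,
    bulk_density: float,
    site_radius: float = 1.0,
) -> HydrationSite:
    """Translational and orientational entropy of a site relative to bulk.

    The site water's positions across occupied frames define a spatial
    distribution p(x); its time-averaged local density is occupancy * p(x),
    and S_trans = -k_B <ln(rho_local/rho_bulk)> = k_B (H[p] - ln(occ/rho_bulk))
    with H[p] estimated by the k=1 nearest-neighbour (Kozachenko-Leonenko)
    estimator.  S_orient = k_B (H[u] - ln 4pi) compares the orientation
    distribution against uniform on the sphere.  Both vanish for a bulk-like
    site and go negative as the water localises or aligns.
    """
    if bulk_density <= 0:
        raise ValueError("bulk density must be positive")
    positions, orientations = [], []
    for frame in traj.frames:
        idx = _site_water_in_frame(frame, site.center, site_radius)
        if idx is not None:
            positions.append(frame.positions[idx])
            orientations.append(frame.orientations[idx])
    n_occ = len(positions)
    if n_occ < 2:
        raise ValueError(f"site {site.site_id}: insufficient occupancy ({n_occ})")
    if n_occ < 20:
        warnings.warn(
            f"site {site.site_id}: only {n_occ} occupied frames; entropies noisy",
            stacklevel=2,
        )
    positions = np.asarray(positions)
    orientations = np.asarray(orientations)
    occupancy = n_occ / traj.n_frames
    h_trans = kl_entropy(positions)
    s_trans = K_B * (h_trans - np.log(occupancy / bulk_density))
    h_orient = sphere_nn_entropy(orientations)
    s_orient = K_B * (h_orient - np.log(4.0 * np.pi))
    return replace(
        site,
        s_trans=float(s_trans),
        s_orient=float(s_orient),
        minus_t_ds=float(-traj.temperature * (s_trans + s_orient)),
    )


def analyze_sites(
    traj: Trajectory,
    pair_potential,
    bulk_density: float,
    site_radius: float = 1.0,
    min_occupancy: float = 0.5,
) -> list[HydrationSite]:
    """Cluster and fully characterise the hydration sites of a trajectory."""
    sites = cluster_sites(traj, site_radius, min_occupancy)
    out = []
    for s in sites:
        s = site_energies(s, traj, pair_potential, site_radius)
        s = site_entropy(s, traj, bulk_density, site_radius)
        out.append(s)
    return out


@dataclass(frozen=True)
class SiteMatch:
    """One matched pair of hydration sites across two complexes (B - A)."""

    a_id: int
    b_id: int
    distance: float
    d_e_ww: float
    d_e_pw: float
    d_minus_t_ds: float

    @property
    def d_e_surroundings(self) -> float:
        return self.d_e_ww + self.d_e_pw


@dataclass
class NetworkComparison:
    """Difference of two hydration networks (state B relative to A).

    Sites present only in A are "displaced" in B and contribute the loss of
    their full energies to the totals; B-only sites contribute their gain.
    ``d_e_total`` = d_e_ww_total + d_e_pw_total holds exactly.
    """

    matches: list[SiteMatch]
    displaced_site_ids: list[int]
    b_only_site_ids: list[int]
    d_e_ww_total: float
    d_e_pw_total: float
    d_minus_t_ds_total: float = 0.0

    @property
    def d_e_total(self) -> float:
        return self.d_e_ww_total + self.d_e_pw_total


def _val(x: float | None) -> float:
    return 0.0 if x is None else float(x)


def compare_networks(
    sites_a: list[HydrationSite],
    sites_b: list[HydrationSite],
    match_radius: float = 1.5,
) -> NetworkComparison:
    """Greedy one-to-one nearest-center matching and energy differencing.

    Pairs are formed in order of increasing center distance until no pair
    closer than ``match_radius`` remains; unmatched A-sites are flagged as
    displaced.  Energy and entropy differences are B minus A.
    """
    pairs = []
    for i, sa in enumerate(sites_a):
        for j, sb in enumerate(sites_b):
            d = float(np.linalg.norm(sa.center - sb.center))
            if d <= match_radius:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[SiteMatch] = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        sa, sb = sites_a[i], sites_b[j]
        matches.append(
            SiteMatch(
                a_id=sa.site_id,
                b_id=sb.site_id,
                distance=d,
                d_e_ww=_val(sb.e_ww) - _val(sa.e_ww),
                d_e_pw=_val(sb.e_sw) - _val(sa.e_sw),
                d_minus_t_ds=_val(sb.minus_t_ds) - _val(sa.minus_t_ds),
            )
        )
    displaced = [s.site_id for i, s in enumerate(sites_a) if i not in used_a]
    b_only = [s.site_id for j, s in enumerate(sites_b) if j not in used_b]
    d_ww = sum(m.d_e_ww for m in matches)
    d_pw = sum(m.d_e_pw for m in matches)
    d_ts = sum(m.d_minus_t_ds for m in matches)
    for i, s in enumerate(sites_a):
        if i not in used_a:
            d_ww -= _val(s.e_ww)
            d_pw -= _val(s.e_sw)
            d_ts -= _val(s.minus_t_ds)
    for j, s in enumerate(sites_b):
        if j not in used_b:
            d_ww += _val(s.e_ww)
            d_pw += _val(s.e_sw)
            d_ts += _val(s.minus_t_ds)
    return NetworkComparison(
        matches=matches,
        displaced_site_ids=displaced,
        b_only_site_ids=b_only,
        d_e_ww_total=float(d_ww),
        d_e_pw_total=float(d_pw),
        d_minus_t_ds_total=float(d_ts),
    )
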