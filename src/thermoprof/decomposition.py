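"""Enthalpy decomposition into ligand and surroundings contributions.

Neglecting the pressure-volume term, the relative binding enthalpy splits as

    ddH ~= ddU_L + ddU_S,

where ddU_L collects the terms that involve the ligand (receptor-ligand
interaction, ligand internal/strain energy, and ligand desolvation) and can
be averaged directly from end-state trajectories, while ddU_S — everything
within the surroundings (receptor, membrane, solvent) — converges far too
slowly for direct averaging and is obtained indirectly as ddH - ddU_L with
ddH taken from van't Hoff analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import block_sem
from .fep import RelativeBindingFreeEnergy
from .vanthoff import VantHoffProfile

#: Energy-term columns of a tagged end-state energy table.
TAG_COLUMNS = ("receptor_ligand", "ligand_internal", "ligand_water")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class LigandEnergyComponents:
    """Components of the ligand contribution ddU_L (kcal/mol).

    All values are B-minus-A differences between the two ligands.
    ``desolvation`` = ligand_water_bound - ligand_water_unbound, and
    ``ddu_l`` = receptor_ligand + ligand_internal + desolvation; both
    identities hold exactly by construction.
    """

    receptor_ligand: float
    ligand_internal: float
    ligand_water_bound: float
    ligand_water_unbound: float
    sem_receptor_ligand: float = 0.0
    sem_ligand_internal: float = 0.0
    sem_ligand_water_bound: float = 0.0
    sem_ligand_water_unbound: float = 0.0

    @property
    def desolvation(self) -> float:
        return self.ligand_water_bound - self.ligand_water_unbound

    @property
    def ddu_l(self) -> float:
        return self.receptor_ligand + self.ligand_internal + self.desolvation

    @property
    def sem_desolvation(self) -> float:
        return float(np.hypot(self.sem_ligand_water_bound, self.sem_ligand_water_unbound))

    @property
    def sem_ddu_l(self) -> float:
        return float(
            np.sqrt(
                self.sem_receptor_ligand**2
                + self.sem_ligand_internal**2
                + self.sem_desolvation**2
            )
        )


@dataclass(frozen=True)
class EnthalpyDecomposition:
    """ddH split into ligand (ddU_L) and surroundings (ddU_S) parts."""

    ddh: float
    ddu_l: float
    sem_ddh: float = 0.0
    sem_ddu_l: float = 0.0

    @property
    def ddu_s(self) -> float:
        return self.ddh - self.ddu_l

    @property
    def sem_ddu_s(self) -> float:
        return float(np.hypot(self.sem_ddh, self.sem_ddu_l))


@dataclass(frozen=True)
class ThermodynamicProfile:
    """Side-by-side ddG / ddH / -TddS profile at one temperature.

    ``ddg`` is assembled as ddH + (-T ddS), so the additivity identity is
    exact; ``ddg_input`` keeps the independently computed free energy and
    ``consistent`` flags whether the two agree within the combined SEM.
    """

    ddh: float
    minus_t_dds: float
    temperature: float
    ddg_input: float
    discrepancy: float
    consistent: bool

    @property
    def ddg(self) -> float:
        return self.ddh + self.minus_t_dds


def _mean_terms(table: pd.DataFrame, require_receptor: bool) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for col in TAG_COLUMNS:
        if col not in table.columns:
            if col == "receptor_ligand" and not require_receptor:
                out[col] = (0.0, 0.0)
                continue
            raise ValueError(f"energy table is missing tagged column '{col}'")
        vals = table[col].to_numpy(dtype=float)
        out[col] = (float(vals.mean()), block_sem(vals))
    return out


def ligand_components(
    bound_a: pd.DataFrame,
    bound_b: pd.DataFrame,
    unbound_a: pd.DataFrame,
    unbound_b: pd.DataFrame,
) -> LigandEnergyComponents:
    """ddU_L from tagged per-frame end-state energy tables.

    Each table carries per-frame energies tagged ``receptor_ligand``,
    ``ligand_internal`` and ``ligand_water`` (unbound tables may omit the
    receptor term).  Every component is the B-minus-A difference of time
    averages, differenced again between bound and unbound states where both
    contribute; SEMs come from block averaging and add in quadrature.
    """
    ba = _mean_terms(bound_a, require_receptor=True)
    bb = _mean_terms(bound_b, require_receptor=True)
    ua = _mean_terms(unbound_a, require_receptor=False)
    ub = _mean_terms(unbound_b, require_receptor=False)

    rl = bb["receptor_ligand"][0] - ba["receptor_ligand"][0]
    sem_rl = float(np.hypot(bb["receptor_ligand"][1], ba["receptor_ligand"][1]))
    # strain: internal-energy change on binding, differenced between ligands
    internal = (bb["ligand_internal"][0] - ba["ligand_internal"][0]) - (
        ub["ligand_internal"][0] - ua["ligand_internal"][0]
    )
    sem_internal = float(
        np.sqrt(
            sum(
                t["ligand_internal"][1] ** 2
                for t in (ba, bb, ua, ub)
            )
        )
    )
    lw_bound = bb["ligand_water"][0] - ba["ligand_water"][0]
    sem_lw_bound = float(np.hypot(bb["ligand_water"][1], ba["ligand_water"][1]))
    lw_unbound = ub["ligand_water"][0] - ua["ligand_water"][0]
    sem_lw_unbound = float(np.hypot(ub["ligand_water"][1], ua["ligand_water"][1]))
    return LigandEnergyComponents(
        receptor_ligand=rl,
        ligand_internal=internal,
        ligand_water_bound=lw_bound,
        ligand_water_unbound=lw_unbound,
        sem_receptor_ligand=sem_rl,
        sem_ligand_internal=sem_internal,
        sem_ligand_water_bound=sem_lw_bound,
        sem_ligand_water_unbound=sem_lw_unbound,
    )


def surroundings_energy(
    ddh: float,
    ddu_l: float,
    sem_ddh: float = 0.0,
    sem_ddu_l: float = 0.0,
) -> EnthalpyDecomposition:
    """Indirect surroundings contribution: ddU_S = ddH - ddU_L.

    ddH comes from van't Hoff analysis, ddU_L from direct trajectory
    averages; SEMs combine in quadrature.
    """
    if not (np.isfinite(ddh) and np.isfinite(ddu_l)):
        raise ValueError("ddH and ddU_L must be finite")
    return EnthalpyDecomposition(
        ddh=float(ddh), ddu_l=float(ddu_l), sem_ddh=sem_ddh, sem_ddu_l=sem_ddu_l
    )


def assemble_profile(
    ddg: RelativeBindingFreeEnergy | float,
    profile: VantHoffProfile,
    ddg_sem: float = 0.0,
    temperature: float | None = None,
) -> ThermodynamicProfile:
    """Combine a computed ddG with a van't Hoff profile at T_ref.

    The profile's ddH + (-T_ref ddS) is compared against the independently
    computed ddG; the consistency flag is raised when the discrepancy
    exceeds the combined SEM (with a 1e-9 floor for exact inputs).
    """
    if isinstance(ddg, RelativeBindingFreeEnergy):
        ddg_value = ddg.ddg
        ddg_sem = ddg.sem
        temperature = ddg.temperature if temperature is None else temperature
    else:
        ddg_value = float(ddg)
    t = profile.t_ref if temperature is None else temperature
    if abs(t - profile.t_ref) > 1e-9:
        raise ValueError(
            f"temperature mismatch: ddG at {t} K, profile referenced at "
            f"{profile.t_ref} K"
        )
    assembled = profile.ddh + profile.minus_t_dds_at_ref
    discrepancy = abs(ddg_value - assembled)
    combined_sem = float(
        np.sqrt(ddg_sem**2 + profile.se_ddh**2 + profile.se_minus_t_dds**2)
    )
    consistent = discrepancy <= max(combined_sem, _SUM_TOL)
    return ThermodynamicProfile(
        ddh=profile.ddh,
        minus_t_dds=profile.minus_t_dds_at_ref,
        temperature=t,
        ddg_input=ddg_value,
        discrepancy=discrepancy,
        consistent=consistent,
    )
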