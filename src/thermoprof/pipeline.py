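"""Pipeline driver: configuration, stage orchestration, reporting.

The full pipeline chains simulate -> fep -> vanthoff -> decompose (plus
optional hydration and affinity stages) on a configured synthetic system
and writes a JSON results file and a human-readable report.  Every output
embeds the seed and a hash of the configuration; re-running the same config
reproduces the results byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import affinity as affinity_mod
from . import fep, synthetic, vanthoff
from .decomposition import assemble_profile, surroundings_energy
from .hydration import analyze_sites

log = logging.getLogger("thermoprof.pipeline")

_SUM_TOL = 1e-9


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class RunConfig:
    """Parameters for every pipeline stage.

    A seed is mandatory: every stochastic stage derives its substream from
    it, so a config fully determines the results.
    """

    seed: int
    outdir: str = "results"
    # alchemical system (harmonic demo by default)
    system: dict[str, Any] = field(
        default_factory=lambda: {
            "kind": "harmonic",
            "force_constant_a": 1.0,
            "force_constant_b": 2.0,
            "dimensionality": 1,
        }
    )
    n_windows: int = 84
    n_steps: int = 20000
    n_replicates: int = 3
    equil_fraction: float = 0.1
    temperatures: list[float] = field(
        default_factory=lambda: list(synthetic.DEFAULT_TEMPERATURES)
    )
    t_ref: float = 300.0
    n_boot: int = 200
    # optional stages
    hydration: dict[str, Any] | None = None
    affinity: list[dict[str, Any]] | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build_system(cfg: RunConfig, temperature: float):
    sysd = dict(cfg.system)
    kind = sysd.pop("kind", "harmonic")
    if kind == "harmonic":
        return synthetic.HarmonicSpec(temperature=temperature, **sysd)
    raise PipelineError(f"stage simulate: unknown system kind '{kind}'")


def _identity_flags(results: dict[str, Any]) -> dict[str, bool]:
    """The three bookkeeping identities restated on every report."""
    flags = {}
    f = results.get("fep")
    if f:
        flags["leg_sum"] = (
            abs(f["bound_leg_dG_kcal_mol"] - sum(f["bound_window_dGs"])) < _SUM_TOL
        )
    d = results.get("decomposition")
    if d:
        flags["enthalpy_split"] = (
            abs(
                d["ddH_kcal_mol"]
                - (d["ddU_L_kcal_mol"] + d["ddU_S_kcal_mol"])
            )
            < _SUM_TOL
        )
    p = results.get("profile")
    if p:
        flags["profile_additivity"] = (
            abs(p["ddG_kcal_mol"] - (p["ddH_kcal_mol"] + p["minus_TddS_kcal_mol"]))
            < _SUM_TOL
        )
    return flags


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write results + report.

    Returns the report bundle as a dict; raises :class:`PipelineError` with
    the stage name on any failure.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s [%(name)s] %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    root_seq = np.random.SeedSequence(config.seed)
    sim_seed, hyd_seed, boot_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root_seq.spawn(3)
    )

    # -- simulate + fep + vanthoff ---------------------------------------
    ladder = fep.LambdaLadder.evenly_spaced(config.n_windows)
    try:
        log.info("simulate: %s system, %d windows, %d temperatures, %d replicates",
                 config.system.get("kind", "harmonic"), ladder.n_windows,
                 len(config.temperatures), config.n_replicates)
        spec = _build_system(config, config.t_ref)
        runs = synthetic.sample_alchemical_scan(
            spec,
            ladder,
            config.temperatures,
            n_replicates=config.n_replicates,
            n_steps=config.n_steps,
            equil_fraction=config.equil_fraction,
            seed=sim_seed,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage simulate: {exc}") from exc

    try:
        rows = []
        ref_results = {}
        for (t, r), run in sorted(runs.items()):
            bound = fep.estimate_leg(run.series, "bound", ladder)
            # the unbound leg of the demo cycle is a null transformation
            unbound = fep.FreeEnergyResult(
                leg_label="unbound",
                window_dgs=np.zeros(ladder.n_windows),
                leg_dg=0.0,
                leg_sem=0.0,
                temperature=t,
                replicate_dgs=[0.0],
            )
            rel = fep.cycle_combine(bound, unbound)
            rows.append({"temperature": t, "replicate": r, "ddg": rel.ddg})
            if t == config.t_ref:
                ref_results.setdefault("bound", []).append(bound)
        table = pd.DataFrame(rows)
        if ref_results:
            pooled = fep.pool_replicates(ref_results["bound"])
        else:
            pooled = fep.estimate_leg(
                sorted(runs.items())[0][1].series, "bound", ladder
            )
        ddg_ref = float(
            table[table.temperature == config.t_ref]["ddg"].mean()
            if (table.temperature == config.t_ref).any()
            else np.interp(
                config.t_ref,
                table.groupby("temperature")["ddg"].mean().index,
                table.groupby("temperature")["ddg"].mean().to_numpy(),
            )
        )
        results["fep"] = {
            "temperature_K": config.t_ref,
            "ddG_kcal_mol": ddg_ref,
            "ddG_sem_kcal_mol": pooled.leg_sem,
            "bound_leg_dG_kcal_mol": pooled.leg_dg,
            "bound_window_dGs": [float(x) for x in pooled.window_dgs],
            "acceptance_rate": sorted(runs.items())[0][1].acceptance_rate,
        }
    except Exception as exc:
        raise PipelineError(f"stage fep: {exc}") from exc

    try:
        prof = vanthoff.fit_with_bootstrap(
            table, t_ref=config.t_ref, n_boot=config.n_boot, seed=boot_seed
        )
        results["vanthoff"] = {
            "ddH_kcal_mol": prof.ddh,
            "ddS_kcal_mol_K": prof.dds,
            "minus_TddS_kcal_mol": prof.minus_t_dds_at_ref,
            "T_ref_K": prof.t_ref,
            "r_squared": prof.r_squared,
            "ci95_ddH_kcal_mol": list(prof.ci_ddh),
            "ci95_minus_TddS_kcal_mol": list(prof.ci_minus_t_dds),
            "n_temperatures": prof.n_temperatures,
        }
    except Exception as exc:
        raise PipelineError(f"stage vanthoff: {exc}") from exc

    try:
        # demo system has no surroundings: ddU_L is the whole enthalpy
        decomp = surroundings_energy(prof.ddh, prof.ddh, sem_ddh=prof.se_ddh)
        profile = assemble_profile(
            ddg_ref, prof, ddg_sem=results["fep"]["ddG_sem_kcal_mol"]
        )
        results["decomposition"] = {
            "ddH_kcal_mol": decomp.ddh,
            "ddU_L_kcal_mol": decomp.ddu_l,
            "ddU_S_kcal_mol": decomp.ddu_s,
        }
        results["profile"] = {
            "ddG_kcal_mol": profile.ddg,
            "ddH_kcal_mol": profile.ddh,
            "minus_TddS_kcal_mol": profile.minus_t_dds,
            "ddG_fep_kcal_mol": profile.ddg_input,
            "discrepancy_kcal_mol": profile.discrepancy,
            "consistent": bool(profile.consistent),
        }
    except Exception as exc:
        raise PipelineError(f"stage decompose: {exc}") from exc

    if config.hydration is not None:
        try:
            hyd = dict(config.hydration)
            sites_cfg = hyd.pop("sites")
            net_spec = synthetic.PlantedNetworkSpec(
                sites=tuple(synthetic.SiteSpec(**s) for s in sites_cfg),
                seed=hyd_seed,
                **hyd,
            )
            traj = synthetic.generate_water_network(net_spec)
            sites = analyze_sites(
                traj,
                synthetic.pseudo_water_potential(),
                bulk_density=net_spec.bulk_density,
            )
            results["hydration"] = {
                "n_sites": len(sites),
                "sites": [
                    {
                        "site_id": s.site_id,
                        "center_A": [float(x) for x in s.center],
                        "occupancy": s.occupancy,
                        "E_ww_kcal_mol": s.e_ww,
                        "E_sw_kcal_mol": s.e_sw,
                        "S_trans_kcal_mol_K": s.s_trans,
                        "S_orient_kcal_mol_K": s.s_orient,
                        "minus_TdS_kcal_mol": s.minus_t_ds,
                    }
                    for s in sites
                ],
            }
        except Exception as exc:
            raise PipelineError(f"stage hydration: {exc}") from exc

    if config.affinity is not None:
        try:
            records = [affinity_mod.AffinityRecord(**r) for r in config.affinity]
            aff = {
                r.compound_id: (
                    affinity_mod.ki_to_dg(r) if r.ki is not None else None
                )
                for r in records
            }
            results["affinity"] = {"dG_kcal_mol": aff}
            if len(records) >= 2 and all(r.ki for r in records[:2]):
                results["affinity"]["ddG_first_pair_kcal_mol"] = (
                    affinity_mod.ddg_from_ki(records[0], records[1])
                )
        except Exception as exc:
            raise PipelineError(f"stage affinity: {exc}") from exc

    results["identities"] = _identity_flags(results)

    (outdir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    (outdir / "report.txt").write_text(_render_report(results))
    log.info("wrote %s and %s", outdir / "results.json", outdir / "report.txt")
    return results


def _render_report(results: dict[str, Any]) -> str:
    lines = [
        "thermoprof pipeline report",
        f"config hash: {results['config_hash']}   seed: {results['seed']}",
        "",
    ]
    if "fep" in results:
        f = results["fep"]
        lines += [
            "Relative binding free energy (thermodynamic cycle)",
            f"  ddG = {f['ddG_kcal_mol']:+.4f} +/- {f['ddG_sem_kcal_mol']:.4f} "
            f"kcal/mol at {f['temperature_K']:.1f} K",
            f"  MC acceptance rate: {f['acceptance_rate']:.2f}",
            "",
        ]
    if "vanthoff" in results:
        v = results["vanthoff"]
        lines += [
            "Van't Hoff analysis (ddG/T vs 1/T)",
            f"  ddH      = {v['ddH_kcal_mol']:+.4f} kcal/mol "
            f"(95% CI {v['ci95_ddH_kcal_mol'][0]:+.4f} .. "
            f"{v['ci95_ddH_kcal_mol'][1]:+.4f})",
            f"  -T ddS   = {v['minus_TddS_kcal_mol']:+.4f} kcal/mol at "
            f"{v['T_ref_K']:.1f} K",
            f"  R^2 = {v['r_squared']:.4f} over {v['n_temperatures']} temperatures",
            "",
        ]
    if "profile" in results:
        p = results["profile"]
        lines += [
            "Thermodynamic profile",
            f"  ddG = {p['ddG_kcal_mol']:+.4f}  ddH = {p['ddH_kcal_mol']:+.4f}  "
            f"-TddS = {p['minus_TddS_kcal_mol']:+.4f} kcal/mol",
            f"  FEP ddG = {p['ddG_fep_kcal_mol']:+.4f}; discrepancy "
            f"{p['discrepancy_kcal_mol']:.4f} "
            f"({'consistent' if p['consistent'] else 'FLAGGED'})",
            "",
        ]
    if "hydration" in results:
        h = results["hydration"]
        lines += [f"Hydration network: {h['n_sites']} sites"]
        for s in h["sites"]:
            lines.append(
                f"  site {s['site_id']}: occ {s['occupancy']:.2f}  "
                f"E_ww {s['E_ww_kcal_mol']:+.2f}  E_sw {s['E_sw_kcal_mol']:+.2f}  "
                f"-TdS {s['minus_TdS_kcal_mol']:+.2f} kcal/mol"
            )
        lines.append("")
    if "affinity" in results:
        lines.append("Experimental affinities")
        for cid, dg in results["affinity"]["dG_kcal_mol"].items():
            lines.append(
                f"  {cid}: dG = "
                + (f"{dg:+.2f} kcal/mol" if dg is not None else "qualitative only")
            )
        lines.append("")
    lines.append("Bookkeeping identities")
    for name, ok in results.get("identities", {}).items():
        lines.append(f"  {name}: {'pass' if ok else 'FAIL'}")
    lines.append("")
    return "\n".join(lines)
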