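# thermoprof

Thermodynamic profiling of ligand binding: alchemical free energy
perturbation, computational van't Hoff analysis, enthalpy decomposition,
and hydration-site thermodynamics — as a tested, reusable pipeline
exercised on analytically solvable synthetic systems.

## Who this is for

Small chemical changes to a ligand can produce large, counter-intuitive
changes in binding affinity ("activity cliffs"), and the driving forces —
ligand strain, desolvation, reorganisation of ordered binding-site waters —
are invisible to a single free energy number. This package implements the
analysis chain that turns relative binding free energies from molecular
simulation into an interpretable thermodynamic profile, for computational
chemists who want to test, teach, or extend the methodology without running
microsecond-scale receptor MD: every stage can be driven by built-in toy
systems whose answers are known in closed form.

## The methods

**Free energy perturbation.** A relative binding free energy comes from a
thermodynamic cycle, ΔΔG = ΔG<sub>transform</sub><sup>bound</sup> −
ΔG<sub>transform</sub><sup>unbound</sup>, where each leg alchemically
transforms ligand A into ligand B along a ladder of λ states with linear
coupling U<sub>λ</sub> = (1−λ)U<sub>A</sub> + λU<sub>B</sub>. Each window is
estimated with the Zwanzig equation,
ΔF<sub>i</sub> = −k<sub>B</sub>T ln ⟨exp(−ΔU/k<sub>B</sub>T)⟩<sub>i</sub>,
with a log-sum-exp, block-averaged SEMs, and an overlap diagnostic.

**Van't Hoff analysis.** With ΔΔG computed at several temperatures,
ΔΔG/T = ΔΔH·(1/T) − ΔΔS, so an OLS fit of ΔΔG/T against 1/T yields ΔΔH
(slope) and ΔΔS (−intercept); −TΔΔS is reported at 300 K. Uncertainties
come from a residual bootstrap with a t-quantile.

**Enthalpy decomposition.** Neglecting the pressure–volume term,
ΔΔH ≈ ΔΔU<sub>L</sub> + ΔΔU<sub>S</sub>: the ligand part (receptor–ligand
interaction, ligand strain, desolvation) averages directly from end-state
trajectories, while the surroundings part — too noisy for direct averaging —
is obtained indirectly as ΔΔU<sub>S</sub> = ΔΔH − ΔΔU<sub>L</sub>.

**Hydration sites.** Water positions pooled over frames are greedily
clustered into sites; each site gets an occupancy, water–water and
solute–water interaction energies, and translational/orientational
entropies relative to bulk from k = 1 nearest-neighbour estimators, in the
spirit of inhomogeneous solvation theory. Site networks of two complexes
are matched one-to-one and differenced, flagging displaced waters.

**Affinities.** Experimental K<sub>i</sub> values convert through
ΔG = RT ln(K<sub>i</sub>/1 M).

## Worked example

Convert the measured affinities of an agonist pair (45 nM vs 39 μM) into a
relative binding free energy:

```sh
$ thermoprof affinity --ki-a 45e-9 --ki-b 39e-6
{
  "dG_A_kcal_mol": -10.02283208334489,
  "dG_B_kcal_mol": -6.014876460350405,
  "ddG_kcal_mol": -4.0079556229944835,
  "temperature_K": 298.15
}
```

The high-affinity compound binds 4.0 kcal/mol more favourably — the
magnitude of an activity cliff caused by a single heavy-atom change.

Run the full simulate → FEP → van't Hoff → decomposition pipeline on the
built-in harmonic demo (a 1D oscillator whose force constant doubles, with
exact ΔF = (k<sub>B</sub>T/2)·ln 2 ≈ 0.2066 kcal/mol at 300 K):

```sh
$ thermoprof run --config examples/demo.yaml   # seed 42, 24 windows, 8 temperatures
```

```
Relative binding free energy (thermodynamic cycle)
  ddG = +0.2064 +/- 0.0005 kcal/mol at 300.0 K
  MC acceptance rate: 0.50

Van't Hoff analysis (ddG/T vs 1/T)
  ddH      = +0.0079 kcal/mol (95% CI -0.0043 .. +0.0200)
  -T ddS   = +0.1987 kcal/mol at 300.0 K
  R^2 = 0.3806 over 8 temperatures

Thermodynamic profile
  ddG = +0.2066  ddH = +0.0079  -TddS = +0.1987 kcal/mol
  FEP ddG = +0.2064; discrepancy 0.0002 (consistent)

Bookkeeping identities
  leg_sum: pass
  enthalpy_split: pass
  profile_additivity: pass
```

The sampler reproduces the closed form within its SEM, and the van't Hoff
stage correctly attributes the whole free energy to entropy (the harmonic
mutation has ΔH = 0 exactly; ΔF/T is independent of T), with the enthalpy
estimate statistically indistinguishable from zero. The low R² is expected
— there is no enthalpic trend for the regression to explain.

Library use mirrors the CLI:

```python
import thermoprof as tp

spec = tp.HarmonicSpec(force_constant_a=1.0, force_constant_b=2.0)
run = tp.sample_alchemical_path(spec, tp.LambdaLadder.evenly_spaced(84),
                                n_steps=100_000, seed=1)
leg = tp.estimate_leg(run.series, "bound")   # 0.2066 +/- 0.0002 kcal/mol
```

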