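# Methods

This note records the models, estimators, default parameters and numerical
choices behind `thermoprof`, and what the synthetic benchmarks do and do
not establish about real simulation data. Units are kcal/mol, Å and K
throughout; k_B = 0.0019872041 kcal/(mol K).

## Alchemical free energies

Each transformation leg is a ladder of λ states with **linear coupling**
U_λ = (1−λ)U_A + λU_B. No soft-core potential is used: the toy systems
never annihilate particles, so the end states have no singularities. The
default ladder has 84 evenly spaced windows (85 states), matching common
practice for single-heavy-atom transformations; the toy benchmarks use
coarser ladders (8–12 windows) because their perturbations are far
smoother — per-window ΔU stays well under k_BT, where the Zwanzig
estimator's exponential average is essentially unbiased. Ladder-refinement
and forward/reverse hysteresis tests guard this choice.

Window free energies use the Zwanzig formula with a log-sum-exp. The SEM
of each window comes from **block averaging with 10 contiguous blocks**:
the window estimate is recomputed per block and the spread of block
estimates gives the SEM, which absorbs the sampler's autocorrelation.
Degenerate (constant-ΔU) windows report SEM 0 since the estimate is exact.
An overlap diagnostic reports the share of the exponential-average weight
carried by the top 5% of frames and logs a warning above 50%.

Replicates are independent-seed repeats of a whole leg; legs aggregate as
mean ± SEM over replicates (default 3), and the cycle ΔΔG uses paired
per-replicate differences when both legs carry equal replicate counts,
quadrature otherwise.

## Monte Carlo samplers

Both toy Hamiltonians are sampled with single-particle Metropolis moves;
all (λ, temperature, replicate) chains advance together as one vectorised
batch, with the inner loop compiled by numba. Proposal randomness is drawn
from a single `numpy` Generator outside the kernel, so a seed fully
determines the output.

* **Harmonic oscillator** (1D/3D): Gaussian proposals with step
  2·sqrt(k_BT/k̄(λ)), giving ≈50% acceptance at every λ. The exact
  transformation free energy is d·(k_BT/2)·ln(k_B/k_A); equipartition
  (⟨x²⟩ = k_BT/k) is asserted within 3 block-SEMs.
* **Host–guest system**: Lennard-Jones particles (Lorentz–Berthelot
  mixing) plus a dipolar term −μᵢμⱼ·g/r³ where g is û·û for two oriented
  pseudo-waters, û·r̂ for a water against an orientation-less particle and
  1 otherwise; pair distances are clamped at 0.5 Å so rejected overlap
  moves stay finite. Translational steps are 0.35 Å, orientation steps
  perturb û by Gaussian noise (σ = 0.5) and renormalise; a radial
  reflection enforces the spherical container. The guest may carry a
  harmonic bond with state-dependent (k, r₀) — its "strain" energy — and a
  positional restraint to its starting point (the restraint is part of the
  sampled potential but not of any tagged physical component).

The standard benchmark (`hostguest_benchmark`) places two host particles
(ε 0.3, σ 3.0, μ 3.0) and two restrained guest particles in a 6.5 Å sphere
with 18 pseudo-waters (ε 0.15, σ 2.8, μ 1.0); the transformation deepens
the guest's ε, strengthens its μ and stiffens/shortens its bond — a
caricature of growing a polar substituent. These values were fixed once so
that the bound and unbound legs differ measurably (ΔΔU of a few tenths of
a kcal/mol) while per-window perturbations stay small. Default sampling
for the multi-temperature scans is 3 000 sweeps per chain with 10%
equilibration discarded and every 5th sweep retained — sized so a full
two-leg, 8-temperature, 3-replicate scan runs in about two minutes on one
CPU while keeping leg SEMs below 0.01 kcal/mol.

Recorded per-frame totals are validated against an independent O(N²)
double-loop recomputation to 10⁻⁸ kcal/mol.

## Van't Hoff analysis

ΔΔG/T versus 1/T is fit by unweighted OLS on replicate means: ΔΔH is the
slope, ΔΔS minus the intercept, −T_refΔΔS reported at T_ref = 300 K. The
default temperature set is 280–315 K in 5 K steps (eight temperatures).
Exact inputs are recovered to machine precision, and the analytically
athermal harmonic mutation yields ΔΔH = 0 and ΔΔS = −(k_B/2)ln 2 exactly.

**Uncertainty.** CIs come from a residual bootstrap: replicate-level
residuals from the fitted line are pooled across temperatures
(homoscedastic noise), rescaled by sqrt(N/(N−2)) for the two fitted
parameters, resampled within each temperature, and the bootstrap SE is
converted to a 95% CI with a t-quantile (n_T − 2 dof). A naive percentile
interval over within-temperature replicate resamples was measured to cover
the true ΔH in only ~77% of nominal-95% cases with 3 replicates — the
well-known small-n undercoverage of the percentile bootstrap — whereas
this scheme measures 95–96% coverage on the same protocol. With a single
replicate per temperature the code falls back to t-scaled regression SEs
and logs a warning.

## Enthalpy decomposition

Tagged per-frame energy tables (receptor–ligand, ligand-internal,
ligand–water) are averaged per end state. The strain component is the
*binding-induced* change in ligand internal energy differenced between
ligands; desolvation is the bound-minus-unbound difference of the
ligand–water term. Both sum identities
(desolvation = ΔE_lw^bound − ΔE_lw^unbound and
ΔΔU_L = ΔE_RL + strain + desolvation) hold to 10⁻⁹ by construction, as
does ΔΔU_S = ΔΔH − ΔΔU_L. Component SEMs come from block averaging and
propagate in quadrature. The pressure–volume contribution to the enthalpy
is neglected. Profile assembly reports ΔΔG, ΔΔH and −TΔΔS side by side and
flags the profile when |ΔΔG − (ΔΔH − TΔΔS)| exceeds the combined SEM (with
a 10⁻⁹ floor so exact inputs flag any genuine discrepancy, e.g. one caused
by rounding the inputs independently).

The end-to-end conservation test closes the loop on the host–guest
benchmark: ΔΔU_L + ΔΔU_S (which equals the van't Hoff ΔΔH by
construction) must agree with the independently measured difference of
mean end-state total energies within 3× the combined SEM. A restrained
variant checks that a four-fold stronger positional restraint moves the
direct ΔΔU by less than 0.5 kcal/mol; the bound is qualitative because a
tether genuinely perturbs the sampled ensemble — the measured shift is
≈0.16 kcal/mol, i.e. the enthalpy signal survives restraining, the same
sense in which a restrained-receptor control is read in practice.

## Hydration sites

**Clustering** is greedy density search over all pooled water
observations: the observation with the most neighbours within the site
radius (default 1.0 Å) becomes a center, its claimed observations are
removed, and the loop stops when the best candidate's distinct-frame
occupancy falls below 0.5. Ties break on the lowest (frame, water_id)
pair, making the result independent of frame order.

**Energies.** E_ww / E_sw are occupied-frame averages of the site water's
pair energy against all other waters / all solute particles; the full pair
energy is assigned to the site water (no ½ factor — conventions differ
between published implementations, so this is stated explicitly).

**Entropies** relative to bulk use k = 1 nearest-neighbour
(Kozachenko–Leonenko) estimators with the ψ(1) log-correction:
S_trans = k_B(H[p] − ln(occ/ρ_bulk)) treats the site water's local
time-averaged density occ·p(x) against a uniform bulk at ρ_bulk;
S_orient = k_B(H[û] − ln 4π) uses geodesic nearest-neighbour angles on the
sphere. Both vanish for a bulk-like site and match the closed-form
Gaussian and von Mises–Fisher entropies within estimator tolerance
(≲0.3 k_B at a few thousand frames, the residual being the known
boundary/curvature bias of k-NN estimators).

**Network comparison** matches sites across complexes by greedy
nearest-center pairing within 1.5 Å; unmatched reference sites are flagged
displaced and contribute the loss of their full energies to the network
totals, so ΔE_total = ΔE_ww + ΔE_pw holds exactly.

The planted-network generator emulates ordered binding-site waters as
Gaussian clouds (default σ 0.25 Å, i.e. 4σ containment inside the 1.0 Å
clustering radius, typical of a well-ordered crystallographic water) with
von Mises–Fisher orientations and Bernoulli occupancy over a uniform
Poisson bulk. Site centers must be separated by more than twice the
clustering radius or generation refuses.

## Affinities

ΔG = RT ln(K_i/1 M) at a default assay temperature of 298.15 K (the
Ki-ratio difference of the worked example reproduces at both 298.15 and
300 K to one decimal). Percent-inhibition measurements carry no K_i and
deliberately raise if converted.

## What the synthetic benchmarks do and do not show

The generators provide exact ground truth (closed-form free energies,
planted site geometry, known ΔH/ΔS lines), so passing tests establish the
*estimators*: unbiasedness of the FEP chain at good overlap, calibration
of the bootstrap, recovery of site geometry/occupancy/entropy, and exact
bookkeeping of every decomposition identity. They do not establish
force-field accuracy, sampling adequacy for slow receptor degrees of
freedom, finite-size or cutoff effects, or the rigid-solute approximation
of hydration-site analysis — properties of real MD data that no toy
system can probe.

## Known limitations

* Only the Zwanzig estimator is provided (no BAR/MBAR); poorly overlapped
  ladders are diagnosed, not repaired.
* Pseudo-waters are single LJ sites with a unit dipole vector — chosen for
  analytic tractability; there is no hydrogen-bond network topology.
* The k-NN entropy estimators assume the site water's frames are
  independent draws; strongly autocorrelated trajectories will
  underestimate the uncertainty of S.
* The pipeline driver orchestrates the built-in synthetic systems;
  external FEP engine outputs enter through the perturbation-TSV and
  multi-model-PDB readers only.
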