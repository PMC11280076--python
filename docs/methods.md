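# Methods

## Scope and model structure

`ocupbpk` implements a compartmental ocular PBPK model for topically
instilled suspensions, with besifloxacin 0.6% as the built-in case study.
The state comprises the pre-corneal tear film (time-varying volume;
dissolved and solid drug; particle radius), a controlled-release (CR)
depot per dose event, nine ocular tissues (cornea epithelium and stroma,
conjunctiva, aqueous humor, iris–ciliary body, sclera, choroid, retina,
vitreous humor), a nasolacrimal/GI depot, a one-compartment systemic pool,
and four elimination sinks (drainage, spillage, systemic clearance,
unabsorbed GI). All amounts are µg, volumes mL, time h; permeabilities
(cm/s), rates (s⁻¹, min⁻¹) and flows (µL/min) are converted on ingestion.

## Pre-corneal dynamics

A dose raises the tear-film volume to at most `V_tear + 30 µL` (35 µL
rabbit, 37 µL human); the unretained fraction of the drop — volume and
drug alike — is booked to a spillage sink. Excess volume drains at
`k_d = 0.1 min⁻¹` (a value representative of a viscous suspension;
plain solutions drain faster), giving an excess-volume half-life of
ln 2/0.1 ≈ 6.93 min. The same fractional rate `k_d·(V − V_tear)/V`
removes dissolved and suspended drug — both phases are carried by the
drained fluid, and we assume equal entrainment since no basis for a
difference is available. Baseline tear turnover (0.66 µL/min rabbit,
1.2 µL/min human; literature defaults) removes dissolved drug only, since
at physiological volume particles are retained in the cul-de-sac mucus
rather than cleared with bulk flow. Evaporation is neglected.

## Dissolution and controlled release

Suspended particles are a monodisperse population with a single radius
state (default 3 µm diameter). The dissolution rate is the shrinking-sphere
Nernst–Brunner form with diffusion-layer thickness `h = min(r, 30 µm)`;
the per-particle radius rate `dr/dt = −D(C_s − C)/(ρh)` is independent of
particle count, so washout (which removes particles, not size) and
dissolution decouple cleanly. Defaults `D = 8×10⁻⁶ cm²/s` and
`ρ = 1.3 g/mL` are typical small-molecule values and configurable. When
the radius falls below 0.01 µm the closed form diverges; the residual mass
(nanograms at most) is dissolved by a fast first-order rate instead,
preserving mass balance. Supersaturation reverses the rate sign
(precipitation onto existing particles); no nucleation is modeled.
Polydisperse size bins are a documented extension point, not implemented.

The CR dosage form splits each dose into a dissolved fraction
(`min(1, solubility/strength)`; 16.7% for a 6 mg/mL suspension of a
1 mg/mL-soluble salt) instilled as solution and a depot emptied by the
Weibull function `F(t) = Max·(1 − exp(−t^b/A))`. The functional form is
fixed by the printed unit of `A` (h^b); no lag time is used. Each dose
spawns an independent depot whose release clock starts at its dose time
(superposition). The depot is not subject to drainage — it represents drug
held by the mucoadhesive polymer film — and the never-released
`100 − Max = 74.53%` stays locked in the depot state, which keeps the mass
balance exact and mirrors the interpretation of the fitted profile as
lumping release with tear-mediated loss. For shape `b < 1` the release
rate diverges at the dose instant; the release clock is clamped at 1e-9 h,
an error many orders below solver tolerance.

## Permeation, systemic absorption, disposition

Tissue-to-tissue transfer is symmetric permeability·area·(Cᵢ − Cⱼ) over a
fixed edge set; no tissue partition coefficients are applied (none are
available for the case study). Each edge uses the permeability of its
distal (inner) tissue — e.g. tear film ↔ cornea epithelium uses the cornea
epithelium permeability, conjunctiva ↔ sclera uses the sclera value. This
convention is a documented design choice; the quantitative checks shipped
with the package are deliberately insensitive to it. Conjunctiva,
iris–ciliary body, choroid and retina lose drug to the systemic pool at
first-order systemic absorption rates; aqueous humor turnover (3 µL/min
rabbit, 2.5 µL/min human, literature defaults) carries drug from the
aqueous humor to the systemic pool.

Drained pre-corneal drug enters a nasolacrimal/GI depot absorbed at
`k_a = 0.5 h⁻¹` with fraction absorbed 0.7 — a deliberately simple stand-in
for full intestinal transit, adequate because systemic levels after
topical ocular dosing are near-negligible and nothing quantitative is made
to depend on it. A solver flag can instead route drained drug directly to
a drainage sink, which is how the isolation property (no permeation ⇒
dose = drainage + spillage + locked CR) is tested. Systemic disposition is
one-compartment: `dA/dt = inflows − (CL/(Vc·BW))·A`, plasma concentration
`A/(Vc·BW)`. `CL` (15.42 L/h) is treated as absolute for the reference
body weight (2.5 kg rabbit, 70 kg human), configurable.

## Physiology defaults

Tear-film constants (tear volume 5/7 µL, pre-cornea maximum 35/37 µL,
drainage 0.1 min⁻¹) are the case study's values. Ocular tissue volumes and
exchange areas are **not** published for the reference parameterization;
the built-in tables (e.g. aqueous humor 0.30 mL rabbit / 0.25 mL human,
cornea area 1.5 / 1.0 cm², conjunctival sac several-fold larger than the
cornea) are stand-ins drawn from standard ocular-anatomy literature,
clearly overridable per field from the configuration file. Consequently
absolute tissue concentrations depend on these defaults; the package's
quantitative acceptance checks (dissolved-fraction arithmetic, Weibull
release, parameter recovery, tear-film rules) are chosen to be insensitive
to them. NZ and DB rabbit physiologies are identical apart from the label:
the only strain difference a fuller model would carry is melanin binding,
which could not be parameterized for besifloxacin and is out of scope.

## Numerics

`scipy.integrate.solve_ivp` with LSODA (stiff-capable), rtol 1e-8,
atol 1e-12 µg; dose events are handled by integration restart with an
instantaneous state update. Mass balance — dose = compartments + sinks,
including the locked CR remainder — is checked at every output point; a
violation above 1e-6 of the dose raises a hard error (observed errors are
~1e-15). Output at a dose time reports the post-dose state. An independent
fixed-step explicit-Euler integration of a two-tissue reduction agrees
with the production solver within 0.5%.

## Fitting

The objective is unweighted least squares on log concentrations
(observations ≤ 1e-4 µg/mL excluded; predictions floored at the same value
inside the log), chosen because ocular profiles span several orders of
magnitude across tissues; a linear WLS objective (1/SD² weights) is also
available. Optimization is Nelder–Mead with box bounds, optional log10
transform per parameter, and seeded multi-start (default 5 starts: the
declared initial point plus uniform draws within bounds); tolerances are
1e-8 (objective) and 1e-6 (parameters), and the reported optimum is never
worse than the initial point. Standard errors come from a central-finite-
difference Hessian of the objective at the optimum under the Gaussian
approximation (`cov = 2σ²H⁻¹`, `σ² = SSR/dof`), with the delta method for
log-scale parameters. Release-curve datasets (pseudo-tissue `cr_release`)
are evaluated against the closed-form Weibull, so release parameters can
be estimated without touching the tissue topology or its default
volumes/areas. Fits are bit-for-bit reproducible given the same seed.

## Synthetic data

The generator reproduces the structure of the case study's designs: 50 µL
drops of a 0.6% suspension, sparse timepoints (default 0.25–24 h grid),
per-timepoint mean/SD/n summaries of tears, cornea, conjunctiva, aqueous
humor and plasma. Noise is multiplicative lognormal, mean-preserving with
specified CV — concentrations are strictly positive and reported SDs in
such studies often exceed means, implying right skew. Destructive sampling
draws independent subjects per timepoint; serial sampling reuses one
deviate per subject across times. The generator emulates inter-animal
variability only: no assay LLOQ/censoring, no inter-study shifts, no
within-animal kinetic heterogeneity — so passing recovery tests show the
estimation machinery is correct and identifiable under the stated designs,
not that real-data fits will be unbiased.

## Problem sizes

The shipped tests and the acceptance script run desk-scale problems chosen
to exercise every code path at high precision: 24–48 h simulations on
~500-point grids, 25-point release curves, 8-point tissue profiles for
single-parameter recovery, a 200-replicate noise/bias simulation study,
and 1e4-replicate checks of the noise model's CLT scaling.

## Known limitations

* Tissue volumes/areas are literature stand-ins (see above); absolute
  tissue predictions should be re-parameterized before quantitative use.
* Melanin binding, corneal metabolism, transporters, evaporation and
  mechanistic polymer-gel dynamics are out of scope.
* The suspension/CR dissolved-fraction question is left to the user: the
  dissolved fraction is an explicit input and the package reproduces each
  candidate arithmetic (16.7%, 41.66%, 1.5%) without adjudicating the true
  in-product value.
* `CL` per-kg vs absolute is ambiguous in the source constants; treated as
  absolute at the reference body weight and configurable.
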