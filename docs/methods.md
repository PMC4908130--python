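# Methods

## The model

`cumoflux` simulates and fits the dynamics of 13C label propagation
through a compartmented metabolic network at metabolic (chemical) steady
state, in the *cumomer* state space.  For a metabolite M with pool size
[M] (mM per liter-cell), the cumomer fraction p_S is the probability that
all carbons in the position set S are 13C.  Each unidirectional flux F_j
into M contributes

    [M] dp_S/dt = Σ_j F_j · Π_s p^(s)_{σ_j⁻¹(S)}  −  (Σ_j F_j) · p_S ,

where σ_j⁻¹ pulls the position set back through the reaction's carbon
atom map.  When S spans carbon coming from several substrate molecules
(condensation steps such as citrate synthase, transketolase,
transaldolase), the influx term is the product of the per-substrate
fragment cumomer fractions, because labeling of distinct molecules is
statistically independent.  Writing the decay term with the total
*influx* (rather than outflux) makes the same equation exact for pools
whose size changes in time (medium lactate filling up under perfusion);
for balanced constant pools the two are identical.

Bonded cumomers restrict S to sets connected along the molecule's carbon
bond graph — precisely the joint-labeling information that 13C NMR fine
structure resolves.  Orders 1–3 suffice for all singlet/doublet/triplet
multiplets of the amino and organic acids observed here.  The unrestricted
("fragmented") mode carries every subset up to each molecule's full
carbon count and is the basis for mass-isotopomer distributions (MIDs).
The state index is closed under atom-map pullback, so every referenced
precursor cumomer is itself a state; pullbacks never increase the order,
which gives the system its triangular ("cascade") structure: order-n
states never depend on orders above n.  The algebraic steady state is
therefore solved order by order with sparse linear solves.

Symmetric molecules (the succinate/fumarate node) are handled by
splitting every flux producing the symmetric pool into two half-flux
variants, identity and symmetry-permuted — equivalent to 50/50 scrambling
and sufficient for the well-known glutamate C2/C3 labeling pattern.

Molecules are not restricted to linear chains: each pool may declare its
carbon bond graph (citrate is branched), and "bonded" means connected in
that graph.

## Transport and perfusion

Boundary species move between medium and cytosol by reversible saturable
carrier kinetics,

    J = Jmax (Me/Km − Mi/Km) / (1 + Me/Km + Mi/Km),

decomposed into its two unidirectional components for label bookkeeping.
Only lactate transport (MCT) is given fitted Michaelis–Menten parameters;
glucose and glutamine uptake are modeled as non-limiting ("balancing")
transports whose net value is fixed by the steady-state flux balance —
the study this preset reproduces fits transport kinetics for lactate
only.  Clamped medium species (glucose, glutamine) are held at the feed
concentration with the feed's isotopomer composition, representing the
feed-adjustment controller without simulating its feedback loop.
Non-clamped medium species (lactate) obey

    d(Me)/dt = r_ie · J_export − (φ/V_m) · Me,

with r_ie the cell-to-media volume ratio and φ the feed (and removal)
rate.  Intracellular pools — including cytosolic lactate — have constant
concentrations, as in the balance formalism itself: the fitted "total
cellular lactate" is the constant pool size, which sets the
intracellular labeling time constant, while the carrier kinetics are
evaluated at that concentration.  The preset starts the medium at its
operating (perfusion-balance) state, since the label switch happens on a
running reactor; a fresh-medium start is available by overriding the
initial concentrations.

## The DB-1 preset

The shipped network covers lumped EMP glycolysis (hexokinase →
phosphoglucose isomerase → a combined aldolase/triose-phosphate step with
the C1–C3 inversion through DHAP → a lumped lower-glycolysis step),
the classical F-type pentose phosphate pathway with explicit TK1/TK2/TA
carbon rearrangements, the TCA cycle with the standard citrate
stereochemistry (acetyl C2 → glutamate C4; OAA C1 lost at isocitrate
dehydrogenase), pyruvate carboxylase, anaplerotic exchange at the
succinyl-CoA level against an unlabeled source, glutaminolysis
(glutamine → glutamate → α-ketoglutarate), the malate–aspartate shuttle
exchange (one parameter drives both the glutamate/α-ketoglutarate and
oxaloacetate/aspartate legs), mitochondrial and cytosolic malic enzymes,
citrate export through ATP-citrate lyase into a two-pool fatty-acyl model
(cytosolic precursor pool plus a 10-fold larger membrane pool), and
Michaelis–Menten lactate transport.  The bonded order-3 system for this
network has 223 state variables, in line with the ~210 quoted for this
class of model.

Flux ground truth is the published extracted flux set.  Free fluxes set
the degrees of freedom; every other net flux is solved from the
steady-state balance (`complete_flux_set`).  Notable derived values:
citrate synthase 11.49 (= F_tca + lipogenic citrate export), fumarase
node 15.25 (= F_tca + glutaminolysis + net anaplerosis), cytosolic malic
enzyme 0.59, combined glycolysis+PPP flux G6P→pyruvate 152.1 — all
matching the published derived table to its printed precision.

Two unit conventions coexist in the published numbers and are kept
explicit here: the carbon balance closes only if the lipogenic citrate
export equals the fatty-acid synthesis flux in *acetyl* units
(0.59 acetyl-CoA/L-cell/h), whereas the published lipogenic NADPH demand
(≈8.3) uses *palmitate* units (14 NADPH × 0.59).  The ledger therefore
defaults to acetyl units for carbon/ATP accounting and the NADPH balance
defaults to palmitate units; both are switchable (`fa_units`).

Pool sizes other than glutamate (9.2 mM, a fitted value) are not printed
in the source study; the preset uses literature-plausible defaults (small
fast intermediates at 0.02–0.5 mM, ~200 mM total fatty-acyl units at
20% of dry weight referenced to palmitate) and documents them as such in
the preset file.  Tracer enrichment is taken as 100%.

## Observables

The nine reported curves are 13C concentrations (mM): glutamate C4/C3/C2
totals and their singlet/doublet components by inclusion–exclusion over
bonded neighbors, total labeled lactate C3 (intracellular + medium,
weighted by the *detection volume* composition — the NMR coil sees the
packed cell bed, so the default cell volume fraction in the sensitive
region is 0.15, far above the whole-reactor cell/medium ratio), and the
fatty-acyl methylene resonance modeled as labeled acetyl-C2 units summed
over the two acyl pools.  MIDs come from
the fragmented (full-order) system by Möbius inversion over the fragment
subset lattice; natural abundance (1.1%/carbon) is off in the state
equations and applied, when wanted, as a binomial convolution /
deconvolution on observables.

## Estimation

The cost is the weighted mean squared error over observations with
per-observation σ.  Optimization runs in log-parameter space with the
simplex (Nelder–Mead) or quasi-Newton (L-BFGS-B) algorithm, seeded
log-uniform multi-starts within bounds (default 8), and a tighter polish
of the best start.  Parameter errors are Monte Carlo: synthetic
replicates at the fitted parameters with the experimental noise level,
refit from the fitted values; SDs and 2.5–97.5% intervals come from the
refit spread.  A default endpoint filter (0.5 mM) drops low
signal-to-noise multiplets from fitting.  χ²/dof in [0.5, 1.5] is
reported as "consistent" — the documented convention.

The default recovery study uses σ = 0.005 mM on a 0.25–6 h grid at
0.25 h cadence and a staged optimization: eight log-uniform quasi-Newton
starts (150 evaluations each, 500 for the winner) locate the basin and
give an *anchor* point — the gradient method descends efficiently from
distant starts but its finite-difference gradients are fragile at the
integrator noise floor, where the simplex is robust — and the estimate
is a fixed-budget simplex refinement (1000 evaluations) from that
anchor.  Monte Carlo errors are a parametric bootstrap with the *exact*
estimator: each noise replicate is refit with the identical simplex
budget from the identical anchor, so the reported SDs measure precisely
the noise sensitivity of the estimate, including the weakly determined
directions (e.g. the transport K_m carries a ~45% SD, mirroring the ±70%
published for that parameter, and the tiny aspartate-efflux flux is
reported with an SD spanning its near-unidentifiability).  In-loop
integrations run at rtol 1e-5 (1e-8 elsewhere).

## Sensitivity analysis

Dynamic isotopomer control coefficients (∂π/π)/(∂F/F) are computed two
ways: central finite differences at ±1% with the derived fluxes
rebalanced at each perturbation, and forward sensitivity equations — the
linear time-varying system ds/dt = A(z(t))s + ∂f/∂F integrated along the
baseline trajectory (one extra system of equal size per parameter, i.e.,
doubled equation count).  The two agree to better than 1e-3 relative
wherever coefficients exceed the masking floor (normalizing states below
1e-6 are reported as undefined rather than infinite).

For the glutaminolysis analysis the coefficients are taken on multiplet
*composition* (each multiplet's share of its carbon's total resonance)
rather than raw fractional enrichments: an increase of unlabeled
glutamine influx dilutes all glutamate multiplets by a common factor
that cancels in the shares, and it is in the shares that the doublet
C4d34 is the most glutaminolysis-sensitive signal at early times, with a
sign crossover near 1.5–3 h.  On raw enrichments the common dilution
dominates and the singlet leads throughout; both normalizations are
available.

The MSE sensitivity of a fitted parameter is
S_i = max± [E(p_i ± 0.05 p_i) − E(p_i)]/(0.05·E), i.e., relative change
of the minimized error per relative parameter change, one parameter at a
time; the raw ΔE is reported alongside because the published definition
of the normalization is ambiguous.

## Energetics

From the completed flux map the ledger counts NADH (by compartment),
FADH2, succinyl-CoA-synthetase GTP, NADPH and substrate-level ATP per
reaction.  Cytosolic NADH surplus (glyceraldehyde-3-phosphate
dehydrogenase minus lactate dehydrogenase and the lipogenic malate
shunt) is moved into the mitochondrion by the malate–aspartate shuttle.
Then MRO2 = (NADH + FADH2)/2 and oxidative ATP = 2.5·NADH + 1.5·FADH2 +
GTP (P/O ratios 2.5 and 1.5).  Conventions chosen where the source is
silent: the mitochondrial malic enzyme sum splits 50/50 between the
NADH- and NADPH-linked isoforms (only the sum is published); anaplerotic
carbon enters below succinyl-CoA synthetase (no GTP on it); glycolytic
ATP is reported both as net substrate-level phosphorylation (≈152) and
as one ATP per lactate (=150), with the per-lactate convention used for
the oxidative fraction.  Under these conventions the preset yields
MRO2 ≈ 31.6 and oxidative ATP ≈ 153.6 against the published 32 and 154.
Oxidation routes for per-molecule ATP yields traverse declared reaction
lists (full glutamine oxidation: 7 NADH + 2 FADH2 + 2 GTP = 22.5 ATP,
with the malic-enzyme step taken as the NADPH-linked isoform).

## What the synthetic data do and do not emulate

The generators reproduce the *structure* of the bioreactor experiments —
continuous labeled feed, saturating multiplet curves sampled at the
spectral cadence, steady-state MIDs with σ = 0.01 Gaussian noise and
renormalization — with independent Gaussian noise and exact model
dynamics as ground truth.  They do not emulate spectral processing
artifacts (baseline, overlap, NOE calibration), spatial heterogeneity in
the bead bed, natural-abundance backgrounds, or model misspecification;
recovery results therefore demonstrate identifiability and correctness
of the estimation machinery under the stated noise model, not robustness
to real-data systematics.

## Numerical choices

Default integrator: BDF with analytic Jacobian assembled from the term
table (concentration couplings by finite-difference columns), rtol 1e-8 /
atol 1e-10; a fixed-step classical Runge–Kutta mode exists for
cross-checks, and non-stiff solvers can be selected for small problems.
Cumomer fractions are clipped to [0,1] on output and a trajectory is
rejected if it leaves the unit interval by more than 1e-6.  Steady-state
concentration solves use a damped fixed point with an fsolve fallback.
Flux completion solves the stoichiometric balance by least squares and
verifies the residual to 1e-9 of the largest flux; rank deficiency and
negative derived irreversible fluxes are hard errors.

## Known limitations

* Isotope effects and natural abundance in the state equations are not
  modeled (enrichment above background is assumed).
* The quasi-steady lumping of lower glycolysis means no predictions for
  glycolytic-intermediate pool dynamics.
* The oracle (full isotopomer system) is limited to small networks by
  design; on the preset it is used only at full-order cumomer level.
* Glutamine consumption by biosynthesis is not tracked beyond the
  glutaminolysis flux; it does not affect labeling but caps what the
  model can say about total glutamine uptake.
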