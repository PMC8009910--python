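# Methods

This note documents the models implemented in `isomix`, the choices made
where the design was genuinely open, and what the validation suite does
and does not establish.

## Isotope algebra

δ¹³C is the per-mil deviation of a sample's ¹³C/¹²C ratio from VPDB
(ratio 0.0112372). All mixing arithmetic is linear in δ, exactly the
mass-balance model δ_mix = Σ_s F_s δ_s with Σ F_s = 1: mixing is *not*
performed in isotope-ratio space. For the δ range relevant here
(−40 to −10‰) the two differ by less than 0.01‰, far below the 0.9‰
analytical precision, and linear-in-δ is the form the mass-balance
theory states.

The intermolecular fractionation factor between co-produced formic and
acetic acid is α = (δ¹³C_F + 10³)/(δ¹³C_A + 10³). Two expressions for
the implied gap δ_F − δ_A are provided:

* the logarithmic form 10³·ln α (the default, and the form used by the
  secondary-source estimator);
* the exact algebraic form (α − 1)(δ¹³C_A + 10³).

At α = 1.002 and tropospheric δ values the two gaps differ by ≈ 0.06‰,
and the solved secondary-source signatures by < 0.05‰ — an order of
magnitude below measurement precision, so the choice is immaterial in
practice; both are kept because published placements of sources on the
δ_F/δ_A = 0.94 line could have used either. A quantitative corollary,
verified by a dedicated test: recomputing α from a ln-form gap
reproduces the input α only to ≈ 7×10⁻⁴ in the worst corner of
α ∈ [0.99, 1.01], δ_A ∈ [−60, 0]‰ (the error is
10³·ln α/(10³ + δ_A) − (α − 1), shrinking to < 10⁻⁴ only near δ_A = 0).

Lifetime arithmetic: a tracer that survives H hours of transport has a
lifetime of at least H/24 days; relative underestimation of that bound
by a modelled lifetime is reported as an integer percent, ties rounded
away from zero (so 56.25% → 56, 117.4% → 117). ‰ values are rounded to
one decimal only at presentation; all internal computation is full
double precision.

## Secondary-biogenic source estimator

The system x + y = 1, x/y = r, x·δ_F + y·δ_A = δ_isoprene,
δ_F − δ_A = 10³·ln α has the unique closed form x = r/(1+r),
y = 1/(1+r), δ_A = δ_isoprene − x·10³·ln α, δ_F = δ_A + 10³·ln α.
Uniqueness and correctness are cross-checked against a brute-force grid
minimiser of the constraint residuals. The precursor δ¹³C defaults to
−27‰ (C3-plant mean) minus 2.8‰ (isoprene-synthesis discrimination)
= −29.8‰; the branching ratio r = 3.9 and α = 1.002 are configuration
defaults of the chamber experiment the generator emulates — none of the
three is hard-wired into the solver. Contributions of non-isoprene VOC
precursors are not modelled; the estimator assumes product carbon ends
up entirely in the two acids, and `verify_carbon_closure` quantifies the
violation of that assumption for measured inputs.

## Bayesian mixing model

Likelihood: each replicate observation of tracer t is
Normal(Σ_s F_s μ_st, √(Σ_s F_s² σ_st² + σ_res,t²)), independent across
tracers and replicates. Source-signature uncertainty enters through the
variance term (the published SIAR likelihood family); a latent-mean
variant (per-source signature means as additional parameters) would be a
natural extension but is not implemented. Priors: Dirichlet(1,…,1) on
the fraction vector, uniform(0, 20‰) on each residual SD.

Sampling is random-walk Metropolis in unconstrained coordinates: the
simplex through a centred stick-breaking transform with its exact
log-Jacobian (verified by quadrature against flat-Dirichlet moments),
residual SDs through their logarithms. A single global proposal scale
adapts every 50 iterations during burn-in toward 30% acceptance and is
frozen afterwards, so chains are valid Markov chains post-burn-in and
exactly reproducible from the seed. Defaults: 10,000 retained draws
after 5,000 burn-in, thin 1, seed 20210330. A split-chain R̂ > 1.05 on
any fraction raises a warning, not an error; short chains on
weakly-identified four-source problems commonly sit near 1.1 without
materially biasing posterior means (the calibration study below is the
operative check). Because the stick-breaking transform is
order-asymmetric, permuting the source order changes the chain's path;
summaries agree across permutations only within Monte Carlo error, and
the test suite checks them at that tolerance.

Identifiability: with T tracers and S sources the likelihood constrains
only T linear combinations of F. The study configuration (four sources,
one or two tracers) is under-determined, which is the normal situation
for isotope mixing models — the posterior then blends data and prior and
its mean need not converge to the truth as replicates grow. The exact
linear solve (`analytic_fractions_when_determined`) covers the
determined case S = T + 1 and deliberately reports infeasible
(outside-simplex) solutions with a flag instead of clipping: a negative
fraction is the algebraic signal of a missing source, mirroring the
geometric enclosure argument.

Study-level numbers pool per-environment posteriors: the overall mean is
the mean of per-environment posterior means, and its SD comes from Monte
Carlo resampling (one draw per environment per resample, averaged),
deterministic under the given seed.

Per-environment fits may use both tracers or acetic acid alone. The
acetic-only four-source mode is the configuration in which tropospheric
acetic-acid apportionments are usually reported; since published
accounts do not always state which mode was run, both are first-class
and tested.

## Geometry diagnostics

Convex hulls are computed by Qhull with explicit degenerate handling
(single point, collinear segment); containment uses polygon predicates
with a ‰ tolerance for the boundary class. For the δ_F/δ_A = 0.94
reference line two classifications are reported side by side: the
quotient class (sign of δ_F/δ_A − 0.94) and the half-plane class (sign
of δ_F − 0.94·δ_A). For the negative δ values of real samples the two
orderings are opposite whenever the point is off the line — the quotient
grows *downward* in the plane — so reporting both avoids silently
choosing an interpretation of "above the line". "On the line" means
|δ_F/δ_A − 0.94| ≤ 0.005 (one unit in the second printed decimal), which
is identical under both conventions.

## Synthetic data

`generate_environment_samples` draws true fractions from a flat
Dirichlet (or takes them fixed), replicate counts uniformly in 3–7 per
environment (the replicate range of the field campaign design), and
replicate noise from exactly the likelihood the mixing model assumes
(variance Σ F² σ² + σ_rep²), so parameter-recovery studies test the
sampler rather than model mismatch; a Student-t (df = 4, variance-matched)
switch provides deliberate misspecification for robustness checks.
Defaults: signature SDs 1.0‰ and replicate SD 0.9‰, the stated
analytical precision — per-environment replicate spreads are not
published numerically, so these are documented assumptions. Default
source signatures (δ_formic, δ_acetic): secondary biogenic
(−29.4, −31.4)‰ from the estimator; marine (−11, −15)‰, fossil
(−20.7, −22)‰ and primary biogenic (−24.9, −26.5)‰ are synthetic
placeholders spanning a realistic non-degenerate hull with fossil and
primary on the 0.94 ray — they are NOT measured values and are configurable
inputs everywhere (published end-member values for these sources exist
only as figure positions, not numbers).

`generate_photooxidation_runs` jitters the closed-form product signature
with independent Gaussian noise (default 0.3‰) per acid per run,
emulating replicate chamber experiments. Note that the noiseless centers
carry the ln-form gap, so the α recomputed from them is 1.00206, which
still prints as 1.002 at three decimals.

What passing synthetic tests do not show: real tropospheric data violate
the shared-signature assumption (source δ¹³C varies by region and
season), replicates are not independent draws of a fixed mixture, and
the four-source closure itself is an assumption — the geometric
containment diagnostic is the in-package check of that closure.

## Validation problem sizes

The calibration study runs 50 independent four-source/two-tracer
datasets with n = 6 replicates and full 10,000/5,000 chains
(≈ 35 s total); acceptance thresholds are ≥ 85% coverage of true
fractions by 95% equal-tailed credible intervals and per-source mean
absolute bias < 0.05. Measured at seed 20210330: 91% coverage, max
|bias| 0.004. The determined-case sampler-versus-oracle check agrees to
< 10⁻⁴ against a 0.02 tolerance. Geometry predicates are verified
against an O(n³) brute-force hull oracle and a half-plane containment
oracle on 1,000 random instances.

## Known limitations

* No concentration-weighted or time-resolved mixing; fractions refer to
  the isotope mass balance only.
* No Rayleigh/open-system fractionation; end-member mixing only.
* No trophic-enrichment offsets (a diet-study feature of SIAR-type
  models that does not apply here).
* The Metropolis sampler targets ≤ ~6 sources; larger source sets would
  warrant a gradient-based sampler.
* Transport durations are inputs; back-trajectory computation is out of
  scope.
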