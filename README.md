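# isomix

Dual-tracer stable carbon isotope source apportionment of atmospheric
formic and acetic acid.

## The problem

Formic and acetic acid are the most abundant organic acids in the
troposphere, yet chemistry-transport models persistently under-predict
their budgets. Because the two acids are co-emitted or co-produced by a
small set of sources — marine release, fossil-fuel combustion, direct
(primary) plant emission, and photochemical oxidation of biogenic
isoprene (secondary biogenic emission) — the paired stable carbon
isotope composition (δ¹³C of formic acid *and* δ¹³C of acetic acid)
fingerprints the origin of the acids in an air or precipitation sample.
`isomix` implements the complete computational chain needed to exploit
that fingerprint, for atmospheric chemists and isotope biogeochemists:

1. **Isotope algebra** (`isomix.isotope`) — δ notation
   (δ¹³C = (R_sample/R_VPDB − 1)·10³, ‰ vs VPDB), the intermolecular
   fractionation factor α = (δ¹³C_F + 10³)/(δ¹³C_A + 10³), linear
   mass-balance mixing δ_mix = Σ_s F_s δ_s, and atmospheric-lifetime
   bounds from back-trajectory transport durations.
2. **Secondary-source estimator** (`isomix.secondary`) — the closed-form
   solution of
   x + y = 1, x/y = r, x·δ¹³C_F + y·δ¹³C_A = δ¹³C_isoprene,
   δ¹³C_F − δ¹³C_A = 10³·ln α,
   giving the δ¹³C signature of acids formed by isoprene photo-oxidation.
3. **Bayesian mixing model** (`isomix.mixing`) — posterior inference of
   the source fractions F_S1..F_S4 (Dirichlet prior on the simplex,
   Gaussian likelihood with per-source signature variance Σ F² σ² plus a
   per-tracer residual term), sampled by an adaptive random-walk
   Metropolis chain in stick-breaking coordinates, with Monte Carlo
   propagation of uncertainty across sample replicates. Exposed as a
   scikit-learn-style estimator (`IsotopeMixingModel.fit`).
4. **Mixing-space geometry** (`isomix.geometry`) — convex source
   polygons, containment tests (a mixture outside the source enclosure
   demands an additional source), and classification against the
   δ¹³C_F/δ¹³C_A = 0.94 reference line.
5. **Synthetic data** (`isomix.simulate`) — generators that mirror the
   replicate sampling design and the photo-oxidation chamber experiment,
   plus a parameter-recovery harness for calibration checks.

## Worked example

Solve for the secondary-biogenic signature with the default inputs
(C3-plant mean −27‰ minus 2.8‰ isoprene-synthesis discrimination gives
the precursor δ¹³C of −29.8‰; branching ratio r = 3.9; α = 1.002):

```
$ isomix estimate-secondary
delta13C_formic_permil = -29.392244  (-29.4‰)
delta13C_acetic_permil = -31.390247  (-31.4‰)
x_formic = 0.795918  (0.796)
y_acetic = 0.204082  (0.204)
formic/acetic delta ratio = 0.9363
```

About 80% of the precursor carbon ends up in formic acid, and the
resulting source signature (−29.4, −31.4)‰ lies on the 0.94 reference
line (ratio 0.9363 ≈ 0.94 at two decimals), to the depleted lower-left
of the fossil and primary-biogenic end-members.

An air mass that carried the acids for 120 h bounds their tropospheric
lifetime from below at 5 days, which recent modelled lifetimes
undershoot:

```
$ isomix lifetime --transport-hours 120 --modeled-days 3.2,4.5,2.3
lifetime lower bound: 5 days (120 h transport)
modelled 3.2 days underestimates the bound by 56%
modelled 4.5 days underestimates the bound by 11%
modelled 2.3 days underestimates the bound by 117%
```

The full pipeline runs from the shell: `isomix simulate` writes a
synthetic multi-environment dataset (sources.csv, mixtures.csv, ground
truth, manifest), `isomix fit` apportions each environment and pools
the posteriors, and `isomix diagnose` reports hull containment and
0.94-line classes for a points file. The same operations are available
as library calls (`generate_environment_samples`, `fit_mixing_model`,
`propagate_across_replicates`, …).

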