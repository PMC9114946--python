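# Methods

## Constitutive model

Tendon is treated as an incompressible, transversely isotropic,
pseudoelastic composite of a non-collagenous matrix (NCM) and axially
aligned collagen fibrils.  The strain-energy density decouples the two
phases by volume fraction φ:

    W(I1, I4) = (1 − φ) μ/2 (I1 − 3) + φ E w_coll(I4),

with the NCM neo-Hookean (shear modulus μ) and the fibril energy driven by
the fourth invariant I4 = λ², the squared stretch along the fibril axis.
Each fibril is slack until the tissue stretch reaches its recruitment
stretch λr and Hookean afterwards,

    σ_fib(λ, λr) = E (λ − λr)/λr   for λ > λr,   0 otherwise,

and λr follows a triangular probability density on [a, b] with mode c.
The symmetric triangle (`st`, c = (a + b)/2) has four free parameters and
the general triangle (`gt`) five.  Because μ, E and φ enter only through
the products (1 − φ)μ and φE, those two moduli are the identifiable
material parameters; the package never attempts to separate them.

Integrating Hooke's law against the triangular density gives the
population (Cauchy) stress in closed form,

    σ_F(I4) = E (A + B √I4 + C I4 + (D/2) √I4 log I4),

with constants A–D that change between four recruitment regimes
(slack √I4 < a, rising branch a ≤ √I4 < c, falling branch c ≤ √I4 < b,
fully recruited √I4 ≥ b).  The constants are derived by analytic
integration of the convolution integral (rederived independently with
sympy in the test suite, and checked against adaptive quadrature to a
relative 1e−8); they are *not* transcribed from any table.  The energy
w_coll follows from σ_F = 2 I4 dW/dI4 and carries one additional
per-regime constant G fixed by continuity and w_coll(a²) = 0.  Regime
boundaries are assigned half-open (slack [0, a²), rising [a², c²), falling
[c², b²), full [b², ∞)); all quantities are continuous across them, so the
assignment is observationally irrelevant.  The degenerate modes c = a and
c = b are supported as one-sided limits (the density keeps only the
non-degenerate branch), which the general-triangle sampler needs when the
posterior concentrates near the edges of the skewness range.

Uniaxial engineering stress is obtained from the Cauchy stress with the
incompressibility pressure eliminated through the traction-free lateral
surface (σ_rr = 0) and division by λ:

    N(λ) = (1 − φ)μ (λ − 1/λ²) + φE (A/λ + B + C λ + D log λ).

No general 3-D tensor evaluation is implemented; the analytic uniaxial
reduction is the model surface.

Two benchmarks are included.  The transversely isotropic HGO model

    W = c_HGO/2 (I1 − 3) + k1/(2 k2) (exp(k2 (I4 − 1)²) − 1)

yields N_HGO = c_HGO(λ − 1/λ²) + 2 k1 λ (λ² − 1) exp(k2 (λ² − 1)²).  The
squared exponent follows from differentiating the energy; the
energy–stress consistency tests enforce this form.  The exponent is
clipped at the double-precision overflow threshold and overflowing
parameter vectors return ±inf, which the samplers treat as rejections.
The second benchmark is a crimp-angle tendon model (sequential
recruitment from the fascicle core outwards, outermost crimp angle θo)
extended with a shift strain γ, entering through I4 = (λ − γ)²; its
engineering stress has three branches, continuous at λ = 1 + γ and
λ = 1/cos θo + γ.

## Nonlinear fitting

All models are fitted by Nelder–Mead on unconstrained coordinates: logs of
the positive natural increments ((1 − φ)μ, φE, a − 1, b − a; c − a and
b − c for the general triangle; a logit map for θo and log γ for the
crimp-angle model).  This encodes the ordering/positivity constraints in
the geometry of the search space, identical to the parameterization used
for sampling.  Two data-dependent constraints — recruitment onset inside
the tested range (a < λ_max) and γ < λ_max − 1 — are enforced by an
infinite objective.  Each run is capped at 1000 simplex iterations and the
fitter is restarted from the previous endpoint, five runs total by
default; the end-of-run objective trace is returned and is non-increasing.

The objective is the mean absolute error Δ by default; the mean relative
error δ and the sum of squared errors are selectable.  δ is undefined when
the record contains zero observed stresses (e.g. the unloaded first point
of a synthetic grid); the standalone metric raises in that case, and a fit
report shows NaN for δ rather than silently excluding points.

Default initial estimates come from a two-segment linear pre-fit: the
toe-region slope estimates the NCM modulus via dN/dλ ≈ 3(1 − φ)μ near
λ = 1, the final-fifth slope minus the toe slope proxies the recruited
fibril stiffness, and the recruitment window starts at 10% and 90% of the
tested strain range.  Placing the onset much closer to λ = 1 was found to
start the simplex on a degenerate ridge — recruitment never completing
inside the data, with b and φE diverging jointly — so the 10%/90%
placement is the package default; all initials are configurable.

## Statistical model and posterior

Observed stresses are the forward curve plus IID mean-zero Gaussian noise
of unknown variance σ² (MPa²).  σ² carries a conjugate
inverse-gamma(ασ, βσ) hyperprior, with defaults ασ = 3, βσ = 0.3, and is
marginalized analytically: the resulting "likelihood" in the remaining
parameters is a multivariate Student-t with 2ασ degrees of freedom,
location M(θ) and diagonal scale (βσ/ασ) I_d, evaluated in log space using
only the residual sum of squares (no d × d matrix is formed).  A 1-D
quadrature over σ² reproduces the closed form to better than 1e−6 in log
in the tests; so does scipy's multivariate-t density.

Sampling operates on the transformed coordinates θ (the same unconstrained
coordinates as the fitter).  Natural increments carry lognormal priors,
whose pullback through the transform — lognormal density times the
Jacobian |det DT⁻¹| = exp(Σθi) (exactly, for the log-coordinates; the
logit coordinate of the crimp-angle model contributes its own closed-form
term) — collapses to independent Gaussian densities on θ.  The prior is
therefore specified as per-coordinate (mean, sd) on the transformed scale.
Defaults are weakly informative: centred on the transformed optimization
estimate with sd 2.0 (a multiplicative factor of e² ≈ 7.4 on each natural
increment).  Priors, hyperparameters and the chain configuration are all
arguments (and YAML-configurable through the CLI); nothing is hard-coded.

## Adaptive random-walk Metropolis

The sampler is a Gaussian random-walk Metropolis with proposal covariance
Σ = β²ζ, adapted only during burn-in:

- initial β² = 2.38²/h (h the parameter dimension), ζ = I;
- after every block of 500 samples, ζ is recomputed as the empirical
  covariance of the trailing 10 000 chain positions (all available
  positions early on) plus a 1e−5 ridge, which guarantees positive
  definiteness;
- β² is multiplied by 0.95² when the block acceptance rate falls below
  0.184, by 1.05² when it exceeds 0.284, and kept otherwise — a tolerance
  band of 0.234 ± 0.05 around the optimal multivariate RWM acceptance
  rate;
- adaptation stops at the end of burn-in (diminishing adaptation), and the
  frozen Σ is used for the remainder of the chain.

The ridge does useful work beyond regularization: from the deliberately
over-dispersed initial scale the first stuck block collapses ζ to ≈ 1e−5 I,
after which β² climbs back into the tolerance band within a few tens of
blocks.  Chains are reproducible bit-for-bit from a single integer seed.

Default chain sizes are 150 000 samples with a 50 000-sample burn-in.
These desk-scale defaults sample the four-parameter posterior on a
200-point record in ~15 s on one core and leave 100 adaptation blocks,
ample for the scale to settle; longer production chains (e.g. 1.5 million
samples with 500 000 burn-in) are available by argument.

## Synthetic data

The generator evaluates the symmetric-triangle forward curve at
[(1 − φ)μ, φE, a, b] = [7 MPa, 800 MPa, 1.03, 1.13] — the canonical
validation conditions — on a stretch grid and adds IID N(0, 0.01 MPa²)
noise.  The default grid is 200 uniform stretches on [1.0, 1.10],
standing in for the strain schedule of a high-resolution equine tendon
test whose elastic region ends near 10% strain (the exact experimental
abscissa lives in an external deposit and is not shipped; any grid can be
passed instead).  Note that b = 1.13 lies beyond the largest tested
stretch, so full recruitment is never observed and b is informed only
through the curvature of the falling recruitment branch — its posterior is
accordingly the widest, which is a property of the experimental design,
not of the sampler.

What the generator does *not* emulate: viscoelastic hysteresis and
preconditioning, strain-rate dependence, heteroscedastic or correlated
measurement noise, slack/toe-region artefacts, and the approach to
failure.  Passing recovery tests therefore demonstrates correctness of the
pipeline under the stated noise model, not robustness to those real-data
features.

## Posterior summaries

Credible intervals are equal-tailed sample percentiles (the construction
is a package choice; no method is canonical).  Intervals and correlations
are computed on the unthinned post-burn-in chain; `thin` exists for
visualization and export.  Predictive bands subsample up to 50 000
post-burn-in parameter vectors without replacement — with a dedicated
seeded RNG stream, independent of the chain's — and report the pointwise
mean ± k standard deviations of the predicted stress (k = 5 by default).
The band carries parameter uncertainty only; observation noise is not
added, so when comparing raw noisy data against the band the noise
standard deviation should be added to the band half-width.  The skewness
of a general-triangle posterior draw is summarized by
(2c − b − a)/(b − a) ∈ [−1, 1], evaluated as ((c − a) − (b − c))/(b − a)
so the one-sided limits are float-exact.

## Numerical choices and edge cases

- Quadrature oracle: the recruitment integral is integrated with the mode
  passed as a breakpoint; near the recruitment onset both the quadrature
  and the closed form lose relative accuracy to cancellation (the stress
  vanishes cubically), so oracle comparisons use a small absolute floor
  alongside the 1e−8 relative tolerance.
- Derivative oracles in the tests use fourth-order central differences;
  plain central differences are visibly polluted by the large curvature of
  the exponential benchmark and by cancellation near recruitment onset.
- Maximum-gradient truncation uses forward differences, ties broken to the
  earliest index, and keeps the points strictly before the max-gradient
  point.  The operation tags the record's provenance and is a no-op on an
  already-tagged record: the cut is meant to remove the approach to
  failure once, and re-applying the argmax rule to an already-cut record
  would otherwise keep shrinking monotone-gradient data.
- Fixed-strain truncation keeps the boundary point (λ ≤ 1 + ε_max with a
  1e−12 slack for decimal round-off).
- Records enforce strictly increasing stretch ≥ 1 and finite stresses at
  construction.

## Known limitations

- Elastic loading only: no viscoelasticity, preconditioning, damage or
  failure modelling; fits are specific to the strain rate of the data.
- Only the products (1 − φ)μ and φE are identifiable from uniaxial data.
- Convergence diagnostics are limited to acceptance-rate tracking, the β²
  trajectory and seed-level repeatability; formal diagnostics (R-hat,
  ESS) are out of scope, though saved chains are plain CSV and easy to
  pass to external tools.
- Single-record calibration only; joint multi-dataset fitting with shared
  constitutive parameters is not implemented.
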