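# tendonfit

Microstructural, hyperelastic modelling of tendon stress–strain behaviour,
with classical nonlinear fitting and fully Bayesian calibration.

Tendon owes its nonlinear tensile response to the gradual recruitment of
initially crimped collagen fibrils: each fibril is slack until the tissue
stretch reaches its recruitment stretch λr, and linearly elastic (modulus
E) afterwards.  `tendonfit` models the recruitment stretches with a
triangular distribution on [a, b] (mode c), embedded in an incompressible,
transversely isotropic composite with a neo-Hookean non-collagenous matrix:

    W(I1, I4) = (1 − φ) μ/2 (I1 − 3) + φE · w_coll(I4),
    N(λ)      = (1 − φ)μ (λ − 1/λ²) + φE (A/λ + B + Cλ + D log λ),

where the constants A–D are piecewise in the recruitment regime and known
in closed form, so the engineering stress N(λ) costs a handful of floating
point operations — cheap enough to evaluate millions of times inside a
Markov chain Monte Carlo loop.  Only the products (1 − φ)μ and φE are
identifiable from uniaxial data.  Both the symmetric (`st`) and general
(`gt`) triangle are provided, along with two benchmarks: the
Holzapfel–Gasser–Ogden model (`hgo`) and a crimp-angle tendon model with a
recruitment shift (`tendon`).

On top of the forward models the package provides:

- **Fitting** — constrained Nelder–Mead in log-transformed coordinates
  (1000 iterations per run, 5 restarted runs), with mean-absolute-error,
  mean-relative-error and sum-of-squares objectives.
- **Bayesian calibration** — the Gaussian noise variance carries a
  conjugate inverse-gamma(ασ, βσ) hyperprior and is marginalized
  analytically, leaving a Student-t posterior over the (log-transformed)
  model parameters sampled by an adaptive random-walk Metropolis: proposal
  covariance β²ζ with ζ re-estimated every 500-sample block from the
  trailing 10 000 positions (+1e−5 ridge) and β² steered into the
  acceptance band 0.234 ± 0.05; adaptation stops when burn-in ends.
- **Summaries** — equal-tailed credible intervals, posterior correlations,
  a triangle-skewness statistic (2c − b − a)/(b − a), predictive
  mean ± k·sd stress bands, and thinning for export.
- **Synthetic data** — a seeded generator producing noisy tensile records
  from known ground-truth parameters.

See `docs/methods.md` for the model derivation, the statistical model and
all numerical choices.

## Worked example

Calibrate the symmetric-triangle model on a synthetic tensile test whose
ground truth is [(1 − φ)μ, φE, a, b] = [7 MPa, 800 MPa, 1.03, 1.13] with
noise variance 0.01 MPa²:

```python
import tendonfit as tf

mat  = tf.MaterialParams(ncm_modulus=7.0, fibril_modulus=800.0)
dist = tf.TriangularRecruitment.symmetric(1.03, 1.13)
rec  = tf.generate_synthetic(mat, dist, noise_var=0.01, seed=1)

fit = tf.fit_model("st", rec)                 # Nelder-Mead point estimate
print({k: round(v, 4) for k, v in fit.as_dict().items()}, round(fit.delta, 4))

chain = tf.run_inference(rec, model="st",     # adaptive RWM, ~15 s
                         n_samples=150_000, burn_in=50_000, seed=42)
summ = tf.summarize_chain(chain, level=0.95)
for name, m, lo, hi in zip(summ.param_names, summ.means, summ.lower, summ.upper):
    print(f"{name:16s} mean={m:9.4f}  95% CI=({lo:.4f}, {hi:.4f})")
print("acceptance:", round(chain.acceptance_rate, 3))
```

Output:

```
{'ncm_modulus': 7.0616, 'fibril_modulus': 780.2936, 'a': 1.0305, 'b': 1.128} 0.0709
ncm_modulus      mean=   6.9359  95% CI=(6.6228, 7.2461)
fibril_modulus   mean= 784.2155  95% CI=(735.4192, 839.8405)
a                mean=   1.0302  95% CI=(1.0292, 1.0311)
b                mean=   1.1286  95% CI=(1.1242, 1.1334)
acceptance: 0.226
```

Every generating value lies inside its 95% credible interval; the mean
absolute error of the point fit (0.071 MPa) is at the level of the added
noise, and the posterior reproduces the physically expected correlation
structure (later recruitment onset trades off against a stiffer matrix,
stiffer fibrils against a longer recruitment window).  `b` has the widest
interval because the test never stretches past full recruitment
(λ ≤ 1.10 < b).

The same workflow is available from the shell:

```sh
tendonfit simulate --params params.yaml --noise-var 0.01 --seed 1 --out syn.csv
tendonfit fit      --model st --data syn.csv --dialect stretch
tendonfit sample   --model st --data syn.csv --dialect stretch \
                   --n 150000 --burn-in 50000 --seed 42 --out chain.csv
tendonfit summarize --chain chain.csv --out posterior
```

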