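# Methods

## Model

A ligand in solution binds targets immobilized on beads. Binding the first
target carries the full localization-entropy penalty; each subsequent binding
to a colocalized target is entropically free and contributes only its
residual (intrinsic) binding free energy, assumed identical across the up to
`N − 1` additional bindings. The bound/unbound ligand ratio is then a
partition function over the number of additional targets a surface-localized
ligand can reach:

```
ρ(T, s) = (T / K_nc) · Σ_m P(m) (1 + w)^m
```

where `P(m)` is the prior occupancy distribution of additional reachable
targets and `w` the statistical weight of one additional binding. Two
occupancy priors give the two DDC models:

* **Poisson** (targets sprinkled at random on the surface, no ceiling):
  the sum is `exp(λw)`; with `λw = κ∞ T/s` this yields the asymptotic model
  `ρ = (T/K_nc) exp(κ∞ T/s)`. Two parameters; accurate at modest TSD.
* **Binomial** (`N − 1` slots, per-slot probability `p`): the sum is
  `(1 + pw)^{N−1}`; with `pw = κT/(N s)` this yields the complete model
  `ρ = (T/K_nc) (1 + κT/(N s))^{N−1}`, valid at all TSD. As `N → ∞` at fixed
  `κ` it converges to the asymptotic form.

`ddcbind.oracle` recomputes these sums term by term (log-space accumulation;
Poisson truncated where the *weighted* tail falls below 1e−12 of the partial
sum, since the reweighted tail — not the raw Poisson tail — controls the
error) and is the arbiter of the closed forms: the test suite demands
agreement to 1e−10 relative over a randomized sweep with `T/K_nc` in
[1e−3, 1e3], cooperative load `κT/s` in [0, 20] and `N` in 1…8. The
posterior occupancy of a bound ligand is the prior tilted by `(1+w)^m`:
Poisson(λ(1+w)) and Binomial(N−1, p(1+w)/(1+pw)) respectively, both verified
by enumeration.

Retention after washing is linear in the bound fraction,
`f_ret = b(1 − f_B) + r f_B`, with background retention `b` and bound-ligand
retention `r` (r < 1 is interpreted as loss of bound ligand during the
washes). Free and total target are identified (target excess); no kinetics
(equilibrium only); no allosteric mechanism anywhere — cooperativity is
purely geometric/entropic.

### Units

Package-wide: `T` in molar, `s` as the dimensionless fraction of reaction
volume occupied by packed beads (30 µl beads in 0.5 ml → s = 0.06), so `κ`
and `κ∞` carry (volume fraction)·M⁻¹ and `κT/s` is dimensionless. File
columns are suffixed `_molar` / `_volfrac`; a `--units uM` flag converts
micromolar tables on input.

### Derived design quantities

Along a CTSD dilution path `s = s*·T/T*` the TSD is constant and the
complete model is exactly `ρ = T/K_c` with
`K_c = K_nc / (1 + κT*/(N s*))^{N−1}`; the enhancement `K_nc/K_c` measures
how much immobilization density amplifies affinity. The VTSD log–log slope
`d ln ρ / d ln T = 1 + (N−1)·cT/(1+cT)` (`c = κ/(N s)`) rises from 1 toward
`N`; the CTSD slope is identically 1.

### Inflection detection

`has_inflection` decides whether `f_B(T)` on linear axes has an inflection,
numerically: the sign of `f_B''` equals the sign of `ρ''(1+ρ) − 2ρ'²`, which
is evaluated from analytic first/second derivatives of `ρ` entirely in log
space (so `exp(κ∞T/s)` overflow cannot corrupt the sign), scanned on a
600-point log grid spanning `1e−6·K_nc` to `1e6·K_nc`, with the bracketed
sign change refined by Brent root finding. A Langmuir curve is concave
everywhere; strong cooperativity makes the curve convex at low `T` (for the
asymptotic model, exactly when `κ∞K_nc/s > 1`, i.e. when binding two targets
is more likely than one at `T = K_nc`), producing an inflection; weak
cooperativity can enhance affinity with no inflection at all. The numerical
detector is authoritative; the analytic low-T criterion is only a
cross-check.

## Fitting

All estimators minimize `Σ w_i (f_ret,i − model_i)²` with
`scipy.optimize.least_squares` (trf, bounded). Weights: inverse variance
`1/se²` when per-point standard errors are supplied, else a
constant-coefficient-of-variation scheme `1/(cv·max(f, floor))²` with
cv = 0.05, floor = 0.01 (count-ratio data have roughly multiplicative
error; the floor keeps near-zero points from dominating), or uniform on
request.

Parameters are transformed for optimization: log for `K_nc`, `K_c`, `κ`, `κ∞`
(positivity and order-of-magnitude scale disparities), logit for `b`, `r`,
linear for `N` bounded to [1, 20]. Multi-start: a deterministic grid of
initial values around data-driven heuristics (K from the half-max `T`, κ from
unit cooperative load at the top of the titration, N ∈ {2, 4, 8}), plus
optional seeded random restarts; the best objective wins, ties broken by
smaller parameter-vector norm; convergence at 1e−12 relative tolerances. In
the joint VTSD+CTSD fit, `b` and `r` are shared between designs (same
ligand, beads and wash protocol), and the VTSD arm uses the complete-DDC
curve while the CTSD arm uses its Langmuir reduction — one parameter set,
two design geometries.

Covariance is Gauss–Newton `(JᵀJ)⁻¹` at the optimum scaled by the reduced
chi-square, mapped to the natural scale by the delta method; standard errors
are square roots of its diagonal. An estimate whose standard error exceeds
half its magnitude is flagged `nd` (not determined accurately) in the
parameter table. The `K_c` implied by a joint fit carries a delta-method
standard error propagated through `K_c(K_nc, κ, N)` with a numerical
gradient. `N` pinned at a bound is reported with a warning rather than
silently accepted.

Verified estimator properties (test suite): exact recovery on noise-free
data; `κ = 0` constraints reproduce the nested Langmuir fits; Langmuir-on-
CTSD `K_c` equals the analytic `K_c` of the generating DDC parameters; the
covariance is PSD with consistent standard errors.

## Synthetic data

`ddcbind.simulate` emulates the reference bench protocol: `s* = 0.06`
(30 µl packed beads per 0.5 ml reaction), `T` log-spaced over 0.0024–50 µM —
13 points for VTSD titrations, 9 for CTSD — with `T* = 50 µM` the
common top concentration where the two designs coincide. Default noise is
proportional Gaussian with cv = 0.05 and an absolute sd floor of 0.005,
independent across points and designs, reproducible from the scenario seed;
retained fractions are clipped to [0, 1.05] (a ceiling above 1 avoids
asymmetric censoring of near-saturation noise, which would bias `r`).
Recorded per-point `se` equals the generating sd, so inverse-variance
weighting downstream is correctly calibrated.

Six presets (`reference_scenarios`) span the observed regimes. Their labels
echo the aptamer∘peptide pairs of the motivating experiments, but their
parameter values are synthetic constructions: all have `N = 4`,
`b = 0.02`, `r = 0.8`; cooperative constants `K_c` sit in 0.21–1.6 µM; the
enhancement folds are 600 (strongest), 150, 100, 40, 30 and 10, the last —
`ns2_h3c_like` — constructed to raise affinity tenfold with *no* inflection
point, reproducing the qualitative dichotomy between curve-shape change and
affinity enhancement. `κ` is solved from the enhancement and `K_nc = K_c × E`,
so each preset is specified by the two quantities a titration actually pins
down.

What the generator does *not* emulate: radiolabel decay, bead-handling and
pipetting error structure, replicate correlation, target depletion at low
excess, and surface heterogeneity (pores/convolutions). Passing recovery
tests therefore demonstrate estimator correctness under the stated noise
model, not robustness to every real-data pathology.

## Calibration study

`ddcbind.calibration.recovery_study` simulates the `N = 4`, enhancement-100
preset (`K_nc = 50 µM`, `K_c = 0.5 µM`) on the reference grids with pure
proportional noise at cv = 0.03, refits each replicate jointly plus a
separate Langmuir fit of the CTSD arm, and summarizes: median relative error
of `K_nc` and of the implied `K_c`, the fraction of runs with `N` within ±1,
and the fraction where the two `K_c` estimates agree within twice their
combined standard error (the 2σ criterion is the natural reading of
"agreement within standard errors" for a ~95% event). 200 replicates run in
about a minute on one CPU; the acceptance script exposes `--n-recovery` to
scale this.

## Numerical choices

* `ρ` computations are vectorized; `T = 0` returns `ρ = 0` and retention `b`
  exactly, and is excluded from log–log transforms (the ρ transform is
  hypersensitive to fluctuations near the `f_ret` boundaries).
* `fraction_bound` maps `ρ = inf` to 1, so overflow in the asymptotic
  exponential degrades gracefully during optimizer exploration.
* Oracle sums, inflection curvature and Poisson truncation all work in log
  space; no closed-form-vs-enumeration comparison is allowed to pass through
  a subtraction of near-equal large terms.
* CSV round-trips use `float_precision="round_trip"` so written datasets
  reload bit-identically.
* Design-inequality checks (CTSD > VTSD) compare on the ρ scale, where the
  strict inequality survives in floating point; `f_B` saturates to 1.0 at
  extreme cooperative load.

## Known limitations

* The asymptotic and complete cooperativity constants are stored separately;
  no automatic κ∞ ↔ κ conversion is applied (their equality is a large-N
  limit, not an identity).
* The selectivity ratio is the minimal core of enrichment analysis — the
  ratio of retained fractions of two ligands at one condition; no
  multi-round selection simulator is included.
* Membrane/filament target geometries (binomial/Poisson occupancy on lines
  or fluid surfaces) are compatible with the formalism but not separately
  implemented.
* `N` is an effective, possibly non-integer ceiling; its physical
  interpretation as a literal maximum holds only for a sharp cutoff.
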