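# Methods

## Model

The toolkit implements a six-compartment tumor–immune system

```
T'    = alpha*T*(1 - beta*T) - gamma*T - phi*C*T
C'    = phi*C*T + rho*C*D - kappa*C
D'    = mu - rho*C*D - omega*D - lam*D
IL2'  = lam*D - d*IL2
IL12' = d*IL2 - psi*IL12
Z'    = psi*IL12 - a*Z
```

where `T` is the tumor burden with logistic growth (rate `alpha`, inverse
carrying capacity `beta`) killed by dendritic cells (`gamma`) and CD8+
T cells (`phi`); `C` is the CD8+ pool, recruited through tumor and
dendritic-cell contact (`phi`, `rho`) and dying at `kappa`; `D` the
dendritic pool with constant source `mu` and decay `omega`; and
`D -> IL2 -> IL12 -> Z` a linear cytokine chain (rates `lam`, `d`, `psi`)
feeding the anti-PD-L1 inhibitor `Z` (decay `a`). All rates are per day
(assumed unit; the reference scenario states none). The time derivative is
replaced by the fractal-fractional operator of order `xi` and fractal
dimension `eta` (both in `(0, 1]`) with Mittag-Leffler kernel, the
Atangana–Baleanu construction with normalization
`AB(xi) = 1 - xi + xi/Gamma(xi)`; `xi = eta = 1` recovers the classical
system.

The CD8+ compartment plays the role of an epidemic "infected" class: its
persistence threshold is `R0 = mu*rho / (kappa*(lam + omega))`, derived in
`model.reproduction_number` and cross-checked by an explicit one-compartment
next-generation-matrix construction (`reproduction_number_ngm`) with
new-infection term `rho*C*D` linearized at the disease-free point. The
infected set is `{C}` alone; this is the unique choice reproducing the
closed form, because `phi*C*T` vanishes at `T = 0`.

### Equilibria

* Disease-free point `D1 = (0, 0, mu/s, mu*lam/(d*s), mu*lam/(psi*s),
  mu*lam/(a*s))` with `s = omega + lam`; always returned.
* Interior point via the closed forms with discriminant
  `A = sqrt(4*beta*alpha*mu*rho^2*phi^2 + (rho*alpha*(phi - beta*kappa) +
  phi*(-rho*gamma + phi*(omega + lam)))^2)`. Both `+/-A` branches are
  evaluated with the published per-coordinate sign pattern; a branch is
  returned only when all six components are strictly positive *and* the
  residual `||rhs||_inf < 1e-8*(1 + max|state|)` holds. Positivity is the
  only biologically meaningful branch selector; the sign pattern alone mixes
  branches across coordinates.
* Tumor-free boundary point `T = 0`, `D = kappa/rho`,
  `C = mu/kappa - (omega + lam)/rho`, cytokines at chain balance. It exists
  iff `R0 > 1` and is computed in addition to the interior forms because in
  the slow-tumor regime (`alpha < gamma`, including the reference scenario)
  the interior closed forms yield a nonpositive tumor coordinate and the
  "endemic" notion would otherwise be vacuous.

### Sensitivity

`dR0/d(mu, rho, kappa, lam, omega)` are the analytic partial derivatives of
the closed form, with normalized elasticities `(p/R0)*dR0/dp`. The sign of
`dR0/dmu` is positive — `rho/(kappa*(lam + omega)) > 0`; a warning is logged
when the table is emitted because the derivative is sometimes tabulated
with the opposite sign. Tests compare every derivative against a central
finite difference evaluated in extended precision (in double precision the
symmetric difference cancels catastrophically when, e.g., `lam ~ 1e-7`
perturbs `lam + omega ~ 0.24`).

## Mittag-Leffler evaluation

`E_xi(z) = sum_k z^k / Gamma(xi*k + 1)` is evaluated by the power series
with adaptive truncation (`|term|` below `series_tolerance`, default 1e-16,
past the term-magnitude peak; cap 10,000 terms). For `z < 0` the series
alternates and the largest term is ~`exp(|z|^(1/xi))` while the result lies
in `(0, 1]`, so the sum is accumulated with mpmath at a working precision
of 30 digits plus the decimal size of the peak term, and the truncation
cutoff is absolute rather than relative. Arguments are restricted to
`|z| <= 1e4`; when the cancellation guard would exceed 300 digits the
evaluation raises a convergence error instead of silently degrading.
Asymptotic and Pade branches are deliberately out of scope — every
in-package use is a moderate negative argument.

Two gotchas encountered and now guarded by tests: the truncation test must
be absolute for negative arguments (a relative test against the huge
mid-series partial sums truncates with an O(1) error), and the gamma
argument `xi*k + 1` must be formed in extended precision (a double-precision
argument perturbs `Gamma` by enough to destroy the cancellation entirely).

### Positivity bounds

Each compartment `x` with sup-norm loss rate `r` (e.g.
`r_T = alpha*beta*||T|| + gamma + phi*||C||`, `r_Z = a`) obeys

```
x(t) >= x(0) * E_xi( -b^(1-eta) * xi * r * t^xi / (AB(xi) - (1-xi)*r) )
```

`b` is a caller-supplied time-scale constant defaulting to 1 (no value is
prescribed by the construction). When `(1-xi)*r >= AB(xi)` the denominator
is nonpositive and the bound's premises fail; the function raises a domain
error rather than guessing a continuation. At `xi = eta = 1` the bound for
`Z` collapses to `Z(0)*exp(-a*t)`, which is tested.

## The memory integrator

The Volterra form of the fractal-fractional system is

```
x(t) = x(0) + eta*(1-xi)/AB(xi) * t^(eta-1) * F(t, x(t))
     + xi*eta/(AB(xi)*Gamma(xi)) * Int_0^t s^(eta-1) F(s, x(s)) (t-s)^(xi-1) ds
```

On the uniform grid `t_k = k*dt`, the fractal-weighted history
`y(s) = s^(eta-1) F(s, x(s))` is interpolated by piecewise quadratic
(three-point backward Newton) polynomials on each panel `[t_w, t_{w+1}]`,
`w = 2..k`, and integrated against the kernel exactly; this gives the three
weighted history sums with the bracket weights implemented in
`kernel_weights` (prefactors `xi*eta*dt^xi / (AB(xi)*Gamma(xi+1,2,3))`, the
third halved). Design choices:

* **Initial-condition term and leading panels.** The Volterra form requires
  the `x(0)` term and the full memory range `[0, t]`. Presentations of this
  scheme that start the history sums at `w = 2` silently drop the `[0, t_2]`
  panels; with them dropped, the first two steps' worth of integral is
  missing and the classical limit disagrees with an adaptive reference at
  O(1) relative error near `t = 0`. Here the two leading panels are
  integrated with the same exact-moment Newton quadrature using the first
  available nodes (nodes `0,1,2`), so at `xi = eta = 1` the update telescopes
  into a consistent classical linear-multistep method (observed
  self-convergence order ~2-3, classical-limit agreement ~1e-3 relative on
  the reference scenario).
* **Bootstrap.** Step 1 is a one-term fractional (Atangana-Baleanu) Euler
  step — constant interpolant on `[t_0, t_1]`; step 2 uses linear
  interpolation through nodes 0, 1. From step 3 on the full quadratic
  scheme applies.
* **Third-sum prefactor.** `xi*eta` uniformly across all compartments
  (dimensional consistency; one published display drops the `eta`).
* **Fractal weight at t = 0.** `t^(eta-1)` is singular at 0 for `eta < 1`;
  the node weight at `t_0` is clamped to `dt^(eta-1)` (the first positive
  grid node). Exact at `eta = 1`. The residual effect is an O(dt^eta)
  contribution confined to the first panel.
* **History handling.** Sums are recomputed from scratch each step
  (O(N^2) total) with numpy vectorization; no fast-convolution
  approximation. At desk scale (N <= 1e4) exactness beats speed; a
  5,000-step run takes about a second.
* **Determinism.** No randomness anywhere in the integrator; repeated runs
  are bit-identical, and `store_every` only thins the stored output.

### Convergence measurement

`convergence_order` runs `dt, dt/2, dt/4` against a `dt/8` reference and
reports log2 error ratios of the **terminal-time** max-norm difference
(relative to the reference scale). For `xi < 1` the solution carries a
weakly singular `t^(eta-1)`-type transient at `0+`; pointwise errors on the
first few grid nodes saturate for every memory discretization of this
family, so the endpoint error is the appropriate self-convergence measure.
Observed: order ~2 at `xi = 1`, ~1.1-1.5 at `xi = 0.9` on the reference
scenario (study sizes: `t_end = 10`, base `dt = 0.2`).

## Stability machinery

At the disease-free point the Jacobian is lower triangular; the closed-form
spectrum is `{-a, -d, alpha-gamma, -psi, -lam-omega,
(mu*rho - kappa*(lam+omega))/(lam+omega)}`, so local asymptotic stability
holds iff `alpha < gamma` and `R0 < 1`. Verdicts use a `+/-1e-12` tie band
around zero ("marginal") so numerically zero eigenvalues never silently
classify. For fractional orders the Matignon sector `|arg| > xi*pi/2` is
weaker than real-part negativity, so real-part verdicts remain sufficient
for all `xi` in `(0, 1]`; no sector-specific criterion is implemented.

Linear feedback control subtracts `w_i*(x_i - x_i*)` per equation; at any
equilibrium this shifts the Jacobian diagonal by `-w_i`. At the disease-free
point the controlled matrix stays triangular and the controlled spectrum is
the shifted diagonal exactly. The gain vector
`(1, 0.5038, 3, 4.0027, 5.0027, 6)` used in tests and the acceptance script
is *inferred* by inverting those diagonal closed forms against the published
controlled spectrum (the gains themselves are not published). Controlled
spectra at interior points are computed numerically from the Jacobian of the
vector field; no closed form is asserted there because the published
interior control matrix contains entries inconsistent with the vector
field's partial derivatives (an extra `d` coupling in the inhibitor row and
a `-rho*D*` term in the IL-2 row), and the published interior eigenvalue
list is therefore not used as a reference value.

The Lyapunov function is the Volterra/Goh form
`L = sum_i (x_i - x_i* - x_i* log(x_i/x_i*))`, defined for componentwise
positive states and reference points. Its derivative along trajectories is
split term-for-term into a positive aggregate `Sigma` and a negative
aggregate `Omega` exactly as the decomposition is published — including the
sign-ambiguous `+psi*IL12 - psi*IL12*` pair kept inside `Sigma` — because
the decision rule under test is `Sigma < Omega  =>  L decreasing`, not a
cleaned-up derivation. `global_stability_scan` evaluates the records along
a trajectory, skips (and counts) steps with nonpositive components, and
reports how often the finite-difference `L` is non-increasing where the
certificate holds; the 95% test threshold allows for discretization noise
at sign changes.

## Well-posedness constants

With the global-derivative reading `D_n x = x'/n'` and default `n(t) = t`
(`n' = 1`; the fractal choice `n(t) = t^eta` is available by supplying the
sup of `eta*t^(eta-1)`), each right-hand side satisfies
`|X_i|^2 <= K_i (1 + |x_i|^2)` and a Lipschitz bound `Kbar_i`, with the
constants and the six uniqueness ratios evaluated verbatim from their
published forms (e.g. `K3 = 2*||n'||^2*mu^2`, `Kbar6 = ||n'||^2*a^2`, ratio
`d^2/(lam^2*||D||^2)`). Zero denominators give an infinite ratio — the
condition simply fails — never an exception. The composite `Kbar1..3`
reference two sup-norms of the same compartment (two candidate solutions);
the single trajectory sup-norm is used for both, as no operational
distinction is ever given. Sup-norms are estimated empirically as
componentwise maxima over a trajectory.

Boundedness is operationalized as an empirical monitor (component exceeding
10x `max(x0_i, mu/(omega+lam))` flags unbounded growth; excursions below
`-1e-9` flag positivity violations) rather than transcribing the symbolic
invariant-set construction, whose displayed inequality involves quantities
that are never defined.

## Scenarios and scope of the synthetic generator

The built-in `paper` preset is the reference simulation scenario
(`alpha=0.0514, beta=1.02e-9, gamma=0.1, phi=1e-7, rho=1e-8, kappa=0.02,
mu=480, omega=0.24, lam=2e-7, d=3e-4, psi=3e-4, a=0.04`; initial state
`(1.0, 0.8, 0.3, 0.4, 0.4, 0.3)`), run by default at `xi = eta = 0.95`,
`dt = 0.05`, `t_end = 100` — the step and horizon are package choices (no
grid is published) sized so the dendritic compartment visibly saturates at
`mu/(omega+lam) ~ 2000` within the run. `scenario_random(seed)` draws each
rate log-uniformly within two decades of the reference value (deterministic
per seed); `force_R0_above_1` rescales `rho` so `R0` lands in `[1.5, 5]`,
giving supercritical test fixtures. These synthetic scenarios exercise the
full qualitative range of the model (sub/supercritical, fast/slow chains)
but are not fitted to any patient data; passing tests demonstrate internal
mathematical consistency of the machinery, not clinical validity.

## Known limitations

* Single kernel family: no Caputo power-law or Caputo-Fabrizio exponential
  variants, and no adaptive stepping for the memory scheme.
* `ml` is real-argument, one-parameter only, and refuses arguments whose
  series cancellation exceeds its precision budget instead of switching to
  asymptotics.
* Interior-equilibrium control analysis is purely numerical.
* No parameter estimation, units conversion, or data ingestion: inputs are
  configurations, outputs are trajectories and JSON reports.
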