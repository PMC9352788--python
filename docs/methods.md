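# Methods

## Experiment representation and units

Concentrations are mmol/l, volumes ml, time s, power µcal/s, heats
kcal per mole of injected ligand.  With these units the moles injected
at step i are c_L·V_i µmol, so one constant (1 µcal/µmol = 10⁻³
kcal/mol) converts integrated power to q_i; the unit of q then matches
ΔH°, and K_a carries l/mmol (the reciprocal of the concentration
unit — a common rescaling of l and m only moves the unit of K_a, which
the Wiseman function is invariant to).

Total concentrations after injection i follow the displacement-
corrected mass balance

    l_i = c_L (ΣV_k)(2V0 − ΣV_k) / (2V0²),
    m_i = c_M (2V0 − ΣV_k) / (2V0 + ΣV_k),

valid while ΣV_k < 2V0 (enforced at construction).  l is strictly
increasing and m strictly decreasing for any valid schedule.

Power traces are assumed already deconvolved.  Integration fits a
degree-5 univariate spline per injection window [t_i, t_{i+1}) (the
last window runs to the trace end; at least 6 samples per window are
required) and integrates it.  By default a straight baseline through
the mean power of the first and last 5% of each window's samples is
subtracted first; peak-shaped synthetic fixtures with quiet window
edges are unaffected, while a pure linear drift integrates to zero.
The spline smoothing factor defaults to 0 (interpolation) so that
closed-form integral checks hold exactly; both the baseline and the
smoothing are caller-configurable, since instrument noise in real
traces may warrant smoothing.

## Wiseman model

`WisemanModel.fit` minimises the Euclidean norm of the (optionally
weighted) residual q − W·ΔH° by Nelder–Mead over (log K_a, log n, ΔH°);
the log parametrisation enforces positivity without constraints.
Initial values, unless supplied: K_a = 1/m at the injection whose heat
is closest to q₁/2 (half-saturation heuristic), n = molar ratio there,
ΔH° = q₁.  Tolerances 10⁻⁸ on parameters and objective, at most 10⁵
evaluations.  Thermodynamics use R = 1.98720425·10⁻³ kcal/(mol·K) and
default T = 298.15 K.  At least four usable injections are required
for the three-parameter fit.

## Multivalent state space and generator

An s-valent ligand on an s-site receptor (1 ≤ s ≤ 4) occupies states
that are partial matchings between ligand and receptor sites —
C(s,b)²·b! states with b bonds; 2, 7, 34 states for s = 1, 2, 3.  One
bond changes per transition: the first bond forms at k_on₁[L] into
each of the s² singly-bound states, a (b+1)-th bond at k_on_{b+1} for
each admissible free-site pair, and every bond of a b-bond state
breaks at k_off_b.  Diagonals close the columns of Qᵀ to zero.  For
s = 2 this reproduces the 7×7 bivalent generator with unbound diagonal
−4α (α = k_on₁[L]), singly-bound diagonals −(k_off₁ + k_on₂) and
doubly-bound diagonals −2k_off₂, each doubly-bound state exchanging
with exactly two singly-bound ones.  States are ordered by bond count,
then lexicographically, so matrices are bit-for-bit reproducible.

Rates are relative: every derived quantity (per-injection K_i, the fit
objective) is invariant under a common rescaling of all 2s rates, so
only the stepwise ratios K_j = k_on_j/k_off_j are identifiable.

## Coarse graining

The macroscopic association constant at one [L] comes from projecting
the generator onto two macro states (unbound/bound) with PCCA+:
memberships χ from the inner simplex algorithm (ISA) on the two
dominant eigenvectors, then Q_c = (χᵀΠχ)⁻¹χᵀΠQχ with Π = diag(π),
where π is the unique stationary distribution (Qᵀπ = 0, available for
[L] > 0; the formula is applied to the generator in its from-state row
convention, in which χ spans an invariant subspace, and reported
transposed).  The 2×2 template [[−k_on[L], k_off], [k_on[L], −k_off]]
yields K = k_on/k_off; the macro state with the larger membership-
weighted stationary mass on the unbound micro state is labelled
"unbound".

One design choice deserves emphasis.  The full generator's slowest
eigenmode is not always the binding/unbinding process: for the
bivalent chain there is an [L]-independent antisymmetric mode
(exchange between the two doubly-bound configurations) that is slower
than the binding mode at low [L].  ISA on that eigenvector splits the
two doubly-bound states instead of bound from unbound, and the
projected "K" degenerates to exactly 1/[L] for *any* rates — the
kinetic parameters become unidentifiable.  Calorimetry, however,
observes only how many bonds exist, never which sites carry them; and
because the generator is symmetric under permutations of ligand sites
and of receptor sites, the chain lumps *exactly* onto the bond count
(an (s+1)-state birth–death chain: b → b+1 at (s−b)²k_on_{b+1},
b → b−1 at b·k_off_b).  Memberships are therefore built from the
dominant eigenvectors of this observable chain and lifted to the full
space (states with equal bond count share a membership row).  The
lifted χ still spans an invariant subspace of the full generator, all
projection identities hold, and the projected K equals the one
computed on the lumped chain to machine precision — the package uses
the small chain on hot paths.  The identity K·[L] =
(Σχ_bound π)/(Σχ_unbound π) holds to ~10⁻⁹ on random instances and is
the oracle the tests check against; with a wide observable spectral
gap, χ sharpens towards the crisp bond-count indicator and K
approaches the crisp occupancy ratio π_bound/π_unbound/[L].

χ is recomputed at every injection, since Q depends on [L].  Negative
ISA memberships are clipped and rows renormalised (the full PCCA+
optimisation is not needed for two clusters).  Eigen-computations run
in double precision; imaginary parts of the dominant pair above 10⁻¹⁰
(relative to the spectral radius) raise, a spectral gap degenerate to
10⁻¹² warns.  Random rate draws for which the 2-state split is not a
binding/unbinding split (e.g. the projection returns nonpositive
macroscopic rates) raise `ValueError` and are skipped by the search.

## Free-ligand recursion

The generator needs [L]ᵢ, but only totals are known.  The bound-ligand
concentration for totals (l, m), stoichiometry n and constant K_a is
the physical root of the 1:1 quadratic, L_b ∈ [0, min(nm, l)].  The
series is built iteratively: [L]₁ = l₁ and
[L]ᵢ = [L]ᵢ₋₁ + lᵢ − (L_b)ᵢ₋₁, where (L_b)ᵢ₋₁ uses the coarse-grained
K at [L]ᵢ₋₁ (lagged evaluation resolves the circular dependence of K
on [L]).  In the default "cumulative" mode lᵢ is the total ligand
concentration — the literal reading of the recursion, which can
overshoot the physically available ligand late in a titration; the
"increment" mode uses lᵢ − lᵢ₋₁ instead, which can undershoot (the
bound-ligand term is evaluated at totals) and is floored at zero with
a warning.  Neither variant is exact mass-balance bookkeeping; both
are provided because the published form of the recursion is ambiguous,
and the choice shifts the spectral diagnostics (below) while the fit
itself is far less sensitive, since K(L) varies slowly over the
relevant range.

## Per-step-K fitting

`QcModel` evaluates the weighted residual of q against W(K_i, n; l_i,
m_i)·ΔH°.  Optional Gaussian weighting exp(−(r−µ)²/2σ²) on the
molar-ratio axis concentrates the fit around the isotherm slope
(defaults µ = 0.3, σ = 0.1758, mirroring the trivalent study case, in
which the first injection is also excluded as an outlier); weighting
is off for the bivalent configuration.  The kernel is unnormalised — a
global weight scale does not move the minimiser.

Estimation is a seeded random search: rates log-uniform within bounds
(default 10⁻²..10⁴), n uniform on (0.05, 2), ΔH° at the Wiseman
estimate; the loop breaks once a candidate beats the reference norm
(by default the Wiseman fit's, computed with the same weighting).  The
winning candidate is refined by Nelder–Mead over (n, ΔH°) with rates
held fixed.  An optional full polish over all parameters
(`polish_rates=True`), restartable from the `n_polish` best
candidates, is available for parameter-recovery work where the rough
rate landscape's local minima matter; it is off by default.  Identical
seeds give bit-identical results.  A globally optimal search is out of
scope.

## Spectral diagnostics and robustness

For model selection the eigenvalues of Q along the titration are
sorted by |Re λ| ascending (λ₁ = 0 always); ratio_2state = |λ₃|/|λ₂|
measures how well the slowest process separates from the next one —
values well above 1 justify the 2-state projection — and ratio_3state
= |λ₄|/|λ₃| plays the same role for a hypothetical two-step (3-state)
model.  For s = 1 there is a single nonzero eigenvalue and the ratios
are reported as inf.  Two caveats: the slow spectrum contains
symmetry-degenerate and unobservable (antisymmetric) modes, so
consecutive-ratio diagnostics on the full matrix can saturate at
exactly 1 (degenerate pairs) or reflect the internal-exchange mode
rather than binding; and the values depend on the free-ligand mode
(cumulative/increment).  The diagnostics are reported for the full
spectrum, which is the conservative choice.

The robustness protocol multiplies every heat by an independent
uniform draw from [1−w, 1+w] (w = 0.01 for the ±1% study), refits both
models with identical search settings, and reports percentage changes
of each parameter and of the norm.  On synthetic bivalent data the
Wiseman refit moves n and ΔH° by order 1%; the trivalent micro-rate
ratios can shift by orders of magnitude under the same protocol — an
expected symptom of the weak timescale separation, reported but not
asserted.

## Synthetic data

The generators emulate the study conditions: the bivalent
(c_M = 0.071, c_L = 0.7 mmol/l) and trivalent (c_M = 0.0918,
c_L = 0.978 mmol/l) schedules with V0 = 1.442 ml and injections
0.001 ml + 13×0.01 ml are built in; heats are W·ΔH° under either
truth model with multiplicative uniform noise (the same model as the
perturbation protocol; default width 0, i.e. noise-free, since the
recovery suites probe the estimators, not the noise).  Synthetic power
traces carry one rectangular (integral exact) or exponential
(integral A·τ·(1−e^{−Δ/τ})) peak per window, sized so the per-window
integral reproduces the requested heats; rectangular round trips
recover heats to 10⁻⁸ relative, exponential to 10⁻⁴ with dense
sampling.  What the generator does not emulate: instrument response
and deconvolution artifacts, baseline drift with structure, heats of
dilution, or correlated noise — passing recovery tests show estimator
correctness on the model's own data, not accuracy on real traces.

## Problem sizes

All shipped analyses are desk-scale: 14-injection titrations, state
spaces up to 34 states (s = 3), random-search budgets of a few hundred
draws with up to five polish restarts.  The full test suite runs in
about a minute; the diagnostics script in seconds.

## Known limitations

- The 2-state projection is the only one implemented; a 3-macrostate
  projection (two-step binding) is future work.
- Microscopic rates are relative; no absolute kinetic units are
  produced.
- The free-ligand recursion is heuristic (see above); its cumulative
  default can exceed total-ligand mass balance late in a titration.
- 1:1 ligand:receptor complex stoichiometry only — no cross-linking
  states, no n:m generalisations of the Wiseman function.
- Proprietary calorimeter file formats are not parsed; inputs are the
  JSON/CSV formats described in the README.
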