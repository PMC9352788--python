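# mvitc — multivalent binding analysis for ITC data

`mvitc` estimates binding parameters from isothermal titration
calorimetry (ITC) experiments, aimed at biophysicists studying
multivalent ligand–receptor systems (e.g. lectins binding
glycomacromolecules with several sugar ligands).

An ITC run titrates ligand into a cell of macromolecule and records the
compensation heat of each injection.  The classical analysis fits the
integrated heats q₁..q_T with the **Wiseman isotherm** for 1:1 binding,

```
W(K_a, n; l, m) = ½ (1 + (n − l/m − 1/(mK_a)) / sqrt((n + l/m + 1/(mK_a))² − 4n l/m)),

min over (K_a, n, ΔH°) of ‖ q − W(K_a, n; L_t, M_t) · ΔH° ‖
```

with total concentrations (l, m) per injection, association constant
K_a, stoichiometry n and binding heat ΔH°.  A single global K_a,
however, cannot express the sequential intermediate steps of a
multivalent binding.

`mvitc`'s second model replaces the global constant with a
**per-injection association constant** derived from microscopic
kinetics: the s-valent complex is a continuous-time Markov chain over
all partial matchings between ligand and receptor sites, with
microscopic rates k_on₁..k_on_s, k_off₁..k_off_s.  At the free-ligand
concentration [L]ᵢ of each injection, the transition-rate matrix Q is
coarse-grained with PCCA+ (fuzzy memberships χ from the dominant
eigenvectors, projection Q_c = (χᵀΠχ)⁻¹χᵀΠQχ with Π = diag(π)) to a
2-state bound/unbound model whose macroscopic ratio K_i = k_on/k_off
enters the Wiseman function injection by injection:

```
min over (k_on₁..s, k_off₁..s, n, ΔH°) of ‖ q − W(K_i, n; L_t, M_t) · ΔH° ‖
```

Only the stepwise ratios K_j = k_on_j / k_off_j are identifiable — the
fit yields relative, not absolute, kinetics.  Spectral
(timescale-separation) diagnostics tell whether the 2-state projection
is adequate, and a ±1% input-perturbation protocol probes robustness.

## Worked example

```python
import mvitc as mv

# the bivalent study schedule: V0 = 1.442 ml, c_L = 0.7 mmol/l,
# c_M = 0.071 mmol/l, injections 0.001 ml then 13 x 0.01 ml
schedule = mv.bivalent_schedule()

# synthetic heats from a known Wiseman truth, 1% multiplicative noise
truth = mv.WisemanParams(K_a=100.0, n=0.5, dH=-50.0)
heats = mv.simulate_heats(mv.SimulationSpec(schedule=schedule, truth=truth,
                                            noise_width=0.01, seed=3))

res = mv.WisemanModel.from_schedule(heats, schedule).fit()
print(res.summary())
```

prints

```
Wiseman isotherm fit
====================
K_a         101.4960  l/mmol
K_d         0.009853  mmol/l
n             0.5021
dH          -49.5643  kcal/mol
dG           -2.7373  kcal/mol (at 298.15 K)
dS         -157.0585  cal/(mol K)
norm        0.447940  kcal/mol
nfev       291   converged: True
```

K_a comes back within 1.5% of the generating value under 1% noise; the
norm is the Euclidean residual in kcal/mol.  The multivalent fit works
the same way through `QcModel` (returning the microscopic rate ratios
K_j and the per-injection K_i series), and
`mvitc.eigenvalue_ratio_series` reports the eigenvalue ratios that
justify — or warn against — the 2-state coarse graining.

The same operations are available from the shell:

```sh
mvitc simulate --config cfg.json --truth truth.json --noise 0.01 --seed 3 --out heats.csv
mvitc fit-wiseman --config cfg.json --heats heats.csv
mvitc fit-qc --config cfg.json --heats heats.csv --valency 2 --seed 0 --out qc.json
mvitc diagnose --config cfg.json --fit qc.json
mvitc perturb --config cfg.json --heats heats.csv --width 0.01 --seed 0
```

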