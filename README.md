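# covkin

Kinetic dissection of irreversible covalent inhibition, built around the
KRas G12C switch II pocket inhibitor class (acrylamide, chloroacetamide,
imidazole carboxamide and aziridine carboxamide warheads, with ARS-1620
as the clinical reference).

Covalent drugs act in two steps: reversible recognition of the target,
then chemistry,

```
E + I  <=(k1 / k-1)=>  E·I  --(k_inact)-->  E–I,     K_I = k-1 / k1
```

Under rapid pre-equilibrium and inhibitor excess, the fraction of
covalently labelled protein rises as a one-phase association with the
observed rate

```
k_obs(c) = k_inact · c / (K_I + c)
```

which saturates at `k_inact`; the low-concentration slope `k_inact/K_I`
is the second-order efficiency that ranks covalent inhibitors.  Two
closed-form transforms then separate *recognition* from *reactivity*:

* `ΔG_bind = RT ln K_I` (K_I in M) — the noncovalent binding free energy;
* `ΔG‡ = RT ln(k_B T / (h k))` — the Eyring activation free energy of a
  rate constant `k`, applied to `k_inact` (target arm) and to the
  glutathione-surrogate second-order rate
  `k₂ = (ln 2 / t_1/2) / [GSH⁻]` with the thiolate concentration from
  Henderson–Hasselbalch, `[GSH⁻] = [GSH] / (1 + 10^(pKa − pH))`
  (intrinsic warhead arm).

The package covers every stage between raw assay tables and those
numbers: MS occupancy time courses → `k_obs` → (K_I, k_inact);
degradation-corrected GSH half-lives (`k_app = k_deg + k_GSH`,
`t_1/2 = ln 2 / k_GSH`, censored beyond the 72 h assay horizon);
MANT-GDP exchange traces → normalised rates → IC50; cell-viability
plates → IC50s → G12C-vs-wild-type selectivity factors.  A mass-action
ODE of the two-step scheme validates the rapid-equilibrium
approximation, and seeded generators emulate all four assay designs so
the whole pipeline is testable without instrument data.

The fitting stages are scikit-learn-style estimators
(`OnePhaseAssociation`, `SaturationKinetics`, `LogLinearDecay`,
`SingleExponentialTrace`, `FourParameterLogistic`) with
`fit`/`predict`/`get_params` and trailing-underscore fitted attributes;
thin functions (`fit_one_phase`, `fit_kobs_vs_conc`, `fit_ic50`, ...)
wrap them for pipeline use.

## Worked example

Simulate one occupancy plate for the acrylamide lead (K_I = 34.8 μM,
k_inact = 10.1×10⁻³ s⁻¹) at the published design — 20/40/80/160 μM
probe sampled at 0.5–60 min in duplicate, 2% occupancy noise — fit it
end to end, and derive the energies:

```python
from covkin import synthetic as syn, pipeline as pl
from covkin.kinetics import TwoStepParams
from covkin.thermo import ThermoContext, binding_free_energy, eyring_barrier, gsh_barrier

params = TwoStepParams(K_I=34.8e-6, k_inact=10.1e-3)
design = syn.occupancy_design("fast", seed=1, noise_sd=0.02)
plate  = syn.generate_occupancy_plate(params, design, compound_id="1a")
fit    = pl.fit_occupancy_table(plate).iloc[0]
print(f"K_I = {fit['KI_uM']:.1f} uM, k_inact = {fit['kinact_s']*1e3:.1f}e-3 /s, "
      f"k_inact/K_I = {fit['kinact_over_KI']:.1f} /M/s")

ctx = ThermoContext()   # 298.15 K, 5 mM GSH, pH 7.4, thiol pKa 8.7
print(f"dG_bind    = {binding_free_energy(fit['KI_uM']*1e-6, ctx):.1f} kcal/mol")
print(f"dG_barrier = {eyring_barrier(fit['kinact_s'], ctx):.1f} kcal/mol")
print(f"dG_gsh(19 h) = {gsh_barrier(19.0, ctx)[0]:.1f} kcal/mol")
```

prints

```
K_I = 29.8 uM, k_inact = 9.5e-3 /s, k_inact/K_I = 319.1 /M/s
dG_bind    = -6.2 kcal/mol
dG_barrier = 20.2 kcal/mol
dG_gsh(19 h) = 19.3 kcal/mol
```

With this single noisy duplicate plate the two-stage fit lands within
~15% of the generating constants (noiseless plates recover them to
1 part in 10⁶ — see the tests); the derived energies say that for this
compound recognition contributes about −6 kcal/mol and the covalent
step faces a ~20 kcal/mol barrier, essentially the same barrier the
free glutathione reaction shows, i.e. the pocket neither activates nor
shields the warhead much.

The same stages run from the shell:

```
covkin fixtures --out study/ --seed 1      # nine-compound synthetic study
covkin fit-occupancy study/occupancy.csv
covkin fit-gsh study/reactivity.csv
covkin report config.yaml                  # full pipeline + rendered tables
```

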