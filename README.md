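# mrkinet

Kinetic analysis of Maillard browning in membrane-clarified sugarcane
juice (MCSJ) during vacuum evaporation.

When clarified cane juice is concentrated (60–90 °C under vacuum),
reducing sugars and free amino acids react non-enzymatically and form
melanoidins — the brown pigments that limit white-sugar quality.  This
package implements the quantitative toolkit for studying that process in
the sugar/amino-acid model system:

* **Simple-order kinetics** — ordinary-least-squares fits of the
  integrated rate laws *C = C₀ + k₀t*, *C = C₀·exp(k₁t)* and
  *1/C − 1/C₀ = k₂t* to color values (CIELAB L\*, a\*, b\*, ΔE\*) and
  reaction products, with R²-based order selection and Arrhenius
  regression (ln|k| on 1/T, Eₐ = −slope·R) for activation energies.
* **Melanoidin-formation network** — an 11-species, 15-step
  pseudo-first-order reaction network (sucrose hydrolysis; glucose ⇌
  1,2-enediol ⇌ fructose enolization; 3-deoxyglucosone, 5-HMF, glyoxal,
  methylglyoxal; CML/CEL; melanoidins), integrated as a stiff linear ODE
  system dy/dt = M(k)·y with both an implicit Radau solver and the exact
  matrix-exponential propagator.
* **Multi-response estimation** — weighted least-squares recovery of the
  15 rate constants from observed timecourses, with multistart bounded
  optimization in log-parameter space, linearized or bootstrap 95%
  intervals, and automatic flagging of structurally indeterminate steps.
* **Synthetic data** — a generator reproducing the study design (four
  temperatures, 0–30 min sampling, multiplicative measurement noise) so
  every pipeline stage is testable end to end.
* **Descriptive metrics** — ΔE\* color difference, perceivability
  categories, consumption-rate and group-sum arithmetic.

## Worked example

Activation energy of glyoxal formation from its zero-order rate
constants at the four evaporation temperatures:

```python
from mrkinet import arrhenius_fit

pairs = [(0.1476, 60.0), (0.1644, 70.0), (0.1770, 80.0), (0.2106, 90.0)]
res = arrhenius_fit(pairs)
print(f"Ea = {res.Ea:.3f} kJ/mol (R^2 = {res.r_squared:.3f})")
```

prints

```
Ea = 11.426 kJ/mol (R^2 = 0.944)
```

meaning a ~11.4 kJ/mol temperature barrier: glyoxal formation speeds up
by roughly 40% between 60 and 90 °C.  The full study pipeline runs from
the shell:

```sh
mrkinet synth --seed 3 -o bundle/          # synthetic 60/70/80/90 °C study
mrkinet report bundle/ --seed 3 -o out/    # fits, Ea table, network fit
```

`out/report.json` then contains, per response, the rate constant and R²
at each order with the selected order, the Arrhenius table, and the 15
network rate-constant estimates per temperature with 95% half-widths and
`*ind` indeterminacy flags (sucrose hydrolysis and the
enediol-to-glucose step are flagged: with the enolization intermediate
unmeasurable, the data carry no information about them).

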