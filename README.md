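# simep

Steady-state electrochemical models of **singularity-induced
micro-electroporation** devices: two coplanar electrodes separated by a
nanometre-scale insulator under an electrolyte, where the field diverging at
the insulator edges permeabilizes cell membranes (reversible
electroporation at ~1–3 kV/cm, irreversible at ~10 kV/cm) with only a few
volts applied.  For device designers and modellers who want to know how
insulator thickness, channel height, water conductivity and electrode
kinetics set the achievable field and the power budget.

Two models, one finite-difference core:

* **Primary current distribution** (non-dimensional channel model): ohmic
  losses only, equipotential electrodes, ∇²Φ = 0 with Φ = 1/0 on the anode/
  cathode and zero flux elsewhere.  Geometry reduces to the aspect ratio
  G = h/l and relative insulator thickness ε = d/l; fields scale back to
  dimensions as E = E*·V_d/l.
* **Secondary current distribution** (dimensional cell model): adds
  Butler–Volmer electrode kinetics,
  i = i₀[exp(α_a F η/RT) − exp(−α_c F η/RT)], as nonlinear flux boundary
  conditions, solved by damped Newton iteration with voltage continuation.
  The packaged `platinum_water()` couple (O₂ anode: E_eq = 1.23 V,
  i₀ = 10⁻⁸ A/cm²; H₂ cathode: E_eq = −0.83 V, i₀ = 10 A/cm²;
  E_cell_eq = 2.06 V) describes water electrolysis on inert platinum.  The
  solver reports the potential and field everywhere, the centreline field
  profile above the insulator, electrode currents, and power per device
  footprint.

Everything is deterministic — there is no random number generator in the
package.

## Worked example

How much field does a thicker insulator cost in the channel?

```python
from simep import ChannelGeometryND, percent_increase, solve_primary

shallow = ChannelGeometryND(G=0.1, epsilon=0.0)   # zero-width insulator
res0 = solve_primary(shallow, n_base=96)
res9 = solve_primary(ChannelGeometryND(G=0.1, epsilon=0.9), n_base=96)
print(res0.probe_value, res9.probe_value)
print(percent_increase(res0.probe_value, res9.probe_value))
```

prints

```
5.00003089888196 0.9825534728324409
408.88130133703544
```

i.e. at aspect ratio 0.1 the mid-plane probe field is 5.0 (in units of
V_d/l) for the singular insulator and 0.98 for a thick one — shrinking the
insulator from 90% of the electrode length to zero raises the field by
~409%.  The same call at G = 2 gives ~107%: deep channels barely care.

And the kinetic cell in low-conductivity water (`python
examples/kinetic_cell_fields_and_power.py`):

```
V_app=2.7 V: |E| at insulator centre =    1.362 kV/cm; reversible threshold reached up to  0.04 um; P =       1028 uW/cm^2 (eta_a=0.59 V, ohmic=0.050 V)
V_app=3.1 V: |E| at insulator centre =   14.983 kV/cm; reversible threshold reached up to  1.09 um; P =       8629 uW/cm^2 (eta_a=0.71 V, ohmic=0.334 V)
V_app=3.5 V: |E| at insulator centre =   36.841 kV/cm; reversible threshold reached up to  1.97 um; P =  2.083e+04 uW/cm^2 (eta_a=0.75 V, ohmic=0.693 V)
```

The sluggish oxygen anode (η_a column) throttles the current below ~3 V;
past that, the ohmic share of the voltage budget — and with it the field —
rises steeply until the anode kinetics cap it.

More in `examples/`: `channel_insulator_thickness.py`,
`electrode_kinetics_1d.py`, `kinetic_cell_fields_and_power.py`.

## Command line

```sh
simep primary --sweep-G 0.1,0.5,1,2 --sweep-eps 0,0.3,0.6,0.9 --out sweep.csv
simep secondary --sigma 0.0005 --vapp 2.9 --profile centerline.csv --out res.csv
simep run channel_sweep          # packaged fixture; also: centerline_profiles
simep run my_run.cfg             # plain-text key = value config
```

CSV outputs carry `#`-prefixed provenance headers and 12 significant
digits; identical inputs give byte-identical outputs.

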