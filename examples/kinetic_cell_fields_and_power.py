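"""Fields and power of the singularity-induced micro-electroporation cell.

Solves the full 2D secondary current distribution model (Laplace bulk +
Butler-Volmer electrodes) for low-conductivity water at two applied
voltages, prints the field at the insulator centre, how far the reversible
1 kV/cm threshold reaches into the channel, and the power drawn per unit
device footprint.
"""

from simep import SecondaryCellSpec, centerline_profile, solve_secondary
from simep.secondary import insulator_centre_field

for V in (2.7, 3.1, 3.5):
    spec = SecondaryCellSpec(sigma=0.0005, V_app=V)
    sol = solve_secondary(spec, n_base=48, grading=2.5)
    prof = centerline_profile(sol)
    reach = prof[prof.E_kV_cm >= 1.0].y_um.max() if (prof.E_kV_cm >= 1.0).any() else 0.0
    d = sol.diagnostics
    print(
        f"V_app={V:.1f} V: |E| at insulator centre = "
        f"{insulator_centre_field(sol):8.3f} kV/cm; reversible threshold "
        f"reached up to {reach:5.2f} um; P = {sol.P:10.4g} uW/cm^2 "
        f"(eta_a={d['eta_a_mean']:.2f} V, ohmic={d['ohmic_drop']:.3f} V)"
    )

print(
    "\nReading: below ~3 V the anode kinetics throttle the current and the "
    "field above the insulator is weak; a few hundred millivolts more and "
    "the ohmic share of the voltage budget -- and with it the field -- "
    "rises steeply, until the low anode exchange current density caps it."
)
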