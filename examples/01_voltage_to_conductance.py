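"""From wristband volts to skin conductance.

The wristband measures skin resistance through a voltage divider against an
826 kΩ reference at 3.3 V. This example converts a few output-voltage
readings to resistance and conductance and prints the electrode geometry
(contact area and current density) implied by the 0.80 cm electrodes.
"""

from microeda import (
    DeviceConfig,
    electrode_geometry,
    resistance_to_conductance,
    voltage_to_resistance,
)

device = DeviceConfig()
print(f"device: Vdd={device.supply_voltage} V, Rref={device.reference_resistance:.0f} Ω")

for vout in (0.0, 0.4, 0.825, 1.2):
    r = voltage_to_resistance(vout, device)
    g = resistance_to_conductance(r)
    print(f"Vout={vout:5.3f} V  ->  R_skin={r/1000:8.1f} kΩ  ->  G_skin={g:6.3f} μS")

geom = electrode_geometry(device)
print(f"\nelectrode area: {geom['area_cm2']:.2f} cm², "
      f"current density: {geom['current_density_uA_cm2']:.2f} μA/cm² "
      "(safe: below the 10 μA/cm² recommendation)")
# Higher Vout means lower skin resistance, i.e. higher conductance — more
# sweat-gland activity. Conductance is the quantity all later stages use.
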