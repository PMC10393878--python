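"""Energy and campaign cost of simulation arms.

Applies the constant-power model (50 W CPU arm, 295 W GPU arm) to
recorded simulation durations: energy = P x t / 3600 Wh, and a campaign
of 1000 cases is billed per kWh.
"""
from vffrcfd import campaign_cost, energy_wh

for label, power, seconds in [("CPU arm, median case", 50.0, 607.5),
                              ("GPU arm, pooled median", 295.0, 31.7),
                              ("GPU arm, 100% fidelity", 295.0, 40.5)]:
    e = energy_wh(power, seconds)
    print(f"{label}: {power:.0f} W x {seconds:.1f} s = {e:.2f} Wh")
e_cpu = energy_wh(50.0, 607.5)
print(f"1000 cases on the CPU arm at 0.25/kWh: "
      f"{campaign_cost(e_cpu, 1000, 0.25):.2f} currency units "
      f"({e_cpu:.2f} kWh total)")
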