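"""Steady-state microbial community across storage temperatures.

At each constant temperature the store is simulated (f_resid = 0.95) until
the per-group biomass settles.  Total methanogen biomass is negligible below
about 10 degC and rises smoothly with temperature, while the dominant group
shifts from cold- to warm-adapted populations.
"""

from slurrygas import steady_state_biomass

print(f"{'T (degC)':>8} {'total (g COD-B)':>16}  dominant group")
for T in (5.0, 15.0, 25.0, 35.0):
    b = steady_state_biomass(T=T)
    groups = {k: v for k, v in b.items() if k != "total_methanogen"}
    dom = max(groups, key=groups.get)
    print(f"{T:8.0f} {b['total_methanogen']:16.1f}  {dom}")
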