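"""Sample the flow field and, when the interior point is a saddle, the
four basin rectangles it delimits.

An interior equilibrium exists only in two regimes: a saddle (bistable
corner pair) or a linear center (closed orbits, no stable corner).  The
portrait assigns rectangle regions in the saddle regime and stays
field-only — still reporting the point — in the cycling regime.
"""

from precautiongame import GameParams, find_scenario_params, phase_portrait

saddle_params = find_scenario_params(3)
pp = phase_portrait(saddle_params, resolution=11)
print(f"saddle regime {saddle_params.cc=:g} {saddle_params.cs=:g} {saddle_params.p=:g} "
      f"{saddle_params.a=:g} {saddle_params.b=:g}")
print(f"  interior saddle at ({pp.interior[0]:.4f}, {pp.interior[1]:.4f})")
for name in ("I", "II", "III", "IV"):
    print(f"  region {name:>3} -> attractor {pp.regions[name]['attractor']}")

center = phase_portrait(GameParams(cc=10, cs=6, p=5, a=0.0, b=1.0), resolution=11)
print(f"\ncycling regime (cc=10, cs=6, p=5, a=0, b=1):")
print(f"  interior center at ({center.interior[0]:.4f}, {center.interior[1]:.4f})")
print(f"  regions: {center.regions}   flag: {center.flag}")
print("\nin the cycling regime trajectories orbit the center, so no corner")
print("basin assignment is meaningful and only the sampled field is returned.")
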