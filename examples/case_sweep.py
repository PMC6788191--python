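"""Sweep the liability shares for the high-accident-loss case and inspect
how the simulated outcomes compare with the claimed ones.

With p=12, cc=8, cs=4 both pi2 = 4 + 4b and pi3 = 8 are positive for every
share choice, so mutual caution (1, 1) is the stable corner on the whole
(a, b) grid.  The claimed proportional-rule outcome (no caution, caution)
therefore disagrees with the dynamics everywhere — the sweep records the
disagreement instead of resolving it.
"""

from collections import Counter

from precautiongame import CASES, run_case

result = run_case(CASES[3], grid_resolution=11)

counts = Counter(v for row in result.verdicts for v in row)
print(f"verdict counts over the 11x11 grid: {dict(counts)}")
print(f"modal proportional verdict:  {result.proportional_modal_verdict}")
print(f"strict (a=b=1 parametric):   {result.strict_parametric_verdict}")
print(f"strict (override table):     {result.strict_override_verdict}")
print(f"claimed outcomes:            {result.expected}")
print(f"recorded disagreement cells: {len(result.disagreements)}")
if result.disagreements:
    d = result.disagreements[0]
    print(f"  e.g. rule={d['rule']} (a={d['a']:.1f}, b={d['b']:.1f}): "
          f"expected {d['expected']}, observed {d['observed']}")
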