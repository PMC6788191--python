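"""Classify every rest point by the determinant/trace rule.

A rest point is evolutionarily stable (ESS) when Det(J) > 0 and Tr(J) < 0
at the linearization.  Here (cc=16, cs=4, p=12, a=b=0.5) only the students
profit from caution, so (0, 1) — school careless, students cautious — is
the unique stable corner.
"""

from precautiongame import GameParams, classify_equilibria

report = classify_equilibria(GameParams(cc=16, cs=4, p=12, a=0.5, b=0.5))

print(f"corner net gains: pi1={report.gains.pi1:g}, pi2={report.gains.pi2:g}, "
      f"pi3={report.gains.pi3:g}, pi4={report.gains.pi4:g}")
print(f"scenario: {report.scenario}   tabulated stable corner: {report.predicted_ess}")
print()
for eq in report.equilibria:
    print(f"  {eq.kind:<8} ({eq.coords[0]:.3g}, {eq.coords[1]:.3g}): "
          f"Det={eq.det:>8.3g}  Tr={eq.tr:>8.3g}  -> {eq.classification}")
print()
print("Det < 0 marks a saddle, Det > 0 with Tr > 0 an unstable node; the")
print("single ESS corner is where the replicator flow actually settles.")
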