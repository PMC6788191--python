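"""Build the payoff tables under both liability rules and read the corner gains.

The proportional (parametric) rule splits the accident loss p by the share
a and the students' prevention cost by the share b; the strict override
table charges the school the full loss whenever an accident happens.
"""

from precautiongame import (
    APPROPRIATE_CAUTION,
    NO_CAUTION,
    GameParams,
    build_payoff_matrix,
    classify_scenario,
    net_gains,
)

params = GameParams(cc=10, cs=6, p=5, a=0.5, b=0.5)
matrix = build_payoff_matrix(params)

print("proportional rule (cc=10, cs=6, p=5, a=b=0.5); cells are (student, school):")
for student in (APPROPRIATE_CAUTION, NO_CAUTION):
    for school in (APPROPRIATE_CAUTION, NO_CAUTION):
        print(f"  students {student:<20} school {school:<20} -> {matrix.cell(student, school)}")

strict = build_payoff_matrix(GameParams.strict(cc=10, cs=6, p=5))
print("\nstrict override, same costs:")
for student in (APPROPRIATE_CAUTION, NO_CAUTION):
    for school in (APPROPRIATE_CAUTION, NO_CAUTION):
        print(f"  students {student:<20} school {school:<20} -> {strict.cell(student, school)}")

gains = net_gains(GameParams(cc=10, cs=6, p=5, a=1.0, b=0.5))
print(f"\ncorner net gains at a=1, b=0.5: {gains.as_tuple()}")
print(f"scenario: {classify_scenario(gains)}")
print("all four gains are negative: neither side profits from caution at any")
print("corner, so the populations drift to mutual carelessness (0, 0).")
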