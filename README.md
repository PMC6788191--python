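# precautiongame

Evolutionary-game analysis of who takes precautions against school sports
injury accidents — and how court liability rules change that.

## The problem

When a student is injured during school sports, a court must divide the
loss between the school and the student's family.  Whatever rule it
applies reshapes both sides' incentives to invest in prevention *before*
the next accident: safety training, equipment maintenance, warm-ups,
physical monitoring.  This package models that feedback as a
two-population evolutionary game and asks which liability rule actually
sustains "appropriate caution" on both sides.

Each population — schools and student/guardian households — mixes two
strategies, *appropriate caution* (pay a prevention cost, `cc` for the
school, `cs` for students) and *no caution*.  If either side is careless
an accident of total loss `p` occurs.  Under the **proportional rule** the
school bears the share `a` of the loss when neither side was cautious and
the share `b` of the students' prevention cost when only the students were
cautious; under the **strict rule** the school bears the full loss
regardless of its own caution (`a = b = 1`, or a literal override table in
which the students never pay anything beyond their own prevention cost).

## The model

With α the fraction of cautious schools and β the fraction of cautious
households, payoff-monotone imitation gives the two-population replicator
system

    dα/dt = α(1−α) [ β((1−a)p + b·cs) − (cc − a·p) ]
    dβ/dt = β(1−β) [ ((1−a)p − (1−b)cs) − (b·cs − a·p) α ]

Its rest points are the four corners of the unit square plus, when it lies
inside, the interior point

    α* = ((1−a)p − (1−b)cs) / (b·cs − a·p),   β* = (cc − a·p) / ((1−a)p + b·cs).

Outcomes are read off the **corner net gains**

    π1 = a·p − cc          (school's gain from caution vs careless students)
    π2 = p + b·cs − cc     (school's gain from caution vs cautious students)
    π3 = p − cs            (students' gain from caution vs a cautious school)
    π4 = (1−a)p − (1−b)cs  (students' gain from caution vs a careless school)

A corner is an evolutionarily stable strategy (ESS) exactly when the
Jacobian there has Det > 0 and Tr < 0, which reduces to sign conditions on
the π's: (0,0) is stable iff π1 < 0 ∧ π4 < 0; (1,1) iff π2 > 0 ∧ π3 > 0;
(0,1) iff π2 < 0 ∧ π4 > 0; (1,0) iff π1 > 0 ∧ π3 < 0.  The package
enumerates rest points, classifies them, integrates trajectories, sweeps
the liability shares (a, b) over five preset study cases, and renders
phase portraits with basin regions.

## Worked example

```python
from precautiongame import GameParams, classify_equilibria, integrate

params = GameParams(cc=10, cs=6, p=5, a=1.0, b=0.5)   # costly prevention, modest loss
report = classify_equilibria(params)
print(report.gains.as_tuple())    # (-5.0, -2.0, -1.0, -3.0)
print(report.scenario)            # 1
print(report.ess)                 # [(0.0, 0.0)]

traj = integrate(params, (0.5, 0.5))
print(traj.verdict)               # corner (0,0)
```

All four net gains are negative — caution pays neither side at any corner
— so the sign pattern classifies as scenario 1, the origin is the unique
ESS, and a trajectory started from an undecided population (50 % caution
on both sides) collapses to mutual carelessness.  Raising the accident
loss or the school's cost shares flips individual π's and with them the
stable corner; the `examples/` scripts walk through each capability
(payoff tables, trajectories, stability reports, case sweeps, phase
portraits) with printed numbers and what they mean.

A thin CLI wraps the same library:

```sh
precautiongame simulate --cc 10 --cs 6 --p 5 -a 1 -b 0.5
precautiongame classify --cc 16 --cs 4 --p 12 -a 0.5 -b 0.5
precautiongame sweep --case 3 --resolution 11
precautiongame portrait --cc 10 --cs 6 --p 5 -a 0 -b 1 --plot portrait.svg
```

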