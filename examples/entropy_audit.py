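"""Second-law audit of closures on random thermodynamic states.

Draws seeded random compositions, potentials and nonnegative closure
coefficients, evaluates every flux-force term group of the restricted
entropy inequalities through the actual closure relations, and reports the
worst (most negative) group — which must be nonnegative if and only if the
closures respect the inequality.  A deliberately negated coefficient is
then smuggled in to show the auditor flagging the violation.
"""

import numpy as np

from tcatsim import audit_two_phase
from tcatsim.fixtures import random_three_phase_ledger, random_two_phase_ledger

rng = np.random.default_rng(42)
worst = 0.0
for _ in range(100):
    worst = min(worst, random_two_phase_ledger(rng).min_group,
                random_three_phase_ledger(rng).min_group)
print(f"minimum entropy-production group over 200 random states: {worst:.3e}")

sample = random_two_phase_ledger(np.random.default_rng(0))
print("per-group production for one random two-phase state:")
for name, value in sorted(sample.groups.items()):
    print(f"  {name:20s} {value: .3e}")
print(f"  {'total':20s} {sample.total: .3e}")

bad = audit_two_phase(310.0, reaction_terms=[(-1.0e-12, 3.0e5)])
print(f"negated rate coefficient -> flagged groups: {bad.flagged}")
# All groups are quadratic forms coefficient * force^2 / temperature, so any
# nonnegative coefficient set is certified; a negative coefficient (a closure
# violating the inequality) produces a negative group and is flagged.
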