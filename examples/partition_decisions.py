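"""The Harris-Boyd partition rule on its own.

A subgroup deserves a separate reference interval only when the omnibus
test rejects (p < 0.05) AND the two-sample deviate z exceeds
z* = 3*sqrt((n1+n2)/240) — a threshold that grows with n so that trivially
significant differences at large samples do not multiply partitions.
"""

import numpy as np

import lymphoref as lr

print(f"z* at the enrolled cohort total (938):  {lr.z_star(469, 469):.2f}")
print(f"z* at two reference groups of 120:      {lr.z_star(120, 120):.2f}")
print(f"z* for a 476 vs 337 sex comparison:     {lr.z_star(476, 337):.2f}")

rng = np.random.default_rng(0)
boys, girls = rng.normal(50, 8, 476), rng.normal(50, 8, 337)
res = lr.test_sex_partition(boys, girls)
print(f"\nsame-distribution sexes: p={res.p_omnibus:.2f}, z={res.z:.2f} "
      f"vs z*={res.z_star:.2f} -> {res.decision}")

# five age bins from one distribution collapse to a single interval
bins = {f"bin{i}": rng.normal(50, 8, n) for i, n in enumerate((187, 154, 197, 155, 120))}
hist = lr.merge_adjacent_age_groups(bins)
print(f"null age bins -> final groups: {hist.final_labels()}")

# a genuinely different neonatal bin survives merging
bins["bin0"] = rng.normal(90, 8, 187)
hist = lr.merge_adjacent_age_groups(dict(sorted(bins.items())))
print(f"shifted first bin -> final groups: {hist.final_labels()}")
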