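"""Amdahl's-law accounting for the parallel clustering stage.

The spatial-clustering stage dominates the workflow's runtime and can run
per plowing row with no data dependency.  Given measured wall-clock times by
process count, the speedup table recovers the effectively parallel fraction
P of the stage.
"""

from cropgeobia import amdahl_speedup, speedup_table

# measured clustering times (minutes) by number of worker processes
times = {1: 508.76, 2: 263.26, 4: 141.04, 6: 101.01, 8: 77.41, 10: 65.22}

table = speedup_table(times)
print(table.to_string(index=False))

p = table.set_index("n_procs").loc[10, "parallel_fraction"]
print(f"\nwith P = {p}, the asymptotic speedup limit is {1 / (1 - p):.1f}x")
print(f"predicted speedup on 16 processes: {amdahl_speedup(p, 16):.2f}x")
# P ~ 0.97: the stage is almost entirely parallel, but the remaining 3%
# serial part caps the achievable speedup near 30x no matter the core count.
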