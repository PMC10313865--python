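"""Reproduce the headline method-comparison numbers at reduced size.

Runs the null (type I error) and low-effect (power/coverage) campaigns at
200 replicates per cell — enough to see every qualitative conclusion in
about 10 seconds.  scripts/acceptance.py runs the same thing at 1000
replicates per cell.
"""

from stratcrt.study import headline_summaries, run_null_study, run_power_study

SEED, REPS = 20230314, 200

null_table = run_null_study(SEED, REPS)
power_table = run_power_study(SEED, REPS)

for key, value in headline_summaries(null_table, power_table).items():
    print(f"{key:35s} {value:6.2f}%")

print(
    "\nReading the numbers: GEE and meta-regression show >10% type I error"
    "\nwith 6 clusters per stratum and slight inflation at 24-34, while the"
    "\nmixed model and cluster-level regression hold ~5% everywhere.  Power"
    "\nat the small effect (0.11 SD) is modest and falls as the ICC rises;"
    "\nCI coverage is near 95% once there are 34+ clusters per stratum."
)
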