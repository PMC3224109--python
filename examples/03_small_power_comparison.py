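"""A desk-scale power comparison of the four methods.

Runs 40 replications x 100 permutations of one simulation condition
(two causal SNPs, MAF 0.5, independent markers) and tabulates, per
method, the power to reject globally and to pinpoint at least one or
both causal SNPs.  Full-scale studies use the same engine via
`run_power_study`; see also the `grlr-power` command.
"""

from grlrscan import aggregate_power
from grlrscan.power import run_condition

records = run_condition(
    scenario="A",      # two causal SNPs
    corr=0.0,
    maf=0.5,
    n_reps=40,
    n_perms=100,
    master_seed=2024,
)
table = aggregate_power(records)

print(f"{'method':>6} {'>=1 causal':>11} {'both causal':>12}")
for method in ("LR", "FPM", "TPM", "GRLR"):
    sub = table[table["method"] == method].set_index("strategy")
    print(f"{method:>6} {sub.loc['I', 'power']:>11.3f} "
          f"{sub.loc['II', 'power']:>12.3f}")

print("\n(40 replications; Monte-Carlo SE is about 0.06-0.08 per entry)")
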