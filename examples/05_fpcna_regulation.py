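"""The FPCNA regulatory-effect index.

Plants a common driver (one FPCNA ROI) that feeds the default-network
subsystems, then quantifies regulation as the drop in summed Fisher-z
connectivity once all FPCNA signals are regressed out. With driver variance v
each driven pair correlates at v/(v+1) fully and ~0 partially.
"""

import numpy as np

from gcflow import default_partition, regulation_table, regulation_tests
from gcflow.synthetic import simulate_common_driver_cohort

partition = default_partition()
records = simulate_common_driver_cohort(partition, n=10, driver_sd=1.0, T=190, seed=2, group="NC")
records += simulate_common_driver_cohort(partition, n=10, driver_sd=1.4, T=190, seed=3, group="AD")

table = regulation_table(records, partition)
for block in ("within-Core", "within-MTL", "Core-DAN"):
    sub = table[table.block == block]
    print(f"{block}: full = {sub['full'].mean():.1f}, partial = {sub['partial'].mean():.2f}, "
      f"effect = {sub['effect'].mean():.1f}")

res = next(r for r in regulation_tests(table) if r.block == "within-Core")
print(f"within-Core paired t (full vs partial), NC: t = {res.paired_t_nc:.1f} (p = {res.paired_p_nc:.2g})")
print(f"group contrast on the regulatory effect: t({res.between.df}) = {res.between.t:.1f}, "
      f"p = {res.between.p:.2g}")
# The stronger driver in the second group yields a larger regulatory effect;
# the 36 within-Core pairs each contribute ~atanh(v/(v+1)) to the index.
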