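"""Simulate a two-group synthetic cohort and write it to disk.

Builds the 52-ROI, six-subsystem partition, plants a block-structured VAR(1)
coupling (denser within subsystems, sparse between), attenuates every
default-network-incident coupling by 0.5 in the AD group, and simulates
27 NC + 24 AD subjects of 190 timepoints at TR = 2 s — the study's stated
cohort dimensions.
"""

import numpy as np

from gcflow import default_partition, write_cohort
from gcflow.synthetic import save_ground_truth, simulate_cohort

partition = default_partition()
records, truth = simulate_cohort(partition, n_nc=27, n_ad=24, T=190, seed=7)

n_edges = len(truth["planted_edges"])
control_a = truth["control"].A
print(f"cohort: {len(records)} subjects "
      f"({sum(r.group == 'NC' for r in records)} NC, {sum(r.group == 'AD' for r in records)} AD)")
print(f"series: {records[0].data.shape[0]} timepoints x {records[0].data.shape[1]} ROIs, "
      f"TR = {records[0].tr_seconds} s")
print(f"planted directed edges: {n_edges} "
      f"(max |coupling| = {np.abs(control_a - np.diag(np.diag(control_a))).max():.3f})")

manifest = write_cohort(records, partition, "scratch/example_cohort")
save_ground_truth(truth, "scratch/example_cohort/ground_truth.json")
print(f"wrote per-subject TSVs + manifest to {manifest.parent}/")
# The ground-truth JSON holds the coupling matrices and planted edge list, so
# downstream analyses can be scored against what was actually simulated.
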