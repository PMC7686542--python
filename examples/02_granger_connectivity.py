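"""Directed connectivity from one subject: condition the series, estimate
bivariate Granger causality for every ordered ROI pair, and check that the
strongest estimated connections sit on planted edges.
"""

import numpy as np

from gcflow import condition, default_partition, pairwise_gc
from gcflow.synthetic import build_coupling, simulate_subject

partition = default_partition()
coupling = build_coupling(partition, "control", seed=7)
record = simulate_subject(coupling, T=190, seed=1, subject_id="demo")

from scipy.stats import rankdata

planted = coupling.planted_edges()
edge = np.zeros((partition.n_rois,) * 2, dtype=bool)
for s, t in planted:
    edge[s, t] = True
off = ~np.eye(partition.n_rois, dtype=bool)


def edge_auc(F):
    ranks = rankdata(F[off])
    n_pos = int(edge[off].sum())
    return (ranks[edge[off]].sum() - n_pos * (n_pos + 1) / 2) / (
        n_pos * (edge[off].size - n_pos)
    )


ecm_raw = pairwise_gc(record, order=1, partition=partition)
conditioned = condition(record)  # confound regression + 0.01-0.08 Hz bandpass
ecm_filt = pairwise_gc(conditioned, order=1, partition=partition)

F = ecm_raw.values
strongest = np.unravel_index(np.argmax(F), F.shape)
print(f"GC matrix: {F.shape}, all entries >= 0, diagonal zero")
print(f"strongest raw connection: {ecm_raw.roi_labels[strongest[0]]} -> "
      f"{ecm_raw.roi_labels[strongest[1]]} (F = {F[strongest]:.3f} nats)")
print(f"planted-edge ranking AUC, raw series:        {edge_auc(ecm_raw.values):.3f}")
print(f"planted-edge ranking AUC, bandpass-filtered: {edge_auc(ecm_filt.values):.3f}")
# F_{i->j} is the log ratio of restricted to full prediction-error variance:
# how much ROI i's past improves the prediction of ROI j beyond j's own past.
# The narrow 0.01-0.08 Hz band smears lag-1 structure across many samples, so
# single-subject edge ranking degrades after filtering; group contrasts (see
# the other examples) survive because the attenuation affects all subjects.
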