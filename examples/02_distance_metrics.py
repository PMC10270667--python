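"""Compute the five network distance metrics for one pair of scans.

Each metric captures a different notion of dissimilarity between two
subjects' networks on the same task; all use the off-diagonal upper
triangle of the correlation matrices.
"""

from bantor import (
    SimConfig,
    euclidean_distance,
    jaccard_distance,
    ks_distance,
    lerm_distance,
    pearson_correlation_distance,
    simulate_dataset,
    threshold_top_fraction,
)

ds = simulate_dataset(SimConfig(n_subjects=2, n_nodes=60, n_timepoints=1000,
                                signal_percent=1.0, seed=0))
c1 = next(s for s in ds.scans if s.subject_id == "s1" and s.task_id == "task1"
          and s.repetition_id == "rep1")
c2 = next(s for s in ds.scans if s.subject_id == "s2" and s.task_id == "task1"
          and s.repetition_id == "rep1")

print(f"comparing {c1.key} with {c2.key}\n")
print(f"log KS statistic : {ks_distance(c1, c2).value: .4f}  "
      "(log of the max gap between edge-weight ECDFs; less negative = more different)")
print(f"Euclidean        : {euclidean_distance(c1, c2).value: .4f}  "
      "(norm of the edge-weight difference)")
print(f"Pearson corr dist: {pearson_correlation_distance(c1, c2).value: .4f}  "
      "(0 = identical edge pattern, 1 = perfectly anti-correlated)")
print(f"log-Euclidean    : {lerm_distance(c1, c2).value: .4f}  "
      "(Riemannian distance between the SPD matrices' logarithms)")
b1 = threshold_top_fraction(c1, 0.2)
b2 = threshold_top_fraction(c2, 0.2)
print(f"Jaccard (top 20%): {jaccard_distance(b1, b2).value: .4f}  "
      "(share of key edges not common to both graphs)")
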