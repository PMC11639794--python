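"""Cluster housekeeping-gene profiles with optimal-k selection.

Three criteria vote on the number of clusters: the elbow of the WSS curve,
the mean silhouette width and the gap statistic.  Here they are shown on
planted Gaussian blobs (where the true k is known) and then used to cluster
the atlas's called HKGs.
"""

import warnings

from tissueatlas import (
    classify,
    cluster_hkg_profiles,
    filter_min_tpm,
    generate_atlas,
    generate_blobs,
    optimal_k,
    score_matrix,
)

# sanity check on data with a known answer: four well-separated blobs
points, _ = generate_blobs(k=4, n_per_cluster=100, separation=10.0, seed=11)
report = optimal_k(points, k_range=range(1, 9), seed=3, gap_B=50)
print("planted k=4 blobs ->", report.chosen_k, "consensus:", report.consensus_k)

# now the atlas housekeeping genes
matrix, _ = generate_atlas(seed=42)
filtered = filter_min_tpm(matrix, 1.0)
classes = classify(score_matrix(filtered))
hkg_ids = list(classes.index[classes["label"] == "HKG"])
print(f"\nclustering {len(hkg_ids)} called HKGs (z-scored log2 profiles)")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result, summary = cluster_hkg_profiles(filtered, hkg_ids, k=4, seed=3)
print("per-cluster size and mean expression (ranked, 1 = most expressed):")
print(summary.to_string())
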