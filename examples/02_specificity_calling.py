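"""Score tissue specificity and call TSGs and HKGs by 2-of-3 voting.

Each gene gets three statistics in [0, 1] (tau, Gini, counts; 0 = uniform,
1 = single-tissue).  A gene is a tissue-specific gene (TSG) when at least
two statistics exceed 0.8, and a housekeeping gene (HKG) when at least two
fall below 0.2.  TSGs are then attributed to their maximum-TPM tissue.
"""

from tissueatlas import (
    assign_tsg_tissue,
    classify,
    filter_min_tpm,
    generate_atlas,
    score_matrix,
)

matrix, truth = generate_atlas(seed=42)
filtered = filter_min_tpm(matrix, 1.0)  # genes with max TPM < 1 are dropped

scores = score_matrix(filtered, threshold=1.0)
classes = classify(scores, high=0.8, low=0.2)
print(classes["label"].value_counts().to_string())

tsg_ids = classes.index[classes["label"] == "TSG"]
by_tissue = assign_tsg_tissue(filtered, tsg_ids).value_counts()
print("\nTSGs per tissue (planted: 50 each):")
print(by_tissue.to_string())

recovered = set(tsg_ids) & set(truth.tsg_ids)
print(f"\nplanted-TSG recall: {len(recovered) / len(truth.tsg_ids):.1%}")
# the called HKG set is larger than the planted one because quiet background
# genes legitimately satisfy the housekeeping definition
hkg_ids = set(classes.index[classes["label"] == "HKG"])
print(f"planted-HKG recall: {len(hkg_ids & set(truth.hkg_ids)) / len(truth.hkg_ids):.1%}")
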