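"""Inter-tissue similarity: Pearson correlation, PCA and a dendrogram.

All three views work on log2(TPM + 1) with tissues as observations.  On the
synthetic atlas the tissues are exchangeable by construction, so the
correlations are high and uniform and no principal component dominates —
real atlases show much stronger block structure (e.g. near-duplicate organ
pairs).
"""

from tissueatlas import generate_atlas, hclust_samples, pca, pearson_matrix

matrix, _ = generate_atlas(seed=42)

corr = pearson_matrix(matrix)  # log2(TPM+1) scale by default
tri = corr.where(~(corr == 1.0))
print(f"tissue-tissue Pearson r: min {tri.min().min():.3f}, "
      f"max off-diagonal {tri.max().max():.3f}")

res = pca(matrix)
print("variance explained by PC1..PC3 (%):",
      [round(float(v), 1) for v in res.variance_explained[:3]])
print(f"PC1+PC2 together: {res.variance_explained[:2].sum():.1f}%")

dend = hclust_samples(corr)
print("\naverage-linkage dendrogram (Newick):")
print(dend.to_newick())
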