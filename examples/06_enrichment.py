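"""Over-representation of a gene set against a GMT-style annotation map.

A term is retained when its Benjamini-Hochberg FDR is <= 0.05 AND at least
three query genes overlap it — a tiny but perfectly significant overlap of
two genes is deliberately not reported.
"""

from tissueatlas import AnnotationMap, enrich, generate_atlas

matrix, truth = generate_atlas(seed=42)
universe = set(matrix.gene_ids)

ann = AnnotationMap()
# a term that truly covers one planted module, and two decoys
ann.add("MOD1_PATHWAY", truth.module_map["M1"], name="planted module 1", category="pathway")
ann.add("RANDOM_SMALL", list(universe)[:40], name="random forty", category="pathway")
ann.add("HK_BLOCK", truth.hkg_ids[:120], name="housekeeping block", category="GO")

query = set(truth.module_map["M1"]) | set(truth.hkg_ids[:10])
table = enrich(query, universe, ann, fdr_max=0.05, min_overlap=3)
print(table[["term", "category", "k", "K", "p", "fdr", "retained"]].to_string(index=False))
print("\nthe planted-module term is retained with the smallest FDR;")
print("the housekeeping term overlaps 10 genes but is diluted; the decoy is not enriched")
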