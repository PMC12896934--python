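"""Hub-gene ranking on an interaction network and gene-set enrichment.

Uses a small hand-built interaction network and two gene sets to show
degree-based hub selection and the hypergeometric over-representation test.
"""

from hetex import EdgeList, GeneSetCollection, enrich, hub_genes

# a lipid-metabolism-flavored toy network: FASN is the most connected node
edges = EdgeList([
    ("FASN", "ACACA"), ("FASN", "SREBF1"), ("FASN", "PPARA"), ("FASN", "DGAT1"),
    ("ACACA", "SREBF1"), ("PPARA", "CPT1A"), ("DGAT1", "FABP3"), ("SREBF1", "PPARA"),
])
query = ["FASN", "ACACA", "SREBF1", "PPARA", "DGAT1", "CPT1A", "FABP3"]
hubs = hub_genes(edges, query, k=3)
print("top hub genes by degree in the query-induced subgraph:")
print(hubs.to_string(index=False))

universe = query + [f"OTHER{i}" for i in range(193)]  # 200-gene background
sets = GeneSetCollection({
    "fatty_acid_synthesis": ["FASN", "ACACA", "SREBF1", "DGAT1"],
    "unrelated_set": [f"OTHER{i}" for i in range(20)],
})
rows = enrich(["FASN", "ACACA", "SREBF1", "DGAT1", "CPT1A"], sets, universe)
print("\nhypergeometric over-representation (BH-adjusted across sets):")
print(rows[["set_name", "overlap", "set_size", "p_value", "p_adjusted"]].to_string(index=False))
# A 4/4 overlap out of a 200-gene universe with a 5-gene query is wildly
# unlikely by chance, hence the tiny p-value for the synthesis set.
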