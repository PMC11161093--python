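"""Fisher exact overlap between gene lists.

Builds a small synthetic example: a phenotype gene list, a
disorder-associated list sharing some members, and an expressed-gene
universe, then tests whether the overlap is larger than chance.  The
universe matters: the same overlap is more surprising in a bigger
background.
"""

import phenofreeze as pf

universe = pf.GeneSet.from_symbols("expressed", [f"GENE{i}" for i in range(2000)])
genes = sorted(universe.genes)

phenotype_degs = pf.GeneSet.from_symbols("phenotype_degs", genes[:120])
disorder_set = pf.GeneSet.from_symbols("disorder", genes[90:190])  # 30 shared

res = pf.fisher_overlap(phenotype_degs, disorder_set, universe)
a, b = res.table[0]
c, d = res.table[1]
print(f"universe {res.universe_n} genes; table: both={a}, A-only={b}, "
      f"B-only={c}, neither={d}")
print(f"odds ratio {res.odds_ratio:.2f}, two-sided p = {res.p_value:.3g}")
print("\nAn odds ratio well above 1 with small p indicates the phenotype list")
print("is enriched for the disorder set relative to the expressed background.")

combined = pf.combine_sets([phenotype_degs,
                            pf.GeneSet.from_symbols("male_degs", genes[100:140])])
print(f"\ncombined sex lists: {len(combined)} unique symbols "
      f"(union handles duplicates)")
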