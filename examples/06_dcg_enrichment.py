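"""Are differentially coexpressed genes also differentially expressed?

Ranks genes by a signed DE score, then asks whether a DCG set occupies a
nonrandom position in that ranking via the weighted running-sum enrichment
statistic with a gene-label permutation p-value.
"""

import numpy as np
import pandas as pd

import dclink as dl

rng = np.random.default_rng(9)
genes = [f"g{i:03d}" for i in range(200)]
normal = pd.DataFrame(rng.standard_normal((200, 30)), index=genes)
tumor = pd.DataFrame(rng.standard_normal((200, 30)), index=genes)
tumor.loc[["g000", "g001", "g002"]] += 1.5  # a few genuinely DE genes

ranked = dl.rank_genes_by_de(normal, tumor, paired=True)

de_coupled_set = {"g000", "g001", "g002", "g010", "g011"}
random_set = set(rng.choice(genes, size=5, replace=False))

for label, gene_set in (("DE-coupled DCGs", de_coupled_set),
                        ("random DCGs", random_set)):
    res = dl.permutation_pvalue(ranked, gene_set, n_perm=1000, weight=1.0, seed=4)
    print(f"{label:16s}: ES = {res.es:+.3f}, permutation p = {res.p:.4f}")
# A set packed with truly shifted genes lands at the top of the ranking
# (large |ES|, small p); a random set does not — the comparison the method
# uses to ask whether differential coexpression is reducible to DE.
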