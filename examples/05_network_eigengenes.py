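"""Module eigengenes, the permutation null, and protein categorization.

Each co-expression module is summarized by its eigengene (first-PC score
of member expression). Proteins are correlated against all eigengenes and
against their seed genes; each protein is assigned the class of its
strongest significant predictor — seed gene, tissue-specific GRN, or
cross-tissue GRN. Shuffling eigengene sample labels gives the empirical
null against which the observed p-value inflation is judged.
"""

from collections import Counter

import numpy as np
from scipy import stats

import plasmanet as pn
from plasmanet.network import eigengene_matrix
from plasmanet.synthetic import membership_table, protein_gene_map

config = pn.SimulationConfig(n_samples=400, n_genes=120, n_tissues=4,
                             snps_per_gene=2, n_modules=8, module_size=8,
                             rng_seed=5)
truth, expected = pn.make_category_design(config, n_per_class=20)
_, expression, proteins, truth, _ = pn.simulate_dataset(config, truth=truth)
p2g = protein_gene_map(config)
membership = membership_table(truth)

eigengenes, definitions = eigengene_matrix(expression, membership)
classes = {m: d.tissue_class for m, d in definitions.items()}
print("modules:", Counter(classes.values()))

eig_records = pn.correlate_eigengenes(proteins, eigengenes, classes)
seed_records = pn.correlate_seed_genes(expression, proteins, p2g)
categories = pn.categorize_proteins(seed_records, eig_records, p2g,
                                    membership)
correct = sum(categories[p].category == c for p, c in expected.items())
print(f"planted-category recovery: {correct}/{len(expected)} "
      "(20 seed-driven, 20 tissue-specific-GRN, 20 cross-tissue-GRN)")

null_p = pn.permutation_null(proteins, eigengenes, n_perm=100, rng_seed=6)
ks = stats.kstest(null_p, "uniform").statistic
obs_median = np.median(eig_records["p"])
frac_sig = eig_records["significant"].mean()
print(f"\npermutation null: KS distance to uniform = {ks:.3f} "
      f"(calibrated); observed grid: median p = {obs_median:.3g}, "
      f"{frac_sig:.1%} of pairs significant — the excess over the null "
      "is the planted module-to-protein signal")
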