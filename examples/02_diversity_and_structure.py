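"""Per-locus diversity, Hardy-Weinberg deviation, and Weir-Cockerham
F-statistics with permutation significance on a synthetic study."""
import numpy as np

from pangotrace import (
    default_partitions,
    default_study_config,
    filter_by_completeness,
    fst_permutation_test,
    locus_summary,
    simulate_dataset,
    wc_f_statistics,
)

ds, _ = simulate_dataset(default_study_config(seed=1))
ds = filter_by_completeness(ds, 0.75)   # keep samples typed at >= 15/20 loci

table, means = locus_summary(ds)
print(table.head(5).round(3))
print(f"\nmeans across loci: Na={means['Na']:.2f}  Ho={means['Ho']:.3f}  "
      f"He={means['He']:.3f}  Ar={means['Ar']:.2f}")
# He > Ho signals a heterozygote deficit, the classic inbreeding signature.

partition = default_partitions(ds, min_n=7)  # forest populations with >= 7 samples
fst = fst_permutation_test(ds, partition, n_perm=999, seed=1)
iu = np.triu_indices(len(fst.labels), 1)
print(f"\npairwise FST: mean={fst.theta.values[iu].mean():.3f}, "
      f"{(fst.pvalues.values[iu] < 0.05).sum()}/{len(iu[0])} pairs significant")
wc = wc_f_statistics(ds, partition)
print(f"multilocus FIS={wc.f:.3f}, FST={wc.theta:.3f} "
      f"(variance components summed over loci)")
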