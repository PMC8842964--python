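"""mtDNA haplotype diversity and neutrality tests with coalescent-simulated
p-values, plus K2P lineage assignment of a query sequence."""
from pangotrace import (
    assign_lineage,
    coalescent_pvalues,
    collapse_haplotypes,
    simulate_coalescent_sample,
)
from pangotrace.genodata import HaplotypeAlignment

aln = simulate_coalescent_sample(n_seqs=126, n_segsites=13, seed=1, length=432)
hs = collapse_haplotypes(aln)
print(f"n={hs.n_sequences}: h={hs.h} haplotypes, Hd={hs.Hd:.3f}, "
      f"pi={hs.pi:.5f} per site")

stats = coalescent_pvalues(aln, reps=1000, seed=1)
for k in ("D", "Fs", "R2", "raggedness"):
    obs = getattr(stats, k if k != "D" else "D") if k != "raggedness" else stats.raggedness
    print(f"  {k:10s} = {obs: .4f}   p = {stats.pvalues[k]:.3f}")
# p-values compare the observation with 1000 neutral constant-size coalescent
# replicates at the same n and S; small p rejects that scenario.

panel = HaplotypeAlignment(
    ["dgl_ref", "wca_ref"],
    ["A" * 432, "G" * 20 + "A" * 412],
)
query = HaplotypeAlignment(["market_sample"], ["G" + "A" * 431])
print(assign_lineage(query, panel, {"dgl_ref": "DahomeyGap", "wca_ref": "WCAfrica"})
      .to_string(index=False))
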