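"""Forensic discriminating power: genotype matching and probability of
identity on a synthetic study with one deliberately duplicated sample."""
import numpy as np

from pangotrace import (
    GenotypeDataset,
    allele_frequencies,
    default_study_config,
    filter_by_completeness,
    match_genotypes,
    min_loci_curve,
    pi_sibs,
    simulate_dataset,
    unbiased_pi,
)

ds, _ = simulate_dataset(default_study_config(seed=1))
ds = filter_by_completeness(ds)

# plant a duplicate: the same pangolin sold twice on different stalls
dup = GenotypeDataset(
    ds.sample_ids + ["DUP_of_first"],
    ds.locus_names,
    np.concatenate([ds.calls, ds.calls[:1]]),
    ds.population + [ds.population[0]],
    ds.site_class + ["market"],
)
report = match_genotypes(dup, min_shared_loci=15)
print(f"match groups: {report.groups}  (psex={report.psex[0]:.2e})")
# A tiny psex says a repeated genotype is the same individual, not chance.

pooled = allele_frequencies(ds, {"all": list(ds.sample_ids)})
_, upi = unbiased_pi(pooled)
_, pis = pi_sibs(pooled)
curve = min_loci_curve(pooled, threshold=0.01)
print(f"uPI = {upi:.3e}, PIsibs = {pis:.3e} over {ds.n_loci} loci")
print(f"{curve.min_loci} best loci suffice for PIsibs < 0.01")
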