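"""Generate a synthetic pedigree methylation study and inspect its pieces.

Builds nuclear families, gene-dropped cis genotypes and pre/post-treatment
beta-value matrices with a few planted treatment-responsive sites, then
prints the study dimensions.  The truth table records each site's class
and causal SNP so downstream analyses can be scored.
"""

from methscreen import SimulationConfig, extract_sibling_pairs, generate_study

cfg = SimulationConfig(
    n_pedigrees=100,
    sibship_size_probs={2: 0.5, 3: 0.5},
    n_sites=500,
    site_class_fractions={"null": 0.98, "constitutive_meqtl": 0.01, "responsive": 0.01},
    seed=11,
)
study = generate_study(cfg)

pairs = extract_sibling_pairs(study.ped)
post_ids = set(study.post.sample_ids)
post_pairs = [p for p in pairs if p.first in post_ids and p.second in post_ids]

print(f"pedigrees:           {len(study.ped.pedigree_ids)}")
print(f"individuals:         {study.ped.n_individuals} pre, {len(post_ids)} post")
print(f"sibling pairs:       {len(pairs)} pre, {len(post_pairs)} post")
print(f"CpG sites:           {len(study.pre.site_ids)}")
print(f"cis SNPs simulated:  {study.genotypes.n_snps}")
print("site classes:")
print(study.truth["class"].value_counts().to_string())
print()
print("Planted responsive sites carry a causal cis-SNP whose effect on the")
print("latent methylation scale is present only post-treatment:")
print(study.truth[study.truth["class"] == "responsive"][["causal_snp", "beta_pre", "beta_post"]])
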