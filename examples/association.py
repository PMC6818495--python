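"""Sex-stratified quantitative-trait association on simulated data.

Plants a male-only additive effect at one SNP, rank-inverse-normal
transforms the trait, and compares per-SNP OLS association in the male and
female strata — the design that reveals sex-specific signals.
"""

from popvar.assoc import normalize_trait, quantitative_assoc
from popvar.simulate import SimConfig, simulate_phenotypes, simulate_two_pop_genotypes

cfg = SimConfig(seed=23, n_pop1=200, n_pop2=200, n_sites=20, F=0.0, phenotype_noise_sd=0.7)
matrix, _ = simulate_two_pop_genotypes(cfg)
pheno, truth = simulate_phenotypes(cfg, matrix, causal={0: 0.6}, male_only=True)

trait = normalize_trait(pheno["trait"].to_numpy())
sex = pheno["sex"].to_numpy()
snp = matrix.variants[0].id

for label, mask in [("male", sex == "male"), ("female", sex == "female")]:
    res = quantitative_assoc(matrix, trait, stratum=mask).set_index("id")
    row = res.loc[snp]
    print(f"{label:6s} stratum: effect={row['effect']:+.3f}  P={row['p']:.2e}  n={int(row['n'])}")
# The planted SNP is strongly associated in males and consistent with the
# null in females — the pattern a sex-stratified scan is designed to expose.
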