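"""BayesR: mixture-of-normals SNP effects via Gibbs sampling.

A trait driven by a handful of large QTL, tagged (but not included) by the
genotyping panel.  BayesR's four-component mixture (variances 0, 0.0001,
0.001, 0.01 x sigma_g2) lets a few markers carry large effects, which is
exactly where it outruns GBLUP.
"""

import numpy as np

import ovinepred as op

cfg = op.PopulationConfig(
    n_breeds=1, breed_labels=("Merino",), n_snps_dense=1500, n_reference=700,
    n_founders_per_breed=120, divergence_generations=30, n_qtl=15,
    qtl_effect_distribution="few_large", var_breed=0.0, h2_target=0.5,
    n_validation_sires_per_breed=20, seed=21,
)
geno, ped, truth = op.simulate_population(cfg)
design = op.simulate_phenotypes(geno, ped, truth, cfg, seed=22)
panel = op.subset_density(geno, 1.0, seed=1, exclude_snp_ids=truth.qtl_ids)
val_ids = list(ped.table.loc[ped.table["role"] == "validation_sire", "id"])
sub = panel.loc_individuals(list(design.animal_ids) + val_ids)

priors = op.BayesRPriors(sigma_g2=0.5, n_iter=6000, burn_in=1500, thin=5, seed=23)
post = op.run_bayesr(design, sub, priors)

print(f"posterior mixture proportions: {np.round(post.pi_mean, 4)}")
print(f"mean # non-null SNPs per iteration: {post.chain_diagnostics['mean_nonzero']:.0f} "
      f"of {sub.n_snps}")
print(f"sigma_e2 posterior mean {post.sigma_e2_mean:.3f}, "
      f"ESS {post.chain_diagnostics['ess_sigma_e2']:.0f}")

G = op.compute_grm(sub)
vc = op.VarianceComponents(v_additive=0.5, v_residual=0.4, v_maternal=0.05, v_sireflock=0.05)
pr = op.solve_mme(design, G, vc, predict_ids=val_ids)
tb = truth.tbv_for(val_ids)
print(f"accuracy on validation sires (corr with true breeding value): "
      f"BayesR {np.corrcoef(post.gbv_for(val_ids), tb)[0, 1]:.2f} vs "
      f"GBLUP {np.corrcoef(pr.gbv_for(val_ids), tb)[0, 1]:.2f}")
print("(with few large QTL the mixture prior concentrates signal on the tag "
      "SNPs and beats the uniform shrinkage of GBLUP)")
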