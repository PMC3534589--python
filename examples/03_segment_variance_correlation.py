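"""Correlate segment-variance maps between two related populations.

Fits BayesR separately on a source and a target population that share QTL,
computes each population's posterior segment-variance profile, and reports
their Pearson correlation before and after excluding the single dominant
segment — the analysis used to ask whether two breeds place trait variance
in the same genome regions (with the major-gene segment removed so it does
not swamp the correlation).
"""

import numpy as np

import bayesrs as b
from bayesrs.mcmc import GibbsConfig, MixtureSpec, fit_bayesr
from bayesrs.segments import correlate_profiles, partition

cfg = b.SimConfig(n_source=1000, n_target=1000, n_validation=50,
                  m_markers=1000, n_chromosomes=5, n_qtl=10,
                  effect_correlation=0.9, seed=5)
study = b.simulate_study(cfg)
part = partition(study.map, 50)
chain = dict(n_iter=2000, burn_in=1000)


def seg_profile(G, pheno, seed):
    W = b.standardize(G)
    y = pheno.values_for(G.sample_ids, "sim")
    mix = MixtureSpec.from_phenotypes(y, pheno.mean_reliability("sim"))
    s = fit_bayesr(W, y, mix, part, cfg=GibbsConfig(seed=seed, **chain))
    return s.segment_variances


prof_src = seg_profile(study.source, study.source_pheno, seed=51)
prof_tgt = seg_profile(study.target_ref, study.target_ref_pheno, seed=52)

r_all = correlate_profiles(prof_src, prof_tgt)
dominant = int(np.argmax(prof_src.variances))
r_drop = correlate_profiles(prof_src, prof_tgt, exclude={dominant})

print(f"segments: {part.n_segments} of {part.segment_size} markers")
print(f"correlation of segment variances, all segments : {r_all:.3f}")
print(f"after removing the dominant segment ({dominant})   : {r_drop:.3f}")
print("\nHigh correlation after removing the outlier segment indicates the "
      "two populations place trait variance in the same genome regions — "
      "the premise that makes cross-population priors informative.")
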