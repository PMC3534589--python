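"""Fit BayesR on a simulated reference population and map segment variances.

Simulates one population with a handful of QTL, fits the four-component
mixture model by Gibbs sampling, and prints the top genome segments ranked
by the share of summed posterior segment variance — the table one would use
to locate major loci (in real cattle data the DGAT1 region on chromosome 14
dominates exactly this ranking for milk traits).
"""

import numpy as np

import bayesrs as b
from bayesrs.mcmc import GibbsConfig, MixtureSpec, fit_bayesr
from bayesrs.segments import partition

cfg = b.SimConfig(n_source=800, n_target=100, n_validation=60,
                  m_markers=1000, n_chromosomes=5, n_qtl=8, seed=11)
study = b.simulate_study(cfg)

W = b.standardize(study.source)
y = study.source_pheno.values_for(study.source.sample_ids, "sim")
mixture = MixtureSpec.from_phenotypes(
    y, study.source_pheno.mean_reliability("sim"))
part = partition(study.map, 50)

summary = fit_bayesr(W, y, mixture, part,
                     cfg=GibbsConfig(n_iter=2000, burn_in=1000, seed=1))

table = summary.segment_variances.to_frame(part)
table["prop_var_pct"] = 100 * table["prop_var"]
top = table.sort_values("variance", ascending=False).head(8)
print("Top segments by share of summed posterior segment variance:")
print(top[["segment_index", "chrom", "start_bp", "end_bp",
           "prop_var_pct"]].to_string(index=False,
                                      float_format=lambda v: f"{v:.2f}"))

seg_of = part.segment_of_marker()
qtl_segs = sorted(set(seg_of[study.truth.qtl_indices()].tolist()))
print(f"\nSegments truly containing QTL: {qtl_segs}")
print("Large-effect QTL dominate the ranking; QTL whose mixture-drawn "
      "effect is small blend into the near-zero background shares that "
      "the remaining segments carry.")
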