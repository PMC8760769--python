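"""Does dominance rank predict cortisol concentration?

Fits untransformed cortisol on sampling time, rank index, their
interaction, body weight, measurement and housing group, with a per-
individual random intercept plus sampling-time random slopes (unstructured
covariance). Estimated marginal means per sampling time and Satterthwaite
pairwise contrasts quantify the response to the stressor.
"""

import repeatkit as rk
from repeatkit.lmm import emmeans, fixed_effects_table, pairwise_contrasts
from repeatkit.pipeline import PipelineConfig, analysis_frames, \
    rank_cortisol_spec

dataset, _ = rk.generate_study(rk.SyntheticParams(seed=5))
_, long = analysis_frames(dataset, PipelineConfig())

fit = rk.fit_reml(long, rank_cortisol_spec())
print(f"n = {fit.n_obs} samples, {fit.n_groups} individuals; "
      f"converged = {fit.converged}")
print()
table = fixed_effects_table(fit)
print(table.to_string(index=False,
                      float_format=lambda v: f"{v:.3f}"))
print()
emms = emmeans(fit, "sampling_time")
print("estimated marginal means (assay units):")
print(emms.to_frame().to_string(index=False,
                                float_format=lambda v: f"{v:.1f}"))
print()
for c in pairwise_contrasts(emms):
    print(f"  {c.name}: t = {c.t_value:.3f}, df = {c.df:.1f}, "
          f"p = {c.p_value:.4g}")
print()
print("Large positive sampling-time contrasts confirm the stress response; "
      "a rank or sampling-time:rank term near zero means rank does not "
      "predict cortisol, as in the generative model.")
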