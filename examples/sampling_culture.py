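"""Why lab cultures lose diversity: sampling and resource supply.

Sampling a wild community keeps each consumer with probability s (thinning
the producers of every metabolite to y_m = s z_m); supplying resources in
culture satisfies each requirement with probability r (thinning effective
requirements to y_c = (1-r) z_c).  The cultured community follows a
warm-started path and can be trapped on the low-diversity branch.
"""

from crossfeednet import (
    CommunityEnsemble,
    PerturbationParams,
    culture_diversity,
    culture_ensemble_run,
)

wild = CommunityEnsemble.poisson(4.0, 4.0)
for retention, supply in [(0.9, 0.3), (0.3, 0.3), (0.3, 0.9)]:
    params = PerturbationParams(sample_retention=retention, supply_fraction=supply)
    out = culture_diversity(wild, params)
    sim = culture_ensemble_run(1000, 1000, 4.0, 4.0, params, replicates=10, seed=0)
    print(
        f"s = {retention:.1f}, r = {supply:.1f}: wild c* = {out.path.wild_c:.3f}"
        f" -> sampled {out.path.sampled_c:.3f} -> cultured {out.path.cultured_c:.3f}"
        f"   (simulated {sim.cultured_c.mean():.3f} +/- {sim.cultured_c.sem():.3f})"
    )
print(
    "\nHeavy sampling collapses the cross-feeding network even on a rich "
    "medium;\ngenerous resource supply partially rebuilds it. The analytic "
    "path and the\nnetwork simulations agree within sampling error."
)
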