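"""Inter-locus spacer sharing against simulated nulls.

Simulates a study where 58% of second-locus events reuse prespacers already
sampled by the first locus, then asks: is the observed overlap explainable
by independent sampling (uniform-random null) or by shared motif preference
alone (PAM-adjacent null)?  The observed fraction should exceed both null
means by many standard deviations.
"""
import dataclasses

from spaceraq import AcquisitionParams, NullModelConfig, observed_overlap, run_null
from spaceraq.estimation import _phage_subpool, run_synthetic_pipeline

params = AcquisitionParams(n_events=300, pam_preference=0.63,
                           self_fraction=0.0, shared_pool_fraction=0.58)
art = run_synthetic_pipeline(params, seed=21, phage_length=47_000,
                             host_length=60_000)

ref = _phage_subpool(art["pools"]["II-C"], art["hits"]["II-C"])
query = _phage_subpool(art["pools"]["VI-B"], art["hits"]["VI-B"])
cfg = NullModelConfig(n_iterations=300, sample_size=len(query), seed=22)

obs = observed_overlap(query, ref, cfg)
print(f"observed: {100 * obs:.1f}% of {len(query)} unique second-locus spacers "
      f"match the {len(ref)}-spacer first-locus pool at 90% identity")
for mode in ("random", "pam_adjacent"):
    res = run_null(art["phage"], ref, dataclasses.replace(cfg, sampling_mode=mode),
                   observed=obs)
    print(f"{mode:>13} null: mean {100 * res.mu:.1f}% (SD {100 * res.sigma:.2f}%), "
          f"normal-tail p = {res.p_normal:.3g}, empirical p = {res.p_empirical:.3g}")
# PAM-conditioning raises the null mean above uniform sampling, but neither
# null reaches the observed sharing: the loci draw from one prespacer pool.
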