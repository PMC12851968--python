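"""Ectopic-beat rejection and zero-phase smoothing.

Corrupts a synthetic recording with 5% ectopic-like spikes (40-60%
interval distortion, alternating short/long), then runs the
local-regression/MAD cleaning rule and reports its sensitivity against
the injection ground truth.
"""

from cardiocas import (
    CASParameters,
    COHORT_CAS_MEANS,
    inject_artifacts,
    preprocess,
    remove_ectopic,
    simulate_rri_trajectory,
)

params = CASParameters(**COHORT_CAS_MEANS, sigma=30.0)
rec = simulate_rri_trajectory(params, seed=2)
corrupted, truth_mask = inject_artifacts(rec, ectopic_rate=0.05,
                                         magnitude_range=(0.4, 0.6), seed=3)

cleaned, removed = remove_ectopic(corrupted)
tp = int((removed & truth_mask).sum())
print(f"injected ectopics : {int(truth_mask.sum())} of {rec.n_beats} beats")
print(f"flagged beats     : {int(removed.sum())}")
print(f"sensitivity       : {tp / truth_mask.sum():.1%}  "
      "(fraction of injected spikes caught)")
print(f"false positives   : {int((removed & ~truth_mask).sum())}  "
      "(clean beats in the ~4.6% Gaussian tail)")

smooth, report = preprocess(corrupted)
print(f"full cleaning pass: kept {smooth.n_kept}/{report['n_beats']} beats "
      f"(removal fraction {report['removal_fraction']:.1%})")
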