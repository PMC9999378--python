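"""Synthesize gait trials and extract the nine stance-phase load instances.

Each trial's hip contact force (HCF) has the double-peaked stance profile
typical of walking; the representative trial minimizes the RMS distance to
the mean waveform, and the nine load instances anchor on the two peaks and
the valley between them.  The table prints the stance percentage and HCF
magnitude (in body weights) of each instance.
"""

import numpy as np

from gpfem import (
    select_load_instances,
    select_representative_trial,
    synthesize_trials,
)

BODY_MASS = 36.8  # kg
trials = synthesize_trials("TD", n_trials=10, body_mass=BODY_MASS, seed=7)
rep = select_representative_trial(trials)
print(f"{len(trials)} trials synthesized; representative trial: #{rep}")

bw = BODY_MASS * 9.81
peaks = [tr.resultant.max() / bw for tr in trials]
print(f"HCF peak range across trials: {min(peaks):.2f} - {max(peaks):.2f} BW")

instances = select_load_instances(trials[rep])
print("\ninstance  stance%   |HCF| (N)   |HCF| (BW)   muscle total (N)")
for li in instances:
    mus = np.linalg.norm(np.sum([f for _, _, f in li.muscle_point_loads], axis=0))
    mag = np.linalg.norm(li.hcf_vector)
    print(f"   {li.instance_id}      {li.stance_pct:5.1f}   {mag:9.1f}   {mag / bw:8.2f}    {mus:10.1f}")
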