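"""Firing-rate change around a 60 s static soma compression.

Twenty units fire spontaneously at 2 Hz; during the compression their rate
is modulated by a ground-truth factor of 1.25.  Rates are measured in the
before / during / after epochs (2.5 min / 60 s / 2.5 min) and compared
with the paired Wilcoxon signed-rank test.
"""

import numpy as np

from mechanoephys import EpochSet, MechStimulus, epoch_firing_rates, paired_wilcoxon
from mechanoephys.synthetic import StimulusEffect, SynthConfig, gen_spike_population

stim = MechStimulus(kind="static", setpoint_force=200.0, approach_speed=10.0,
                    contact_on=170.0, contact_off=230.0)
cfg = SynthConfig(seed=0, n_units=20, duration=400.0, burst_model=None,
                  base_rate=2.0, stimulus_schedule=(stim,),
                  stimulus_effects=(StimulusEffect(rate_factor_during=1.25),))
trains, _, _ = gen_spike_population(cfg)

epochs = EpochSet.around(stim, pre=150.0, post=150.0)
before, during, after = [], [], []
for tr in trains:
    b, d, a = epoch_firing_rates(tr, epochs)
    before.append(b)
    during.append(d)
    after.append(a)
before, during, after = map(np.asarray, (before, during, after))

pct = 100.0 * (during - before) / before
W, p = paired_wilcoxon(before, during)
print(f"mean rate before {before.mean():.2f} Hz, during {during.mean():.2f} Hz, "
      f"after {after.mean():.2f} Hz")
print(f"median rate change during compression: {np.median(pct):+.1f} % "
      f"(injected +25 %)")
print(f"Wilcoxon signed-rank before vs during: W = {W:.1f}, p = {p:.2e}")
print("A p below 0.05 with a ~25 % median change is the recovery of the "
      "injected modulation; the after epoch returns to baseline.")
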