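"""Waveform-feature changes across a unit's electrode footprint.

A compression applied over the target electrode scales the extracellular
templates by 1.13 during the stimulus.  Features (trough amplitude, FWHM,
repolarization slope) are extracted per electrode and epoch, and their
during/before ratios are tabulated against distance from the target.
"""

from mechanoephys.synthetic import SynthConfig, gen_footprint
from mechanoephys.waveforms import amplitude_change_vs_distance

cfg = SynthConfig(seed=0, during_scale=1.13)
footprint = gen_footprint(cfg, (0.0, 0.0), epochs=["before", "during"], n_side=5)
table = amplitude_change_vs_distance(footprint)

print(table.head(8).to_string(index=False,
                              float_format=lambda v: f"{v:.4f}"))
print(f"\nmean amplitude ratio : {table['amplitude_ratio'].mean():.4f} "
      f"(injected 1.13)")
print(f"mean halfwidth ratio : {table['halfwidth_ratio'].mean():.4f} "
      f"(spike width is unchanged by a pure amplitude scaling)")
print("The ratio is flat in distance here because the injected change is "
      "uniform; distance-dependent effects would appear as a trend.")
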