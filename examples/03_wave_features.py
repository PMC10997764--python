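"""Extract the stress-identifying wave features from a concentration trace.

Generates the heat-stress archetype's noise-free ground truth and reads
off the features that distinguish stresses: FWHM (wave duration),
production/decay rates (flank slopes), SA onset, and the two wave
velocities.  Heat is the most asymmetric archetype: a very fast rise
with a slow relaxation.
"""

from leafwave.synth import ground_truth_series, make_fields, preset
from leafwave.wave_features import extract_features, sa_wave_velocity

cfg = preset("heat")
truth = make_fields(cfg)
rois = cfg.rois()

h = extract_features(ground_truth_series(truth, rois, "h2o2", cfg))
sa = truth.features["sa"]

print(f"H2O2 FWHM        = {h.fwhm:5.1f} min   (time between amplitude midpoints)")
print(f"H2O2 production  = {h.production_rate:5.1f} uM/h (10-90% rising-flank slope)")
print(f"H2O2 decay       = {h.decay_rate:5.1f} uM/h")
print(f"SA onset         = {sa.onset_time:5.1f} min  post-stress")
print(f"SA wave velocity = {sa_wave_velocity(1.0, sa.onset_time):.3f} cm/min "
      "(1.0 cm site-to-sensor distance)")
print(f"ROS front speed  = {truth.velocities['h2o2']:.3f} cm/min "
      "(distance-vs-arrival regression)")
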