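# Continuous-score reference model (stand-in for the proprietary 0-5 index).
#
# Honors the published interface: four channels (spo2, rr, hr, sbp), a score
# is valid only when at least three are present, output lies in [0, 5], and
# the alert threshold is 3.  The aggregate is the root-mean-square of the
# per-channel standardized deviations over present channels, mapped by the
# saturating function  score = score_max * r / (r + softness).
center:
  spo2: 96.5
  rr: 16.0
  hr: 78.0
  sbp: 122.0
scale:
  spo2: 2.0
  rr: 3.0
  hr: 10.0
  sbp: 15.0
softness: 1.5
score_max: 5.0
alert_threshold: 3.0
min_channels: 3
half_window_min: 5
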