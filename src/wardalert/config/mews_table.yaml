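# Modified Early Warning Score banding used by the periodic scenario.
#
# This is a standard MEWS-style table with oxygen-delivery and AVPU add-ons.
# It is a documented stand-in: the exact hospital-protocol bands behind the
# reference counts are not public, so no fidelity to any specific local
# protocol is claimed.  Bands are half-open [lo, hi) and must tile the
# physiologic range of each channel.
alert_threshold: 6
oxygen_points: 2
avpu_points:
  A: 0
  V: 1
  P: 2
  U: 3
bands:
  hr:
    - [10, 40, 2]
    - [40, 51, 1]
    - [51, 101, 0]
    - [101, 111, 1]
    - [111, 131, 2]
    - [131, 300, 3]
  rr:
    - [0, 9, 2]
    - [9, 15, 0]
    - [15, 21, 1]
    - [21, 30, 2]
    - [30, 80, 3]
  spo2:
    - [30, 92, 3]
    - [92, 94, 2]
    - [94, 96, 1]
    - [96, 101, 0]
  sbp:
    - [30, 70, 3]
    - [70, 81, 2]
    - [81, 101, 1]
    - [101, 200, 0]
    - [200, 300, 2]
  temp:
    - [25, 35, 2]
    - [35, 38.5, 0]
    - [38.5, 45, 2]
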