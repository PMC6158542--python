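# Species islet-size profiles: diameter range and average diameter (mean ± sd, μm)
# compiled from published surveys of isolated islets. Where a range was not
# reported (NR) it is null and the generator falls back to mean ± 6 sd.
#
# Caveat (goat): the source table prints "50 ± 250", which reads as a size
# range typographically formatted as mean ± sd; it is shipped here as the
# range 50-250 with no mean, so the goat profile cannot be sampled without
# the user supplying a mean and sd explicitly.
human:
  d_min: 30.0
  d_max: 450.0   # upper end open in the literature ("30 to >400")
  mean_d: 108.0
  sd_d: 6.0
rat:
  d_min: 30.0
  d_max: 350.0
  mean_d: 115.0
  sd_d: 5.0
mouse:
  d_min: 20.0
  d_max: 350.0
  mean_d: 116.0
  sd_d: 80.0
monkey:
  d_min: 25.0
  d_max: 340.0
  mean_d: 67.0
  sd_d: 38.0
adult_pig:
  d_min: 50.0
  d_max: 250.0
  mean_d: 156.0
  sd_d: 8.0
fetal_pig:
  d_min: null
  d_max: null
  mean_d: 83.0
  sd_d: 1.0
rabbit:
  d_min: 25.0
  d_max: 160.0
  mean_d: 64.0
  sd_d: 28.0
canine:
  d_min: 50.0
  d_max: 375.0
  mean_d: 158.0
  sd_d: 2.0
goat:
  d_min: 50.0
  d_max: 250.0
  mean_d: null
  sd_d: null
bird:
  d_min: 10.0
  d_max: 50.0
  mean_d: 24.0
  sd_d: 6.0
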