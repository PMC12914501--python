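# Tissue-mimicking sampling intervals for the 7T rat-brain CW-CEST simulator.
# Uniform (lo, hi) intervals; rates in s^-1, times in s, shifts in ppm.
# Literature-typical rat-brain values at 7 T; every entry is overridable.
water:
  t1w_s: [1.4, 2.2]
  t2w_s: [0.03, 0.06]
pools:
  amide:
    delta_ppm: [3.5, 3.5]
    fs: [0.0005, 0.002]
    ksw: [10.0, 100.0]
    r2s: [20.0, 100.0]
  amine:
    delta_ppm: [3.0, 3.0]
    fs: [0.001, 0.005]
    ksw: [1000.0, 6000.0]
    r2s: [30.0, 120.0]
  guan:
    delta_ppm: [2.0, 2.0]
    fs: [0.0002, 0.002]
    ksw: [50.0, 500.0]
    r2s: [20.0, 70.0]
  noe16:
    delta_ppm: [-1.6, -1.6]
    fs: [0.001, 0.004]
    ksw: [10.0, 60.0]
    r2s: [15.0, 60.0]
  noe35:
    delta_ppm: [-3.5, -3.5]
    fs: [0.003, 0.01]
    ksw: [10.0, 40.0]
    r2s: [15.0, 60.0]
  mt:
    delta_ppm: [0.0, 0.0]
    fs: [0.05, 0.15]
    ksw: [20.0, 60.0]
    r2s: [50000.0, 200000.0]
b0_shift_ppm: [-0.1, 0.1]
b1_scale: [0.9, 1.1]
noise_sigma: 0.01
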