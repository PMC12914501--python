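# Fully-synthetic sampling intervals: deliberately broader than the
# tissue-mimicking set to stand in for the mismatch between simulation
# assumptions and actual tissue composition.
water:
  t1w_s: [1.2, 2.6]
  t2w_s: [0.02, 0.08]
pools:
  amide:
    delta_ppm: [3.4, 3.6]
    fs: [0.0002, 0.003]
    ksw: [5.0, 150.0]
    r2s: [10.0, 150.0]
  amine:
    delta_ppm: [2.8, 3.2]
    fs: [0.0005, 0.008]
    ksw: [500.0, 8000.0]
    r2s: [20.0, 200.0]
  guan:
    delta_ppm: [2.0, 2.0]
    fs: [0.0001, 0.003]
    ksw: [30.0, 700.0]
    r2s: [15.0, 90.0]
  noe16:
    delta_ppm: [-1.8, -1.4]
    fs: [0.0005, 0.006]
    ksw: [5.0, 80.0]
    r2s: [10.0, 80.0]
  noe35:
    delta_ppm: [-3.7, -3.3]
    fs: [0.002, 0.015]
    ksw: [5.0, 60.0]
    r2s: [10.0, 80.0]
  mt:
    delta_ppm: [-0.5, 0.5]
    fs: [0.03, 0.2]
    ksw: [10.0, 80.0]
    r2s: [30000.0, 300000.0]
b0_shift_ppm: [-0.1, 0.1]
b1_scale: [0.9, 1.1]
noise_sigma: 0.01
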