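# Default CH-CDF boundary parameters.
#
# ch: the charge-hydropathy boundary line <R> = slope * <H> + intercept from the
#     classical CH-plot classifier (Uversky-style boundary for Kyte-Doolittle
#     hydropathy rescaled to [0, 1]).
#
# cdf: SYNTHETIC stand-in boundary. The published CDF boundary points belong to a
#     proprietary PONDR predictor and are not reproduced here; these seven points
#     form a plausible diagonal separation for probability-valued disorder scores
#     and are intended only as a usable default. Supply a calibrated boundary for
#     any real analysis; every test in this package uses explicit fixture
#     boundaries rather than these values.
ch:
  slope: 2.785
  intercept: -1.151
cdf:
  - [0.2, 0.40]
  - [0.3, 0.47]
  - [0.4, 0.54]
  - [0.5, 0.61]
  - [0.6, 0.68]
  - [0.7, 0.75]
  - [0.8, 0.82]
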