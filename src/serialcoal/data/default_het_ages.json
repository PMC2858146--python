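{
  "description": "Default heterochronous sampling fixture: 37 tip ages in years BP, evenly spaced over the Holocene span of a serial ancient-mtDNA collection (youngest 2,000 BP, oldest 12,000 BP). Edit or replace to use real radiocarbon ages.",
  "ages_bp": [
    2000.0, 2277.7777777777778, 2555.5555555555557, 2833.3333333333335,
    3111.111111111111, 3388.888888888889, 3666.6666666666665, 3944.4444444444443,
    4222.222222222223, 4500.0, 4777.777777777777, 5055.555555555556,
    5333.333333333333, 5611.111111111111, 5888.888888888889, 6166.666666666667,
    6444.444444444444, 6722.222222222223, 7000.0, 7277.777777777777,
    7555.555555555556, 7833.333333333333, 8111.111111111111, 8388.888888888889,
    8666.666666666666, 8944.444444444445, 9222.222222222223, 9500.0,
    9777.777777777777, 10055.555555555555, 10333.333333333334, 10611.111111111111,
    10888.888888888889, 11166.666666666666, 11444.444444444445, 11722.222222222223,
    12000.0
  ]
}
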