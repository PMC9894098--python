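{
 "phenotype": "healthy",
 "protocol": "500 beats at 1 Hz from published resting state, default solver schedule",
 "state": [
  -87.85174895461685,
  7.189751236577438,
  7.189835618414264,
  143.80961526376836,
  143.80958886775122,
  8.553592329558684e-05,
  8.43792188559691e-05,
  1.6109257104965469,
  1.5688215047896528,
  0.0009801675183868006,
  0.8094728644832485,
  0.809305147908558,
  0.0001937087682824552,
  0.4968572401875993,
  0.2672362609938522,
  0.0010112822792911896,
  0.999542306864876,
  0.5926569030474099,
  0.0005152781945287164,
  0.9995423141029118,
  0.6453763445080188,
  2.425380884822601e-09,
  0.9999999904965021,
  0.9121541974799727,
  0.999999990496565,
  0.9998298308752567,
  0.9999784811222502,
  0.002681876507603122,
  0.9999999904936369,
  0.9999999904938103,
  8.247959278726622e-06,
  0.4507463138834031,
  0.2658388966870843,
  0.00019611441682930683,
  0.9967989664775495,
  2.571002136325707e-07,
  3.212260228920075e-07,
  0.011902794314759645,
  -49.6,
  0.0,
  1.0,
  -60.0,
  0.0,
  1.0,
  1.0,
  0.0,
  1.0,
  0.0,
  1.0,
  1.0,
  0.0,
  1.0,
  1.0,
  1.0,
  1.0,
  1.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.99,
  0.0,
  1.0,
  0.0,
  0.0,
  1.0,
  0.0,
  1.0,
  0.0,
  1.0,
  0.0,
  1.0,
  0.0,
  0.0,
  0.0,
  1.0
 ]
}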