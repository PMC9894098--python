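{
 "phenotype": "hf+fibrosis",
 "protocol": "500 beats at 1 Hz from published resting state, default solver schedule",
 "state": [
  -85.7507076473507,
  8.622521060551746,
  8.622681459777606,
  142.57575659602168,
  142.5757261098114,
  0.00010048328740739155,
  9.639491545955717e-05,
  0.701830616481858,
  0.6919214078479967,
  0.0015356946562581943,
  0.7588845969429082,
  0.7584564233612148,
  0.0002887029908513119,
  0.4313631553458316,
  0.2282166448151036,
  0.0011651404364094971,
  0.9993388261485052,
  0.623295224463134,
  0.0005937183195930864,
  0.9993388446974965,
  0.6889203687752004,
  3.985668560180829e-09,
  0.999999983217809,
  0.9564155190059304,
  0.9999999832180826,
  0.9999574767148576,
  0.9999934211808477,
  0.0044539630712362435,
  0.9999999832078168,
  0.9999999832085436,
  1.1211276369645923e-05,
  0.39828548200867114,
  0.16711715770037336,
  0.0002481922859493121,
  0.9973010848900136,
  1.4595174091623632e-09,
  1.8239035371412838e-09,
  0.00872712814283959,
  -79.54312401375103,
  0.0044398957126878654,
  0.9752649911011742,
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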