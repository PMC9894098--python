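{
 "phenotype": "hf",
 "protocol": "500 beats at 1 Hz from published resting state, default solver schedule",
 "state": [
  -87.48479508986797,
  8.495006073026262,
  8.495184846377773,
  142.68468734822665,
  142.6846605357838,
  0.00010902403396607276,
  0.00010439951818252918,
  0.7795185220533857,
  0.7611238356753031,
  0.0010604109189245752,
  0.8012855698147202,
  0.8007736324236892,
  0.00020769279015739407,
  0.48006026938310475,
  0.2479701759640925,
  0.0010366213892030786,
  0.9995118099901833,
  0.5695813990951858,
  0.0005281957906523412,
  0.9995118345633807,
  0.6174847309556608,
  2.645275681992157e-09,
  0.9999999895000174,
  0.8966402805593747,
  0.9999999895002512,
  0.9997406283464499,
  0.9999643005885992,
  0.006027624200388101,
  0.9999999894899501,
  0.9999999894905697,
  8.831919280560429e-06,
  0.4758989552974911,
  0.3030524280200477,
  0.00020447335869221747,
  0.9968936439381847,
  2.06587498505535e-09,
  2.581030847034637e-09,
  0.013422795678205274,
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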