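chromophore,wavelength_nm,absorption_mm1_per_unit_fraction
hb,700,0.9612
hb,710,0.8721
hb,720,0.7897
hb,730,0.7265
hb,740,0.7103
hb,750,0.7528
hb,760,0.8296
hb,770,0.7029
hb,780,0.5761
hb,790,0.4843
hb,800,0.4081
hb,810,0.3841
hb,820,0.3717
hb,830,0.3713
hb,840,0.3709
hb,850,0.3703
hbo2,700,0.1554
hbo2,710,0.1682
hbo2,720,0.1832
hbo2,730,0.2089
hbo2,740,0.2389
hbo2,750,0.2775
hbo2,760,0.3139
hbo2,770,0.3482
hbo2,780,0.3803
hbo2,790,0.4087
hbo2,800,0.4372
hbo2,810,0.4634
hbo2,820,0.4907
hbo2,830,0.5218
hbo2,840,0.5475
hbo2,850,0.5668
water,700,0.00060
water,710,0.00070
water,720,0.00105
water,730,0.00180
water,740,0.00270
water,750,0.00260
water,760,0.00250
water,770,0.00230
water,780,0.00225
water,790,0.00230
water,800,0.00220
water,810,0.00230
water,820,0.00260
water,830,0.00290
water,840,0.00350
water,850,0.00430
fat,700,0.00090
fat,710,0.00091
fat,720,0.00092
fat,730,0.00094
fat,740,0.00096
fat,750,0.00099
fat,760,0.00103
fat,770,0.00104
fat,780,0.00104
fat,790,0.00105
fat,800,0.00106
fat,810,0.00107
fat,820,0.00108
fat,830,0.00109
fat,840,0.00110
fat,850,0.00111
melanin,700,21.31
melanin,710,20.26
melanin,720,19.29
melanin,730,18.38
melanin,740,17.54
melanin,750,16.76
melanin,760,15.99
melanin,770,15.29
melanin,780,14.62
melanin,790,13.98
melanin,800,13.39
melanin,810,12.81
melanin,820,12.27
melanin,830,11.77
melanin,840,11.28
melanin,850,10.83
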