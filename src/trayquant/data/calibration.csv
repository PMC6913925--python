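# Generator calibration: mean (mu) and SD (sigma) of log10 E. coli
# concentration in matrix reporting units, by sample type and stratum,
# from the 2017 urban Dhaka environmental surveillance campaign
# (10 neighborhoods x 10 sample types x 10 samples).  "overall" rows pool
# all 10 neighborhoods; category rows pool neighborhoods of one
# socio-economic stratum.  Units: water per 100 mL, latrine_swab per swab,
# produce per serving, street_food and soil per gram.
sample_type,stratum,mu,sigma
latrine_swab,overall,0.20,0.73
soil,overall,2.29,1.29
drain_water,overall,6.91,0.92
bathing_water,overall,1.34,1.34
municipal_water,overall,1.17,1.55
non_municipal_water,overall,0.45,0.94
surface_water,overall,5.28,1.37
produce,overall,3.19,1.36
street_food,overall,1.79,1.18
floodwater,overall,4.60,1.02
latrine_swab,low_income,0.22,0.72
soil,low_income,2.55,1.34
drain_water,low_income,7.11,0.86
bathing_water,low_income,1.92,1.32
municipal_water,low_income,1.55,1.73
non_municipal_water,low_income,0.81,1.19
surface_water,low_income,6.21,1.01
produce,low_income,3.10,1.13
street_food,low_income,1.62,1.11
floodwater,low_income,4.86,0.88
latrine_swab,high_income,0.07,0.63
soil,high_income,1.63,1.16
drain_water,high_income,6.95,0.84
bathing_water,high_income,0.94,1.23
municipal_water,high_income,1.07,1.41
non_municipal_water,high_income,0.18,0.60
surface_water,high_income,4.29,1.01
produce,high_income,3.15,1.37
street_food,high_income,1.91,1.21
floodwater,high_income,4.38,0.98
latrine_swab,floating,0.42,0.91
soil,floating,3.09,0.79
drain_water,floating,6.46,1.11
bathing_water,floating,0.99,1.24
municipal_water,floating,0.64,1.30
non_municipal_water,floating,0.26,0.73
surface_water,floating,5.40,1.32
produce,floating,3.45,1.49
street_food,floating,1.92,1.28
floodwater,floating,4.51,1.28
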