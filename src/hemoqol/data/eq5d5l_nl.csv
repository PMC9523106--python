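# EQ-5D-5L Dutch tariff value set (additive decrement model).
# Source: M. Versteegh et al., "Dutch Tariff for the Five-Level Version of
# EQ-5D", Value in Health 19 (2016) 343-352. Utility index = 1 minus the sum
# of the per-dimension decrements; level 1 carries no decrement. The worst
# state 55555 scores 1 - 1.446 = -0.446, the published range minimum.
# Dimensions: MO mobility, SC self-care, UA usual activities,
# PD pain/discomfort, AD anxiety/depression.
dimension,level,decrement
MO,1,0.000
MO,2,0.035
MO,3,0.058
MO,4,0.244
MO,5,0.323
SC,1,0.000
SC,2,0.040
SC,3,0.061
SC,4,0.168
SC,5,0.212
UA,1,0.000
UA,2,0.034
UA,3,0.056
UA,4,0.160
UA,5,0.204
PD,1,0.000
PD,2,0.060
PD,3,0.094
PD,4,0.272
PD,5,0.346
AD,1,0.000
AD,2,0.080
AD,3,0.107
AD,4,0.260
AD,5,0.361
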