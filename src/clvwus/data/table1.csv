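name,carpels_per_flower,se,threshold_error,role
wild_type,2.0,0.0,,reference
crn1,3.9,0.1,0.1,optimization
clv1_11,3.9,0.1,0.1,optimization
crn1_clv2_1,3.8,0.1,0.1,optimization
clv1_1,4.2,0.1,0.1,optimization
crn1_clv1_11,5.3,0.1,0.5,validation
crn1_clv1_1,4.5,0.1,0.5,validation
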