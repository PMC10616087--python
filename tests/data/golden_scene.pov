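// generated by hybridboss
#version 3.7;
global_settings { assumed_gamma 1.0 }
background { color rgb <1,1,1> }
camera { location <400.0, 400.0, 400.0> look_at <0, 0, 0> }
light_source { <400.0, 800.0, 400.0> color rgb <1,1,1> }
sphere { <0.000, 0.000, 0.000>, 8.400 pigment { color rgb <0.20, 0.40, 1.00> } }
sphere { <20.000, 0.000, 5.000>, 8.400 pigment { color rgb <0.20, 0.40, 1.00> } }
sphere { <-20.000, 10.000, 0.000>, 6.000 pigment { color rgb <1.00, 0.15, 0.15> } }
sphere { <0.000, -15.000, 10.000>, 8.400 pigment { color rgb <0.45, 0.30, 0.15> } }
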