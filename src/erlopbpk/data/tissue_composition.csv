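# Reference adult male (70 kg) tissue volumes, regional blood flows and
# fractional composition for partition-coefficient calculation.
# volume_l and flow_l_h are rescaled to the subject's body weight at build
# time (volumes linearly, flows allometrically with exponent 0.75).
# f_ew/f_iw: extracellular/intracellular water; f_nl/f_np: neutral lipid /
# neutral phospholipid; ra_albumin: tissue:plasma albumin ratio
# (lipoprotein ratio for adipose).
tissue,volume_l,flow_l_h,f_ew,f_iw,f_nl,f_np,ra_albumin
lung,0.50,336.0,0.336,0.446,0.0030,0.0090,0.212
adipose,18.20,17.0,0.135,0.017,0.7900,0.0020,0.049
bone,10.50,17.0,0.100,0.346,0.0740,0.0011,0.100
brain,1.45,40.0,0.162,0.620,0.0510,0.0565,0.048
gut,1.65,54.0,0.282,0.475,0.0487,0.0163,0.158
heart,0.33,13.4,0.320,0.456,0.0115,0.0166,0.157
kidney,0.31,64.0,0.273,0.483,0.0207,0.0162,0.130
liver,1.80,22.0,0.161,0.573,0.0348,0.0252,0.086
muscle,29.00,57.0,0.118,0.630,0.0238,0.0072,0.064
skin,3.30,17.0,0.382,0.291,0.0284,0.0111,0.277
spleen,0.15,10.0,0.207,0.579,0.0201,0.0198,0.097
reproductive,0.04,1.7,0.400,0.400,0.0200,0.0100,0.100
rest,3.00,23.0,0.300,0.450,0.0500,0.0100,0.100
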