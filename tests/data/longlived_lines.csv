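line,pct_pooled,pct_male,pct_female,asp_pooled,asp_male,asp_female,sig_L,sig_LxS,sig_L_male,sig_L_female,category
BG00004,9.0,16.6,2.3,0.18,0.36,0.04,1,ns,2,ns,both sexes
BG00008,9.8,21.1,0.1,0.20,0.46,0.00,3,2,4,ns,male-specific
BG00010,14.4,22.1,8.0,0.29,0.48,0.15,4,ns,4,ns,both sexes
BG00028,12.1,27.8,-1.2,0.24,0.61,-0.02,4,4,4,ns,male-specific
BG00037,10.0,3.3,16.5,0.20,0.07,0.32,3,1,ns,4,female-specific
BG00039,8.0,-0.5,16.2,0.16,-0.01,0.31,1,2,ns,3,female-specific
BG00041,3.7,14.7,-5.8,0.07,0.32,-0.11,ns,2,3,ns,male-specific
BG00042,16.3,33.4,1.2,0.33,0.73,0.02,4,3,4,ns,male-specific
BG00043,21.4,27.2,16.7,0.43,0.60,0.32,4,ns,4,4,both sexes
BG00080,8.3,7.7,6.9,0.24,0.18,0.33,1,ns,ns,2,both sexes
BG00106,19.8,25.6,14.6,0.40,0.68,0.26,4,ns,4,1,both sexes
BG00121,3.7,9.3,-1.2,0.12,0.27,-0.05,1,2,2,ns,male-specific
BG00218,12.6,22.8,4.6,0.32,0.65,0.13,4,4,4,1,male-biased
BG00297,14.0,23.8,5.6,0.28,0.52,0.11,4,2,4,ns,male-specific
BG00336,14.6,18.6,11.0,0.42,0.44,0.54,4,ns,4,3,both sexes
BG00346,12.8,26.8,1.5,0.27,0.57,0.04,4,4,4,ns,male-specific
BG00472,9.7,18.0,2.4,0.19,0.40,0.05,2,1,4,ns,male-specific
BG00495,27.3,32.7,22.9,0.55,0.72,0.44,4,ns,4,4,both sexes
BG00528,11.1,0.6,22.8,0.24,0.01,0.63,4,3,ns,4,female-specific
BG00719,-0.7,5.5,-6.2,-0.02,0.16,-0.25,ns,2,1,1,sex-antagonistic
BG00757,10.2,26.8,-4.5,0.20,0.59,-0.09,2,4,4,ns,male-specific
BG00761,14.5,14.0,15.3,0.29,0.31,0.29,4,ns,2,4,both sexes
BG00767,13.9,5.8,22.6,0.30,0.13,0.62,4,2,1,4,female-biased
BG00817,5.1,12.7,-1.7,0.16,0.37,-0.07,1,2,3,ns,male-specific
BG00864,-1.3,-14.9,14.4,-0.03,-0.35,0.40,ns,4,4,2,sex-antagonistic
BG00890,10.4,19.1,3.0,0.21,0.42,0.06,2,1,3,ns,male-specific
BG00907,12.5,26.7,0.6,0.25,0.71,0.01,3,3,4,ns,male-specific
BG00915,16.1,26.0,7.4,0.32,0.57,0.14,4,1,4,ns,male-specific
BG01004,9.3,18.0,1.5,0.19,0.48,0.03,2,1,4,ns,male-specific
BG01030,3.0,5.3,27.7,0.08,0.15,0.64,4,4,ns,4,female-specific
BG01031,16.3,13.3,-8.4,0.35,0.34,-0.16,ns,2,2,ns,male-specific
BG01042,3.9,21.1,-9.8,0.10,0.55,-0.29,ns,4,4,2,sex-antagonistic
BG01085,11.7,20.1,4.1,0.24,0.53,0.07,2,1,4,ns,male-specific
BG01121,0.6,6.6,-5.0,0.02,0.23,-0.13,ns,1,2,ns,male-specific
BG01283,12.3,20.2,6.1,0.32,0.53,0.18,4,1,4,ns,male-specific
BG01345,21.3,21.5,21.0,0.45,0.55,0.38,4,ns,4,4,both sexes
BG01403,13.6,7.1,20.4,0.29,0.18,0.37,4,1,1,4,female-biased
BG01540,4.6,-5.3,13.4,0.14,-0.16,0.46,ns,4,ns,4,female-specific
BG01550,-3.0,6.2,-11.6,-0.09,0.21,-0.30,ns,2,1,m,sex-antagonistic
BG01551,5.2,10.0,0.6,0.15,0.35,0.01,1,ns,2,ns,both sexes
BG01553,8.9,16.7,3.0,0.23,0.44,0.09,3,1,4,ns,male-specific
BG01615,17.0,22.0,11.8,0.36,0.57,0.22,4,ns,4,1,both sexes
BG01677,19.4,16.9,21.9,0.41,0.44,0.40,4,ns,4,4,both sexes
BG01700,11.9,17.6,6.9,0.35,0.61,0.18,4,1,4,1,male-biased
BG01701,11.0,5.8,15.8,0.32,0.20,0.41,1,ns,1,m,both sexes
BG01702,1.0,8.2,-7.0,0.03,0.24,-0.17,ns,2,1,ns,male-specific
BG01710,5.3,3.2,7.2,0.14,0.09,0.17,1,ns,ns,1,both sexes
BG01878,8.3,-6.1,24.9,0.18,-0.14,0.69,3,4,ns,4,female-specific
BG01918,4.8,9.0,1.0,0.13,0.26,0.02,m,ns,1,ns,male-specific
BG01950,-13.1,-29.8,15.9,-0.29,-0.69,0.44,3,4,4,4,sex-antagonistic
BG01976,6.2,-9.2,24.0,0.13,-0.21,0.66,1,4,1,4,sex-antagonistic
BG02019,3.0,-6.7,14.0,0.07,-0.16,0.39,ns,4,ns,4,female-specific
BG02039,9.0,10.7,7.3,0.23,0.31,0.18,3,ns,2,ns,both sexes
BG02049,12.2,5.5,19.6,0.27,0.13,0.54,4,1,ns,4,female-specific
BG02128,5.0,-0.7,10.7,0.11,-0.02,0.30,ns,1,ns,3,female-specific
BG02257,8.9,10.3,7.4,0.25,0.30,0.20,4,ns,4,2,both sexes
BG02395,8.0,10.4,4.6,0.23,0.24,0.23,2,ns,1,ns,both sexes
BG02644,5.2,12.9,-1.5,0.15,0.30,-0.07,1,3,3,ns,male-specific
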