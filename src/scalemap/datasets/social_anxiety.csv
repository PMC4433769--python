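trial_id,arm_index,n_control,n_arm,instrument,mean_diff,se,pooled_sd,basis
Kasper2005,1,176,177,LSAS,-6.6,3.21,30.2,unknown
Asakura2007,1,89,176,LSAS,-7.2,3.07,16.9,unknown
Asakura2007,1,89,176,SDS,-1.2,0.72,5.42,unknown
Davidson2004,1,126,121,LSAS,-13.8,3.05,28.7,unknown
Davidson2004,1,126,121,CGI-S,-0.5,0.14,1.11,unknown
Davidson2004,1,126,121,SDS,-2.3,1.00,7.81,unknown
Westenberg2004,1,148,146,LSAS,-8.8,3.61,32.6,unknown
Westenberg2004,1,148,146,CGI-S,-0.5,0.14,1.21,unknown
Westenberg2004,1,148,146,SDS,-2.0,0.92,8.47,unknown
Liebowitz2005a,1,138,133,LSAS,-8.0,3.14,25.8,unknown
Liebowitz2005a,1,138,133,CGI-S,-0.4,0.14,1.16,unknown
Liebowitz2005a,1,138,133,SPIN,-3.1,1.65,13.62,unknown
Rickels2004,1,135,126,LSAS,-8.3,3.79,30.6,unknown
Rickels2004,1,135,126,CGI-S,-0.3,0.16,1.31,unknown
Rickels2004,1,135,126,SPIN,-4.7,1.97,15.9,unknown
Stein1998,1,92,90,LSAS,-21.4,2.75,18.6,unknown
Stein1998,1,92,90,SADS,-4.8,1.13,7.63,unknown
Stein1998,1,92,90,SDS,-2.6,0.66,4.47,unknown
Stein1999,1,44,42,LSAS,-14.2,4.56,22.8,unknown
Stein1999,1,44,42,BSPS,-7.2,2.63,13.6,unknown
Stein1999,1,44,42,SPIN,-6.7,3.31,15.39,unknown
Liebowitz2003,1,196,205,LSAS,-11.9,2.79,28.0,unknown
Liebowitz2003,1,196,205,CGI-S,-0.4,0.12,1.20,unknown
Liebowitz2003,1,196,205,BSPS,-5.2,1.45,14.5,unknown
Allgulander1999,1,48,44,LSAS,-24.8,4.78,28.7,unknown
Allgulander1999,1,48,44,BSPS,-11.4,2.68,12.5,unknown
Allgulander1999,1,48,44,FNE,-6.0,1.17,6.89,unknown
Kobak2002,1,30,30,LSAS,1.03,6.62,25.6,unknown
Kobak2002,1,30,30,BSPS,0.4,3.0,11.6,unknown
Kobak2002,1,30,30,FQ-SP,-0.54,2.01,7.78,unknown
Baldwin1999,1,151,139,LSAS,-9.3,3.96,33.1,unknown
Baldwin1999,1,151,139,CGI-S,-0.7,0.30,1.18,unknown
Baldwin1999,1,151,139,SADS,-3.3,1.41,8.25,unknown
Pfizer2007,1,78,74,LSAS,-12.6,4.24,16.1,unknown
Pfizer2007,1,78,74,CGI-S,-0.5,0.18,1.20,unknown
Pfizer2007,1,78,74,SDS,-2.3,1.13,7.82,unknown
Lepola2004,1,185,184,LSAS,-13.3,1.86,17.8,unknown
Lepola2004,1,185,184,CGI-S,-0.7,0.11,1.09,unknown
Lepola2004,1,185,184,SADS,-2.5,0.74,7.05,unknown
Lepola2004,1,185,184,SDS,-2.8,0.35,3.71,unknown
VanAmeringen2001,1,69,134,CGI-S,-0.69,0.13,0.85,unknown
VanAmeringen2001,1,69,134,BSPS,-7.81,1.85,12.50,unknown
VanAmeringen2001,1,69,134,FNE,-3.52,0.85,5.74,unknown
VanAmeringen2001,1,69,134,FQ-SP,-5.19,0.91,6.16,unknown
VanAmeringen2001,1,69,134,SADS,-3.26,0.88,5.95,unknown
VanAmeringen2001,1,69,134,SPAI-SP,-23.3,4.19,28.3,unknown
Stein2005,1,134,131,LSAS,-14.6,4.41,35.5,unknown
Stein2005,2,134,30,LSAS,-14.1,4.33,35.5,unknown
Liebowitz2005b,1,144,133,LSAS,-12.8,3.62,30.6,unknown
Liebowitz2005b,1,144,133,CGI-S,-0.56,0.10,0.83,unknown
Liebowitz2005b,2,144,136,LSAS,-17.0,3.57,30.6,unknown
Liebowitz2005b,2,144,136,CGI-S,-0.73,0.10,0.83,unknown
GSK2006,1,130,133,LSAS,-7.6,2.47,20.0,unknown
GSK2006,1,130,133,CGI-S,-0.2,0.10,0.87,unknown
GSK2006,2,130,136,LSAS,-6.1,2.46,20.0,unknown
GSK2006,2,130,136,CGI-S,-0.2,0.10,0.87,unknown
Allgulander2004,1,132,129,LSAS,-16.9,3.36,27.4,unknown
Allgulander2004,1,132,129,SPIN,-8.7,1.72,14.01,unknown
Allgulander2004,2,132,128,LSAS,-16.3,3.44,27.4,unknown
Allgulander2004,2,132,128,SPIN,-7.7,1.76,14.01,unknown
Davidson,1,36,39,CGI-S,-0.60,0.29,1.23,unknown
Davidson,1,36,39,BSPS,-5.9,3.09,13.1,unknown
Davidson,1,36,39,SPAI-SP,-25.5,7.57,32.5,unknown
Davidson,2,36,42,CGI-S,-0.60,0.29,1.23,unknown
Davidson,2,36,42,BSPS,-5.1,2.97,13.1,unknown
Davidson,2,36,42,SPAI-SP,-18.7,6.74,32.5,unknown
Blomhoff,1,92,98,CGI-S,-0.59,0.21,1.46,unknown
Blomhoff,1,92,98,BSPS,-4.99,1.37,9.38,unknown
Blomhoff,1,92,98,FNE,-2.11,1.37,8.42,unknown
Blomhoff,1,92,98,FQ-SP,-4.88,1.24,8.52,unknown
Blomhoff,1,92,98,SDS,-4.86,0.68,4.67,unknown
Blomhoff,2,92,95,CGI-S,-0.39,0.21,1.46,unknown
Blomhoff,2,92,95,BSPS,-2.32,1.36,9.38,unknown
Blomhoff,2,92,95,FNE,-0.93,1.23,8.42,unknown
Blomhoff,2,92,95,FQ-SP,-4.35,1.23,8.52,unknown
Blomhoff,2,92,95,SDS,-3.28,0.68,4.67,unknown
Liebowitz2002,1,95,97,LSAS,-9.9,4.38,30.2,unknown
Liebowitz2002,1,95,97,CGI-S,-0.5,0.18,1.23,unknown
Liebowitz2002,1,95,97,SADS,-2.2,1.28,8.80,unknown
Liebowitz2002,1,95,97,SDS,-1.2,0.71,4.85,unknown
Liebowitz2002,2,95,95,LSAS,-5.3,4.45,30.2,unknown
Liebowitz2002,2,95,95,CGI-S,-0.5,0.18,1.23,unknown
Liebowitz2002,2,95,95,SADS,-2.3,1.30,8.80,unknown
Liebowitz2002,2,95,95,SDS,-1.3,0.72,4.85,unknown
Liebowitz2002,3,95,97,LSAS,-6.6,4.41,30.2,unknown
Liebowitz2002,3,95,97,CGI-S,-0.5,0.18,1.23,unknown
Liebowitz2002,3,95,97,SADS,-2.7,1.29,8.80,unknown
Liebowitz2002,3,95,97,SDS,-1.4,0.71,4.85,unknown
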