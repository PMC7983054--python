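name,nu_00_cm,sigma2_00_gm,omega,omega_sd,gamma_deg,gamma_err_deg,dmu_d,delta_deg,beta_deg,eps_00
DsRed2,17857,55,0.674,0.002,9,1,3.96,-28,-19,103000
mCherry pH 11.4,17731,33,0.671,0.004,7,4,3.44,-32,-25,81000
mScarlet,17575,34,0.687,0.001,15,1,3.07,-38,-23,100000
XRFP (red-shifted),16821,,0.708,0.002,22,1,3.46,-44,-22,82000
XRFP (main),17483,41,0.667,0.002,0,2,3.61,-35,-35,82000
mPlum (red-shifted),16598,,0.727,0.004,26,1,2.87,-58,-32,65000
mPlum (main),17094,15,0.698,0.004,19,,2.76,-51,-32,65000
mCherry pH 7.4,17036,24,0.714,0.002,23,0.5,2.83,-51,-28,93000
eqFP670,16611,30,0.678,0.002,12,1,3.58,-45,-33,67000
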