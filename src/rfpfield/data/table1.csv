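name,lambda_abs_nm,eps_max,lambda_fl_nm,phi,tau_ns,kR_printed_ns,kNR_printed_ns,kNR_err_ns
DsRed2,558,103000,587,0.67,3.35,0.198,0.099,0.016
mScarlet,569,100000,595,0.70,3.78,0.186,0.079,0.013
mCherry pH 11.4,564,81000,602,0.48,2.85,0.170,0.182,0.020
mCherry pH 7.4,587,93000,611,0.22,1.53,0.144,0.510,0.051
mPlum,587,65000,645,0.147,1.09,0.135,0.780,0.078
XRFP,575,82000,650,0.31,1.79,0.170,0.385,0.039
eqFP670,602,67000,670,0.061,0.58,0.105,1.62,0.16
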