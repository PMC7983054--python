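name,dmu_x_d,dmu_y_d,ex_mvcm,ex_err,ey_mvcm,ey_err,quadrant
DsRed2,3.50,-1.85,9.9,0.4,57,2,IV
mCherry pH 11.4,2.89,-1.87,12.9,0.5,57,2,IV
mScarlet,2.41,-1.91,15.3,0.6,55,2,IV
XRFP (red-shifted),2.49,-2.40,14.9,0.6,33.5,1.3,IV
XRFP (main),2.97,-2.06,12.5,0.5,48.3,1.9,IV
mCherry pH 7.4,1.79,-2.20,18.3,0.7,42,1.7,IV
mPlum (red-shifted),1.52,-2.43,19.6,0.8,30.2,1.2,IV
mPlum (main),1.73,-2.15,18.6,0.7,44.3,1.8,IV
eqFP670 (IV),2.54,-2.52,14.3,0.6,28.3,1.1,IV
eqFP670 (II),-2.54,2.52,39.5,1.6,247,10,II
eqFP670 (III),-2.54,-2.52,39.5,1.6,28.3,1.1,III
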