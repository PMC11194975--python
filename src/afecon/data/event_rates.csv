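strategy,event,mean,ci_low,ci_high
apixaban,ischemic_stroke,0.950,0.719,1.212
apixaban,ich,0.348,0.199,0.538
apixaban,other_mb,1.898,1.085,2.935
apixaban,crnmb,2.083,1.191,3.221
apixaban,mi,0.530,0.303,0.820
apixaban,se,0.090,0.051,0.139
apixaban,cv_hosp,10.460,5.979,16.174
vka,ischemic_stroke,0.950,0.791,1.250
vka,ich,0.582,0.612,1.176
vka,other_mb,2.360,1.349,3.446
vka,crnmb,2.995,2.625,3.562
vka,mi,0.610,0.461,0.811
vka,se,0.100,0.057,0.155
vka,cv_hosp,10.460,5.979,16.174
rivaroxaban,ischemic_stroke,1.030,0.770,1.380
rivaroxaban,ich,1.730,1.080,2.770
rivaroxaban,other_mb,1.410,1.130,1.750
rivaroxaban,crnmb,1.520,1.280,10
rivaroxaban,mi,1.060,0.730,1.520
rivaroxaban,se,0.850,0.350,2.060
rivaroxaban,cv_hosp,1.000,0.900,1.100
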