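drug,model,volume_l,t_half_h,tmax_h,cmax_ng_ml,ref_dose_mg,ka_per_h,vm_ng_ml_h,km_ng_ml,interval_h,standard_dose_mg,citation
fluoxetine,mm,1033,48,7,35,40,0.53,6.5,448,24,40,"model constants fitted to adult single-dose observables (Cmax 35 ng/ml, Tmax 7 h, t1/2 48 h after 40 mg)"
sertraline,linear,1400,26,6.5,,,,,,24,51.0,"adult PK literature: V 1400 l, t1/2 26 h, Tmax 6.5 h"
citalopram,linear,840,35,4,,,,,,24,20.7,"adult PK literature: V 840 l, t1/2 35 h, Tmax 4 h"
venlafaxine,linear,426,16.9,8,,,,,,24,228.6,"combined venlafaxine + O-desmethylvenlafaxine moiety: V 426 l, t1/2 16.9 h, Tmax 8 h"
paroxetine,mm_observables,,16,6.3,17.6,30,,,,24,41.4,"adult single-dose observables after 30 mg; saturable clearance at therapeutic doses"
fluvoxamine,mm_observables,,19,6,30,50,,,,12,41.0,"adult single-dose observables after 50 mg; saturable clearance at therapeutic doses"
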