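drug,population,t_half_h,rr_sre,citation
fluoxetine,adult,96.0,0.92,"illustrative adult t1/2 (active moiety); RR from the 2004 FDA pediatric meta-analysis"
citalopram,adult,35.0,1.37,"illustrative adult t1/2; RR from the 2004 FDA pediatric meta-analysis"
sertraline,adult,26.0,1.48,"illustrative adult t1/2; RR from the 2004 FDA pediatric meta-analysis"
paroxetine,adult,21.0,2.15,"illustrative adult t1/2; RR from the 2004 FDA pediatric meta-analysis"
venlafaxine,adult,16.9,4.97,"illustrative adult t1/2 (with O-desmethylvenlafaxine); RR from the 2004 FDA pediatric meta-analysis"
fluvoxamine,adult,15.6,5.52,"illustrative adult t1/2; RR from the 2004 FDA pediatric meta-analysis"
fluoxetine,pediatric,96.0,0.92,"pediatric t1/2 taken equal to the adult value; RR from the 2004 FDA pediatric meta-analysis"
citalopram,pediatric,38.4,1.37,"illustrative pediatric t1/2; RR from the 2004 FDA pediatric meta-analysis"
sertraline,pediatric,27.1,1.48,"illustrative pediatric t1/2; RR from the 2004 FDA pediatric meta-analysis"
paroxetine,pediatric,11.1,2.15,"illustrative pediatric t1/2; RR from the 2004 FDA pediatric meta-analysis"
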