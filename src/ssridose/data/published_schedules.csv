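drug,day,dose_mg
fluoxetine,1,40.0
fluoxetine,2,40.0
fluoxetine,3,40.0
fluoxetine,4,40.0
fluoxetine,5,40.0
fluoxetine,6,40.0
fluoxetine,7,40.0
fluoxetine,8,40.0
fluoxetine,9,40.0
fluoxetine,10,40.0
fluoxetine,11,40.0
fluoxetine,12,40.0
fluoxetine,13,40.0
fluoxetine,14,40.0
fluoxetine,15,40.0
fluoxetine,16,40.0
fluoxetine,17,40.0
fluoxetine,18,40.0
fluoxetine,19,40.0
fluoxetine,20,40.0
fluoxetine,21,40.0
fluoxetine,22,40.0
fluoxetine,23,40.0
fluoxetine,24,40.0
fluoxetine,25,40.0
fluoxetine,26,40.0
fluoxetine,27,40.0
fluoxetine,28,40.0
fluoxetine,29,40.0
fluoxetine,30,40.0
paroxetine,1,19.2
paroxetine,2,24.6
paroxetine,3,28.8
paroxetine,4,31.8
paroxetine,5,33.6
paroxetine,6,35.4
paroxetine,7,36.0
paroxetine,8,37.8
paroxetine,9,37.8
paroxetine,10,39.0
paroxetine,11,39.0
paroxetine,12,39.6
paroxetine,13,39.6
paroxetine,14,40.2
paroxetine,15,40.2
paroxetine,16,40.2
paroxetine,17,40.8
paroxetine,18,40.8
paroxetine,19,40.8
paroxetine,20,40.8
paroxetine,21,40.8
paroxetine,22,40.8
paroxetine,23,41.4
paroxetine,24,40.8
paroxetine,25,40.8
paroxetine,26,41.4
paroxetine,27,40.8
paroxetine,28,41.4
paroxetine,29,40.8
paroxetine,30,41.4
citalopram,1,11.5
citalopram,2,13.4
citalopram,3,14.7
citalopram,4,15.7
citalopram,5,16.6
citalopram,6,17.4
citalopram,7,17.9
citalopram,8,18.5
citalopram,9,18.8
citalopram,10,19.2
citalopram,11,19.5
citalopram,12,19.6
citalopram,13,19.8
citalopram,14,20.0
citalopram,15,20.2
citalopram,16,20.3
citalopram,17,20.3
citalopram,18,20.4
citalopram,19,20.5
citalopram,20,20.4
citalopram,21,20.6
citalopram,22,20.6
citalopram,23,20.6
citalopram,24,20.7
citalopram,25,20.6
citalopram,26,20.7
citalopram,27,20.6
citalopram,28,20.8
citalopram,29,20.6
citalopram,30,20.7
sertraline,1,23.7
sertraline,2,28.9
sertraline,3,33.1
sertraline,4,36.4
sertraline,5,39.4
sertraline,6,41.3
sertraline,7,43.1
sertraline,8,44.6
sertraline,9,45.8
sertraline,10,46.9
sertraline,11,47.5
sertraline,12,48.3
sertraline,13,48.8
sertraline,14,49.1
sertraline,15,49.7
sertraline,16,49.8
sertraline,17,50.0
sertraline,18,50.3
sertraline,19,50.6
sertraline,20,50.6
sertraline,21,50.6
sertraline,22,50.7
sertraline,23,51.0
sertraline,24,50.8
sertraline,25,51.0
sertraline,26,51.1
sertraline,27,50.9
sertraline,28,51.2
sertraline,29,51.1
sertraline,30,51.0
venlafaxine,1,82.8
venlafaxine,2,111.2
venlafaxine,3,134.1
venlafaxine,4,152.6
venlafaxine,5,166.5
venlafaxine,6,178.2
venlafaxine,7,187.7
venlafaxine,8,195.3
venlafaxine,9,201.6
venlafaxine,10,206.1
venlafaxine,11,210.6
venlafaxine,12,213.8
venlafaxine,13,216.5
venlafaxine,14,218.7
venlafaxine,15,220.5
venlafaxine,16,222.3
venlafaxine,17,223.2
venlafaxine,18,224.1
venlafaxine,19,225.0
venlafaxine,20,225.9
venlafaxine,21,226.4
venlafaxine,22,226.8
venlafaxine,23,227.3
venlafaxine,24,227.3
venlafaxine,25,227.7
venlafaxine,26,228.2
venlafaxine,27,228.2
venlafaxine,28,228.2
venlafaxine,29,228.6
venlafaxine,30,228.6
fluvoxamine,1,20.5
fluvoxamine,2,21.0
fluvoxamine,3,25.0
fluvoxamine,4,29.0
fluvoxamine,5,31.0
fluvoxamine,6,33.0
fluvoxamine,7,34.0
fluvoxamine,8,36.0
fluvoxamine,9,37.0
fluvoxamine,10,37.0
fluvoxamine,11,38.0
fluvoxamine,12,39.0
fluvoxamine,13,39.0
fluvoxamine,14,40.0
fluvoxamine,15,40.0
fluvoxamine,16,40.0
fluvoxamine,17,41.0
fluvoxamine,18,40.0
fluvoxamine,19,41.0
fluvoxamine,20,41.0
fluvoxamine,21,41.0
fluvoxamine,22,41.0
fluvoxamine,23,41.0
fluvoxamine,24,41.0
fluvoxamine,25,41.0
fluvoxamine,26,41.0
fluvoxamine,27,41.0
fluvoxamine,28,41.0
fluvoxamine,29,41.0
fluvoxamine,30,41.0
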