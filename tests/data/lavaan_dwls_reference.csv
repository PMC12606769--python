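"seed","term","loading_std"
0,"fatigue",0.810188173623365
0,"general_pain",0.682630127700918
0,"decreased_appetite",0.610361082266623
0,"shortness_of_breath",0.64921735361196
0,"nausea",0.559960588832829
0,"sad",0.568912724938704
0,"constipation",0.50120082946902
0,"cough",0.482407265037911
1,"fatigue",0.80573757876757
1,"general_pain",0.67151865747268
1,"decreased_appetite",0.69377058558521
1,"shortness_of_breath",0.630630416563014
1,"nausea",0.546357746914649
1,"sad",0.645049400291216
1,"constipation",0.512260967315967
1,"cough",0.412111856417263
2,"fatigue",0.938715948120953
2,"general_pain",0.694693619581532
2,"decreased_appetite",0.64045584125926
2,"shortness_of_breath",0.609747906698597
2,"nausea",0.580668461279835
2,"sad",0.556210377474444
2,"constipation",0.429343401750441
2,"cough",0.492259034779888
3,"fatigue",0.846074283509624
3,"general_pain",0.730718716622583
3,"decreased_appetite",0.664164959174095
3,"shortness_of_breath",0.618460512864566
3,"nausea",0.589396932649365
3,"sad",0.593474312945031
3,"constipation",0.532317403440298
3,"cough",0.393454899794849
4,"fatigue",0.83668526318048
4,"general_pain",0.74782485675419
4,"decreased_appetite",0.6246772401014
4,"shortness_of_breath",0.557607395404437
4,"nausea",0.544138922886325
4,"sad",0.500292047747087
4,"constipation",0.547062061032245
4,"cough",0.417625332077574
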