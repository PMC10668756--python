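individual,trial,storage_months,viability
fem-3-1,trial-3,0,100
fem-4-1,trial-4,0,100
fem-1-4,trial-1,0,99
fem-1-2,trial-1,0,98
fem-1-3,trial-1,0,97
fem-1-1,trial-1,0,96
fem-4-2,trial-4,1.0,98
fem-6-2,trial-6,1.0,96
fem-6-1,trial-6,1.0,31
fem-5-1,trial-5,2.0,99
fem-6-3,trial-6,2.0,96
fem-4-3,trial-4,2.0,83
fem-6-5,trial-6,3.0,81
fem-6-6,trial-6,3.0,55
fem-6-4,trial-6,3.0,8
fem-3-2,trial-3,4.6,30
fem-3-3,trial-3,5.2,62
fem-3-4,trial-3,5.5,44
fem-3-5,trial-3,5.5,24
fem-3-6,trial-3,5.6,18
fem-4-4,trial-4,9.8,26
fem-2-1,trial-2,10.5,47
fem-2-2,trial-2,11.0,1
fem-3-7,trial-3,11.6,0
fem-2-3,trial-2,12.2,1
fem-2-4,trial-2,12.3,0
fem-5-2,trial-5,12.3,0
fem-1-5,trial-1,12.6,1
fem-5-3,trial-5,13.2,0
fem-2-5,trial-2,14.0,0
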