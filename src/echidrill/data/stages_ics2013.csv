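name,older_bound_ma,younger_bound_ma
Aalenian,174.1,170.3
Bajocian,170.3,168.3
Bathonian,168.3,166.1
Callovian,166.1,163.5
Oxfordian,163.5,157.3
Kimmeridgian,157.3,152.1
Tithonian,152.1,145.0
Berriasian,145.0,139.8
Valanginian,139.8,132.9
Hauterivian,132.9,129.4
Barremian,129.4,125.0
Aptian,125.0,113.0
Albian,113.0,100.5
Cenomanian,100.5,93.9
Turonian,93.9,89.8
Coniacian,89.8,86.3
Santonian,86.3,83.6
Campanian,83.6,72.1
Maastrichtian,72.1,66.0
Danian,66.0,61.6
Selandian,61.6,59.2
Thanetian,59.2,56.0
Ypresian,56.0,47.8
Lutetian,47.8,41.2
Bartonian,41.2,37.8
Priabonian,37.8,33.9
Rupelian,33.9,28.1
Chattian,28.1,23.03
Aquitanian,23.03,20.44
Burdigalian,20.44,15.97
Langhian,15.97,13.82
Serravallian,13.82,11.63
Tortonian,11.63,7.246
Messinian,7.246,5.333
Zanclean,5.333,3.6
Piacenzian,3.6,2.58
Gelasian,2.58,1.8
Calabrian,1.8,0.774
Chibanian,0.774,0.129
Upper Pleistocene,0.129,0.0117
Holocene,0.0117,0.0
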