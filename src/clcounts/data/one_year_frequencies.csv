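arm,declared_n,count_value,observed_pct
no_therapy,50,0,27.5
no_therapy,50,1,13.7
no_therapy,50,2,41.2
no_therapy,50,3,13.7
no_therapy,50,4,3.9
sc_ifn_beta1a,46,0,73.9
sc_ifn_beta1a,46,1,17.4
sc_ifn_beta1a,46,2,6.5
sc_ifn_beta1a,46,3,2.2
im_ifn_beta1a,47,0,38.0
im_ifn_beta1a,47,1,28.0
im_ifn_beta1a,47,2,20.0
im_ifn_beta1a,47,3,10.0
im_ifn_beta1a,47,4,4.0
ga,48,0,45.8
ga,48,1,33.3
ga,48,2,16.7
ga,48,3,4.2
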