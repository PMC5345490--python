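zone,size_class,event_index,start_month,end_month,pre_gsi,post_gsi,density
HP,US,1,2014-03,2014-05,4.4,1.3,2.7
HP,CS,1,2014-03,2014-05,6.6,1.6,0.6
LP,US,1,2013-06,2013-12,5.2,1.0,0.4
LP,US,2,2014-02,2014-05,4.0,1.2,0.4
LP,CS,1,2013-06,2013-12,6.7,2.5,2.7
LP,CS,2,2014-02,2014-04,5.4,2.5,2.7
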