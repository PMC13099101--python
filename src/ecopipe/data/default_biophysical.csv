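landuse_code,landuse_name,usle_c,usle_p,load_n,load_p,ndr_n,ndr_p,habitat_h,threat_weight,threat_decay
1,cropland,0.23,0.40,12.0,1.6,0.45,0.40,0.30,0.6,4.0
2,forestland,0.003,1.00,1.8,0.15,0.20,0.18,1.00,0.0,1.0
3,grassland,0.04,1.00,3.5,0.35,0.30,0.28,0.70,0.0,1.0
4,water,0.0,0.00,0.0,0.0,0.05,0.05,0.85,0.0,1.0
5,builtup,0.01,0.00,8.5,1.1,0.08,0.08,0.05,1.0,8.0
6,unused,0.35,1.00,2.0,0.22,0.35,0.32,0.35,0.0,1.0
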