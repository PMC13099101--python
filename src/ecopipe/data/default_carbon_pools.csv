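landuse_code,landuse_name,c_above,c_below,c_soil,c_dead
1,cropland,5.7,8.1,80.8,1.2
2,forestland,42.3,10.7,120.1,3.5
3,grassland,3.1,8.6,99.9,1.0
4,water,0.3,0.0,0.0,0.0
5,builtup,1.2,0.5,45.2,0.0
6,unused,0.9,0.2,38.4,0.1
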